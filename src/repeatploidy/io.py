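"""FASTA/FASTQ/BED/TSV input and output (Biopython-backed)."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import Genome, Read, ReadSet


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_fastq(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")}


def read_reads(path) -> dict:
    """Reads from FASTA or FASTQ, sniffed from the first character."""
    path = str(path)
    with open(path) as fh:
        first = fh.read(1)
    return read_fastq(path) if first == "@" else read_fasta(path)


def write_fasta(seqs: dict, path):
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(readset: ReadSet, path, quality: int = 40):
    """Sanger Phred+33 FASTQ; truth tags go into the description and are
    ignored by every analysis module."""
    with open(str(path), "w") as fh:
        for r in readset.reads:
            desc = " ".join(f"{k}={v}" for k, v in r.tags.items())
            fh.write(f"@{r.id} {desc}\n{r.seq}\n+\n{chr(33 + quality) * len(r.seq)}\n")


def load_readset(path, sample_id: str, mode: str = "long_single",
                 path2=None) -> ReadSet:
    """ReadSet from FASTA/FASTQ file(s); two files give an interleaved
    paired set (mates matched by order)."""
    d1 = read_reads(path)
    if path2 is None:
        reads = [Read(rid, seq, {}) for rid, seq in d1.items()]
        return ReadSet(sample_id, reads, mode)
    d2 = read_reads(path2)
    if len(d1) != len(d2):
        raise ValueError("unsynchronised mate files: read counts differ")
    reads = []
    for (id1, s1), (id2, s2) in zip(d1.items(), d2.items()):
        base = id1.rsplit("/", 1)[0]
        reads.append(Read(f"{base}/1", s1, {}))
        reads.append(Read(f"{base}/2", s2, {}))
    return ReadSet(sample_id, reads, "short_paired")


def write_bed(features, path):
    """Truth annotation as BED (0-based half-open)."""
    with open(str(path), "w") as fh:
        for f in features:
            name = f"{f.family}:{f.locus_id}:{f.unit_index}:c{f.cohort}"
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{name}\t0\t+\t{f.copy_class}\n")


def write_genome(genome: Genome, outdir, prefix: str | None = None):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or genome.sample_id
    write_fasta(genome.sequences, outdir / f"{prefix}.fasta")
    write_bed(genome.features, outdir / f"{prefix}.truth.bed")
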