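"""Genome-proportion estimation from read-mapping depth, and parental
additivity.

For each contig, mean read depth RD = (sum of aligned bases) / contig
length; genome representation GR = RD x contig length (i.e. exactly the
aligned bases); genome proportion GP = GR / dataset total bases x 100. A
cluster's GP is the sum of its contigs' GPs. In a symmetrical hybrid (both
progenitors of roughly equal genome size) the additive expectation for a
repeat's GP is the mean of the two parental GPs, and observed/expected
ratios well below 1 flag post-hybridisation sequence loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_EVEN

import numpy as np
import pandas as pd

from ._align import ReferenceIndex
from .cluster import Consensus

DETECTION_LIMIT = 0.01  # GP percent below which a value is below detection


@dataclass(frozen=True)
class MappingResult:
    read_id: str
    contig_id: str
    start: int  # 0-based half-open on the contig
    end: int
    identity: float
    strand: int


def map_reads(reads: dict, contigs, min_identity: float = 0.8,
              min_read_frac: float = 0.5, k: int = 11) -> list:
    """Map each read at most once to its best-scoring contig.

    A read maps iff its best alignment to any contig reaches
    ``min_identity`` over at least ``min_read_frac`` of the read length;
    among passing contigs the highest-scoring alignment (aligned matches)
    wins, ties going to the lowest contig id.
    """
    if isinstance(contigs, dict):
        seqs = dict(contigs)
        depth_rank = {cid: 0.0 for cid in seqs}
    else:
        seqs = {c.contig_id: c.sequence for c in contigs}
        depth_rank = {c.contig_id: float(c.depth.sum()) for c in contigs}
    if not seqs:
        raise ValueError("no contigs to map against")
    if not isinstance(reads, dict):
        items = list(reads)
        if len({rid for rid, _ in items}) != len(items):
            raise ValueError("duplicate read identifiers")
        reads = dict(items)
    ref = ReferenceIndex(seqs, k=k)
    results = []
    for rid in sorted(reads):
        seq = reads[rid]
        min_len = int(np.ceil(min_read_frac * len(seq)))
        cands = []
        for cid, hit in ref.best_hits(seq, min_identity, min_len).items():
            if hit.identity >= min_identity and hit.length >= min_len:
                # score ties (identical aligned matches) go to the deeper
                # (more abundant) contig, then to the lowest contig id
                cands.append((-round(hit.matches, 6), -depth_rank[cid], cid, hit))
        if cands:
            _, _, cid, hit = min(cands)
            results.append(MappingResult(rid, cid, hit.t_start, hit.t_end,
                                         hit.identity, hit.strand))
    return results


@dataclass
class GPTable:
    """Per-contig and per-cluster genome proportions for one sample."""

    contig_table: pd.DataFrame  # index contig_id: length, aligned_bases, rd, gr, gp
    cluster_table: pd.DataFrame | None
    dataset_total: int

    def contig_gp(self, contig_id: str) -> float:
        return float(self.contig_table.loc[contig_id, "gp"])

    def cluster_gp(self, cluster_id: str) -> float:
        return float(self.cluster_table.loc[cluster_id, "gp"])


def compute_gp(mappings: list, contigs, dataset_total: int,
               clusters=None) -> GPTable:
    """Genome-proportion table from mapping results.

    ``dataset_total`` is the sample's total sequenced bases (all reads,
    mapped or not). ``clusters`` optionally maps cluster ids to their member
    contigs so cluster GPs (sums over member contigs) are reported too.
    """
    if dataset_total <= 0:
        raise ValueError("dataset_total must be positive")
    if isinstance(contigs, dict):
        lengths = {cid: len(s) for cid, s in contigs.items()}
    else:
        lengths = {c.contig_id: c.length for c in contigs}
    for cid, L in lengths.items():
        if L == 0:
            raise ValueError(f"zero-length contig {cid}")
    aligned = {cid: 0 for cid in lengths}
    for m in mappings:
        aligned[m.contig_id] += m.end - m.start
    rows = []
    for cid in sorted(lengths):
        gr = float(aligned[cid])
        rd = gr / lengths[cid]
        rows.append((cid, lengths[cid], aligned[cid], rd, gr, gr / dataset_total * 100))
    contig_table = pd.DataFrame(
        rows, columns=["contig_id", "length", "aligned_bases", "rd", "gr", "gp"]
    ).set_index("contig_id")

    cluster_table = None
    if clusters is not None:
        if isinstance(clusters, dict):
            members = {k: [c.contig_id if isinstance(c, Consensus) else c for c in v]
                       for k, v in clusters.items()}
        else:
            members = {cl.cluster_id: [c.contig_id for c in cl.contigs]
                       for cl in clusters}
        crows = [
            (cl, float(contig_table.loc[[m for m in ms if m in contig_table.index],
                                        "gp"].sum()))
            for cl, ms in sorted(members.items())
        ]
        cluster_table = pd.DataFrame(crows, columns=["cluster_id", "gp"]).set_index(
            "cluster_id")
    return GPTable(contig_table, cluster_table, dataset_total)


def additivity(gp_maternal: float, gp_paternal: float,
               detection_limit: float = DETECTION_LIMIT) -> float:
    """Expected GP in a symmetrical allopolyploid: the mean of the parents.

    Below-detection parental values (< ``detection_limit``) count as zero,
    matching the reporting convention for values printed as "<0.01".
    """
    if gp_maternal < 0 or gp_paternal < 0:
        raise ValueError("genome proportions must be non-negative")
    gm = 0.0 if gp_maternal < detection_limit else gp_maternal
    gpat = 0.0 if gp_paternal < detection_limit else gp_paternal
    return (gm + gpat) / 2.0


def deficit(observed: float, expected: float):
    """Observed/expected GP ratio; values well below 1 flag under-
    representation. Undefined (None) when the expectation is zero."""
    if expected < 0 or observed < 0:
        raise ValueError("genome proportions must be non-negative")
    if expected == 0:
        return None
    return observed / expected


def format_gp(value) -> str:
    """Render a GP percent for reporting: 2 decimals (half-even), below-
    detection as "<0.01", missing as "NA"."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "NA"
    if value < DETECTION_LIMIT:
        return "<0.01"
    # settle binary-float residue (0.77499999...96 from (0.15+1.40)/2) before
    # the decimal half-even quantisation
    return str(Decimal(repr(round(float(value), 10))).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_EVEN))
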