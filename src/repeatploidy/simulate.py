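"""Synthetic allopolyploid genomes and reads with ground-truth annotation.

The generator emulates the study system the analysis targets: a paternal
diploid genome carrying a long-monomer (~2.2 kb) tandem satellite occupying
~1.6-1.9% of the genome, partially interspersed with a retroelement family;
a maternal diploid essentially lacking the satellite; and an allopolyploid
that unites both sub-genomes, optionally with a fraction of tandem satellite
units eliminated (unit-boundary-respecting deletions) and rounds of sequence
homogenisation (a donor unit overwriting recipient units within a locus).

Divergence cohorts are shared-mutation cohorts: each cohort derives once
from the family monomer at its substitution rate and all units of the cohort
are identical copies of that variant. Pairwise identities therefore cluster
at 1.0 (within cohort) and 1 - r (cohort r against the undiverged cohort),
the multi-peak signature of repeated amplification/homogenisation episodes.

Coordinates in truth annotations are 0-based half-open. Fixed seeds give
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace, asdict

import numpy as np


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC_TABLE = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _RC_TABLE[_a] = _b

TANDEM = "tandem"
DISPERSED = "dispersed"
RETRO = "retro"


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class RepeatFamilySpec:
    """A repeat family: a tandem satellite with optional dispersed copies and
    an optional interspersed retroelement partner.

    divergence_profile lists (fraction_of_units, substitution_rate) cohorts;
    fractions must sum to 1 and rates lie in [0, 1). ``dispersed_span``
    selects which slice of the monomer the dispersed copies carry (the
    dispersed component of real satellites is typically fragmentary).
    """

    name: str = "satellite"
    monomer_length: int = 2200
    tandem_units_per_locus: int = 4
    n_loci: int = 4
    dispersed_copies: int = 2
    divergence_profile: tuple = ((0.4, 0.0), (0.3, 0.05), (0.3, 0.10))
    retro_partner_length: int | None = 4800
    retro_copies: int = 3
    dispersed_span: tuple | None = (0, 500)
    # when set, the family's monomer and retro sequences are drawn from this
    # dedicated seed, so genomes sharing it carry the same ancestral family
    sequence_seed: int | None = None

    def validate(self):
        if self.monomer_length <= 0:
            raise ValueError("monomer_length must be positive")
        fracs = [f for f, _ in self.divergence_profile]
        rates = [r for _, r in self.divergence_profile]
        if any(r < 0 or r >= 1 for r in rates):
            raise ValueError("substitution rates must lie in [0, 1)")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("cohort fractions must sum to 1")
        if self.dispersed_span is not None:
            s, e = self.dispersed_span
            if not (0 <= s < e <= self.monomer_length):
                raise ValueError("dispersed_span must be a sub-interval of the monomer")

    @property
    def total_tandem_units(self) -> int:
        return self.n_loci * self.tandem_units_per_locus

    def repeat_bases(self) -> int:
        n = self.total_tandem_units * self.monomer_length
        if self.dispersed_copies:
            s, e = self.dispersed_span or (0, self.monomer_length)
            n += self.dispersed_copies * (e - s)
        if self.retro_partner_length:
            n += (self.retro_copies + self.dispersed_copies) * self.retro_partner_length
        return n


@dataclass(frozen=True)
class GenomeSpec:
    sample_id: str = "genome"
    genome_length: int = 2_000_000
    families: tuple = (RepeatFamilySpec(),)
    background_gc: float = 0.40
    seed: int = 0

    def validate(self):
        for fam in self.families:
            fam.validate()
        if sum(f.repeat_bases() for f in self.families) > self.genome_length:
            raise ValueError("repeat content exceeds genome_length")


@dataclass(frozen=True)
class AllopolyploidSpec:
    maternal: GenomeSpec = None
    paternal: GenomeSpec = None
    tandem_elimination_fraction: float = 0.0
    whole_locus_losses: int = 0
    homogenisation_sweeps: int = 0
    seed: int = 0
    sample_id: str = "allopolyploid"
    eliminate_dispersed: bool = False
    elimination_mode: str = "contiguous"  # or "scattered"
    sweep_recipients: int = 4

    def validate(self):
        if not (0.0 <= self.tandem_elimination_fraction <= 1.0):
            raise ValueError("tandem_elimination_fraction must lie in [0, 1]")
        if self.elimination_mode not in ("contiguous", "scattered"):
            raise ValueError("elimination_mode must be 'contiguous' or 'scattered'")


@dataclass(frozen=True)
class ReadSimParams:
    mode: str = "long_single"  # or "short_paired"
    read_length: int = 360
    insert_size_mean: int = 300
    insert_size_sd: int = 30
    coverage: float = 5.0
    error_rate: float = 0.0
    n_rate: float = 0.0
    seed: int = 0

    def validate(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.mode not in ("long_single", "short_paired"):
            raise ValueError("mode must be 'long_single' or 'short_paired'")
        if self.mode == "short_paired" and self.insert_size_mean < self.read_length:
            raise ValueError("insert size must be at least the read length")


# ---------------------------------------------------------------------------
# Genomes


@dataclass(frozen=True)
class Feature:
    """One truth-annotation interval (0-based half-open on its chromosome)."""

    chrom: str
    start: int
    end: int
    family: str
    copy_class: str  # tandem | dispersed | retro
    locus_id: str
    unit_index: int
    cohort: int


@dataclass
class Genome:
    sample_id: str
    sequences: dict
    features: list
    spec: object = None

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def family_bases(self, family: str, classes=(TANDEM, DISPERSED)) -> int:
        return sum(
            f.end - f.start
            for f in self.features
            if f.family == family and f.copy_class in classes
        )

    def tandem_units(self, family: str | None = None) -> list:
        return [
            f
            for f in self.features
            if f.copy_class == TANDEM and (family is None or f.family == family)
        ]


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.40) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = _BASES[rng.choice(4, size=length, p=p)]
    return arr.tobytes().decode()


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability ``rate``
    (always to a different base)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < rate
    idx = np.flatnonzero(mask)
    if idx.size:
        base_i = np.empty(idx.size, dtype=np.int64)
        for bi, b in enumerate(_BASES):
            base_i[arr[idx] == b] = bi
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(base_i + shift) % 4]
    return arr.tobytes().decode()


def _cohort_counts(fractions, total):
    """Largest-remainder apportionment of ``total`` units over cohorts."""
    raw = [f * total for f in fractions]
    counts = [int(x) for x in raw]
    rem = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def build_genome(spec: GenomeSpec) -> Genome:
    """Assemble one progenitor genome plus its truth annotation."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    inserts = []  # (sequence, list of (offset_in_insert, length, family, class, locus, unit, cohort))

    for fam in spec.families:
        seq_rng = (np.random.default_rng(fam.sequence_seed)
                   if fam.sequence_seed is not None else rng)
        monomer = _random_seq(seq_rng, fam.monomer_length, spec.background_gc)
        retro = (
            _random_seq(seq_rng, fam.retro_partner_length, spec.background_gc)
            if fam.retro_partner_length
            else None
        )
        variants = [mutate(monomer, rate, seq_rng) for _, rate in fam.divergence_profile]

        cohorts = []
        for ci, n in enumerate(
            _cohort_counts([f for f, _ in fam.divergence_profile], fam.total_tandem_units)
        ):
            cohorts.extend([ci] * n)
        cohorts = list(rng.permutation(cohorts)) if cohorts else []

        ui = 0
        for li in range(fam.n_loci):
            parts, ann, off = [], [], 0
            for u in range(fam.tandem_units_per_locus):
                ci = int(cohorts[ui])
                seq = variants[ci]
                ann.append((off, len(seq), fam.name, TANDEM, f"{fam.name}_L{li}", u, ci))
                parts.append(seq)
                off += len(seq)
                ui += 1
            inserts.append(("".join(parts), ann))

        span = fam.dispersed_span or (0, fam.monomer_length)
        for di in range(fam.dispersed_copies):
            ci = int(rng.choice(len(variants), p=[f for f, _ in fam.divergence_profile]))
            frag = variants[ci][span[0] : span[1]]
            parts, ann = [frag], [
                (0, len(frag), fam.name, DISPERSED, f"{fam.name}_D{di}", 0, ci)
            ]
            if retro is not None:
                # dispersed copies sit adjacent to a retroelement partner copy
                ann.append((len(frag), len(retro), fam.name, RETRO, f"{fam.name}_DR{di}", 0, 0))
                parts.append(retro)
            inserts.append(("".join(parts), ann))

        if retro is not None:
            for ri in range(fam.retro_copies):
                inserts.append(
                    (retro, [(0, len(retro), fam.name, RETRO, f"{fam.name}_R{ri}", 0, 0)])
                )

    total_insert = sum(len(s) for s, _ in inserts)
    bg_len = spec.genome_length - total_insert
    background = _random_seq(rng, bg_len, spec.background_gc)

    # splice inserts into the background at sorted, well-separated random points
    n = len(inserts)
    if n:
        min_gap = max(10, min(1000, bg_len // (2 * n + 2)))
        usable = bg_len - (n + 1) * min_gap
        if usable <= n:
            raise ValueError("genome too small to separate repeat insertions")
        cuts = np.sort(rng.choice(usable, size=n, replace=False))
        cuts = cuts + min_gap + np.arange(n) * min_gap
    else:
        cuts = np.array([], dtype=int)

    order = rng.permutation(n)
    pieces, features = [], []
    pos = 0  # position in final sequence
    prev_cut = 0
    for slot, cut in enumerate(cuts):
        pieces.append(background[prev_cut:cut])
        pos += cut - prev_cut
        seq, ann = inserts[order[slot]]
        for off, length, famname, cls, locus, unit, cohort in ann:
            features.append(
                Feature(spec.sample_id, pos + off, pos + off + length, famname, cls,
                        locus, unit, cohort)
            )
        pieces.append(seq)
        pos += len(seq)
        prev_cut = cut
    pieces.append(background[prev_cut:])
    sequence = "".join(pieces)
    assert len(sequence) == spec.genome_length
    features.sort(key=lambda f: f.start)
    return Genome(spec.sample_id, {spec.sample_id: sequence}, features, spec)


# ---------------------------------------------------------------------------
# Allopolyploid


def _delete_intervals(seq: str, features: list, intervals: list) -> tuple:
    """Excise sorted, disjoint [start, end) intervals; drop features inside
    them and shift the remainder."""
    if not intervals:
        return seq, features
    intervals = sorted(intervals)
    keep_parts, removed = [], set()
    prev = 0
    for s, e in intervals:
        keep_parts.append(seq[prev:s])
        prev = e
    keep_parts.append(seq[prev:])
    new_seq = "".join(keep_parts)

    starts = [s for s, _ in intervals]
    ends = [e for _, e in intervals]
    import bisect

    def shift(x):
        i = bisect.bisect_right(ends, x)
        return x - sum(e - s for s, e in intervals[:i])

    new_features = []
    for f in features:
        inside = any(s <= f.start and f.end <= e for s, e in intervals)
        if inside:
            continue
        new_features.append(replace(f, start=shift(f.start), end=shift(f.end)))
    return new_seq, new_features


def build_allopolyploid(spec: AllopolyploidSpec) -> Genome:
    """Union of both progenitor sub-genomes with tandem-unit elimination,
    whole-locus losses and homogenisation sweeps applied."""
    spec.validate()
    maternal = build_genome(spec.maternal)
    paternal = build_genome(spec.paternal)
    rng = np.random.default_rng(spec.seed)

    sequences, features = {}, []
    for parent in (maternal, paternal):
        chrom = parent.sample_id
        seq = parent.sequences[chrom]
        feats = list(parent.features)

        units = [f for f in feats if f.copy_class == TANDEM]
        if spec.eliminate_dispersed:
            units = units + [f for f in feats if f.copy_class == DISPERSED]
        loci: dict[str, list] = {}
        for f in units:
            loci.setdefault(f.locus_id, []).append(f)

        doomed = []
        # whole-locus losses first
        locus_ids = sorted(loci)
        n_lose = min(spec.whole_locus_losses, len(locus_ids))
        if n_lose:
            for lid in rng.choice(locus_ids, size=n_lose, replace=False):
                doomed.extend(loci.pop(lid))
        # then fractional elimination of the remaining units
        e = spec.tandem_elimination_fraction
        if e > 0:
            if spec.elimination_mode == "scattered":
                pool = [f for fs in loci.values() for f in fs]
                k = int(round(e * len(pool)))
                if k:
                    idx = rng.choice(len(pool), size=k, replace=False)
                    doomed.extend(pool[i] for i in idx)
            else:  # contiguous block per locus, from a random end
                # apportion the genome-wide elimination count over loci by
                # largest remainder so the realised fraction matches e even
                # when per-locus rounding would not
                locus_ids = sorted(loci)
                sizes = [len(loci[lid]) for lid in locus_ids]
                total = sum(sizes)
                if total:
                    k_total = int(round(e * total))
                    ks = _cohort_counts([s / total for s in sizes], k_total)
                    for lid, size, k in zip(locus_ids, sizes, ks):
                        k = min(k, size)
                        if not k:
                            continue
                        fs = sorted(loci[lid], key=lambda f: f.start)
                        doomed.extend(fs[:k] if rng.random() < 0.5 else fs[-k:])

        intervals = sorted((f.start, f.end) for f in doomed)
        seq, feats = _delete_intervals(seq, feats, intervals)

        # homogenisation sweeps: donor unit overwrites recipients in one locus
        seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        for _ in range(spec.homogenisation_sweeps):
            loci_now: dict[str, list] = {}
            for i, f in enumerate(feats):
                if f.copy_class == TANDEM:
                    loci_now.setdefault(f.locus_id, []).append(i)
            eligible = sorted(lid for lid, idx in loci_now.items() if len(idx) >= 2)
            if not eligible:
                break
            lid = eligible[int(rng.integers(len(eligible)))]
            idx = loci_now[lid]
            donor_i = idx[int(rng.integers(len(idx)))]
            others = [i for i in idx if i != donor_i]
            n_rec = min(spec.sweep_recipients, len(others))
            rec = rng.choice(others, size=n_rec, replace=False)
            donor = feats[donor_i]
            donor_seq = seq_arr[donor.start : donor.end]
            for i in rec:
                r = feats[i]
                if r.end - r.start == donor.end - donor.start:
                    seq_arr[r.start : r.end] = donor_seq
                    feats[i] = replace(r, cohort=donor.cohort)
        seq = seq_arr.tobytes().decode()

        sequences[chrom] = seq
        features.extend(replace(f, chrom=chrom) for f in feats)

    return Genome(spec.sample_id, sequences, features, spec)


# ---------------------------------------------------------------------------
# Reads


@dataclass(frozen=True)
class Read:
    id: str
    seq: str
    tags: dict


@dataclass
class ReadSet:
    """Simulated (or loaded) reads for one sample.

    ``total_bases`` is the denominator used for genome-proportion estimates:
    every base sequenced for the sample, mapped or not.
    """

    sample_id: str
    reads: list
    mode: str = "long_single"
    params: ReadSimParams | None = None

    @property
    def total_bases(self) -> int:
        return sum(len(r.seq) for r in self.reads)

    def as_dict(self) -> dict:
        return {r.id: r.seq for r in self.reads}

    def pairs(self):
        """Yield (pair_id, seq1, seq2) for paired-mode read sets."""
        if self.mode != "short_paired":
            raise ValueError("not a paired read set")
        for i in range(0, len(self.reads), 2):
            r1, r2 = self.reads[i], self.reads[i + 1]
            yield r1.id.rsplit("/", 1)[0], r1.seq, r2.seq


def _classify_interval(genome: Genome, chrom: str, start: int, end: int) -> tuple:
    best_cls, best_fam, best_ov = "background", "", 0
    for f in genome.features:
        if f.chrom != chrom or f.start >= end or f.end <= start:
            continue
        ov = min(end, f.end) - max(start, f.start)
        if ov > best_ov:
            best_ov, best_cls, best_fam = ov, f.copy_class, f.family
    if best_ov < (end - start) / 2:
        return "background", ""
    return best_cls, best_fam


def _apply_errors(arr: np.ndarray, rng: np.random.Generator, error_rate: float,
                  n_rate: float) -> np.ndarray:
    if error_rate > 0:
        mask = rng.random(arr.size) < error_rate
        idx = np.flatnonzero(mask)
        if idx.size:
            base_i = np.zeros(idx.size, dtype=np.int64)
            for bi, b in enumerate(_BASES):
                base_i[arr[idx] == b] = bi
            shift = rng.integers(1, 4, size=idx.size)
            arr[idx] = _BASES[(base_i + shift) % 4]
    if n_rate > 0:
        mask = rng.random(arr.size) < n_rate
        arr[mask] = ord("N")
    return arr


def simulate_reads(genome: Genome, params: ReadSimParams) -> ReadSet:
    """Uniform shotgun reads (single long or inward-facing paired short).

    The expected read count is coverage x genome_length / read_length with
    both mates counted; per-base substitution errors and N substitutions are
    i.i.d. Reads carry truth tags (source chromosome/position/strand and the
    majority copy class) in their tags dict; analysis modules ignore them.
    """
    params.validate()
    if genome.total_length == 0:
        raise ValueError("genome is empty")
    rng = np.random.default_rng(params.seed)
    chroms = sorted(genome.sequences)
    arrays = {c: np.frombuffer(genome.sequences[c].encode(), dtype=np.uint8)
              for c in chroms}
    lengths = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    reads = []

    def make_seq(chrom, start, length, strand):
        arr = arrays[chrom][start : start + length].copy()
        if strand < 0:
            arr = _RC_TABLE[arr][::-1]
        arr = _apply_errors(arr, rng, params.error_rate, params.n_rate)
        return arr.tobytes().decode()

    if params.mode == "long_single":
        n_reads = int(round(params.coverage * genome.total_length / params.read_length))
        which = rng.choice(len(chroms), size=n_reads, p=weights)
        for i in range(n_reads):
            chrom = chroms[which[i]]
            L = len(genome.sequences[chrom])
            rl = min(params.read_length, L)
            start = int(rng.integers(0, L - rl + 1))
            strand = 1 if rng.random() < 0.5 else -1
            cls, fam = _classify_interval(genome, chrom, start, start + rl)
            reads.append(Read(
                f"{genome.sample_id}_r{i}", make_seq(chrom, start, rl, strand),
                {"chrom": chrom, "start": start, "strand": strand,
                 "class": cls, "family": fam},
            ))
    else:
        n_pairs = int(round(params.coverage * genome.total_length /
                            (2 * params.read_length)))
        which = rng.choice(len(chroms), size=n_pairs, p=weights)
        for i in range(n_pairs):
            chrom = chroms[which[i]]
            L = len(genome.sequences[chrom])
            insert = int(round(rng.normal(params.insert_size_mean, params.insert_size_sd)))
            insert = max(params.read_length, min(insert, L))
            start = int(rng.integers(0, L - insert + 1))
            rl = params.read_length
            cls1, fam1 = _classify_interval(genome, chrom, start, start + rl)
            cls2, fam2 = _classify_interval(genome, chrom, start + insert - rl,
                                            start + insert)
            pid = f"{genome.sample_id}_p{i}"
            reads.append(Read(f"{pid}/1", make_seq(chrom, start, rl, 1),
                              {"chrom": chrom, "start": start, "strand": 1,
                               "class": cls1, "family": fam1}))
            reads.append(Read(f"{pid}/2",
                              make_seq(chrom, start + insert - rl, rl, -1),
                              {"chrom": chrom, "start": start + insert - rl,
                               "strand": -1, "class": cls2, "family": fam2}))
    return ReadSet(genome.sample_id, reads, params.mode, params)


# ---------------------------------------------------------------------------
# In-silico digest


def in_silico_digest(seq: str, recognition_site: str) -> list:
    """Fragment lengths from cutting at every occurrence of the site.

    Cuts fall at the start of each site occurrence; zero-length fragments are
    dropped. A sequence without the site yields one full-length fragment. A
    perfect head-to-tail array with one site per monomer collapses to a
    single band at the monomer length — the classic satellite ladder logic.
    """
    if len(recognition_site) < 4:
        raise ValueError("recognition site must be at least 4 bp")
    cuts, i = [], seq.find(recognition_site)
    while i != -1:
        cuts.append(i)
        i = seq.find(recognition_site, i + 1)
    bounds = [0] + cuts + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:]) if b - a > 0]


# ---------------------------------------------------------------------------
# Study-condition trio


def default_trio(seed: int = 0, genome_length: int = 2_000_000,
                 tandem_elimination_fraction: float = 0.9,
                 homogenisation_sweeps: int = 2,
                 whole_locus_losses: int = 0,
                 monomer_length: int = 2200) -> tuple:
    """Specs for the study conditions: a paternal genome with the satellite
    at ~1.76% plus its retroelement partner, a maternal genome carrying only
    the retroelement family, and the allopolyploid union.

    Scaled to desk size (default 2 Mb per sub-genome) with repeat fractions
    preserved, so the genome-proportion arithmetic matches the full-scale
    system. Seeds for the three genomes are derived deterministically.
    """
    ss = np.random.SeedSequence(seed)
    s_m, s_p, s_a, s_fam = (int(x) for x in ss.generate_state(4) % (2**31))
    scale = genome_length / 2_000_000
    units = max(2, int(round(4 * np.sqrt(scale))))
    loci = max(2, int(round(4 * np.sqrt(scale))))
    # dispersed copies are short monomer fragments: long enough for
    # paired-end mates to detect, shorter than the long-read clustering
    # overlap so junction reads cannot chain the satellite into its
    # retroelement partner's cluster
    satellite = RepeatFamilySpec(
        name="satellite", monomer_length=monomer_length,
        tandem_units_per_locus=units, n_loci=loci,
        dispersed_copies=max(2, int(round(4 * scale))),
        retro_partner_length=4800, retro_copies=max(1, int(round(3 * scale))),
        dispersed_span=(0, min(150, monomer_length)), sequence_seed=s_fam,
    )
    maternal_retro = RepeatFamilySpec(
        name="satellite", monomer_length=monomer_length,
        tandem_units_per_locus=0, n_loci=0, dispersed_copies=0,
        divergence_profile=((1.0, 0.0),), dispersed_span=None,
        retro_partner_length=4800, retro_copies=max(1, int(round(2 * scale))),
        sequence_seed=s_fam,
    )
    maternal = GenomeSpec("maternal", genome_length, (maternal_retro,), 0.40, s_m)
    paternal = GenomeSpec("paternal", genome_length, (satellite,), 0.40, s_p)
    allo = AllopolyploidSpec(
        maternal=maternal, paternal=paternal,
        tandem_elimination_fraction=tandem_elimination_fraction,
        whole_locus_losses=whole_locus_losses,
        homogenisation_sweeps=homogenisation_sweeps, seed=s_a,
    )
    return maternal, paternal, allo


def spec_to_json(spec) -> str:
    return json.dumps(asdict(spec), indent=2, default=str)
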