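"""Paired-end classification of repeat reads into dual vs solo HSPs.

For a target repeat contig, a read pair with both mates matching the target
is a dual HSP; a pair with exactly one matching mate is a solo HSP — its
partner lies in some other sequence, so solo HSPs mark junctions between
the repeat and whatever abuts or interrupts it. Provisional solos whose
partner matches another contig of the same cluster are reassigned as dual.
The positional profile of solo proportion along the monomer shows where the
dispersed component truncates or interrupts the repeat; a rise in the
overall solo fraction in the allopolyploid relative to its progenitor
indicates preferential loss of the tandem component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import ReferenceIndex
from .cluster import Consensus


@dataclass
class PairRecord:
    pair_id: str
    read1: str
    read2: str
    qc_pass: bool = True
    hit1: tuple | None = None  # (contig_id, start, end, identity)
    hit2: tuple | None = None


def qc_filter(pairs, min_length: int = 95, max_n: int = 5,
              trim_to: int = 95) -> list:
    """Quality screen for read pairs.

    A pair passes iff both mates are at least ``min_length`` bp with no more
    than ``max_n`` unidentified nucleotides; passing mates are trimmed to
    their first ``trim_to`` bases. Failing either mate removes the whole
    pair (qc_pass False, excluded from all downstream counts).
    """
    out = []
    for pair_id, r1, r2 in pairs:
        ok = (len(r1) >= min_length and len(r2) >= min_length
              and r1.upper().count("N") <= max_n and r2.upper().count("N") <= max_n)
        if ok:
            out.append(PairRecord(pair_id, r1[:trim_to], r2[:trim_to], True))
        else:
            out.append(PairRecord(pair_id, r1, r2, False))
    return out


@dataclass
class MateHit:
    pair_id: str
    mate: int  # 1 or 2
    t_start: int
    t_end: int
    solo: bool


@dataclass
class PairClassification:
    n_dual: int = 0
    n_solo: int = 0
    n_reassigned: int = 0
    target_id: str = ""
    thresholds: tuple = (0.90, 0.55)
    mate_hits: list = field(default_factory=list)

    @property
    def solo_fraction(self) -> float:
        denom = self.n_solo + self.n_dual
        return self.n_solo / denom if denom else 0.0


def classify_pairs(pairs, target, cluster_contigs=(), min_identity: float = 0.90,
                   min_read_frac: float = 0.55, k: int = 11) -> PairClassification:
    """Classify QC-passed pairs against the target contig.

    Both mates hit the target -> dual. Exactly one mate hits -> provisional
    solo; if the partner hits any other contig of the same cluster the pair
    is reassigned to dual. Pairs with no target hit are excluded from the
    denominator. Mates hitting the target on both strands or different
    monomer copies are still dual (no distance check).
    """
    if isinstance(target, Consensus):
        target_id, target_seq = target.contig_id, target.sequence
    else:
        target_id, target_seq = target
    if not target_seq:
        raise ValueError("empty target")
    tref = ReferenceIndex({target_id: target_seq}, k=k)
    others = {}
    for c in cluster_contigs:
        cid, seq = (c.contig_id, c.sequence) if isinstance(c, Consensus) else c
        if cid != target_id:
            others[cid] = seq
    oref = ReferenceIndex(others, k=k) if others else None

    def target_hit(read):
        min_len = int(np.ceil(min_read_frac * len(read)))
        hit = tref.best_hits(read, min_identity, min_len).get(target_id)
        if hit is None or hit.identity < min_identity or hit.length < min_len:
            return None
        return hit

    def other_hit(read):
        if oref is None:
            return False
        min_len = int(np.ceil(min_read_frac * len(read)))
        for cid, hit in oref.best_hits(read, min_identity, min_len).items():
            if hit.identity >= min_identity and hit.length >= min_len:
                return True
        return False

    cls = PairClassification(target_id=target_id,
                             thresholds=(min_identity, min_read_frac))
    for p in pairs:
        if not p.qc_pass:
            continue
        h1, h2 = target_hit(p.read1), target_hit(p.read2)
        if h1 is None and h2 is None:
            continue
        if h1 is not None and h2 is not None:
            cls.n_dual += 1
            solo = False
        else:
            partner = p.read2 if h1 is not None else p.read1
            if other_hit(partner):
                cls.n_dual += 1
                cls.n_reassigned += 1
                solo = False
            else:
                cls.n_solo += 1
                solo = True
        for mate, h in ((1, h1), (2, h2)):
            if h is not None:
                cls.mate_hits.append(MateHit(p.pair_id, mate, h.t_start, h.t_end, solo))
    return cls


@dataclass
class SoloProfile:
    monomer_length: int
    solo_coverage: np.ndarray
    total_coverage: np.ndarray

    @property
    def proportion(self) -> np.ndarray:
        """Per-position solo/(solo+dual) mate coverage; NaN where uncovered."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total_coverage > 0,
                            self.solo_coverage / np.maximum(self.total_coverage, 1),
                            np.nan)


def solo_profile(classification: PairClassification, monomer_start: int,
                 monomer_length: int) -> SoloProfile:
    """Fold target-hitting mate intervals onto the monomer and profile the
    per-position solo proportion.

    Contig coordinates are folded as (pos - monomer_start) mod monomer
    length, so the partial second monomer a tandem contig carries contributes
    to the same monomer positions as the first.
    """
    if monomer_length <= 0:
        raise ValueError("monomer_length must be positive")
    solo_cov = np.zeros(monomer_length)
    total_cov = np.zeros(monomer_length)
    for h in classification.mate_hits:
        pos = (np.arange(h.t_start, h.t_end) - monomer_start) % monomer_length
        np.add.at(total_cov, pos, 1)
        if h.solo:
            np.add.at(solo_cov, pos, 1)
    return SoloProfile(monomer_length, solo_cov, total_cov)


def compare_solo_fractions(a: PairClassification, b: PairClassification) -> tuple:
    """Solo fractions of two samples and their difference (b - a).

    Refuses to compare classifications computed under different thresholds.
    """
    if a.thresholds != b.thresholds:
        raise ValueError("classifications were computed with different thresholds")
    return a.solo_fraction, b.solo_fraction, b.solo_fraction - a.solo_fraction
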