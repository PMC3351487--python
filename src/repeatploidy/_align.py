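"""Seed-and-extend pairwise alignment engine.

All similarity decisions in this package (read clustering, read-to-contig
mapping, pair classification, all-vs-all family similarity) go through the
same contract: the best local alignment between two sequences, on either
strand, reported as an identity fraction over an aligned span.

The engine seeds candidate alignments with shared k-mers, picks the best
diagonal band, and scores candidate windows with edlib edit distance.
Identity is defined as matching columns / alignment columns, with gaps
counted as mismatches.
"""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import edlib

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC N preserved)."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class LocalHit:
    """Best local alignment of a query against a target.

    ``q_start``/``q_end`` index into the *oriented* query, i.e. into
    ``revcomp(query)`` when ``strand == -1``. ``t_start``/``t_end`` are
    0-based half-open coordinates on the target.
    """

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    identity: float
    strand: int  # +1 or -1

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    @property
    def matches(self) -> float:
        return self.identity * self.length

    def oriented_query(self, query: str) -> str:
        return query if self.strand == 1 else revcomp(query)


class KmerIndex:
    """Exact k-mer position index of a single target sequence."""

    __slots__ = ("seq", "k", "index")

    def __init__(self, seq: str, k: int = 13):
        if k < 4:
            raise ValueError("k-mer size must be >= 4")
        self.seq = seq
        self.k = k
        index: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            index.setdefault(km, []).append(i)
        self.index = index


def _window_identity(q: str, t: str, q0: int, q1: int, diag: int):
    """Clip window (q0,q1) on the given diagonal to both sequences and score it."""
    # shift so that both windows lie inside their sequences
    q0 = max(q0, 0, -diag)
    q1 = min(q1, len(q), len(t) - diag)
    if q1 - q0 <= 0:
        return None
    a = q[q0:q1]
    b = t[q0 + diag : q1 + diag]
    res = edlib.align(a, b, mode="NW", task="distance")
    cols = max(len(a), len(b))
    identity = 1.0 - res["editDistance"] / cols
    return (q0, q1, identity)


def _best_on_strand(q: str, index: KmerIndex, min_identity: float, min_length: int,
                    band: int = 3, max_bands: int = 3):
    k = index.k
    idx = index.index
    t = index.seq
    diag_hits: dict[int, list[int]] = {}
    for i in range(len(q) - k + 1):
        km = q[i : i + k]
        positions = idx.get(km)
        if not positions:
            continue
        for tp in positions:
            diag_hits.setdefault(tp - i, []).append(i)
    if not diag_hits:
        return None
    counts = {d: len(v) for d, v in diag_hits.items()}
    band_count = {
        d: sum(counts.get(d + o, 0) for o in range(-band, band + 1)) for d in counts
    }
    # evaluate the few best-seeded, well-separated diagonal bands: for a
    # tandem target the same query seeds several diagonals one period apart,
    # and the most-seeded one is not always the best-scoring alignment
    # (e.g. a clipped same-cohort window at a contig end can out-seed the
    # full-length cross-cohort diagonal)
    chosen: list[int] = []
    for d in sorted(counts, key=lambda d: (-band_count[d], abs(d), d)):
        if all(abs(d - c) > 2 * band for c in chosen):
            chosen.append(d)
            if len(chosen) == max_bands:
                break

    windows = []
    for d in chosen:
        qpos = []
        for o in range(-band, band + 1):
            qpos.extend(diag_hits.get(d + o, ()))
        qs, qe = min(qpos), max(qpos) + k
        for w in (_window_identity(q, t, qs, qe, d),
                  _window_identity(q, t, 0, len(q), d)):
            if w is not None:
                windows.append((w[0], w[1], w[2], d))
    if not windows:
        return None

    def passing(w):
        return w[2] >= min_identity and (w[1] - w[0]) >= min_length

    ok = [w for w in windows if passing(w)]
    pool = ok if ok else windows
    q0, q1, ident, d = max(pool, key=lambda w: ((w[1] - w[0]) * w[2], w[2], -abs(w[3])))
    return (q0, q1, q0 + d, q1 + d, ident)


def best_local_alignment(query: str, index: KmerIndex, min_identity: float = 0.0,
                         min_length: int = 0) -> LocalHit | None:
    """Best seeded local alignment of ``query`` against the indexed target.

    Both strands are tried; among windows meeting ``min_identity`` /
    ``min_length`` the longest (then highest-identity) wins, falling back to
    the highest-scoring sub-threshold window so callers can inspect near
    misses. Returns None when the pair shares no k-mer seed.
    """
    cands = []
    fwd = _best_on_strand(query, index, min_identity, min_length)
    if fwd is not None:
        cands.append((fwd, 1))
    rev = _best_on_strand(revcomp(query), index, min_identity, min_length)
    if rev is not None:
        cands.append((rev, -1))
    if not cands:
        return None

    def key(c):
        (q0, q1, t0, t1, ident), _ = c
        length = q1 - q0
        ok = ident >= min_identity and length >= min_length
        return (ok, length * ident, ident, -abs(t0 - q0))

    (q0, q1, t0, t1, ident), strand = max(cands, key=key)
    return LocalHit(q0, q1, t0, t1, ident, strand)


def _canonical(km: str) -> str:
    rc = revcomp(km)
    return km if km <= rc else rc


def candidate_pairs(seqs: dict[str, str], k: int = 13, sample_rate: int = 4,
                    min_shared: int = 2, max_neighbors: int | None = None):
    """Candidate read pairs sharing sampled canonical k-mers.

    Deterministic subsampling (CRC32 of the canonical k-mer) keeps the
    all-vs-all candidate search near-linear in dataset size; unrelated
    random-sequence reads essentially never share a sampled k-mer.
    ``max_neighbors`` optionally keeps, per read, only the highest-sharing
    partners — a performance valve for very deep tandem families where the
    full candidate set is quadratic (connected components are unaffected).
    Returns a list of ((id_a, id_b), shared_count) with id_a < id_b.
    """
    buckets: dict[str, list[str]] = {}
    for rid in sorted(seqs):
        s = seqs[rid]
        seen: set[str] = set()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if "N" in km:
                continue
            ckm = _canonical(km)
            if sample_rate > 1 and zlib.crc32(ckm.encode()) % sample_rate:
                continue
            if ckm not in seen:
                seen.add(ckm)
                buckets.setdefault(ckm, []).append(rid)
    pair_counts: Counter = Counter()
    for members in buckets.values():
        if len(members) < 2:
            continue
        for a, b in combinations(members, 2):
            pair_counts[(a, b) if a < b else (b, a)] += 1
    pairs = [(p, c) for p, c in sorted(pair_counts.items()) if c >= min_shared]
    if max_neighbors is not None:
        per_read: dict[str, list] = {}
        for (a, b), c in pairs:
            per_read.setdefault(a, []).append((c, b))
            per_read.setdefault(b, []).append((c, a))
        keep = set()
        for rid, partners in per_read.items():
            partners.sort(key=lambda x: (-x[0], x[1]))
            for c, other in partners[:max_neighbors]:
                keep.add((rid, other) if rid < other else (other, rid))
        pairs = [(p, c) for p, c in pairs if p in keep]
    return pairs


class ReferenceIndex:
    """Shared k-mer index over a set of reference contigs.

    Used for mapping many reads against few references: a cheap shared-k-mer
    screen selects candidate contigs, then the full seed-and-extend alignment
    runs only against those.
    """

    def __init__(self, contigs: dict[str, str], k: int = 11):
        self.k = k
        self.contigs = dict(contigs)
        self.indexes = {cid: KmerIndex(seq, k) for cid, seq in contigs.items()}
        global_map: dict[str, set[str]] = {}
        for cid, idx in self.indexes.items():
            for km in idx.index:
                # index both strands so minus-strand reads hit on their own k-mers
                global_map.setdefault(km, set()).add(cid)
                global_map.setdefault(revcomp(km), set()).add(cid)
        self.global_map = global_map

    def candidate_contigs(self, read: str, min_hits: int = 2,
                          scan_stride: int = 4) -> list[str]:
        """Contigs sharing k-mers with the read.

        A strided pre-scan rejects the (typically overwhelming) majority of
        unrelated reads cheaply; reads with any strided hit get a full scan,
        so genuinely matching reads always reach the alignment stage.
        """
        k = self.k
        gmap = self.global_map
        if scan_stride > 1:
            if not any(read[i : i + k] in gmap
                       for i in range(0, len(read) - k + 1, scan_stride)):
                return []
        counts: Counter = Counter()
        for i in range(len(read) - k + 1):
            hit = gmap.get(read[i : i + k])
            if hit:
                counts.update(hit)
        return sorted([c for c, n in counts.items() if n >= min_hits])

    def best_hits(self, read: str, min_identity: float = 0.0, min_length: int = 0,
                  min_seed_hits: int = 2) -> dict[str, LocalHit]:
        hits = {}
        for cid in self.candidate_contigs(read, min_seed_hits):
            h = best_local_alignment(read, self.indexes[cid], min_identity, min_length)
            if h is not None:
                hits[cid] = h
        return hits
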