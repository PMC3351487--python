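"""Graph-based identification of repeat families from unassembled reads.

Reads are nodes; an edge joins two reads whose best local alignment (either
strand) reaches an identity threshold over a minimum overlap. Connected
components of this mutual-similarity graph are repeat families; each family
is assembled into consensus contigs by greedy overlap layout, and a tandem
satellite's monomer is recovered from the terminal direct repeat its contig
carries (a contig assembled across a head-to-tail junction contains one full
monomer plus the start of the next).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._align import KmerIndex, best_local_alignment, candidate_pairs

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class Consensus:
    """Assembled contig: majority-vote sequence plus per-position read depth."""

    contig_id: str
    sequence: str
    depth: np.ndarray
    monomer: tuple | None = None  # (start, length)

    def __post_init__(self):
        if len(self.depth) != len(self.sequence):
            raise ValueError("depth array must match sequence length")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class RepeatCluster:
    cluster_id: str
    reads: list
    contigs: list = field(default_factory=list)
    merged_from: list = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.reads)


def build_graph(reads: dict, min_identity: float = 0.9, min_overlap: int = 50,
                k: int = 13, sample_rate: int = 4, min_shared: int = 2,
                max_neighbors: int | None = None) -> nx.Graph:
    """Mutual-similarity graph over reads.

    An edge (a, b) is present iff the best local alignment between the two
    reads (either strand) has identity >= ``min_identity`` over at least
    ``min_overlap`` aligned bases, within the sensitivity of the shared
    k-mer candidate screen. Edges carry ``identity`` and ``length``.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(reads))
    indexes: dict[str, KmerIndex] = {}
    for (a, b), _count in candidate_pairs(reads, k=k, sample_rate=sample_rate,
                                          min_shared=min_shared,
                                          max_neighbors=max_neighbors):
        idx = indexes.get(b)
        if idx is None:
            idx = indexes[b] = KmerIndex(reads[b], k)
        hit = best_local_alignment(reads[a], idx, min_identity, min_overlap)
        if hit is not None and hit.identity >= min_identity and hit.length >= min_overlap:
            g.add_edge(a, b, identity=hit.identity, length=hit.length)
    return g


def cluster_graph(graph: nx.Graph) -> list:
    """Connected components as clusters, largest first, named CL1, CL2, ...

    Singleton nodes are excluded (they remain part of the dataset total used
    downstream for genome-proportion denominators, just not of any family).
    """
    comps = [sorted(c) for c in nx.connected_components(graph) if len(c) > 1]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return [RepeatCluster(f"CL{i + 1}", c) for i, c in enumerate(comps)]


@dataclass(frozen=True)
class MergeEvidence:
    """Evidence for merging two clusters: read pairs spanning them and/or
    consensus-to-consensus similarity."""

    spanning_pairs: int = 0
    consensus_identity: float = 0.0
    consensus_overlap: int = 0


def merge_clusters(a: RepeatCluster, b: RepeatCluster, evidence: MergeEvidence,
                   min_spanning_pairs: int = 20, min_consensus_identity: float = 0.8,
                   min_consensus_overlap: int = 200):
    """Merge two clusters when the evidence threshold is met.

    Returns the merged cluster (id "CLx/y", provenance in ``merged_from``),
    the cluster itself for a self-merge, or None when evidence is
    insufficient (callers keep the originals).
    """
    if a is b or a.cluster_id == b.cluster_id:
        return a
    by_pairs = evidence.spanning_pairs >= min_spanning_pairs
    by_consensus = (evidence.consensus_identity >= min_consensus_identity
                    and evidence.consensus_overlap >= min_consensus_overlap)
    if not (by_pairs or by_consensus):
        return None
    merged_id = f"{a.cluster_id}/{b.cluster_id[2:]}"
    return RepeatCluster(
        merged_id,
        sorted(set(a.reads) | set(b.reads)),
        contigs=list(a.contigs) + list(b.contigs),
        merged_from=[a.cluster_id, b.cluster_id],
    )


def consensus_similarity(a: Consensus, b: Consensus, k: int = 13) -> MergeEvidence:
    """Consensus-vs-consensus similarity evidence for cluster merging."""
    hit = best_local_alignment(a.sequence, KmerIndex(b.sequence, k))
    if hit is None:
        return MergeEvidence()
    return MergeEvidence(consensus_identity=hit.identity, consensus_overlap=hit.length)


def _rebuild_consensus(placements: list) -> tuple:
    """Majority-vote consensus over placed oriented reads.

    Ties break lexicographically (A < C < G < T); uncovered columns become N
    (they do not arise for contiguously tiled layouts).
    """
    length = max(off + len(s) for s, off in placements)
    counts = np.zeros((4, length), dtype=np.int32)
    for s, off in placements:
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        for bi, base in enumerate(_BASE_BYTES):
            counts[bi, off : off + len(s)] += arr == base
    depth = counts.sum(axis=0)
    call = counts.argmax(axis=0)  # argmax returns the first (lexicographic) max
    seq_arr = _BASE_BYTES[call].copy()
    seq_arr[depth == 0] = ord("N")
    return seq_arr.tobytes().decode(), depth


def assemble_contigs(cluster: RepeatCluster, reads: dict, min_identity: float = 0.9,
                     min_overlap: int = 40, k: int = 13,
                     max_rounds: int = 60) -> list:
    """Greedy overlap-layout-consensus assembly of a cluster's reads.

    Seeds a contig with the longest unplaced read, then repeatedly aligns the
    remaining reads to the evolving consensus and stacks every read that
    passes the overlap contract at its best offset. Reads that never attach
    seed further contigs, so irreconcilable overlaps yield multiple contigs
    rather than a failure. Contigs are ordered by total mapped depth.
    """
    remaining = set(cluster.reads)
    raw = []
    while remaining:
        seed = max(remaining, key=lambda r: (len(reads[r]), r))
        remaining.discard(seed)
        placements = [(reads[seed], 0)]
        consensus, depth = reads[seed], np.ones(len(reads[seed]), dtype=np.int32)
        for _ in range(max_rounds):
            if not remaining:
                break
            idx = KmerIndex(consensus, k)
            placed_now = []
            for rid in sorted(remaining):
                hit = best_local_alignment(reads[rid], idx, min_identity, min_overlap)
                if (hit is not None and hit.identity >= min_identity
                        and hit.length >= min_overlap):
                    placed_now.append((rid, hit.oriented_query(reads[rid]),
                                       hit.t_start - hit.q_start))
            if not placed_now:
                break
            for rid, s, off in placed_now:
                placements.append((s, off))
                remaining.discard(rid)
            shift = min(off for _, off in placements)
            if shift < 0:
                placements = [(s, off - shift) for s, off in placements]
            consensus, depth = _rebuild_consensus(placements)
        raw.append((consensus, depth))

    raw.sort(key=lambda cd: (-int(cd[1].sum()), cd[0]))
    contigs = [
        Consensus(f"{cluster.cluster_id}_contig{i + 1}", seq, depth)
        for i, (seq, depth) in enumerate(raw)
    ]
    cluster.contigs = contigs
    return contigs


def detect_monomer(contig, min_monomer: int = 100, min_terminal: int = 50,
                   min_identity: float = 0.7):
    """Tandem monomer from the contig's longest terminal direct repeat.

    Shifting the contig against itself by its tandem period aligns the
    terminal repeat with the contig start, so the period shows up as a sharp
    global maximum of shifted self-identity. The detector takes the smallest
    period within 0.01 of that maximum (the longest terminal repeat), and
    reports the monomer as the contig's first ``period`` bases. A floor of
    ``min_identity`` rejects aperiodic contigs — kept permissive because the
    two monomer copies a contig carries may come from divergence cohorts
    ~15% apart, while aperiodic sequence scores near 0.25. Returns
    (monomer_length, monomer_sequence) or None. Idempotent: the monomer of a
    monomer has no terminal repeat and reports absent.
    """
    seq = contig.sequence if isinstance(contig, Consensus) else contig
    L = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    win = min_terminal
    scores = []
    for p in range(min_monomer, L - min_terminal + 1):
        eq = (arr[p:] == arr[:-p]).astype(np.float64)
        if eq.size < win:
            scores.append(0.0)
            continue
        # best window of the shifted self-comparison: contig ends may run
        # into mixed flanking sequence, but a true period always has a clean
        # junction-crossing stretch, while wrong periods score ~0.25 anywhere
        c = np.cumsum(np.concatenate([[0.0], eq]))
        scores.append(float((c[win:] - c[:-win]).max() / win))
    if not scores:
        return None
    idents = np.array(scores)
    top = idents.max()
    if top < min_identity:
        return None
    p = min_monomer + int(np.argmax(idents >= top - 0.01))
    monomer = seq[:p]
    if isinstance(contig, Consensus):
        contig.monomer = (0, p)
    return p, monomer


def layout_graph(graph: nx.Graph, seed: int = 0) -> dict:
    """Seeded Fruchterman-Reingold 2D layout (diagnostic only; nothing
    downstream depends on coordinates)."""
    if graph.number_of_nodes() == 0:
        return {}
    if graph.number_of_nodes() == 1:
        return {next(iter(graph.nodes)): np.zeros(2)}
    return nx.spring_layout(graph, seed=seed)
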