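"""Within-family pairwise similarity distributions and homogenisation
signatures.

All-vs-all pairwise identities among a repeat family's reads form a
distribution whose modes record amplification/homogenisation episodes: a
peak at 1.0 marks recently homogenised copies, lower peaks mark older
cohorts. A kernel density estimate with boundary reflection at 1.0
characterises the peaks; a two-sample rank-sum test compares the similarity
location between samples; and a positional consensus-match profile shows
whether divergence is concentrated in particular regions of the monomer.

Caveat carried in the output metadata: pairwise scores within a sample are
not independent observations (each read contributes many pairs), so the
rank-sum p-value describes the score sets, not independent sampling units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from ._align import KmerIndex, ReferenceIndex, best_local_alignment, candidate_pairs


@dataclass
class SimilarityDistribution:
    sample_id: str
    scores: np.ndarray  # pairwise identity fractions, self-hits excluded

    @property
    def mean(self) -> float:
        return float(self.scores.mean()) if self.scores.size else float("nan")


def pairwise_similarity(reads: dict, sample_id: str = "", min_overlap: int = 100,
                        min_identity: float = 0.5, k: int = 13,
                        sample_rate: int = 4, min_shared: int = 2) -> SimilarityDistribution:
    """All-vs-all best-local-alignment identities within one read family.

    Each unordered pair with a qualifying alignment (>= ``min_overlap``
    aligned bases at identity >= ``min_identity``, either strand)
    contributes one score; self-comparisons are excluded and no
    low-complexity masking is applied. Fewer than two reads yield an empty
    distribution.
    """
    if len(reads) < 2:
        return SimilarityDistribution(sample_id, np.array([]))
    indexes: dict[str, KmerIndex] = {}
    scores = []
    for (a, b), _count in candidate_pairs(reads, k=k, sample_rate=sample_rate,
                                          min_shared=min_shared):
        idx = indexes.get(b)
        if idx is None:
            idx = indexes[b] = KmerIndex(reads[b], k)
        hit = best_local_alignment(reads[a], idx, min_identity, min_overlap)
        if hit is not None and hit.identity >= min_identity and hit.length >= min_overlap:
            scores.append(hit.identity)
    return SimilarityDistribution(sample_id, np.array(sorted(scores)))


def mix_distributions(dists, weights=None, seed: int = 0) -> SimilarityDistribution:
    """Pool score sets from several samples with explicit mixing weights
    (weights are relative subsampling fractions; None pools everything)."""
    if weights is None:
        pooled = np.concatenate([d.scores for d in dists])
    else:
        rng = np.random.default_rng(seed)
        parts = []
        for d, w in zip(dists, weights):
            n = int(round(w * d.scores.size))
            if n >= d.scores.size:
                parts.append(d.scores)
            else:
                parts.append(rng.choice(d.scores, size=n, replace=False))
        pooled = np.concatenate(parts)
    return SimilarityDistribution("+".join(d.sample_id for d in dists),
                                  np.sort(pooled))


@dataclass
class DensityResult:
    grid: np.ndarray
    density: np.ndarray
    peaks: list  # (location, height), descending by height
    bandwidth: float


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25])) if n > 1 else 0.0
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        return 1e-3
    return 0.9 * spread * n ** (-0.2)


def density_and_peaks(dist: SimilarityDistribution, grid_size: int = 1024,
                      prominence_frac: float = 0.05,
                      bandwidth: float | None = None) -> DensityResult:
    """Gaussian-kernel density of similarity scores with reflection at 1.0.

    Identity scores cannot exceed 1, and the identical-copy peak sits exactly
    on the boundary; reflecting the sample about 1.0 prevents that peak from
    leaking mass past the boundary. Peaks are local maxima of the reflected
    density with prominence at least ``prominence_frac`` of the maximum,
    reported in descending height order.
    """
    x = dist.scores
    if x.size == 0:
        return DensityResult(np.array([]), np.array([]), [], 0.0)
    h = bandwidth if bandwidth is not None else _silverman_bandwidth(x)
    lo = max(0.0, float(x.min()) - 4 * h)
    binw = max((1.0 - lo) / grid_size, 1e-6)
    h = max(h, 2 * binw)
    radius = 4 * h
    # histogram-convolution KDE on an extended axis, with the sample
    # reflected about 1.0
    ext_hi = 1.0 + radius
    nbins = int(np.ceil((ext_hi - lo) / binw))
    edges = lo + binw * np.arange(nbins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    data = np.concatenate([x, 2.0 - x])
    hist, _ = np.histogram(data, bins=edges)
    kr = int(np.ceil(radius / binw))
    kx = np.arange(-kr, kr + 1) * binw
    kernel = np.exp(-0.5 * (kx / h) ** 2) / (h * np.sqrt(2 * np.pi))
    # the reflected sample doubles the mass, and only the half-axis below 1.0
    # is reported, so dividing by the original n normalises the kept half to 1
    dens = np.convolve(hist, kernel)[kr : kr + hist.size] / x.size

    # prominence is judged against the local flanks (a ~0.05-wide window in
    # score units) relative to the peak's own height: a ripple on a flat
    # plateau is not a mode even if it is the global maximum, while a genuine
    # cohort peak riding on its neighbours' shoulders still qualifies
    wlen = max(5, int(np.ceil(0.05 / binw)))
    peak_idx, props = signal.find_peaks(dens, prominence=1e-12, wlen=wlen)
    keep_peak = ((props["prominences"] >= prominence_frac * dens[peak_idx])
                 & (dens[peak_idx] >= prominence_frac * dens.max()))
    peak_idx = peak_idx[keep_peak]
    peaks = []
    for i in peak_idx:
        loc = min(centers[i], 1.0)
        peaks.append((float(loc), float(dens[i])))
    # the reflection makes the density symmetric about 1.0; a mode at the
    # boundary appears once, modes past 1.0 are mirror images — drop them
    peaks = [(l, ht) for l, ht in peaks if l <= 1.0 + binw]
    peaks.sort(key=lambda p: (-p[1], p[0]))
    keep = centers <= 1.0 + 1e-12
    return DensityResult(centers[keep], dens[keep], peaks, h)


@dataclass
class LocationComparison:
    mean_a: float
    mean_b: float
    statistic: float
    pvalue: float
    method: str
    note: str = ("pairwise scores are not independent observations; "
                 "the test describes the score sets")


def compare_locations(a: SimilarityDistribution, b: SimilarityDistribution) -> LocationComparison:
    """Two-sample Wilcoxon rank-sum comparison of similarity scores.

    Exact null distribution for small tie-free samples, normal approximation
    with tie correction otherwise. Two identical constant samples report
    p = 1 rather than failing on zero rank variance.
    """
    xa, xb = a.scores, b.scores
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both distributions must be non-empty")
    pooled = np.concatenate([xa, xb])
    if np.all(pooled == pooled[0]):
        return LocationComparison(float(xa.mean()), float(xb.mean()),
                                  xa.size * xb.size / 2, 1.0, "degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    small = max(xa.size, xb.size) <= 50
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
    return LocationComparison(float(xa.mean()), float(xb.mean()),
                              float(res.statistic), float(res.pvalue), method)


@dataclass
class ConsensusMatchProfile:
    match_coverage: np.ndarray
    total_coverage: np.ndarray
    window: int = 20

    @property
    def proportion(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total_coverage > 0,
                            self.match_coverage / np.maximum(self.total_coverage, 1),
                            np.nan)

    @property
    def windowed(self) -> np.ndarray:
        """Mean per-position match proportion over consecutive windows; the
        trailing short window averages over its actual width."""
        p = self.proportion
        n = int(np.ceil(p.size / self.window))
        out = np.empty(n)
        for i in range(n):
            chunk = p[i * self.window : (i + 1) * self.window]
            out[i] = np.nanmean(chunk) if np.any(~np.isnan(chunk)) else np.nan
        return out


def consensus_match_profile(reads: dict, consensus: str, min_identity: float = 0.8,
                            min_read_frac: float = 0.5, window: int = 20,
                            k: int = 11) -> ConsensusMatchProfile:
    """Per-position proportion of covering reads matching the consensus base.

    Reads are aligned with the same engine and thresholds as read mapping;
    each aligned column contributes to coverage, matching columns to the
    match count.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    L = len(consensus)
    match_cov = np.zeros(L)
    total_cov = np.zeros(L)
    ref = ReferenceIndex({"consensus": consensus}, k=k)
    cons_arr = np.frombuffer(consensus.encode(), dtype=np.uint8)
    for rid in sorted(reads):
        seq = reads[rid]
        min_len = int(np.ceil(min_read_frac * len(seq)))
        hit = ref.best_hits(seq, min_identity, min_len).get("consensus")
        if hit is None or hit.identity < min_identity or hit.length < min_len:
            continue
        qseg = hit.oriented_query(seq)[hit.q_start : hit.q_end]
        n = min(len(qseg), hit.t_end - hit.t_start)
        q_arr = np.frombuffer(qseg[:n].encode(), dtype=np.uint8)
        t0 = hit.t_start
        total_cov[t0 : t0 + n] += 1
        match_cov[t0 : t0 + n] += q_arr == cons_arr[t0 : t0 + n]
    return ConsensusMatchProfile(match_cov, total_cov, window)
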