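"""Pairwise similarity distributions, KDE peaks, rank-sum comparison and the
consensus-match profile."""

import itertools

import numpy as np
import pytest

from repeatploidy import simulate
from repeatploidy.similarity import (SimilarityDistribution, compare_locations,
                                     consensus_match_profile, density_and_peaks,
                                     mix_distributions, pairwise_similarity)
from tests.conftest import random_seq


def dist(scores, sample_id="s"):
    return SimilarityDistribution(sample_id, np.asarray(scores, dtype=float))


class TestPairwiseSimilarity:
    def test_identical_reads_score_one(self, rng):
        s = random_seq(rng, 200)
        d = pairwise_similarity({"a": s, "b": s, "c": s}, min_overlap=100)
        assert d.scores.size == 3  # three unordered pairs, no self-hits
        assert np.all(d.scores == 1.0)

    def test_ninety_matching_columns_score_point_nine(self, rng):
        t = random_seq(rng, 100)
        q = list(t)
        for i in (15, 16, 35, 36, 55, 56, 70, 71, 84, 85):
            q[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[i]]
        d = pairwise_similarity({"a": t, "b": "".join(q)}, min_overlap=95)
        assert d.scores.size == 1
        assert d.scores[0] == pytest.approx(0.90, abs=1e-9)

    def test_single_read_empty_distribution(self, rng):
        d = pairwise_similarity({"a": random_seq(rng, 100)})
        assert d.scores.size == 0

    def test_two_cohorts_are_bimodal(self, rng):
        a = random_seq(rng, 250)
        b = simulate.mutate(a, 0.05, rng)
        reads = {f"a{i}": a for i in range(8)} | {f"b{i}": b for i in range(8)}
        d = pairwise_similarity(reads, min_overlap=200)
        within = d.scores[d.scores > 0.99]
        between = d.scores[(d.scores > 0.9) & (d.scores < 0.99)]
        assert within.size == 2 * (8 * 7 // 2)
        assert between.size == 64
        assert np.mean(between) == pytest.approx(0.95, abs=0.02)

    def test_symmetry_and_order_invariance(self, rng):
        t = random_seq(rng, 300)
        reads = {f"r{i}": simulate.mutate(t, 0.03, rng) for i in range(6)}
        d1 = pairwise_similarity(reads, min_overlap=150)
        d2 = pairwise_similarity(dict(reversed(list(reads.items()))),
                                 min_overlap=150)
        assert np.allclose(np.sort(d1.scores), np.sort(d2.scores))

    def test_mix_distributions_weights(self):
        a, b = dist([1.0] * 10, "a"), dist([0.5] * 10, "b")
        pooled = mix_distributions([a, b])
        assert pooled.scores.size == 20
        half = mix_distributions([a, b], weights=[1.0, 0.5], seed=1)
        assert half.scores.size == 15


class TestDensityAndPeaks:
    def test_all_identical_scores_single_peak_at_one(self):
        res = density_and_peaks(dist([1.0] * 50))
        assert len(res.peaks) == 1
        assert res.peaks[0][0] == pytest.approx(1.0, abs=0.01)

    def test_three_cohorts_three_peaks(self, rng):
        scores = np.concatenate([
            rng.normal(1.0, 0.004, 400).clip(max=1.0),
            rng.normal(0.95, 0.006, 300),
            rng.normal(0.90, 0.006, 300),
        ])
        res = density_and_peaks(dist(scores))
        locs = [p[0] for p in res.peaks]
        for target in (1.0, 0.95, 0.90):
            assert any(abs(l - target) < 0.01 for l in locs)

    def test_flat_scores_no_prominent_peak(self):
        res = density_and_peaks(dist(np.linspace(0.8, 1.0, 400)))
        assert res.peaks == []

    def test_density_integrates_to_one(self, rng):
        scores = rng.uniform(0.85, 1.0, 500)
        res = density_and_peaks(dist(scores))
        area = np.trapezoid(res.density, res.grid)
        assert area == pytest.approx(1.0, abs=0.05)


def _ranksum_permutation_p(x, y):
    """Exhaustive permutation two-sided p-value for the rank-sum statistic."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    obs = ranks[:n].sum()
    sums = [ranks[list(c)].sum() for c in itertools.combinations(range(n + m), n)]
    sums = np.asarray(sums)
    centre = sums.mean()
    p = np.mean(np.abs(sums - centre) >= abs(obs - centre) - 1e-12)
    return p


class TestCompareLocations:
    def test_identical_samples_null(self, rng):
        x = rng.normal(0.9, 0.02, 40)
        res = compare_locations(dist(x, "a"), dist(x.copy(), "b"))
        assert res.pvalue >= 0.99

    def test_identical_constant_samples_report_p_one(self):
        res = compare_locations(dist([0.9] * 10), dist([0.9] * 10))
        assert res.pvalue == 1.0

    def test_exact_small_sample_disjoint(self):
        res = compare_locations(dist([0.1, 0.2, 0.3]), dist([0.7, 0.8, 0.9]))
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.1, abs=1e-9)  # 2/20

    @pytest.mark.parametrize("nx,ny,seed", [(4, 4, 0), (5, 3, 1), (6, 6, 2),
                                            (8, 5, 3)])
    def test_agrees_with_exhaustive_permutation(self, nx, ny, seed):
        r = np.random.default_rng(seed)
        x = r.normal(0.90, 0.03, nx)
        y = r.normal(0.93, 0.03, ny)
        res = compare_locations(dist(x), dist(y))
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(_ranksum_permutation_p(x, y), abs=1e-9)

    def test_power_on_shifted_samples(self, rng):
        x = rng.normal(0.90, 0.02, 500)
        y = rng.normal(0.95, 0.02, 500)
        res = compare_locations(dist(x), dist(y))
        assert res.pvalue < 1e-5
        assert res.mean_a < res.mean_b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_locations(dist([]), dist([0.9]))

    def test_survivor_bias_orders_means(self, rng):
        """When old divergent cohorts survive elimination preferentially,
        the allopolyploid's similarity scores sit below the progenitor's."""
        progenitor = np.concatenate([np.full(60, 1.0), np.full(40, 0.90)])
        allo = np.concatenate([np.full(20, 1.0), np.full(80, 0.90)])
        res = compare_locations(dist(progenitor, "prog"), dist(allo, "allo"))
        assert res.mean_b < res.mean_a


class TestConsensusMatchProfile:
    def test_error_free_reads_match_everywhere(self, rng):
        cons = random_seq(rng, 400)
        reads = {f"r{i}": cons[i * 40:i * 40 + 120] for i in range(7)}
        prof = consensus_match_profile(reads, cons)
        covered = prof.total_coverage > 0
        assert np.all(prof.proportion[covered] == 1.0)

    def test_uniform_substitution_depresses_profile(self, rng):
        cons = random_seq(rng, 400)
        reads = {f"r{i}": simulate.mutate(cons, 0.05, rng) for i in range(30)}
        prof = consensus_match_profile(reads, cons)
        assert np.nanmean(prof.windowed) == pytest.approx(0.95, abs=0.02)

    def test_divergent_terminal_region_localised(self, rng):
        """Reads diverged only over the consensus's final 100 bp depress
        exactly those windows."""
        cons = random_seq(rng, 400)
        reads = {}
        for i in range(30):
            r = cons[:300] + simulate.mutate(cons[300:], 0.15, rng)
            reads[f"r{i}"] = r
        prof = consensus_match_profile(reads, cons)
        w = prof.windowed
        assert np.nanmean(w[:15]) > 0.995
        assert np.nanmean(w[15:]) < 0.90

    def test_trailing_window_uses_actual_width(self, rng):
        cons = random_seq(rng, 410)
        reads = {"r0": cons}
        prof = consensus_match_profile(reads, cons)
        assert prof.windowed.size == int(np.ceil(410 / 20))
        assert prof.windowed[-1] == 1.0

    def test_no_aligned_reads_empty_profile(self, rng):
        cons = random_seq(rng, 300)
        prof = consensus_match_profile({"r0": random_seq(rng, 100)}, cons)
        assert prof.total_coverage.sum() == 0


class TestHomogenisationSignature:
    def test_sweeps_increase_high_identity_mass(self):
        """Homogenisation sweeps strictly increase the share of pairwise
        scores >= 0.99, across ten seeds."""
        wins = 0
        for seed in range(10):
            masses = []
            for sweeps in (0, 4):
                fam = simulate.RepeatFamilySpec(
                    name="sat", monomer_length=300, tandem_units_per_locus=12,
                    n_loci=1, dispersed_copies=0, dispersed_span=None,
                    divergence_profile=((0.34, 0.0), (0.33, 0.05), (0.33, 0.10)),
                    retro_partner_length=None, retro_copies=0)
                mat = simulate.GenomeSpec("mat", 60_000, (), 0.5, seed=seed * 3 + 1)
                pat = simulate.GenomeSpec("pat", 60_000, (fam,), 0.5, seed=seed * 3 + 2)
                allo = simulate.build_allopolyploid(simulate.AllopolyploidSpec(
                    mat, pat, 0.0, homogenisation_sweeps=sweeps,
                    sweep_recipients=4, seed=seed * 3 + 3))
                rs = simulate.simulate_reads(allo, simulate.ReadSimParams(
                    mode="long_single", read_length=120, coverage=3,
                    seed=seed * 3 + 4))
                fam_reads = {r.id: r.seq for r in rs.reads
                             if r.tags["class"] == "tandem"}
                d = pairwise_similarity(fam_reads, min_overlap=80)
                masses.append(np.mean(d.scores >= 0.99))
            if masses[1] > masses[0]:
                wins += 1
        assert wins >= 9
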