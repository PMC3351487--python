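"""Synthetic-genome and read-simulator behaviour: truth annotation
structure, determinism, elimination/homogenisation semantics, read
statistics and the in-silico digest ladder."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repeatploidy import io as rio
from repeatploidy._align import revcomp
from repeatploidy.simulate import (AllopolyploidSpec, GenomeSpec, ReadSimParams,
                                   RepeatFamilySpec, build_allopolyploid,
                                   build_genome, in_silico_digest, simulate_reads)


class TestBuildGenome:
    def test_zero_divergence_locus_structure(self, small_genome):
        units = small_genome.tandem_units()
        assert len(units) == 10
        locus_start = units[0].start
        locus_end = units[-1].end
        assert locus_end - locus_start == 1000
        seqs = {small_genome.sequences["s1"][f.start:f.end] for f in units}
        assert len(seqs) == 1  # identical head-to-tail copies
        # head-to-tail: consecutive units are adjacent
        for a, b in zip(units, units[1:]):
            assert a.end == b.start

    def test_dispersed_copies_non_adjacent(self):
        fam = RepeatFamilySpec(name="sat", monomer_length=200,
                               tandem_units_per_locus=0, n_loci=0,
                               dispersed_copies=5, divergence_profile=((1.0, 0.0),),
                               retro_partner_length=None, dispersed_span=(0, 200))
        g = build_genome(GenomeSpec("s1", 50_000, (fam,), 0.5, seed=3))
        disp = [f for f in g.features if f.copy_class == "dispersed"]
        assert len(disp) == 5
        disp.sort(key=lambda f: f.start)
        for a, b in zip(disp, disp[1:]):
            assert b.start > a.end  # separated by background

    def test_seed_determinism_byte_identical(self, simple_family_spec, tmp_path):
        spec = GenomeSpec("s1", 20_000, (simple_family_spec,), 0.5, seed=99)
        g1, g2 = build_genome(spec), build_genome(spec)
        assert g1.sequences == g2.sequences
        assert g1.features == g2.features
        rio.write_genome(g1, tmp_path / "a")
        rio.write_genome(g2, tmp_path / "b")
        assert (tmp_path / "a" / "s1.fasta").read_bytes() == \
               (tmp_path / "b" / "s1.fasta").read_bytes()

    def test_truth_conservation(self):
        fam = RepeatFamilySpec(name="sat", monomer_length=150,
                               tandem_units_per_locus=4, n_loci=3,
                               dispersed_copies=2, dispersed_span=(0, 60),
                               retro_partner_length=500, retro_copies=2)
        g = build_genome(GenomeSpec("s1", 60_000, (fam,), 0.4, seed=5))
        assert g.family_bases("sat", classes=("tandem",)) == 12 * 150
        assert g.family_bases("sat", classes=("dispersed",)) == 2 * 60
        # retro partner: standalone copies plus one alongside each dispersed copy
        assert g.family_bases("sat", classes=("retro",)) == (2 + 2) * 500

    def test_oversized_spec_raises(self, simple_family_spec):
        with pytest.raises(ValueError):
            build_genome(GenomeSpec("s1", 900, (simple_family_spec,), 0.5, seed=1))

    def test_invalid_specs_raise(self):
        with pytest.raises(ValueError):
            RepeatFamilySpec(divergence_profile=((0.5, 0.0), (0.4, 0.05))).validate()
        with pytest.raises(ValueError):
            RepeatFamilySpec(divergence_profile=((1.0, 1.5),)).validate()
        with pytest.raises(ValueError):
            RepeatFamilySpec(monomer_length=0).validate()


def _parent_specs(seed=0, units=10, elim_extra=None):
    fam = RepeatFamilySpec(name="sat", monomer_length=120,
                           tandem_units_per_locus=units, n_loci=1,
                           dispersed_copies=2, dispersed_span=(0, 60),
                           retro_partner_length=None, retro_copies=0)
    pat = GenomeSpec("pat", 30_000, (fam,), 0.5, seed=seed + 1)
    mat = GenomeSpec("mat", 30_000, (), 0.5, seed=seed + 2)
    return mat, pat


class TestAllopolyploid:
    def test_union_is_additive_without_elimination(self):
        mat, pat = _parent_specs()
        allo = build_allopolyploid(AllopolyploidSpec(mat, pat, 0.0, seed=5))
        gm, gp = build_genome(mat), build_genome(pat)
        assert len(allo.tandem_units()) == len(gm.tandem_units()) + len(gp.tandem_units())
        assert allo.total_length == gm.total_length + gp.total_length

    def test_full_elimination_keeps_only_dispersed(self):
        mat, pat = _parent_specs()
        allo = build_allopolyploid(AllopolyploidSpec(mat, pat, 1.0, seed=5))
        assert allo.tandem_units() == []
        disp = [f for f in allo.features if f.copy_class == "dispersed"]
        assert len(disp) == 2
        # surviving copies carry the right sequence at their shifted coordinates
        gp = build_genome(pat)
        origs = {gp.sequences["pat"][f.start:f.end]
                 for f in gp.features if f.copy_class == "dispersed"}
        for f in disp:
            assert allo.sequences[f.chrom][f.start:f.end] in origs

    def test_elimination_fraction_out_of_range(self):
        mat, pat = _parent_specs()
        with pytest.raises(ValueError):
            build_allopolyploid(AllopolyploidSpec(mat, pat, 1.2, seed=1))

    def test_sweep_homogenises_units(self):
        fam = RepeatFamilySpec(name="sat", monomer_length=120,
                               tandem_units_per_locus=10, n_loci=1,
                               dispersed_copies=0, dispersed_span=None,
                               divergence_profile=((0.5, 0.0), (0.5, 0.1)),
                               retro_partner_length=None, retro_copies=0)
        pat = GenomeSpec("pat", 30_000, (fam,), 0.5, seed=2)
        mat = GenomeSpec("mat", 30_000, (), 0.5, seed=3)
        allo = build_allopolyploid(
            AllopolyploidSpec(mat, pat, 0.0, homogenisation_sweeps=1, seed=4))
        unit_seqs = [allo.sequences[f.chrom][f.start:f.end]
                     for f in allo.tandem_units()]
        counts = max(unit_seqs.count(s) for s in set(unit_seqs))
        assert counts >= 2  # donor plus at least one overwritten recipient

    def test_whole_locus_loss(self):
        fam = RepeatFamilySpec(name="sat", monomer_length=100,
                               tandem_units_per_locus=4, n_loci=3,
                               dispersed_copies=0, dispersed_span=None,
                               retro_partner_length=None, retro_copies=0)
        pat = GenomeSpec("pat", 30_000, (fam,), 0.5, seed=2)
        mat = GenomeSpec("mat", 30_000, (), 0.5, seed=3)
        allo = build_allopolyploid(
            AllopolyploidSpec(mat, pat, 0.0, whole_locus_losses=2, seed=4))
        loci = {f.locus_id for f in allo.tandem_units()}
        assert len(loci) == 1

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(e=st.floats(min_value=0.0, max_value=1.0),
           mode=st.sampled_from(["contiguous", "scattered"]))
    def test_elimination_fraction_is_realised(self, e, mode):
        """Surviving tandem units match round((1-e) * total) regardless of
        how the eliminated blocks are placed."""
        mat, pat = _parent_specs(units=8)
        allo = build_allopolyploid(AllopolyploidSpec(
            mat, pat, e, seed=11, elimination_mode=mode))
        total = 8
        assert len(allo.tandem_units()) == total - int(round(e * total))


class TestSimulateReads:
    def test_read_count_expectation(self, small_genome):
        counts = [len(simulate_reads(small_genome, ReadSimParams(
            mode="long_single", read_length=100, coverage=10, seed=s)).reads)
            for s in range(20)]
        assert np.mean(counts) == pytest.approx(10 * 20_000 / 100, rel=0.01)

    def test_error_free_reads_are_substrings(self, small_genome):
        rs = simulate_reads(small_genome, ReadSimParams(
            mode="long_single", read_length=80, coverage=2, seed=1))
        g = small_genome.sequences["s1"]
        for r in rs.reads[:100]:
            assert r.seq in g or revcomp(r.seq) in g

    def test_error_and_n_rates(self, small_genome):
        rs = simulate_reads(small_genome, ReadSimParams(
            mode="long_single", read_length=100, coverage=5,
            error_rate=0.02, n_rate=0.01, seed=2))
        g = small_genome.sequences["s1"]
        n_frac = sum(r.seq.count("N") for r in rs.reads) / rs.total_bases
        assert n_frac == pytest.approx(0.01, rel=0.25)
        mism = []
        for r in rs.reads[:200]:
            if r.tags["strand"] == 1:
                ref = g[r.tags["start"]:r.tags["start"] + 100]
                mism.append(np.mean([a != b for a, b in zip(r.seq, ref)
                                     if a != "N"]))
        assert np.mean(mism) == pytest.approx(0.02, rel=0.3)

    def test_paired_mode_orientation_and_gap(self, small_genome):
        params = ReadSimParams(mode="short_paired", read_length=50,
                               insert_size_mean=150, insert_size_sd=0,
                               coverage=2, seed=3)
        rs = simulate_reads(small_genome, params)
        assert len(rs.reads) % 2 == 0
        g = small_genome.sequences["s1"]
        for r1, r2 in zip(rs.reads[0::2], rs.reads[1::2]):
            s1, s2 = r1.tags["start"], r2.tags["start"]
            assert r1.seq == g[s1:s1 + 50]           # left mate forward
            assert r2.seq == revcomp(g[s2:s2 + 50])  # right mate inward
            assert s2 - s1 == 150 - 50               # gap = insert - 2*readlen

    def test_paired_insert_shorter_than_read_rejected(self, small_genome):
        with pytest.raises(ValueError):
            simulate_reads(small_genome, ReadSimParams(
                mode="short_paired", read_length=100, insert_size_mean=80, seed=1))

    def test_seed_determinism(self, small_genome):
        p = ReadSimParams(mode="long_single", read_length=90, coverage=3, seed=8)
        r1 = simulate_reads(small_genome, p)
        r2 = simulate_reads(small_genome, p)
        assert [(r.id, r.seq) for r in r1.reads] == [(r.id, r.seq) for r in r2.reads]


class TestDigest:
    SITE = "GAATTC"

    def _unit(self, rng, site_at_start=True):
        from tests.conftest import random_seq
        body = random_seq(rng, 2200 - len(self.SITE)).replace(self.SITE, "ACGTAC")
        return self.SITE + body

    def test_perfect_array_collapses_to_monomer_band(self, rng):
        unit = self._unit(rng)
        frags = in_silico_digest(unit * 5, self.SITE)
        assert len(frags) == 5
        assert all(f == 2200 for f in frags)

    def test_no_site_single_fragment(self, rng):
        from tests.conftest import random_seq
        seq = random_seq(rng, 3000).replace(self.SITE, "ACGTAC")
        assert in_silico_digest(seq, self.SITE) == [3000]

    def test_mutated_site_yields_dimer_band(self, rng):
        unit = self._unit(rng)
        broken = "T" + unit[1:]  # kill the site in the third unit
        arr = unit * 2 + broken + unit * 2
        frags = in_silico_digest(arr, self.SITE)
        assert sorted(frags) == [2200, 2200, 2200, 4400]

    def test_short_site_rejected(self):
        with pytest.raises(ValueError):
            in_silico_digest("ACGT" * 100, "AC")
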