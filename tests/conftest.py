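import numpy as np
import pytest

from repeatploidy import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n, gc=0.5):
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return bases[rng.choice(4, size=n, p=p)].tobytes().decode()


@pytest.fixture
def simple_family_spec():
    """One tandem locus of ten identical 100 bp units, nothing else."""
    return simulate.RepeatFamilySpec(
        name="sat", monomer_length=100, tandem_units_per_locus=10, n_loci=1,
        dispersed_copies=0, divergence_profile=((1.0, 0.0),),
        retro_partner_length=None, retro_copies=0, dispersed_span=None,
    )


@pytest.fixture
def small_genome(simple_family_spec):
    spec = simulate.GenomeSpec("s1", 20_000, (simple_family_spec,), 0.5, seed=7)
    return simulate.build_genome(spec)
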