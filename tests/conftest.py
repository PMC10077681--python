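import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cnvsweep.genomic_io import GroupAssignment, HaplotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_haplotypes(rng, n_hap=10, n_sites=40, length=10_000, chrom="1"):
    """Small random phased matrix for oracle comparisons."""
    assert n_hap % 2 == 0
    positions = np.sort(rng.choice(np.arange(1, length + 1), size=n_sites, replace=False))
    alleles = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.uint8)
    # ensure every site is polymorphic
    for j in range(n_sites):
        if alleles[:, j].sum() == 0:
            alleles[rng.integers(n_hap), j] = 1
        elif alleles[:, j].sum() == n_hap:
            alleles[rng.integers(n_hap), j] = 0
    samples = [f"S{i:02d}" for i in range(n_hap // 2)]
    return HaplotypeMatrix(
        chrom=chrom,
        positions=positions,
        alleles=alleles,
        sample_ids=[s for s in samples for _ in range(2)],
    )


@pytest.fixture
def small_hm(rng):
    return random_haplotypes(rng)


@pytest.fixture
def two_groups():
    samples = [f"S{i:02d}" for i in range(10)]
    return GroupAssignment({s: ("A" if i < 5 else "B") for i, s in enumerate(samples)})
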