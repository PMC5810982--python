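import numpy as np
import pytest

from cehkit.haplotypes import CEH, Diplotype
from cehkit.simulate import HaplotypePool, PoolRecipe, build_pool


def make_ceh(tag: str, snp: str = "00000000000") -> CEH:
    """A distinct, well-formed CEH labelled by ``tag`` at every HLA locus."""
    return CEH.from_fields(f"{tag}:01", f"{tag}:01", f"{tag}:01",
                           f"{tag}:01", f"{tag}:01", snp)


def genotype_of(h1, h2):
    """Unphased multi-locus genotype (sorted allele pairs) of a haplotype pair."""
    return tuple(tuple(sorted(p)) for p in zip(h1, h2))


@pytest.fixture
def two_ceh_pool() -> HaplotypePool:
    h1 = make_ceh("01", "00000000000")
    h2 = make_ceh("02", "11111111111")
    return build_pool(haplotypes=[h1, h2], frequencies=[0.5, 0.5])


@pytest.fixture
def skewed_pool() -> HaplotypePool:
    """20 distinct CEHs with Zipf-decreasing frequencies (no rare tail)."""
    return build_pool(PoolRecipe(n_common=20, n_rare=0, common_mass=1.0,
                                 common_skew=1.0, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
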