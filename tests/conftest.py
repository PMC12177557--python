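import numpy as np
import pytest

from bloodeqtl.simulate import SimConfig, simulate_genotypes


@pytest.fixture(scope="session")
def small_geno():
    """120 samples x ~300 LD-structured variants with 1% missing calls."""
    cfg = SimConfig(
        n_samples=120,
        n_variants=300,
        chrom_length=15_000_000,
        seed=7,
    )
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def clean_geno():
    """Complete-call genotype matrix (no missing) for exact algebra checks."""
    cfg = SimConfig(
        n_samples=100,
        n_variants=200,
        chrom_length=10_000_000,
        seed=11,
        missing_rate=0.0,
    )
    return simulate_genotypes(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
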