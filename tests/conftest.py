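import numpy as np
import pytest

from qmtsvr.simdata import SimConfig, forward_split, simulate_population


@pytest.fixture(scope="session")
def small_pop():
    """A small two-trait population: 5 generations x 40 individuals."""
    cfg = SimConfig(
        n_per_generation=40,
        n_generations=5,
        p_snps=200,
        n_qtl=50,
        h2=(0.5, 0.4),
        genetic_corr=0.4,
        residual_corr=0.3,
        seed=42,
    )
    geno, pheno = simulate_population(cfg)
    return geno, pheno


@pytest.fixture(scope="session")
def small_split(small_pop):
    _, pheno = small_pop
    return forward_split(pheno, [0, 1, 2, 3], [4])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
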