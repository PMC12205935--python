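import numpy as np
import pytest

from lnceqtl.synthgen import (
    SimConfig,
    simulate_expression_panel,
    simulate_gene_models,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_individuals=80,
        n_tissues=3,
        n_lnc=12,
        n_mrna=8,
        variants_per_gene=10,
        frac_elnc=0.5,
        beta_sd=1.0,
        theta=0.8,
        gwas_n=1000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """(genes, geno, panel, truth) at desk scale, shared across tests."""
    genes = simulate_gene_models(small_cfg)
    geno = simulate_genotypes(small_cfg, genes, seed=1)
    panel, truth = simulate_expression_panel(geno, genes, small_cfg, seed=2)
    return genes, geno, panel, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
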