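import numpy as np
import pytest

from genepath import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Stratified cohort with one strong planted gene and a causal pathway."""
    config = SimulationConfig(
        n_samples=300,
        group_sizes=(220, 80),
        fst=0.05,
        n_genes=60,
        snps_per_gene=(8, 20),
        intergenic_snps=100,
        ld_rho=0.5,
        causal_genes=((7, 8, 0.25),),
        causal_pathway_index=2,
        n_pathways=6,
        genes_per_pathway=(5, 12),
        seed=11,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def null_cohort():
    """Unstructured cohort with no causal genes (for calibration checks)."""
    config = SimulationConfig(
        n_samples=244,
        group_sizes=(178, 66),
        fst=0.0,
        n_genes=50,
        snps_per_gene=(1, 25),
        intergenic_snps=0,
        ld_rho=0.5,
        n_pathways=5,
        genes_per_pathway=(5, 12),
        seed=5,
    )
    return simulate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
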