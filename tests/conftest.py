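import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import bloodgwas as bg

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """2,000-sample cohort with LD blocks and one common causal variant."""
    from bloodgwas import workflows as wf

    return wf.simulate_sparse_cohort(
        2000, 60, [30], target_z=8.0, seed=11, locus_seed=11
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Pure-noise phenotype over 1,000 independent variants."""
    cfg = bg.SimConfig(
        n_samples=2000, n_variants=1000, ld_block_span=1, seed=5
    )
    G = bg.simulate_genotypes(cfg)
    pheno = bg.simulate_phenotype(G, cfg)
    return G, pheno


@pytest.fixture(scope="session")
def hub_network():
    """Network with strongly connected, mutually correlated core genes."""
    cfg = bg.NetworkSimConfig(
        n_genes=400,
        n_core=20,
        base_degree=5,
        core_degree_multiplier=5,
        core_mutual_correlation=0.3,
        seed=2,
    )
    return bg.simulate_network(cfg)


@pytest.fixture()
def blood_table():
    return pd.DataFrame(
        {
            "WBC": [6.5, 250.0, 8.0, 7.2],
            "HGB": [14.0, 13.5, 21.0, 15.0],
            "HCT": [42.0, 40.0, 44.0, 39.0],
            "PLT": [250.0, 300.0, 260.0, 900.0],
            "age": [45.0, 52.0, 61.0, 48.0],
            "sex": [0, 1, 0, 1],
        }
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
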