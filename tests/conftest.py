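import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from metgwas.genotypes import maf_filter, vanraden_kinship
from metgwas.simulate import (
    default_sim_config,
    simulate_design,
    simulate_genotypes,
    simulate_phenotypes,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_cfg():
    """Small but structured study conditions shared across tests."""
    return default_sim_config(n_entries=300, n_snps=1000, seed=42)


@pytest.fixture(scope="session")
def geno(sim_cfg):
    return simulate_genotypes(sim_cfg)


@pytest.fixture(scope="session")
def geno_maf(geno):
    return maf_filter(geno)


@pytest.fixture(scope="session")
def kinship(geno_maf):
    return vanraden_kinship(geno_maf)


@pytest.fixture(scope="session")
def trial_data(sim_cfg, geno):
    design = simulate_design(sim_cfg)
    pheno, truth = simulate_phenotypes(geno, design, sim_cfg)
    return design, pheno, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
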