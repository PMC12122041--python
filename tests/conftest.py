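import numpy as np
import pytest

from cgwas.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """200 cases / 100 controls / 300 variants, two subgroups, one planted
    subgroup-specific effect. Shared across tests that only read it."""
    cfg = SimConfig(
        n_cases=200,
        n_controls=100,
        n_subgroups=2,
        n_variants=300,
        causal_spec=[(7, 0, 6.0)],
        seed=11,
    )
    gm, pheno, truth = simulate_cohort(cfg)
    return cfg, gm, pheno, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
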