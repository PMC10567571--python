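import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pqtlkit.config import Thresholds
from pqtlkit.synth import SimConfig, simulate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def small_cohort():
    """Shared small two-platform cohort with cis, trans and epitope
    structure; sized for fast end-to-end tests."""
    config = SimConfig(
        seed=7, n_donors=800, n_proteins=12, n_blocks=6,
        variants_per_block=20, shared_target_fraction=0.75,
        epitope_pav_prob=0.25,
        trans_network=[{"variant": "common:0",
                        "proteins": [2, 3, 4], "effect": 0.35}],
        phenotype_spec={
            "binary": [{"name": "disease_1", "weights": {0: 1.0},
                        "prevalence": 0.1}],
            "quantitative": [{"name": "trait_1", "weights": {1: 0.5},
                              "noise_sd": 1.0}],
        })
    return simulate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
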