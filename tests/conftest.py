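import numpy as np
import pytest
from hypothesis import settings

from gnurture.famsim import SimConfig
from gnurture.pipeline import (
    build_score_table,
    infer_transmission,
    simulate_cohort,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mixed_cohort():
    """Small mixed-design cohort: trios plus both pair types, error-free."""
    config = SimConfig(
        n_trios=40,
        n_father_pairs=25,
        n_mother_pairs=25,
        n_markers=3000,
        n_chromosomes=3,
        sibling_rate=0.25,
        beta_T=0.15,
        beta_NT=0.05,
        spousal_corr=0.0,
        phase_error_rate=0.0,
        seed=1234,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def mixed_transmission(mixed_cohort):
    return infer_transmission(mixed_cohort)


@pytest.fixture(scope="session")
def mixed_scores(mixed_cohort, mixed_transmission):
    return build_score_table(mixed_cohort, mixed_transmission)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
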