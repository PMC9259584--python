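import numpy as np
import pytest

from blcohort.simulate import CohortConfig, GeneModel, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Mid-size synthetic cohort with reduced background noise, shared across tests."""
    cfg = CohortConfig(
        n_pediatric=120,
        n_adult=60,
        seed=42,
        n_germline_per_sample=200,
        n_noise_per_sample=80,
        n_artifact_sites=80,
        n_snp_sites=1000,
        n_matched_normals=40,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
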