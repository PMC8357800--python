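import numpy as np
import pytest

from fetalconn import GeneratorConfig, generate_cohort


def truth_codes(cohort):
    """Planted network labels as integer codes aligned with roi order."""
    return cohort.roi_truth["true_network"].astype("category").cat.codes.to_numpy()


@pytest.fixture(scope="session")
def small_cohort():
    """40 subjects, 24 ROIs in 4 planted networks, moderate planted coupling."""
    cfg = GeneratorConfig(n_subjects=40, n_roi=24, n_networks=4,
                          frames_mean=80, frames_sd=5,
                          stress_coupled_pairs=(("N01", "N02"),),
                          coupling_slope=0.05, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
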