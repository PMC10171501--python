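import warnings

import numpy as np
import pytest

from dfcsubtype import generate_cohort, generate_ground_truth

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_gt():
    """Small module bank for fast structural checks (K=4, m=12)."""
    return generate_ground_truth(k_true=4, m=12, sparsity=0.1, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_gt):
    """Tiny cohort shared by I/O and orchestration tests."""
    manifest, series = generate_cohort(
        small_gt,
        n_patients=10,
        n_controls_base=10,
        n_controls_ica=8,
        t_volumes=80,
        tr=2.0,
        noise_sd=0.1,
        seed=42,
    )
    return manifest, series


@pytest.fixture(scope="session")
def pipeline_cohort():
    """Mid-size cohort with planted subtypes for orchestration tests.

    Large enough that the normative folds have the required training size
    and the planted subtype structure survives estimation, small enough to
    run the full pipeline in seconds.
    """
    gt = generate_ground_truth(k_true=6, m=18, sparsity=0.07, seed=7)
    manifest, series = generate_cohort(
        gt,
        n_patients=48,
        n_controls_base=48,
        n_controls_ica=40,
        t_volumes=210,
        tr=2.0,
        noise_sd=0.1,
        seed=7,
    )
    return gt, manifest, series
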