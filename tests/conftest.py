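import numpy as np
import pytest

from voicelung import GenerativeParams, generate_cohort
from voicelung.dsp import FrameGrid
from voicelung.pipeline import analyze_cohort


@pytest.fixture(scope="session")
def grid() -> FrameGrid:
    return FrameGrid()


@pytest.fixture(scope="session")
def small_cohort():
    """Ten 30-s recordings across 4 subjects; default generative params."""
    return generate_cohort(GenerativeParams(seed=7), n_subjects=4, n_recordings=10)


@pytest.fixture(scope="session")
def cohort50():
    """The 50-recording cohort used for segmentation scoring (seed 0)."""
    return generate_cohort(GenerativeParams(seed=0), n_subjects=10, n_recordings=50)


@pytest.fixture(scope="session")
def analysis50(cohort50):
    """Full pipeline output on the 50-recording cohort, scored against
    ground truth."""
    return analyze_cohort(cohort50, seed=0, run_cv=False)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
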