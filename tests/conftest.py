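"""Shared fixtures: study-condition defaults and calibrated dropout specs.

Dropout calibration is the slowest shared step (bisection against a
10,000-mouse calibration cohort), so calibrated specs are session-scoped and
reused across test modules.
"""

import numpy as np
import pytest

from mctmodels import (GrowthTruth, TrialDesign, calibrate_dropout,
                       modelling_frame, simulate_cohort)
from mctmodels.types import DropoutSpec


TRUE_SLOPE = 0.39
CALIBRATION_SEED = 424242


@pytest.fixture(scope="session")
def truth():
    """Simulation-study growth truth: single slope 0.39 log(mm^3)/week."""
    return GrowthTruth()


def single_group_design(n_mice: int) -> TrialDesign:
    return TrialDesign(n_pdx=1, mice_per_pdx=n_mice)


@pytest.fixture(scope="session")
def mar50_dropout(truth):
    """Dropout calibrated to 50% sacrifices (MAR) and no natural deaths."""
    return calibrate_dropout(single_group_design(10_000), truth, 0.0, 0.5,
                             seed=CALIBRATION_SEED)


@pytest.fixture(scope="session")
def mnar50_dropout(truth):
    """Dropout calibrated to 50% natural deaths (MNAR) and no sacrifices."""
    return calibrate_dropout(single_group_design(10_000), truth, 0.5, 0.0,
                             seed=CALIBRATION_SEED)


@pytest.fixture(scope="session")
def seed1_cohort(truth):
    """Fixed 100-mouse cohort under 50% MNAR dropout (oracle comparisons)."""
    drop = DropoutSpec(ethical_threshold_mm3=np.inf, mnar_eta=1.0,
                       mnar_baseline_shape=1.5, mnar_baseline_scale=290.0)
    return simulate_cohort(single_group_design(100), truth, drop, seed=1)


@pytest.fixture(scope="session")
def seed1_frames(seed1_cohort):
    from mctmodels.simstudy import cohort_frames
    return cohort_frames(seed1_cohort)


@pytest.fixture(scope="session")
def clean_cohort_frames(truth):
    """300-mouse cohort with dropout disabled (complete follow-up)."""
    from mctmodels.simstudy import cohort_frames
    coh = simulate_cohort(single_group_design(300), truth, DropoutSpec(), seed=8)
    return cohort_frames(coh)
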