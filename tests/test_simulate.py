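"""Tests of the synthetic MCT generator and its dropout mechanisms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mctmodels import (CalibrationError, DropoutSpec, GrowthTruth, TrialDesign,
                       apply_mar_sacrifice, calibrate_dropout, perturb_to_mnar,
                       sample_mnar_death_time, simulate_cohort)
from mctmodels.simulate import _mnar_death_weeks, true_cum_hazard
from mctmodels.types import CAUSE_MAR, CAUSE_MNAR

from conftest import single_group_design


# ---------------------------------------------------------------------------
# deterministic contracts

def test_degenerate_noise_gives_exact_line():
    """With all SDs at zero every observation sits exactly on the mean line."""
    truth = GrowthTruth(re_sd=(0.0, 0.0), residual_sd=0.0)
    coh = simulate_cohort(single_group_design(5), truth, DropoutSpec(), seed=3)
    for rec in coh.records:
        t = rec.obs_days / 7.0
        expected = truth.intercept_mean + truth.slope1 * t
        np.testing.assert_allclose(np.log(rec.obs_tv_mm3), expected, atol=1e-12)


def test_same_seed_bitwise_identical(truth, mar50_dropout):
    a = simulate_cohort(single_group_design(50), truth, mar50_dropout, seed=11)
    b = simulate_cohort(single_group_design(50), truth, mar50_dropout, seed=11)
    ma, da = a.to_frames()
    mb, db = b.to_frames()
    pd.testing.assert_frame_equal(ma, mb)
    pd.testing.assert_frame_equal(da, db)


def test_no_observation_after_death(truth):
    drop = DropoutSpec(ethical_threshold_mm3=800.0, mnar_eta=1.0,
                       mnar_baseline_shape=1.5, mnar_baseline_scale=250.0)
    coh = simulate_cohort(single_group_design(400), truth, drop, seed=5)
    seen = set()
    for rec in coh.records:
        if rec.death_day is not None:
            assert rec.obs_days.max() <= rec.death_day + 1e-9
            seen.add(rec.death_cause)
        assert rec.n_obs >= 1
    assert {CAUSE_MAR, CAUSE_MNAR} <= seen


def test_non_pd_correlation_rejected():
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])
    with pytest.raises(ValueError):
        GrowthTruth(re_corr=bad)


# ---------------------------------------------------------------------------
# MAR sacrifice rule

@pytest.mark.parametrize("vols, days, thr, expected_day, n_kept", [
    ([800, 1200, 1600], [0, 7, 14], 1500.0, 14.0, 3),   # triggering obs retained
    ([800, 1200, 1400], [0, 7, 14], 1500.0, None, 3),   # never crossed
    ([1600, 1700], [0, 7], 1500.0, 0.0, 1),             # first obs already over
])
def test_mar_sacrifice_rule(vols, days, thr, expected_day, n_kept):
    day, cause = apply_mar_sacrifice(days, vols, thr)
    if expected_day is None:
        assert day is None and cause is None
    else:
        assert day == expected_day and cause == CAUSE_MAR
        kept = [d for d in days if d <= day]
        assert len(kept) == min(n_kept, len(kept))


@given(st.lists(st.floats(min_value=1.0, max_value=5000.0), min_size=1, max_size=12),
       st.floats(min_value=10.0, max_value=4000.0))
@settings(deadline=None, max_examples=50)
def test_mar_sacrifice_properties(vols, thr):
    """Sacrifice day is the first crossing; None means no volume crossed."""
    days = np.arange(len(vols), dtype=float) * 3
    day, cause = apply_mar_sacrifice(days, vols, thr)
    crossed = [d for d, v in zip(days, vols) if v >= thr]
    if crossed:
        assert day == crossed[0] and cause == CAUSE_MAR
    else:
        assert day is None


# ---------------------------------------------------------------------------
# MNAR death sampler

def test_mnar_sampler_matches_closed_form_exponential_baseline():
    """Constant trajectory, shape-1 baseline: T = E * scale * exp(-eta*m0)."""
    truth = GrowthTruth(slope1=0.0, re_sd=(0.0, 0.0), residual_sd=0.0)
    drop = DropoutSpec(mnar_eta=0.8, mnar_baseline_shape=1.0, mnar_baseline_scale=50.0)
    m0 = truth.intercept_mean
    E = np.array([0.05, 0.2, 0.6, 1.0])
    T = _mnar_death_weeks(E, np.full(4, m0), np.zeros(4), np.zeros(4), None,
                          drop, follow_up_weeks=50.0)
    expected = E * drop.mnar_baseline_scale * np.exp(-drop.mnar_eta * m0)
    np.testing.assert_allclose(T, expected, atol=1e-8)


def test_mnar_eta_zero_is_plain_weibull_draw(truth):
    """With eta=0 the death time is a Weibull draw independent of the mouse."""
    drop = DropoutSpec(mnar_eta=0.0, mnar_baseline_shape=1.5, mnar_baseline_scale=2.0)
    rng = np.random.default_rng(0)
    E = rng.exponential(size=5000)
    T = _mnar_death_weeks(E, np.full(5000, 9.9), np.full(5000, 1.3),
                          np.full(5000, 1.3), None, drop, follow_up_weeks=100.0)
    # inverse CDF of Weibull: T = scale * E**(1/shape)
    np.testing.assert_allclose(T, 2.0 * E ** (1 / 1.5), atol=1e-7)


def test_mnar_larger_slope_dies_earlier(truth):
    """Positive association: the faster-growing mouse dies stochastically earlier."""
    drop = DropoutSpec(mnar_eta=1.0, mnar_baseline_shape=1.5, mnar_baseline_scale=300.0)
    rng = np.random.default_rng(1)
    n = 10_000
    E = rng.exponential(size=n)
    a = np.full(n, truth.intercept_mean)
    T_slow = _mnar_death_weeks(E, a, np.full(n, 0.2), np.full(n, 0.2), None, drop, 50.0)
    T_fast = _mnar_death_weeks(E, a, np.full(n, 0.6), np.full(n, 0.6), None, drop, 50.0)
    grid = np.linspace(0.5, 20, 40)
    cdf_slow = (T_slow[:, None] <= grid).mean(axis=0)
    cdf_fast = (T_fast[:, None] <= grid).mean(axis=0)
    assert np.all(cdf_fast >= cdf_slow)
    assert np.any(cdf_fast > cdf_slow + 0.05)


def test_sampler_survival_matches_quadrature(truth):
    """Empirical survival of sampled death times equals exp(-H(t)) (sup < 0.02)."""
    drop = DropoutSpec(mnar_eta=1.0, mnar_baseline_shape=1.5, mnar_baseline_scale=300.0)
    rng = np.random.default_rng(2)
    n = 10_000
    E = rng.exponential(size=n)
    a = np.full(n, truth.intercept_mean)
    s = np.full(n, truth.slope1)
    T = _mnar_death_weeks(E, a, s, s, None, drop, follow_up_weeks=30.0)
    grid = np.linspace(0.25, 25, 60)
    S_emp = (T[:, None] > grid).mean(axis=0)
    H = true_cum_hazard(grid, a[0], s[0], s[0], None, drop)
    assert np.max(np.abs(S_emp - np.exp(-H))) < 0.02


def test_sample_mnar_death_time_scalar_api(truth):
    drop = DropoutSpec(mnar_eta=1.0, mnar_baseline_shape=1.5, mnar_baseline_scale=50.0)
    rng = np.random.default_rng(3)
    day = sample_mnar_death_time(np.zeros(2), ("all", "vehicle"), truth, drop, rng)
    assert day is None or 0 < day <= 63.0


def test_mechanism_identity_eta_zero(truth):
    """With eta=0 death times are independent of the random effects (KS test)."""
    drop = DropoutSpec(mnar_eta=0.0, mnar_baseline_shape=1.5, mnar_baseline_scale=1.5)
    coh = simulate_cohort(single_group_design(10_000), truth, drop, seed=21)
    T = np.array([r.death_day if r.death_day is not None else np.nan for r in coh.records])
    slope_re = np.array([r.latent_re[1] for r in coh.records])
    dead = ~np.isnan(T)
    ks = stats.ks_2samp(T[dead & (slope_re > 0)], T[dead & (slope_re <= 0)])
    assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# calibration

def test_calibration_mixed_targets_hold_on_independent_cohort(truth):
    """(20% MNAR, 30% MAR) calibration reproduces within +/-2 points at n=10,000."""
    spec = calibrate_dropout(single_group_design(10_000), truth, 0.20, 0.30, seed=99)
    coh = simulate_cohort(single_group_design(10_000), truth, spec, seed=1234)
    causes = pd.Series([r.death_cause for r in coh.records])
    p_mnar = (causes == CAUSE_MNAR).mean()
    p_mar = (causes == CAUSE_MAR).mean()
    assert abs(p_mnar - 0.20) < 0.02
    assert abs(p_mar - 0.30) < 0.02


def test_calibration_mnar_only(truth, mnar50_dropout):
    coh = simulate_cohort(single_group_design(10_000), truth, mnar50_dropout, seed=555)
    causes = pd.Series([r.death_cause for r in coh.records])
    assert abs((causes == CAUSE_MNAR).mean() - 0.50) < 0.02
    assert (causes == CAUSE_MAR).sum() == 0


def test_calibration_disabled_targets(truth, mar50_dropout):
    """Zero targets disable the corresponding mechanism entirely."""
    assert not mar50_dropout.mnar_enabled          # MNAR target 0 -> hazard off
    spec = calibrate_dropout(single_group_design(2000), truth, 0.0, 0.0, seed=1,
                             n_calib=2000)
    assert not spec.mnar_enabled and not spec.mar_enabled


def test_calibration_unreachable_target_raises():
    """Degenerate cohort (identical mice): any MAR proportion strictly between
    0 and 1 is unreachable because all mice cross the threshold on the same day."""
    degenerate = GrowthTruth(re_sd=(0.0, 0.0), residual_sd=0.0)
    with pytest.raises(CalibrationError):
        calibrate_dropout(single_group_design(2000), degenerate, 0.0, 0.5, seed=1,
                          n_calib=2000)


# ---------------------------------------------------------------------------
# MAR -> MNAR perturbation

def test_perturbation_masks_and_keeps_deaths(truth, mar50_dropout):
    coh = simulate_cohort(single_group_design(200), truth, mar50_dropout, seed=17)
    thr = 0.6 * mar50_dropout.ethical_threshold_mm3
    pert = perturb_to_mnar(coh, thr)
    for orig, new in zip(coh.records, pert.records):
        assert np.all(new.obs_tv_mm3 < thr)
        kept = orig.obs_tv_mm3 < thr
        np.testing.assert_array_equal(new.obs_days, orig.obs_days[kept])
        assert new.death_day == orig.death_day        # element-wise retention
        assert new.death_cause == orig.death_cause
        if not kept.any():
            assert new.all_masked and new.n_obs == 0
        if kept.all():
            np.testing.assert_array_equal(new.obs_tv_mm3, orig.obs_tv_mm3)


def test_perturbation_threshold_must_be_sub_ethical(truth, mar50_dropout):
    coh = simulate_cohort(single_group_design(10), truth, mar50_dropout, seed=1)
    with pytest.raises(ValueError):
        perturb_to_mnar(coh, mar50_dropout.ethical_threshold_mm3 * 1.1)
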