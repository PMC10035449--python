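"""Tests of the maximum-likelihood linear mixed model for log tumor growth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mctmodels.lmm as lmm_mod
from mctmodels import (DropoutSpec, GrowthTruth, LmmSpec, fit_lmm,
                       modelling_frame, piecewise_basis, select_changepoint,
                       simulate_cohort, slope_table)
from mctmodels.lmm import (_profile_one_level, _profile_two_level, _suffstats,
                           build_design, contrast, theta_from_cov, theta_size)

from conftest import single_group_design, TRUE_SLOPE


# ---------------------------------------------------------------------------
# piecewise basis

@pytest.mark.parametrize("t, c, expected", [
    (0.0, 4.0, (0.0, 0.0)),
    (4.0, 4.0, (4.0, 0.0)),
    (6.0, 4.0, (4.0, 2.0)),
])
def test_piecewise_basis_values(t, c, expected):
    f1, f2 = piecewise_basis(t, c)
    assert (f1, f2) == expected


@given(st.floats(min_value=0, max_value=20), st.floats(min_value=0.1, max_value=10))
@settings(deadline=None, max_examples=50)
def test_piecewise_basis_continuity_and_sum(t, c):
    """f1 + f2 reconstructs t, and the basis is continuous at the knot."""
    f1, f2 = piecewise_basis(t, c)
    assert np.isclose(f1 + f2, t)
    lo = piecewise_basis(c - 1e-9, c)
    hi = piecewise_basis(c + 1e-9, c)
    assert abs((lo[0] + lo[1]) - (hi[0] + hi[1])) < 1e-8


def test_piecewise_basis_none_is_single_slope():
    f1, f2 = piecewise_basis(np.array([0.0, 3.0]), None)
    np.testing.assert_array_equal(f1, [0.0, 3.0])
    np.testing.assert_array_equal(f2, [0.0, 0.0])


def test_piecewise_basis_rejects_nonpositive_changepoint():
    with pytest.raises(ValueError):
        piecewise_basis(1.0, -2.0)


# ---------------------------------------------------------------------------
# fitting

def test_degenerate_data_recovers_least_squares():
    """Zero random effects and zero noise: beta is the exact LS line."""
    truth = GrowthTruth(re_sd=(0.0, 0.0), residual_sd=0.0)
    coh = simulate_cohort(single_group_design(20), truth, DropoutSpec(), seed=2)
    fit = fit_lmm(modelling_frame(coh.to_frames()[0]))
    assert abs(fit.beta["intercept"] - truth.intercept_mean) < 1e-5
    assert abs(fit.beta["slope1"] - truth.slope1) < 1e-6
    assert fit.sigma2 <= 1e-10  # variance floored at the bound


def test_matches_statsmodels_ml(seed1_frames):
    """Fixed cohort: beta and loglik agree with an independent ML mixed fit."""
    import statsmodels.formula.api as smf
    df, _ = seed1_frames
    fit = fit_lmm(df)
    sm_fit = smf.mixedlm("log_tv ~ t_weeks", df, groups=df["mouse_id"],
                         re_formula="~t_weeks").fit(reml=False)
    np.testing.assert_allclose(fit.beta.to_numpy(), sm_fit.fe_params.values, rtol=1e-4)
    assert abs(fit.loglik - sm_fit.llf) < 1e-4 * abs(sm_fit.llf)
    assert fit.converged
    assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params, abs=1e-10)


def test_profiled_beta_equals_closed_form_gls(seed1_frames, truth):
    """At fixed variance components the profiled beta is the GLS solution."""
    df, _ = seed1_frames
    design = build_design(df, LmmSpec())
    G = truth.cov_matrix()
    sigma2 = truth.residual_sd ** 2
    theta = theta_from_cov(G / sigma2)
    det = _profile_one_level(theta, _suffstats(design), 2, design.n_obs,
                             want_details=True)
    # direct GLS with per-mouse dense covariance
    XtVX = np.zeros((2, 2))
    XtVy = np.zeros(2)
    for i in range(design.n_mice):
        sl = slice(design.starts[i], design.starts[i + 1])
        Z = design.Z[sl]
        V = Z @ (G / sigma2) @ Z.T + np.eye(sl.stop - sl.start)
        Vi = np.linalg.inv(V)
        XtVX += design.X[sl].T @ Vi @ design.X[sl]
        XtVy += design.X[sl].T @ Vi @ design.y[sl]
    beta_gls = np.linalg.solve(XtVX, XtVy)
    np.testing.assert_allclose(det["beta"], beta_gls, rtol=1e-10)


def test_two_level_nests_one_level(seed1_frames):
    """PDX variances at (numerical) zero reproduce the one-level deviance."""
    df, _ = seed1_frames
    df = df.copy()
    df["pdx_id"] = "P1"
    spec1 = LmmSpec()
    design1 = build_design(df, spec1)
    theta = np.array([-0.9, 0.1, -1.1])
    dev1 = _profile_one_level(theta, _suffstats(design1), 2, design1.n_obs)
    design2 = build_design(df, LmmSpec(re_levels="two_level"))
    dev2 = _profile_two_level(np.concatenate([theta, [-14.0, -14.0]]),
                              design2, 2, design2.n_obs)
    assert abs(dev1 - dev2) < 1e-6


def test_slope_recovery_no_dropout(clean_cohort_frames):
    """500-mouse-scale recovery: slope within 2 SE of 0.39 without dropout."""
    df, _ = clean_cohort_frames
    fit = fit_lmm(df)
    se = np.sqrt(fit.vcov_beta.loc["slope1", "slope1"])
    assert fit.converged
    assert abs(fit.beta["slope1"] - TRUE_SLOPE) < 2 * se


def test_dose_offset_recovery(truth):
    """Known treatment slope offset is recovered within 2 SE."""
    from mctmodels.types import TrialDesign
    design = TrialDesign(n_pdx=1, mice_per_pdx=200, arm_labels=("vehicle", "dose20"))
    offset = -0.15
    t = GrowthTruth(slope_offsets={("all", "dose20"): (offset,)})
    coh = simulate_cohort(design, t, DropoutSpec(), seed=9)
    fit = fit_lmm(modelling_frame(coh.to_frames()[0]))
    tab = slope_table(fit)
    veh = tab.query("arm == 'vehicle'").iloc[0]
    trt = tab.query("arm == 'dose20'").iloc[0]
    diff = trt.estimate - veh.estimate
    se = np.sqrt(trt.se ** 2 + veh.se ** 2)
    assert abs(diff - offset) < 2 * se


# ---------------------------------------------------------------------------
# contrasts and slope tables

def test_identity_contrast_returns_coefficient(seed1_frames):
    df, _ = seed1_frames
    fit = fit_lmm(df)
    est, se = contrast(fit, [0.0, 1.0])
    assert est == pytest.approx(fit.beta["slope1"])
    assert se == pytest.approx(np.sqrt(fit.vcov_beta.loc["slope1", "slope1"]))
    tab = slope_table(fit)
    assert tab.iloc[0]["estimate"] == pytest.approx(fit.beta["slope1"])
    assert tab.iloc[0]["ci_hi"] == pytest.approx(
        tab.iloc[0]["estimate"] + 1.959963984540054 * tab.iloc[0]["se"])


def test_contrast_se_arithmetic(seed1_frames):
    """With identity vcov a (1,1) contrast has SE sqrt(2)."""
    df, _ = seed1_frames
    fit = fit_lmm(df)
    fit.vcov_beta = pd.DataFrame(np.eye(2), index=fit.beta.index, columns=fit.beta.index)
    _, se = contrast(fit, [1.0, 1.0])
    assert se == pytest.approx(np.sqrt(2.0))


# ---------------------------------------------------------------------------
# changepoint selection (needs follow-up beyond the candidate knots)

def long_followup_design(n_mice):
    from mctmodels.types import TrialDesign
    return TrialDesign(n_pdx=1, mice_per_pdx=n_mice, follow_up_days=63.0,
                       measurement_days=tuple(range(0, 64, 3)))


@pytest.fixture(scope="module")
def long_single_slope_frame():
    """Nearly-single-slope truth: a mild bend keeps all candidates estimable."""
    t = GrowthTruth(slope1=0.39, slope2=0.34, changepoint_weeks=4.0,
                    re_sd=(0.4, 0.15, 0.15), residual_sd=0.15)
    coh = simulate_cohort(long_followup_design(80), t, DropoutSpec(), seed=31)
    return modelling_frame(coh.to_frames()[0])


def test_changepoint_selection_finds_strong_knot():
    """Piecewise truth with a sharp bend at week 4 is selected by AIC."""
    t4 = GrowthTruth(slope1=0.6, slope2=0.05, changepoint_weeks=4.0,
                     re_sd=(0.4, 0.15, 0.15), residual_sd=0.15)
    hits = 0
    for rep in range(10):
        coh = simulate_cohort(long_followup_design(100), t4, DropoutSpec(), seed=500 + rep)
        best, table, _ = select_changepoint(modelling_frame(coh.to_frames()[0]))
        assert set(table["changepoint_weeks"]) == {3.0, 4.0, 5.0}
        hits += best == 4.0
    assert hits >= 9


def test_changepoint_selection_tie_rule_single_slope(long_single_slope_frame):
    """Single-slope truth: AIC differences are small but one value is returned."""
    best, table, _ = select_changepoint(long_single_slope_frame)
    assert best in {3.0, 4.0, 5.0}
    assert table["converged"].all()


def test_changepoint_selection_excludes_nonconverged(monkeypatch, long_single_slope_frame):
    real_fit = lmm_mod.fit_lmm

    def sabotage(frame, spec):
        fit = real_fit(frame, spec)
        if spec.changepoint_weeks == 3.0:
            fit.converged = False
            fit.aic = -1e9  # would win the argmin if not excluded
        return fit

    monkeypatch.setattr(lmm_mod, "fit_lmm", sabotage)
    best, table, _ = lmm_mod.select_changepoint(long_single_slope_frame)
    assert best != 3.0
    assert not table.loc[table.changepoint_weeks == 3.0, "converged"].iloc[0]


def test_rank_deficient_design_raises(seed1_frames):
    df, _ = seed1_frames
    df = df.copy()
    df["t_weeks"] = 0.0  # slope column identical to zero
    with pytest.raises(ValueError):
        fit_lmm(df)
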