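"""Tests of the joint shared-random-effects model of growth and death."""

import numpy as np
import pandas as pd
import pytest

from mctmodels import (DropoutSpec, GrowthTruth, JointModel, JointSpec, LmmSpec,
                       current_level, fit_lmm, hazard, marginal_loglik,
                       modelling_frame, simulate_cohort, weibull_ph_loglik)
from mctmodels.joint import JointParams
from mctmodels.lmm import build_design
from mctmodels.simstudy import cohort_frames
from mctmodels.simulate import true_cum_hazard

from conftest import single_group_design


@pytest.fixture(scope="module")
def seed1_joint(seed1_frames):
    df, surv = seed1_frames
    return JointModel(df, surv, JointSpec())


@pytest.fixture(scope="module")
def seed1_lmm(seed1_frames):
    return fit_lmm(seed1_frames[0])


def pack_at(jm, lf, eta=0.0, baseline=(0.3, 1.2)):
    P = JointParams(beta=lf.beta.to_numpy(),
                    chol_G=np.linalg.cholesky(lf.G + 1e-10 * np.eye(2)),
                    sigma2=lf.sigma2, baseline=np.asarray(baseline, float),
                    gamma=np.zeros(0), eta=eta)
    return jm.pack(P)


# ---------------------------------------------------------------------------
# current level and hazard

def test_current_level_components():
    beta = np.array([5.0, 0.4])
    parts = (np.array([1.0, 0.0]), np.array([0.0, 1.0]), np.zeros(2))
    assert current_level(beta, np.zeros(2), parts, 0.0) == pytest.approx(5.0)
    assert current_level(beta, np.zeros(2), parts, 3.0) == pytest.approx(5.0 + 1.2)
    # b = (0.1, 0.05) at t=2: mean + 0.1 + 0.05*2
    assert current_level(beta, np.array([0.1, 0.05]), parts, 2.0) == pytest.approx(
        5.0 + 0.8 + 0.1 + 0.1)


def test_hazard_constant_when_shape_one_and_eta_zero():
    parts = (np.array([1.0, 0.0]), np.array([0.0, 1.0]), np.zeros(2))
    for t in (0.5, 1.0, 3.0):
        h = hazard(t, np.zeros(0), np.zeros(2), np.array([5.0, 0.4]), parts,
                   (1.0, 4.0), np.zeros(0), 0.0)
        assert h == pytest.approx(1.0 / 4.0)


def test_hazard_proportionality_in_current_level():
    """Adding log(2)/eta to the level doubles the hazard."""
    parts = (np.array([1.0, 0.0]), np.array([0.0, 1.0]), np.zeros(2))
    beta = np.array([5.0, 0.4])
    eta = 0.7
    h1 = hazard(2.0, np.zeros(0), np.zeros(2), beta, parts, (1.5, 4.0), np.zeros(0), eta)
    h2 = hazard(2.0, np.zeros(0), np.array([np.log(2.0) / eta, 0.0]), beta, parts,
                (1.5, 4.0), np.zeros(0), eta)
    assert h2 == pytest.approx(2.0 * h1)


def test_cumulative_hazard_matches_closed_form_exponential_baseline():
    """Exponential baseline, linear m(t): H has a closed form; quadrature ~1e-8."""
    eta, a, bslope, scale = 0.9, 2.0, 0.5, 7.0
    drop = DropoutSpec(mnar_eta=eta, mnar_baseline_shape=1.0, mnar_baseline_scale=scale)
    for T in (0.5, 2.0, 4.0):
        H = true_cum_hazard(np.array([T]), np.array([a]), np.array([bslope]),
                            np.array([bslope]), None, drop)[0]
        closed = np.exp(eta * a) / (scale * eta * bslope) * (np.exp(eta * bslope * T) - 1.0)
        assert H == pytest.approx(closed, rel=1e-8)


# ---------------------------------------------------------------------------
# likelihood oracles

def test_factorization_at_eta_zero(seed1_frames, seed1_joint, seed1_lmm):
    """eta=0: joint loglik = LMM marginal loglik + Weibull PH loglik (1e-6)."""
    df, _ = seed1_frames
    jm, lf = seed1_joint, seed1_lmm
    x = pack_at(jm, lf, eta=0.0)
    ll_joint = jm.loglik(x)
    ll_lmm = marginal_loglik(build_design(df, LmmSpec()), lf.beta.to_numpy(),
                             lf.G + 1e-10 * np.eye(2), lf.sigma2)
    ll_wb = weibull_ph_loglik(np.array([0.3, 1.2]), jm.T, jm.delta)
    assert ll_joint == pytest.approx(ll_lmm + ll_wb, abs=1e-6)


def test_quadrature_matches_monte_carlo(seed1_frames, seed1_joint, seed1_lmm):
    """Per-mouse integrals vs plain Monte-Carlo over the prior (100,000 draws).

    The five mice with the fewest observations are used: their posteriors are
    widest, so prior sampling has high effective sample size.
    """
    jm, lf = seed1_joint, seed1_lmm
    x = pack_at(jm, lf, eta=1.0)
    P = jm.unpack(x)
    ll = jm.loglik_by_mouse(x)
    few = np.argsort(jm.n_i)[:5]
    rng = np.random.default_rng(12345)
    L = np.linalg.cholesky(P.G)
    draws = rng.standard_normal((100_000, 2)) @ L.T
    for i in few:
        rows = jm.row_mouse == i
        y_i, Z_i = jm.y[rows], jm.Z[rows]
        mu_i = jm.X[rows] @ P.beta
        a = P.beta[0] + draws[:, 0]
        slope = P.beta[1] + draws[:, 1]
        resid = y_i[None, :] - mu_i[None, :] - draws @ Z_i.T
        log_long = (-0.5 * np.log(2 * np.pi * P.sigma2) * rows.sum()
                    - 0.5 * (resid ** 2).sum(axis=1) / P.sigma2)
        drop = DropoutSpec(mnar_eta=P.eta, mnar_baseline_shape=np.exp(P.baseline[0]),
                           mnar_baseline_scale=np.exp(P.baseline[1]))
        H = true_cum_hazard(np.full(draws.shape[0], jm.T[i]), a, slope, slope, None, drop)
        log_surv = -H
        if jm.delta[i]:
            m_T = a + slope * jm.T[i]
            log_surv = log_surv + (np.log(np.exp(P.baseline[0]) / np.exp(P.baseline[1]))
                                   + (np.exp(P.baseline[0]) - 1.0)
                                   * np.log(jm.T[i] / np.exp(P.baseline[1]))
                                   + P.eta * m_T)
        vals = log_long + log_surv
        mx = vals.max()
        ll_mc = mx + np.log(np.mean(np.exp(vals - mx)))
        assert ll[i] == pytest.approx(ll_mc, abs=1e-3 * max(1.0, abs(ll_mc)))


def test_node_doubling_stability(seed1_frames):
    """Doubling quadrature nodes (9 -> 15) barely moves the fitted loglik."""
    df, surv = seed1_frames
    jm9 = JointModel(df, surv, JointSpec(nodes=9))
    fit = jm9.fit()
    jm15 = JointModel(df, surv, JointSpec(nodes=15))
    ll15 = jm15.loglik(fit.x)
    assert abs(ll15 - jm9.loglik(fit.x)) < 1e-4 * max(1.0, abs(ll15))


def test_analytic_gradient_matches_finite_differences(seed1_joint, seed1_lmm):
    jm = seed1_joint
    x = pack_at(jm, seed1_lmm, eta=0.6)
    x[0] += 0.03
    jm.freeze_nodes(x, with_survival=True)
    _, g = jm.loglik_grad(x)
    for i in range(x.size):
        h = 1e-6 * max(1.0, abs(x[i]))
        e = np.zeros_like(x); e[i] = h
        fd = (jm.loglik_grad(x + e, want_grad=False)
              - jm.loglik_grad(x - e, want_grad=False)) / (2 * h)
        assert g[i] == pytest.approx(fd, rel=2e-4, abs=1e-5 * max(1.0, abs(fd)))


def test_empty_dataset_loglik_is_zero():
    jm = JointModel(pd.DataFrame(), pd.DataFrame(), JointSpec())
    assert jm.loglik(np.zeros(1)) == 0.0


# ---------------------------------------------------------------------------
# fitting behavior

def test_fit_recovers_truth_under_correct_mnar(seed1_frames):
    """Slope and association recovered within 2 SE on the seed-1 MNAR cohort."""
    df, surv = seed1_frames
    fit = JointModel(df, surv, JointSpec()).fit()
    assert fit.converged
    slope_se = np.sqrt(fit.vcov_beta.loc["slope1", "slope1"])
    assert abs(fit.beta["slope1"] - 0.39) < 2 * slope_se
    assert abs(fit.eta - 1.0) < 2 * fit.eta_se


def test_eta_ci_covers_zero_under_independent_deaths(truth):
    """With eta_true=0 the 95% Wald CI for eta covers 0 at the nominal rate."""
    drop = DropoutSpec(mnar_eta=0.0, mnar_baseline_shape=1.5, mnar_baseline_scale=5.5)
    hits, total = 0, 0
    for rep in range(25):
        coh = simulate_cohort(single_group_design(100), truth, drop, seed=900 + rep)
        df, surv = cohort_frames(coh)
        fit = JointModel(df, surv, JointSpec()).fit()
        if not fit.converged:
            continue
        total += 1
        hits += abs(fit.eta) < 1.959963984540054 * fit.eta_se
    assert total >= 20
    assert hits / total >= 0.80  # binomial floor for 95% nominal at this n


def test_survival_only_mice_enter_survival_part(seed1_frames):
    """Mice with zero longitudinal rows still contribute survival factors."""
    df, surv = seed1_frames
    jm_full = JointModel(df, surv, JointSpec())
    drop_mouse = df["mouse_id"].iloc[0]
    df_red = df[df["mouse_id"] != drop_mouse]
    jm_red = JointModel(df_red, surv, JointSpec())
    assert jm_red.M == jm_full.M
    assert jm_red.n_i[list(jm_red.mouse_ids).index(drop_mouse)] == 0
    x = pack_at(jm_red, fit_lmm(df_red), eta=0.5)
    ll = jm_red.loglik_by_mouse(x)
    assert np.all(np.isfinite(ll))


def test_piecewise_baseline_runs(seed1_frames):
    """The piecewise-constant baseline variant fits and returns finite results."""
    df, surv = seed1_frames
    fit = JointModel(df, surv, JointSpec(baseline="piecewise", nodes=7)).fit()
    assert np.isfinite(fit.loglik)
    assert np.isfinite(fit.beta["slope1"])


def test_joint_spec_validation():
    with pytest.raises(ValueError):
        JointSpec(lmm=LmmSpec(re_levels="two_level"))
    with pytest.raises(ValueError):
        JointSpec(nodes=2)
    with pytest.raises(ValueError):
        JointSpec(baseline="spline")
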