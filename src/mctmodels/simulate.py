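"""Synthetic MCT cohort generator with competing MAR and MNAR dropout.

Log tumor volume grows (piecewise) linearly in time with correlated random
intercept/slope(s) per mouse (optionally nested in PDX).  Two dropout
mechanisms compete:

* MAR sacrifice — a mouse is euthanized at the first scheduled measurement
  whose *observed* (noisy) volume reaches the ethical threshold.  Because the
  decision is a function of recorded data only, this dropout is missing at
  random.
* MNAR death — a latent proportional-hazards death process
  ``h_i(t) = h0(t) exp(eta * m_i(t))`` driven by the *true* current log
  volume ``m_i(t)`` (fixed + random effects, no measurement noise).  Dropout
  then depends on unobserved quantities: missing not at random.  This is
  exactly the association structure of the joint shared-random-effects model,
  so a joint fit is correctly specified under pure MNAR dropout.

The realized death is the earlier of the two, ties resolved in favor of MAR
(the sacrifice is decided at the measurement itself).
"""

from __future__ import annotations

import logging
from dataclasses import replace
from functools import lru_cache

import numpy as np
from scipy.special import roots_jacobi

from .types import (CAUSE_MAR, CAUSE_MNAR, CAUSE_NONE, DAYS_PER_WEEK, Cohort,
                    DropoutSpec, GrowthTruth, MouseRecord, TrialDesign)

logger = logging.getLogger(__name__)

_GL_X, _GL_W = np.polynomial.legendre.leggauss(15)

#: cap on hazard linear predictors before exponentiation
_EXP_CLIP = 50.0


@lru_cache(maxsize=64)
def _jacobi_rule(shape: float):
    """15-point Gauss-Jacobi rule with weight s**(shape-1) on the unit interval.

    Absorbs the Weibull baseline's endpoint singularity at t=0 so the
    remaining integrand is smooth; reduces to Gauss-Legendre at shape=1.
    """
    x, w = roots_jacobi(15, 0.0, shape - 1.0)
    return x, w


class CalibrationError(RuntimeError):
    """Raised when a target dropout proportion cannot be reached."""


# ---------------------------------------------------------------------------
# allocation

def allocate(design: TrialDesign, rng: np.random.Generator | None = None):
    """Per-mouse (pdx_id, subgroup, arm) allocation with randomization within PDX.

    Arms are assigned in balanced blocks within each PDX; when ``rng`` is
    given the within-PDX assignment order is shuffled (randomized), otherwise
    it is cyclic and deterministic.
    """
    pdx_ids, subgroups, arms = [], [], []
    counts = design.mice_counts()
    n_arms = len(design.arm_labels)
    for p in range(design.n_pdx):
        pdx = f"PDX{p + 1:03d}"
        sub = design.subgroup_of_pdx(p)
        assign = [design.arm_labels[k % n_arms] for k in range(counts[p])]
        if rng is not None:
            rng.shuffle(assign)
        pdx_ids += [pdx] * counts[p]
        subgroups += [sub] * counts[p]
        arms += assign
    return pdx_ids, subgroups, arms


# ---------------------------------------------------------------------------
# latent hazard machinery

def _segment_cumhaz(t0, t1, a, slope, eta, shape, scale, from_zero=False):
    """Integral of h0(s)*exp(eta*(a + slope*s)) over (t0, t1], vectorized.

    15-point quadrature per segment; ``t0``/``t1``/``a``/``slope`` are
    broadcastable arrays (times in weeks).  Segments starting at 0 use a
    Gauss-Jacobi rule matched to the Weibull singularity s**(shape-1), which
    makes the quadrature exact up to the smoothness of exp(eta*m(s));
    interior segments use Gauss-Legendre.
    """
    t0, t1 = np.broadcast_arrays(np.asarray(t0, float), np.asarray(t1, float))
    a = np.asarray(a, float)
    slope = np.asarray(slope, float)
    if from_zero:
        x, w = _jacobi_rule(float(shape))
        half = 0.5 * t1
        s = half[..., None] * (1.0 + x)
        lin = np.clip(eta * (a[..., None] + slope[..., None] * s), -_EXP_CLIP, _EXP_CLIP)
        pref = (shape / scale**shape) * np.power(np.maximum(half, 0.0), shape)
        vals = pref * (np.exp(lin) * w).sum(axis=-1)
    else:
        half = 0.5 * (t1 - t0)
        mid = 0.5 * (t1 + t0)
        s = mid[..., None] + half[..., None] * _GL_X  # (..., 15)
        base = (shape / scale) * np.power(np.maximum(s, 1e-300) / scale, shape - 1.0)
        lin = np.clip(eta * (a[..., None] + slope[..., None] * s), -_EXP_CLIP, _EXP_CLIP)
        vals = (base * np.exp(lin) * _GL_W).sum(axis=-1) * half
    return np.where(t1 > t0, vals, 0.0)


def true_cum_hazard(t, a, s1, s2, changepoint, dropout: DropoutSpec):
    """Cumulative MNAR hazard H(t) = int_0^t h0(s) exp(eta*m(s)) ds.

    ``m(s) = a + s1*min(s,c) + s2*max(s-c,0)`` per mouse; all of ``t``, ``a``,
    ``s1``, ``s2`` broadcast.  Piecewise trajectories are integrated exactly
    segment by segment so the quadrature never straddles the changepoint.
    """
    if not dropout.mnar_enabled:
        return np.zeros(np.broadcast(np.asarray(t), np.asarray(a)).shape)
    eta, shape, scale = dropout.mnar_eta, dropout.mnar_baseline_shape, dropout.mnar_baseline_scale
    t = np.asarray(t, float)
    if changepoint is None:
        return _segment_cumhaz(0.0, t, a, s1, eta, shape, scale, from_zero=True)
    c = float(changepoint)
    H1 = _segment_cumhaz(0.0, np.minimum(t, c), a, s1, eta, shape, scale, from_zero=True)
    # on (c, t]: m(s) = a + s1*c - s2*c + s2*s
    a2 = np.asarray(a) + (np.asarray(s1) - np.asarray(s2)) * c
    H2 = _segment_cumhaz(c, np.maximum(t, c), a2, s2, eta, shape, scale)
    return H1 + H2


def _mnar_death_weeks(E, a, s1, s2, changepoint, dropout: DropoutSpec,
                      follow_up_weeks: float, tol: float = 1e-9):
    """Solve H(T) = E per mouse by bracketed bisection on (0, follow-up].

    Returns death times in weeks, ``inf`` where the mouse outlives follow-up.
    """
    E = np.asarray(E, float)
    out = np.full(E.shape, np.inf)
    if not dropout.mnar_enabled:
        return out
    H_end = true_cum_hazard(follow_up_weeks, a, s1, s2, changepoint, dropout)
    hit = H_end >= E
    if not np.any(hit):
        return out
    lo = np.zeros(E.shape)
    hi = np.full(E.shape, follow_up_weeks)
    n_iter = max(1, int(np.ceil(np.log2(follow_up_weeks / tol))))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        below = true_cum_hazard(mid, a, s1, s2, changepoint, dropout) < E
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    out[hit] = (0.5 * (lo + hi))[hit]
    return out


def sample_mnar_death_time(random_effects, covariate_row, truth: GrowthTruth,
                           dropout: DropoutSpec, rng: np.random.Generator,
                           follow_up_days: float = 63.0):
    """Draw one MNAR death time (in days) from the shared-random-effects hazard.

    Inverse-CDF sampling: solve ``H(T) = E`` with ``E ~ Exp(1)`` and
    ``H(t) = int_0^t h0(s) exp(eta * m_i(s)) ds`` by quadrature plus bracketed
    bisection.  ``covariate_row`` is a ``(subgroup, arm)`` pair selecting the
    fixed-effect slope cell.  Returns ``None`` if the drawn death falls beyond
    ``follow_up_days``.
    """
    b = np.asarray(random_effects, float)
    subgroup, arm = covariate_row
    s1, s2 = truth.slopes_for(subgroup, arm)
    a = truth.intercept_mean + b[0]
    s1 += b[1]
    s2 += b[2] if truth.changepoint_weeks is not None else b[1]
    E = rng.exponential()
    T = _mnar_death_weeks(np.array([E]), np.array([a]), np.array([s1]), np.array([s2]),
                          truth.changepoint_weeks, dropout,
                          follow_up_weeks=follow_up_days / DAYS_PER_WEEK)[0]
    return None if np.isinf(T) else float(T * DAYS_PER_WEEK)


# ---------------------------------------------------------------------------
# MAR sacrifice

def apply_mar_sacrifice(obs_days, obs_tv_mm3, threshold_mm3: float):
    """First measurement day whose observed volume reaches the threshold.

    Returns ``(death_day, cause)``; the triggering measurement itself remains
    observed (the sacrifice is decided from it).  ``(None, None)`` if the
    threshold is never crossed.
    """
    days = np.asarray(obs_days, float)
    vols = np.asarray(obs_tv_mm3, float)
    crossed = vols >= threshold_mm3
    if not crossed.any():
        return None, None
    return float(days[int(np.argmax(crossed))]), CAUSE_MAR


# ---------------------------------------------------------------------------
# cohort simulation

def _draw_latents(design: TrialDesign, truth: GrowthTruth, rng: np.random.Generator):
    """All random draws for a cohort, in fixed order (determinism contract)."""
    q = truth.q
    pdx_ids, subgroups, arms = allocate(design)
    M = len(pdx_ids)
    G = truth.cov_matrix()
    if np.any(np.linalg.eigvalsh(G) < -1e-12):
        raise ValueError("random-effect covariance must be positive semi-definite")
    L = np.linalg.cholesky(G + 1e-14 * np.eye(q)) if np.any(G) else np.zeros((q, q))
    pdx_sd = np.sqrt(np.diag(truth.pdx_cov_matrix()))
    pdx_re = rng.standard_normal((design.n_pdx, q)) * pdx_sd
    mouse_re = rng.standard_normal((M, q)) @ L.T
    E = rng.exponential(size=M)
    noise = rng.standard_normal((M, len(design.measurement_days))) * truth.residual_sd
    pdx_index = np.repeat(np.arange(design.n_pdx), design.mice_counts())
    b_total = mouse_re + pdx_re[pdx_index]
    return pdx_ids, subgroups, arms, b_total, E, noise


def simulate_cohort(design: TrialDesign, truth: GrowthTruth, dropout: DropoutSpec,
                    seed: int) -> Cohort:
    """Simulate one MCT cohort under competing MAR/MNAR dropout.

    Per mouse: draw PDX- then mouse-level random effects, compute the true
    log-volume path, sample an MNAR death time from the shared-random-effects
    hazard, generate noisy observations on the measurement grid, scan for MAR
    sacrifice on the observed series, and truncate at the realized (earlier)
    death.  Fully reproducible given the seed.
    """
    rng = np.random.default_rng(seed)
    pdx_ids, subgroups, arms, b, E, noise = _draw_latents(design, truth, rng)
    M = len(pdx_ids)
    days = np.asarray(design.measurement_days, float)
    t = days / DAYS_PER_WEEK
    c = truth.changepoint_weeks

    s1 = np.empty(M)
    s2 = np.empty(M)
    for i, (sg, arm) in enumerate(zip(subgroups, arms)):
        s1[i], s2[i] = truth.slopes_for(sg, arm)
    a = truth.intercept_mean + b[:, 0]
    s1 = s1 + b[:, 1]
    s2 = s2 + (b[:, 2] if c is not None else b[:, 1])

    if c is None:
        m = a[:, None] + s1[:, None] * t
    else:
        m = a[:, None] + s1[:, None] * np.minimum(t, c) + s2[:, None] * np.maximum(t - c, 0.0)
    y = m + noise  # observed log volumes, full schedule
    vols = np.exp(y)

    T_mnar_days = _mnar_death_weeks(E, a, s1, s2, c, dropout, design.follow_up_weeks) * DAYS_PER_WEEK

    records = []
    for i in range(M):
        mar_day, _ = (apply_mar_sacrifice(days, vols[i], dropout.ethical_threshold_mm3)
                      if dropout.mar_enabled else (None, None))
        t_mnar = T_mnar_days[i]
        death_day, cause = None, CAUSE_NONE
        if mar_day is not None and mar_day <= t_mnar:  # tie -> MAR
            death_day, cause = mar_day, CAUSE_MAR
        elif np.isfinite(t_mnar):
            death_day, cause = float(t_mnar), CAUSE_MNAR
        keep = days <= (death_day + 1e-9 if death_day is not None else np.inf)
        records.append(MouseRecord(
            mouse_id=f"M{i + 1:05d}", pdx_id=pdx_ids[i], subgroup=subgroups[i],
            arm=arms[i], obs_days=days[keep], obs_tv_mm3=vols[i, keep],
            death_day=death_day, death_cause=cause, latent_re=b[i].copy()))
    return Cohort(records=records, design=design, truth=truth, dropout=dropout, seed=seed)


# ---------------------------------------------------------------------------
# dropout calibration

def _realized_proportions(days, follow_up_weeks, a, s1, s2, c, E, log_vols,
                          dropout: DropoutSpec, T_mnar_days=None):
    """Realized (p_mnar, p_mar) on fixed latent draws for one DropoutSpec."""
    if T_mnar_days is None:
        T_mnar_days = _mnar_death_weeks(E, a, s1, s2, c, dropout, follow_up_weeks) * DAYS_PER_WEEK
    if dropout.mar_enabled:
        crossed = log_vols >= np.log(dropout.ethical_threshold_mm3)
        any_cross = crossed.any(axis=1)
        first = np.argmax(crossed, axis=1)
        mar_day = np.where(any_cross, days[first], np.inf)
    else:
        mar_day = np.full(len(E), np.inf)
    is_mar = (mar_day <= T_mnar_days) & np.isfinite(mar_day)
    is_mnar = ~is_mar & np.isfinite(T_mnar_days)
    return float(np.mean(is_mnar)), float(np.mean(is_mar)), T_mnar_days


def calibrate_dropout(design: TrialDesign, truth: GrowthTruth,
                      target_prop_mnar: float, target_prop_mar: float, seed: int,
                      mnar_eta: float = 1.0, mnar_baseline_shape: float = 1.5,
                      n_calib: int = 10_000, tol_pp: float = 0.01,
                      n_rounds: int = 3) -> DropoutSpec:
    """Calibrate the MNAR baseline scale and MAR threshold to target proportions.

    A single large calibration cohort (latent trajectories, noisy series and
    unit-exponential draws) is simulated once at the given seed; bisection then
    tunes (i) the Weibull baseline scale until the realized MNAR death
    proportion matches ``target_prop_mnar``, then (ii) the ethical threshold
    until the realized MAR proportion matches ``target_prop_mar`` under the
    calibrated MNAR hazard.  Because the two mechanisms compete, the pair of
    bisections is alternated for ``n_rounds`` rounds.  Raises
    :class:`CalibrationError` when a target cannot be bracketed.
    """
    if not 0 <= target_prop_mnar <= 1 or not 0 <= target_prop_mar <= 1:
        raise ValueError("targets must lie in [0, 1]")
    if target_prop_mnar + target_prop_mar > 1:
        raise ValueError("targets must sum to <= 1")

    rng = np.random.default_rng(seed)
    # calibration cohort: tile the design's cell allocation up to n_calib mice,
    # with PDX effects drawn independently per mouse (marginal distribution)
    _, subgroups, arms = allocate(design)
    idx = np.resize(np.arange(len(subgroups)), n_calib)
    q = truth.q
    G = truth.cov_matrix() + truth.pdx_cov_matrix()
    L = np.linalg.cholesky(G + 1e-14 * np.eye(q)) if np.any(G) else np.zeros((q, q))
    b = rng.standard_normal((n_calib, q)) @ L.T
    E = rng.exponential(size=n_calib)
    days = np.asarray(design.measurement_days, float)
    t = days / DAYS_PER_WEEK
    c = truth.changepoint_weeks
    s1 = np.empty(n_calib)
    s2 = np.empty(n_calib)
    for j, i in enumerate(idx):
        s1[j], s2[j] = truth.slopes_for(subgroups[i], arms[i])
    a = truth.intercept_mean + b[:, 0]
    s1 = s1 + b[:, 1]
    s2 = s2 + (b[:, 2] if c is not None else b[:, 1])
    if c is None:
        m = a[:, None] + s1[:, None] * t
    else:
        m = a[:, None] + s1[:, None] * np.minimum(t, c) + s2[:, None] * np.maximum(t - c, 0.0)
    log_vols = m + rng.standard_normal((n_calib, len(days))) * truth.residual_sd
    fw = design.follow_up_weeks

    def props(spec, T_cache=None):
        return _realized_proportions(days, fw, a, s1, s2, c, E, log_vols, spec, T_cache)

    scale = np.inf
    threshold = np.inf
    log_scale_lo, log_scale_hi = np.log(1e-4), np.log(1e8)
    vol_lo = float(np.exp(log_vols.min()))
    vol_hi = float(np.exp(log_vols.max())) * 2.0

    for _ in range(n_rounds):
        if target_prop_mnar > 0:
            def p_mnar_at(ls):
                spec = DropoutSpec(ethical_threshold_mm3=threshold, mnar_eta=mnar_eta,
                                   mnar_baseline_shape=mnar_baseline_shape,
                                   mnar_baseline_scale=float(np.exp(ls)))
                return props(spec)[0]
            lo, hi = log_scale_lo, log_scale_hi
            if p_mnar_at(lo) < target_prop_mnar:
                raise CalibrationError("MNAR target exceeds maximum achievable proportion")
            if p_mnar_at(hi) > target_prop_mnar:
                raise CalibrationError("MNAR target below minimum achievable proportion")
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                if p_mnar_at(mid) >= target_prop_mnar:
                    lo = mid
                else:
                    hi = mid
            scale = float(np.exp(0.5 * (lo + hi)))
        spec_mnar = DropoutSpec(ethical_threshold_mm3=np.inf, mnar_eta=mnar_eta,
                                mnar_baseline_shape=mnar_baseline_shape,
                                mnar_baseline_scale=scale)
        _, _, T_cache = props(spec_mnar)
        if target_prop_mar > 0:
            def p_mar_at(log_thr):
                spec = DropoutSpec(ethical_threshold_mm3=float(np.exp(log_thr)),
                                   mnar_eta=mnar_eta,
                                   mnar_baseline_shape=mnar_baseline_shape,
                                   mnar_baseline_scale=scale)
                return props(spec, T_cache)[1]
            lo, hi = np.log(vol_lo) - 0.1, np.log(vol_hi)
            if p_mar_at(lo) < target_prop_mar:
                raise CalibrationError(
                    "MAR target exceeds the fraction of trajectories that can be sacrificed")
            for _ in range(50):
                mid = 0.5 * (lo + hi)
                if p_mar_at(mid) >= target_prop_mar:
                    lo = mid
                else:
                    hi = mid
            threshold = float(np.exp(0.5 * (lo + hi)))
        if target_prop_mnar == 0 and target_prop_mar == 0:
            break

    final = DropoutSpec(ethical_threshold_mm3=threshold, mnar_eta=mnar_eta,
                        mnar_baseline_shape=mnar_baseline_shape,
                        mnar_baseline_scale=scale,
                        target_prop_mnar=target_prop_mnar, target_prop_mar=target_prop_mar)
    p_mnar, p_mar, _ = props(final)
    if abs(p_mnar - target_prop_mnar) > tol_pp or abs(p_mar - target_prop_mar) > tol_pp:
        raise CalibrationError(
            f"calibration failed: realized ({p_mnar:.3f}, {p_mar:.3f}) vs "
            f"targets ({target_prop_mnar}, {target_prop_mar})")
    return final


# ---------------------------------------------------------------------------
# MAR -> MNAR perturbation

def perturb_to_mnar(cohort: Cohort, mask_threshold_mm3: float) -> Cohort:
    """Mask every observation at or above a sub-ethical volume threshold.

    Death days and causes are retained unchanged, so the dropout process of
    the perturbed cohort can no longer be explained by the remaining observed
    data: the mechanism becomes MNAR by construction.  Mice whose every
    observation is masked are kept (flagged ``all_masked``); they still carry
    survival information.
    """
    if (cohort.dropout.mar_enabled
            and mask_threshold_mm3 >= cohort.dropout.ethical_threshold_mm3):
        raise ValueError("mask threshold must lie below the ethical threshold")
    new_records = []
    n_empty = 0
    for r in cohort.records:
        keep = r.obs_tv_mm3 < mask_threshold_mm3
        empty = not keep.any()
        n_empty += empty
        new_records.append(replace(
            r, obs_days=r.obs_days[keep], obs_tv_mm3=r.obs_tv_mm3[keep],
            all_masked=empty))
    if n_empty:
        logger.warning("perturbation left %d mice with zero observations", n_empty)
    return Cohort(records=new_records, design=cohort.design, truth=cohort.truth,
                  dropout=cohort.dropout, seed=cohort.seed)
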