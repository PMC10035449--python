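"""Joint shared-random-effects model of tumor growth and death.

The longitudinal submodel is the one-level linear mixed model of
:mod:`mctmodels.lmm`; the survival submodel is a proportional-hazards model

    h_i(t) = h0(t) * exp(gamma' X_Ei + eta * m_i(t)),

where ``m_i(t) = X_i(t)' beta + b_i' z(t)`` is the *current true level* of
log tumor volume (fixed plus random effects, no residual noise) and ``eta``
is the association parameter between tumor burden and the death hazard.
Both submodels share the random effects ``b_i ~ N(0, G)``, which makes the
model a valid likelihood under missing-not-at-random dropout generated by
this very hazard.

Estimation notes
----------------
The marginal likelihood integrates the random effects out with adaptive
Gauss-Hermite quadrature.  Evaluating the model as a standalone function
re-centers the grid per mouse at the posterior mode of ``b`` (Newton on the
log-concave integrand) and re-scales by the curvature there.  During
optimization the centers are *frozen* between refreshes (initially at the
longitudinal posterior, then re-centered once at the interim estimate with
the survival contribution included); with fixed nodes the objective has an
exact analytic gradient, which drives a quasi-Newton search and a
finite-difference-of-gradient observed information matrix.

Cumulative hazards use 15-point quadrature per trajectory segment (split at
the changepoint).  The segment starting at t=0 uses a Gauss-Jacobi rule
whose weight absorbs the Weibull baseline's s**(shape-1) endpoint
singularity, making the rule exact up to the smoothness of the exponential
factor; interior segments use Gauss-Legendre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import norm

from .lmm import (LmmDesign, LmmSpec, build_design, fit_lmm, piecewise_basis,
                  theta_from_cov, chol_from_theta)
from .simulate import _jacobi_rule

_GL_X, _GL_W = np.polynomial.legendre.leggauss(15)
_EXP_CLIP = 50.0
_Z975 = float(norm.ppf(0.975))
_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class JointSpec:
    """Configuration of the joint model.

    ``nodes`` is the number of Gauss-Hermite nodes per random-effect
    dimension; ``adaptive`` re-centers the quadrature per mouse.  The
    baseline hazard is Weibull by default, or piecewise-constant on
    ``n_baseline_pieces`` equal-quantile intervals of the event times.
    """

    lmm: LmmSpec = LmmSpec()
    baseline: str = "weibull"  # "weibull" | "piecewise"
    n_baseline_pieces: int = 5
    survival_covariates: bool = False
    nodes: int = 9
    adaptive: bool = True

    def __post_init__(self) -> None:
        if self.lmm.re_levels != "one_level":
            raise ValueError("the joint model supports one-level random effects only")
        if self.nodes < 3:
            raise ValueError("need at least 3 quadrature nodes per dimension")
        if self.baseline not in ("weibull", "piecewise"):
            raise ValueError("baseline must be 'weibull' or 'piecewise'")


def current_level(beta, random_effects, x_parts, t_weeks, changepoint_weeks=None):
    """Current true level m_i(t): fixed-effect mean plus random effects.

    ``x_parts = (d0, d1, d2)`` are the time-constant components of the fixed
    design row, so that ``X_i(t) = d0 + f1(t) d1 + f2(t) d2``.  No residual
    noise enters: this is the latent biomarker level driving the hazard.
    """
    d0, d1, d2 = (np.asarray(v, float) for v in x_parts)
    b = np.asarray(random_effects, float)
    f1, f2 = piecewise_basis(t_weeks, changepoint_weeks)
    beta = np.asarray(beta, float)
    fixed = d0 @ beta + f1 * (d1 @ beta) + f2 * (d2 @ beta)
    z = b[0] + f1 * b[1] + (f2 * b[2] if b.size > 2 else 0.0)
    return fixed + z


def weibull_log_h0(t, shape, scale):
    t = np.maximum(np.asarray(t, float), 1e-12)
    return np.log(shape / scale) + (shape - 1.0) * np.log(t / scale)


def hazard(t, x_e_row, random_effects, beta, x_parts, params, gamma, eta,
           changepoint_weeks=None):
    """Hazard h0(t) exp(gamma'X_E + eta m_i(t)) with Weibull baseline.

    ``params = (shape, scale)``.  The linear predictor is clipped at +/-50
    before exponentiation as an overflow guard.
    """
    shape, scale = params
    m = current_level(beta, random_effects, x_parts, t, changepoint_weeks)
    lin = np.asarray(x_e_row, float) @ np.asarray(gamma, float) if np.size(gamma) else 0.0
    expo = np.clip(lin + eta * m, -_EXP_CLIP, _EXP_CLIP)
    return np.exp(weibull_log_h0(t, shape, scale) + expo)


# ---------------------------------------------------------------------------
# Weibull proportional-hazards fit (initialization and factorization checks)

def weibull_ph_loglik(params, T, delta, X_E=None):
    """Log-likelihood of a Weibull PH model; params = (log_shape, log_scale, gamma...)."""
    shape, scale = np.exp(params[0]), np.exp(params[1])
    gamma = np.asarray(params[2:], float)
    lin = X_E @ gamma if X_E is not None and gamma.size else np.zeros_like(T)
    lin = np.clip(lin, -_EXP_CLIP, _EXP_CLIP)
    H0 = np.power(np.maximum(T, 1e-12) / scale, shape)
    ll = delta * (weibull_log_h0(T, shape, scale) + lin) - np.exp(lin) * H0
    return float(ll.sum())


def fit_weibull_ph(T, delta, X_E=None):
    """ML fit of the Weibull PH model; returns (log_shape, log_scale, gamma...)."""
    pE = 0 if X_E is None else X_E.shape[1]
    x0 = np.zeros(2 + pE)
    x0[1] = np.log(max(np.median(T), 0.5)) + (1.0 if delta.mean() < 0.5 else 0.0)
    bounds = [(-3, 3), (-10, 15)] + [(-20, 20)] * pE
    res = optimize.minimize(lambda p: -weibull_ph_loglik(p, T, delta, X_E), x0,
                            method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 200, "ftol": 1e-12})
    return res.x


# ---------------------------------------------------------------------------

@dataclass
class JointParams:
    beta: np.ndarray
    chol_G: np.ndarray          # lower Cholesky factor of G
    sigma2: float
    baseline: np.ndarray        # (log_shape, log_scale) or log piecewise levels
    gamma: np.ndarray
    eta: float

    @property
    def G(self) -> np.ndarray:
        return self.chol_G @ self.chol_G.T


class JointModel:
    """Prepared joint-likelihood evaluator for one dataset.

    ``df`` is the long modelling frame (mouse_id, t_weeks, log_tv, plus
    design labels); ``surv`` has one row per mouse with mouse_id, subgroup,
    arm, event_weeks and event (1 = death of any cause, 0 = administrative
    censoring at the end of follow-up).  Mice present in ``surv`` but absent
    from ``df`` contribute survival factors only, with the random-effect
    integral taken over the prior.
    """

    def __init__(self, df: pd.DataFrame, surv: pd.DataFrame, spec: JointSpec = JointSpec()):
        self.spec = spec
        if len(surv) == 0 and len(df) == 0:
            self.M = 0
            self.design = None
            return
        if len(df) == 0:
            raise ValueError("empty longitudinal data frame; need design labels")
        self.design = build_design(df, spec.lmm)
        surv = surv.sort_values("mouse_id", kind="mergesort").reset_index(drop=True)
        self.surv = surv
        self.mouse_ids = surv["mouse_id"].to_numpy()
        self.M = len(surv)
        self.q = spec.lmm.q
        self.c = spec.lmm.changepoint_weeks
        self.T = surv["event_weeks"].to_numpy(dtype=float)
        self.delta = surv["event"].to_numpy(dtype=float)

        d = self.design
        if not set(d.mouse_ids).issubset(set(self.mouse_ids)):
            raise ValueError("every measured mouse must appear in the survival table")
        pos = {m: i for i, m in enumerate(self.mouse_ids)}
        self.row_mouse = np.array([pos[m] for m in d.mouse_ids])[d.mouse_index]
        self.y, self.t, self.X, self.Z = d.y, d.t, d.X, d.Z
        self.p = self.X.shape[1]
        q = self.q
        self.n_i = np.bincount(self.row_mouse, minlength=self.M).astype(float)
        self.ZZ = np.zeros((self.M, q, q))
        for a in range(q):
            for b in range(a + 1):
                v = np.bincount(self.row_mouse, weights=self.Z[:, a] * self.Z[:, b],
                                minlength=self.M)
                self.ZZ[:, a, b] = self.ZZ[:, b, a] = v
        self.XZ = np.zeros((self.M, self.p, q))
        for a in range(self.p):
            for b in range(q):
                self.XZ[:, a, b] = np.bincount(
                    self.row_mouse, weights=self.X[:, a] * self.Z[:, b], minlength=self.M)

        sub = surv["subgroup"].to_numpy() if "subgroup" in surv else np.array(["all"] * self.M)
        arm = surv["arm"].to_numpy() if "arm" in surv else np.array(["all"] * self.M)
        self.D = self._design_parts(d, sub, arm)

        if spec.survival_covariates and len(d.cells) > 1:
            cols, names = [], []
            for (s, a) in d.cells[1:]:
                cols.append(((sub == s) & (arm == a)).astype(float))
                names.append(f"gamma[{s}:{a}]")
            self.X_E = np.column_stack(cols)
            self.gamma_names = names
        else:
            self.X_E = np.zeros((self.M, 0))
            self.gamma_names = []

        self.f1T, self.f2T = piecewise_basis(self.T, self.c)
        self.zT = np.stack([np.ones(self.M), self.f1T, self.f2T][:q], axis=1)
        self.xT = (self.D[0] + self.f1T[:, None] * self.D[1]
                   + self.f2T[:, None] * self.D[2])  # (M, p) design row at T

        nodes, weights = np.polynomial.hermite.hermgauss(spec.nodes)
        grids = np.meshgrid(*([nodes] * q), indexing="ij")
        self.z_grid = np.stack([g.ravel() for g in grids], axis=1)  # (K, q)
        wg = np.meshgrid(*([weights] * q), indexing="ij")
        w_prod = np.prod(np.stack([g.ravel() for g in wg], axis=1), axis=1)
        self.log_w_adj = np.log(w_prod) + (self.z_grid ** 2).sum(axis=1)

        self._baseline_knots = self._make_knots() if spec.baseline == "piecewise" else None
        self._frozen = None

    # -- construction helpers ------------------------------------------------

    def _design_parts(self, d: LmmDesign, sub, arm):
        """(3, M, p) stack: X_i(t) = D[0] + f1 D[1] + f2 D[2] per mouse."""
        p = d.intercept_block.shape[1]
        n_periods = d.slope_blocks.shape[0]
        D = np.zeros((3, self.M, p))
        first = {m: i for i, m in enumerate(d.mouse_ids)}
        for i, m in enumerate(self.mouse_ids):
            if m in first:
                j = first[m]
                D[0, i] = d.intercept_block[j]
                for pi in range(n_periods):
                    D[1 + pi, i] = d.slope_blocks[pi, j]
            else:  # survival-only mouse: rebuild its design row from labels
                row0 = np.zeros(p)
                row0[0] = 1.0
                for k, name in enumerate(d.col_names):
                    if name == f"sub[{sub[i]}]":
                        row0[k] = 1.0
                D[0, i] = row0
                for pi in range(n_periods):
                    rowp = np.zeros(p)
                    tag = (f"slope{pi + 1}[{sub[i]}:{arm[i]}]" if len(d.cells) > 1
                           else f"slope{pi + 1}")
                    rowp[d.col_names.index(tag)] = 1.0
                    D[1 + pi, i] = rowp
        return D

    def _make_knots(self):
        ev = np.sort(self.T[self.delta > 0])
        if ev.size == 0:
            return np.array([max(self.T.max(), 1.0)])
        qs = np.linspace(0, 1, self.spec.n_baseline_pieces + 1)[1:-1]
        return np.unique(np.quantile(ev, qs))

    # -- parameter packing ---------------------------------------------------

    @property
    def n_baseline(self) -> int:
        return 2 if self.spec.baseline == "weibull" else self._baseline_knots.size + 1

    def param_names(self) -> list[str]:
        names = list(self.design.col_names)
        rows, cols = np.tril_indices(self.q)
        names += [f"chol[{a},{b}]" for a, b in zip(rows, cols)]
        names += ["log_sigma"]
        if self.spec.baseline == "weibull":
            names += ["log_shape", "log_scale"]
        else:
            names += [f"log_h0[{k}]" for k in range(self.n_baseline)]
        names += self.gamma_names
        names += ["eta"]
        return names

    def pack(self, params: JointParams) -> np.ndarray:
        th = theta_from_cov(params.G)
        return np.concatenate([params.beta, th, [0.5 * np.log(params.sigma2)],
                               params.baseline, params.gamma, [params.eta]])

    def unpack(self, x: np.ndarray) -> JointParams:
        p, q = self.p, self.q
        i = p
        n_ch = q * (q + 1) // 2
        L = chol_from_theta(x[i:i + n_ch], q)
        i += n_ch
        sigma2 = float(np.exp(2.0 * x[i])); i += 1
        nb = self.n_baseline
        baseline = x[i:i + nb]; i += nb
        pE = self.X_E.shape[1]
        gamma = x[i:i + pE]; i += pE
        return JointParams(beta=x[:p], chol_G=L, sigma2=sigma2,
                           baseline=np.asarray(baseline, float), gamma=gamma,
                           eta=float(x[i]))

    # -- hazard quadrature grid (time axis) ----------------------------------

    def _time_grid(self, shape0: float | None):
        """Fixed node times for cumulative hazards, split at the changepoint.

        ``shape0`` anchors the Gauss-Jacobi rule of the segment starting at
        t=0 (weight s**(shape0-1)); its value is refreshed together with the
        random-effect nodes, and the likelihood corrects the integrand by
        s**(shape-shape0) so the evaluation stays exact in ``shape``.
        """
        T, c, M = self.T, self.c, self.M
        if c is None:
            bounds = [(np.zeros(M), T, True)]
        else:
            bounds = [(np.zeros(M), np.minimum(T, c), True),
                      (np.full(M, c), np.maximum(T, c), False)]
        segs = []
        for (t0, t1, from_zero) in bounds:
            if from_zero and shape0 is not None:
                x, w = _jacobi_rule(float(shape0))
                half = 0.5 * t1
                s = half[:, None] * (1.0 + x)
                # (L/2)^shape0 * w with L = t1: the rule absorbs s**(shape0-1)
                log_w0 = shape0 * np.log(np.maximum(half, 1e-300))[:, None] + np.log(w)
                absorbed = True
            else:
                half = 0.5 * (t1 - t0)
                s = 0.5 * (t1 + t0)[:, None] + half[:, None] * _GL_X
                log_w0 = np.log(np.maximum(half[:, None] * _GL_W, 1e-300))
                absorbed = False
            dead = (t1 > t0)[:, None]
            log_w0 = np.where(dead, log_w0, -np.inf)
            f1, f2 = piecewise_basis(s, c)
            segs.append({"s": s, "f1": f1, "f2": f2, "log_w0": log_w0,
                         "log_s": np.log(np.maximum(s, 1e-300)),
                         "absorbed": absorbed})
        return segs

    def _log_base(self, seg, P, d, gX):
        """b-independent log hazard-quadrature factor, exact in all params.

        For the singularity-absorbing segment the frozen rule carries
        s**(shape0-1); the integrand keeps (shape/scale**shape) *
        s**(shape-shape0).  Interior segments carry the full log h0(s).
        """
        mu_s = d[0][:, None] + d[1][:, None] * seg["f1"] + d[2][:, None] * seg["f2"]
        lin = np.clip(gX[:, None] + P.eta * mu_s, -_EXP_CLIP, _EXP_CLIP)
        if self.spec.baseline == "weibull":
            shape, scale = np.exp(P.baseline[0]), np.exp(P.baseline[1])
            if seg["absorbed"]:
                lh0 = (np.log(shape) - shape * np.log(scale)
                       + (shape - self._frozen["shape0"]) * seg["log_s"])
            else:
                lh0 = (np.log(shape) - shape * np.log(scale)
                       + (shape - 1.0) * seg["log_s"])
        else:
            idx = np.searchsorted(self._baseline_knots, seg["s"], side="right")
            lh0 = P.baseline[idx]
        return seg["log_w0"] + lh0 + lin, mu_s

    def _log_h0_T(self, P, gX):
        if self.spec.baseline == "weibull":
            lh0 = weibull_log_h0(self.T, np.exp(P.baseline[0]), np.exp(P.baseline[1]))
        else:
            idx = np.searchsorted(self._baseline_knots, self.T, side="right")
            lh0 = P.baseline[idx]
        return lh0

    # -- node freezing -------------------------------------------------------

    def _longitudinal_posterior(self, P):
        """Gaussian posterior of b given the longitudinal data alone."""
        r = self.y - self.X @ P.beta
        Zr = np.stack([np.bincount(self.row_mouse, weights=self.Z[:, a] * r,
                                   minlength=self.M) for a in range(self.q)], axis=1)
        Ginv = np.linalg.inv(P.G + 1e-10 * np.eye(self.q))
        A = self.ZZ / P.sigma2 + Ginv
        mean = np.linalg.solve(A, (Zr / P.sigma2)[..., None])[..., 0]
        return mean, np.linalg.inv(A)

    def _posterior_modes(self, P, segs, max_iter=25, tol=1e-8):
        """Newton mode and curvature of the full per-mouse log integrand.

        The integrand is log-concave in b (Gaussian terms plus a negative
        cumulative hazard with PSD second derivative), so undamped Newton
        converges from the longitudinal posterior mean in a few steps.
        """
        q = self.q
        r = self.y - self.X @ P.beta
        Zr = np.stack([np.bincount(self.row_mouse, weights=self.Z[:, a] * r,
                                   minlength=self.M) for a in range(q)], axis=1)
        Ginv = np.linalg.inv(P.G + 1e-10 * np.eye(q))
        d = np.einsum("smp,p->sm", self.D, P.beta)
        gX = self.X_E @ P.gamma if P.gamma.size else np.zeros(self.M)
        bases = [self._log_base(seg, P, d, gX)[0] for seg in segs]
        eta = P.eta
        A_long = self.ZZ / P.sigma2 + Ginv
        b = np.linalg.solve(A_long, (Zr / P.sigma2)[..., None])[..., 0]
        dzT = self.delta[:, None] * eta * self.zT
        for _ in range(max_iter):
            grad = (Zr - np.einsum("mqr,mr->mq", self.ZZ, b)) / P.sigma2
            grad -= np.einsum("qr,mr->mq", Ginv, b)
            grad += dzT
            A = A_long.copy()
            for seg, lb in zip(segs, bases):
                zb = b[:, 0][:, None] + b[:, 1][:, None] * seg["f1"]
                if q > 2:
                    zb = zb + b[:, 2][:, None] * seg["f2"]
                hv = np.exp(np.clip(lb + eta * zb, -_EXP_CLIP * 2, _EXP_CLIP * 2))
                zl = np.stack([np.ones_like(seg["f1"]), seg["f1"], seg["f2"]][:q], axis=2)
                grad -= eta * np.einsum("ml,mlq->mq", hv, zl)
                A += eta * eta * np.einsum("ml,mlq,mlr->mqr", hv, zl, zl)
            step = np.linalg.solve(A, grad[..., None])[..., 0]
            np.clip(step, -4.0, 4.0, out=step)
            b += step
            if np.max(np.abs(step)) < tol:
                break
        return b, np.linalg.inv(A)

    def freeze_nodes(self, x: np.ndarray, with_survival: bool = True) -> None:
        """Fix the quadrature nodes (time grid and random-effect grid) at x.

        With ``spec.adaptive`` the random-effect grid is centered per mouse at
        the posterior mode and scaled by the curvature (including the
        survival factor when ``with_survival``); otherwise it is centered at
        the prior.  All subsequent :meth:`loglik_grad` evaluations use these
        nodes, making the objective a smooth, exactly differentiable function
        of the parameters.
        """
        P = self.unpack(x)
        shape0 = float(np.exp(P.baseline[0])) if self.spec.baseline == "weibull" else None
        self._frozen = {"shape0": shape0}
        segs = self._time_grid(shape0)
        q, M, K = self.q, self.M, self.z_grid.shape[0]
        if not self.spec.adaptive:
            center = np.zeros((M, q))
            Lb = np.broadcast_to(np.linalg.cholesky(P.G + 1e-10 * np.eye(q)),
                                 (M, q, q)).copy()
        elif with_survival:
            mode, Sigma = self._posterior_modes(P, segs)
            center, Lb = mode, np.linalg.cholesky(Sigma)
        else:
            mean, Sigma = self._longitudinal_posterior(P)
            center, Lb = mean, np.linalg.cholesky(Sigma)
        b = center[:, None, :] + np.sqrt(2.0) * np.einsum("mij,kj->mki", Lb, self.z_grid)
        log_det_Lb = np.sum(np.log(np.einsum("mii->mi", Lb)), axis=1)
        self._frozen.update({
            "segs": segs,
            "b": b,                                            # (M, K, q)
            "log_w": (0.5 * q * np.log(2.0) + log_det_Lb[:, None]
                      + self.log_w_adj[None, :]),              # (M, K)
            "bZZb": np.einsum("mkq,mqr,mkr->mk", b, self.ZZ, b),
            "bzT": np.einsum("mkq,mq->mk", b, self.zT),
            "zb_segs": [self._zb(seg, b) for seg in segs],     # (M, K, 15) each
        })

    def _zb(self, seg, b):
        zb = b[:, :, 0][:, :, None] + b[:, :, 1][:, :, None] * seg["f1"][:, None, :]
        if self.q > 2:
            zb = zb + b[:, :, 2][:, :, None] * seg["f2"][:, None, :]
        return zb

    # -- likelihood and gradient ---------------------------------------------

    def loglik_grad(self, x: np.ndarray, want_grad: bool = True):
        """Marginal log-likelihood (and analytic gradient) at frozen nodes."""
        if self.M == 0:
            return (0.0, np.zeros_like(x)) if want_grad else 0.0
        if self._frozen is None:
            self.freeze_nodes(x, with_survival=True)
        P = self.unpack(x)
        fro = self._frozen
        q, M, K = self.q, self.M, self.z_grid.shape[0]
        b = fro["b"]
        sigma2 = P.sigma2

        r = self.y - self.X @ P.beta
        Zr = np.stack([np.bincount(self.row_mouse, weights=self.Z[:, a] * r,
                                   minlength=M) for a in range(q)], axis=1)
        rr = np.bincount(self.row_mouse, weights=r * r, minlength=M)
        d = np.einsum("smp,p->sm", self.D, P.beta)
        gX = self.X_E @ P.gamma if P.gamma.size else np.zeros(M)
        eta = P.eta

        quad_long = rr[:, None] - 2.0 * np.einsum("mkq,mq->mk", b, Zr) + fro["bZZb"]
        g_long = (-0.5 * self.n_i[:, None] * (np.log(sigma2) + _LOG2PI)
                  - 0.5 * quad_long / sigma2)

        Ginv = np.linalg.inv(P.G + 1e-12 * np.eye(q))
        sld_G = float(np.sum(np.log(np.maximum(np.diag(P.chol_G), 1e-300))))
        g_prior = (-0.5 * q * _LOG2PI - sld_G
                   - 0.5 * np.einsum("mkq,qr,mkr->mk", b, Ginv, b))

        # survival: event factor and cumulative hazard
        muT = d[0] + d[1] * self.f1T + d[2] * self.f2T
        log_haz_T = self._log_h0_T(P, gX) + np.clip(gX + eta * muT,
                                                    -_EXP_CLIP, _EXP_CLIP)
        H = np.zeros((M, K))
        hw_list = []
        for seg, zb in zip(fro["segs"], fro["zb_segs"]):
            lb, _ = self._log_base(seg, P, d, gX)
            hw = np.exp(np.clip(lb[:, None, :] + eta * zb, -2 * _EXP_CLIP, 2 * _EXP_CLIP))
            H += hw.sum(axis=2)
            hw_list.append(hw)
        g_surv = self.delta[:, None] * (log_haz_T[:, None] + eta * fro["bzT"]) - H

        g = g_long + g_prior + g_surv
        arg = fro["log_w"] + g
        ll_i = logsumexp(arg, axis=1)
        ll = float(ll_i.sum())
        if not np.all(np.isfinite(ll_i)):
            ll = -np.inf
        if not want_grad:
            return ll
        if not np.isfinite(ll):
            return ll, np.zeros_like(x)

        pk = np.exp(arg - ll_i[:, None])  # (M, K) posterior node weights

        # node-weighted summaries
        bbar = np.einsum("mk,mkq->mq", pk, b)
        bbT = np.einsum("mk,mkq,mkr->mqr", pk, b, b)
        quadbar = np.einsum("mk,mk->m", pk, quad_long)
        bzTbar = np.einsum("mk,mk->m", pk, fro["bzT"])

        shape = np.exp(P.baseline[0]) if self.spec.baseline == "weibull" else None
        log_scale = P.baseline[1] if self.spec.baseline == "weibull" else None

        P0 = np.zeros(M); P1 = np.zeros(M); P2 = np.zeros(M)
        Pls = np.zeros(M); Pmu = np.zeros(M); PzbH = np.zeros(M)
        Ppiece = np.zeros((M, self.n_baseline)) if self.spec.baseline == "piecewise" else None
        for seg, zb, hw in zip(fro["segs"], fro["zb_segs"], hw_list):
            mu_s = d[0][:, None] + d[1][:, None] * seg["f1"] + d[2][:, None] * seg["f2"]
            hk = np.einsum("mk,mkl->ml", pk, hw)  # (M, 15) node-avg hazard weights
            P0 += hk.sum(axis=1)
            P1 += np.einsum("ml,ml->m", hk, seg["f1"])
            P2 += np.einsum("ml,ml->m", hk, seg["f2"])
            Pls += np.einsum("ml,ml->m", hk, seg["log_s"])
            Pmu += np.einsum("ml,ml->m", hk, mu_s)
            PzbH += np.einsum("mk,mkl,mkl->m", pk, hw, zb)
            if Ppiece is not None:
                idx = np.searchsorted(self._baseline_knots, seg["s"], side="right")
                for kk in range(self.n_baseline):
                    Ppiece[:, kk] += np.einsum("ml,ml->m", hk, (idx == kk).astype(float))

        grad = np.zeros_like(x)
        names_end = 0
        # beta
        Xr = np.stack([np.bincount(self.row_mouse, weights=self.X[:, a] * r,
                                   minlength=M) for a in range(self.p)], axis=1)
        g_beta = (Xr - np.einsum("mpq,mq->mp", self.XZ, bbar)).sum(axis=0) / sigma2
        g_beta += eta * np.einsum("m,mp->p", self.delta, self.xT)
        g_beta -= eta * (np.einsum("m,mp->p", P0, self.D[0])
                         + np.einsum("m,mp->p", P1, self.D[1])
                         + np.einsum("m,mp->p", P2, self.D[2]))
        grad[:self.p] = g_beta
        names_end = self.p
        # chol(G)
        S = Ginv @ bbT.sum(axis=0) @ Ginv - M * Ginv
        dL = S @ P.chol_G
        rows, cols = np.tril_indices(q)
        gv = dL[rows, cols]
        diag = rows == cols
        gv[diag] = gv[diag] * np.diag(P.chol_G)
        n_ch = q * (q + 1) // 2
        grad[names_end:names_end + n_ch] = gv
        names_end += n_ch
        # log sigma
        grad[names_end] = float((-self.n_i + quadbar / sigma2).sum())
        names_end += 1
        # baseline
        if self.spec.baseline == "weibull":
            logT = np.log(np.maximum(self.T, 1e-12))
            # d/d(log shape): event term 1 + shape*log(T/scale);
            # hazard term integrates hw * (1 + shape*log(s/scale))
            g_u1 = float((self.delta * (1.0 + shape * (logT - log_scale))).sum()
                         - (P0 + shape * (Pls - log_scale * P0)).sum())
            g_u2 = float(shape * (P0 - self.delta).sum())
            grad[names_end] = g_u1
            grad[names_end + 1] = g_u2
            names_end += 2
        else:
            idxT = np.searchsorted(self._baseline_knots, self.T, side="right")
            for kk in range(self.n_baseline):
                grad[names_end + kk] = float(
                    (self.delta * (idxT == kk)).sum() - Ppiece[:, kk].sum())
            names_end += self.n_baseline
        # gamma
        pE = self.X_E.shape[1]
        if pE:
            grad[names_end:names_end + pE] = self.X_E.T @ (self.delta - P0)
            names_end += pE
        # eta
        g_eta = float((self.delta * (muT + bzTbar)).sum() - (Pmu + PzbH).sum())
        grad[names_end] = g_eta
        return ll, grad

    def loglik(self, x: np.ndarray, refreeze: bool = True) -> float:
        """Adaptive-quadrature marginal log-likelihood at x.

        Standalone evaluations re-center the quadrature at the posterior
        modes for these very parameters (fully adaptive); pass
        ``refreeze=False`` to evaluate on the currently frozen grid.
        """
        if self.M == 0:
            return 0.0
        if refreeze:
            self.freeze_nodes(x, with_survival=True)
        return self.loglik_grad(x, want_grad=False)

    def loglik_by_mouse(self, x: np.ndarray, refreeze: bool = True) -> np.ndarray:
        """Per-mouse log-likelihood contributions (adaptive quadrature)."""
        if self.M == 0:
            return np.zeros(0)
        if refreeze or self._frozen is None:
            self.freeze_nodes(x, with_survival=True)
        # recompute pieces (mirrors loglik_grad without the gradient)
        P = self.unpack(x)
        fro = self._frozen
        q, M = self.q, self.M
        b = fro["b"]
        r = self.y - self.X @ P.beta
        Zr = np.stack([np.bincount(self.row_mouse, weights=self.Z[:, a] * r,
                                   minlength=M) for a in range(q)], axis=1)
        rr = np.bincount(self.row_mouse, weights=r * r, minlength=M)
        d = np.einsum("smp,p->sm", self.D, P.beta)
        gX = self.X_E @ P.gamma if P.gamma.size else np.zeros(M)
        eta = P.eta
        quad_long = rr[:, None] - 2.0 * np.einsum("mkq,mq->mk", b, Zr) + fro["bZZb"]
        g_long = (-0.5 * self.n_i[:, None] * (np.log(P.sigma2) + _LOG2PI)
                  - 0.5 * quad_long / P.sigma2)
        Ginv = np.linalg.inv(P.G + 1e-12 * np.eye(q))
        sld_G = float(np.sum(np.log(np.maximum(np.diag(P.chol_G), 1e-300))))
        g_prior = (-0.5 * q * _LOG2PI - sld_G
                   - 0.5 * np.einsum("mkq,qr,mkr->mk", b, Ginv, b))
        muT = d[0] + d[1] * self.f1T + d[2] * self.f2T
        log_haz_T = self._log_h0_T(P, gX) + np.clip(gX + eta * muT, -_EXP_CLIP, _EXP_CLIP)
        H = np.zeros((M, b.shape[1]))
        for seg, zb in zip(fro["segs"], fro["zb_segs"]):
            lb, _ = self._log_base(seg, P, d, gX)
            H += np.exp(np.clip(lb[:, None, :] + eta * zb,
                                -2 * _EXP_CLIP, 2 * _EXP_CLIP)).sum(axis=2)
        g_surv = self.delta[:, None] * (log_haz_T[:, None] + eta * fro["bzT"]) - H
        return logsumexp(fro["log_w"] + g_long + g_prior + g_surv, axis=1)

    # -- fitting -------------------------------------------------------------

    def initial_params(self, lmm_fit=None) -> JointParams:
        """Separate LMM and Weibull-PH fits, association started at zero."""
        if lmm_fit is None:
            d = self.design
            frame = pd.DataFrame({
                "mouse_id": d.mouse_ids[d.mouse_index],
                "t_weeks": self.t, "log_tv": self.y,
                "subgroup": d.subgroup[d.mouse_index],
                "arm": d.arm[d.mouse_index]})
            lmm_fit = fit_lmm(frame, self.spec.lmm)
        wb = fit_weibull_ph(self.T, self.delta,
                            self.X_E if self.X_E.shape[1] else None)
        if self.spec.baseline == "weibull":
            baseline = wb[:2]
        else:
            lam = max(self.delta.sum(), 0.5) / np.sum(self.T)
            baseline = np.full(self.n_baseline, np.log(lam))
        G0 = lmm_fit.G + 1e-6 * np.eye(self.q)
        return JointParams(beta=lmm_fit.beta.to_numpy(), chol_G=np.linalg.cholesky(G0),
                           sigma2=max(lmm_fit.sigma2, 1e-6), baseline=np.asarray(baseline),
                           gamma=wb[2:] if self.X_E.shape[1] else np.zeros(0), eta=0.0)

    def _bounds(self):
        q = self.q
        b = [(None, None)] * self.p
        rows, cols = np.tril_indices(q)
        b += [(-8.0, 4.0) if r == c else (-10.0, 10.0) for r, c in zip(rows, cols)]
        b += [(-8.0, 2.0)]                      # log_sigma
        if self.spec.baseline == "weibull":
            b += [(-3.0, 3.0), (-12.0, 18.0)]
        else:
            b += [(-20.0, 10.0)] * self.n_baseline
        b += [(-20.0, 20.0)] * self.X_E.shape[1]
        b += [(-20.0, 20.0)]                    # eta
        return b

    def _hessian(self, x, h_rel=1e-4):
        """Observed information by central differences of the analytic gradient."""
        n = x.size
        H = np.empty((n, n))
        h = h_rel * np.maximum(1.0, np.abs(x))
        for i in range(n):
            e = np.zeros(n); e[i] = h[i]
            _, gp = self.loglik_grad(x + e)
            _, gm = self.loglik_grad(x - e)
            H[i] = -(gp - gm) / (2 * h[i])
        return 0.5 * (H + H.T)

    def fit(self, lmm_fit=None, maxiter: int = 200) -> "JointFit":
        """Two-stage quasi-Newton maximization with node refreshing.

        Stage 1 starts from separate LMM and Weibull-PH fits with the
        quadrature centered at the longitudinal posterior; stage 2 re-centers
        at the interim estimate (survival contribution included) and
        re-maximizes.  Convergence requires a positive-definite observed
        information and a negligible Newton step at the optimum.
        """
        x0 = self.pack(self.initial_params(lmm_fit))
        self.freeze_nodes(x0, with_survival=False)
        bounds = self._bounds()

        def nll_grad(x):
            ll, g = self.loglik_grad(x)
            return -ll, -g

        res = optimize.minimize(nll_grad, x0, jac=True, method="L-BFGS-B",
                                bounds=bounds, options={"maxiter": maxiter,
                                                        "ftol": 1e-12})
        self.freeze_nodes(res.x, with_survival=True)
        res2 = optimize.minimize(nll_grad, res.x, jac=True, method="L-BFGS-B",
                                 bounds=bounds, options={"maxiter": maxiter,
                                                         "ftol": 1e-12})
        x, f = res2.x, res2.fun
        H = self._hessian(x)
        eigs = np.linalg.eigvalsh(H)
        converged = bool(np.isfinite(f) and eigs.min() > 0)
        if converged:
            _, g = self.loglik_grad(x)
            step = np.linalg.solve(H, g)
            for _ in range(5):  # Newton polish on the frozen-node objective
                if np.max(np.abs(step)) < 2e-4:
                    break
                trial = np.clip(x + np.clip(step, -0.5, 0.5),
                                [lo if lo is not None else -np.inf for lo, _ in bounds],
                                [hi if hi is not None else np.inf for _, hi in bounds])
                f_trial = -self.loglik_grad(trial, want_grad=False)
                if not np.isfinite(f_trial) or f_trial > f + 1e-9:
                    break
                x, f = trial, f_trial
                _, g = self.loglik_grad(x)
                step = np.linalg.solve(H, g)
            converged = np.max(np.abs(step)) < 5e-3
            if converged:
                H = self._hessian(x)
                eigs = np.linalg.eigvalsh(H)
                converged = eigs.min() > 0
        vcov = np.linalg.inv(H) if eigs.min() > 0 else np.full_like(H, np.nan)
        return JointFit._from_model(self, x, -f, vcov, converged)


@dataclass
class JointFit:
    """Fitted joint model: longitudinal + survival parameters and inference."""

    spec: JointSpec
    beta: pd.Series
    vcov_beta: pd.DataFrame
    G: np.ndarray
    sigma2: float
    baseline: np.ndarray
    gamma: pd.Series
    eta: float
    eta_se: float
    loglik: float
    converged: bool
    n_mice: int
    n_obs: int
    param_names: list[str]
    x: np.ndarray = field(repr=False, default=None)
    vcov: pd.DataFrame = field(repr=False, default=None)
    design: LmmDesign = field(repr=False, default=None)

    @classmethod
    def _from_model(cls, model: JointModel, x, loglik, vcov, converged):
        P = model.unpack(x)
        names = model.param_names()
        p = model.p
        beta = pd.Series(P.beta, index=names[:p])
        vdf = pd.DataFrame(vcov, index=names, columns=names)
        eta_var = vdf.loc["eta", "eta"]
        eta_se = float(np.sqrt(eta_var)) if np.isfinite(eta_var) and eta_var > 0 else np.nan
        return cls(spec=model.spec, beta=beta,
                   vcov_beta=vdf.iloc[:p, :p].copy(), G=P.G, sigma2=P.sigma2,
                   baseline=np.asarray(P.baseline),
                   gamma=pd.Series(P.gamma, index=model.gamma_names),
                   eta=P.eta, eta_se=eta_se, loglik=loglik, converged=converged,
                   n_mice=model.M, n_obs=model.y.size, param_names=names,
                   x=x, vcov=vdf, design=model.design)

    def summary_frame(self) -> pd.DataFrame:
        se = pd.Series(np.sqrt(np.diag(self.vcov_beta)), index=self.beta.index)
        out = pd.DataFrame({"estimate": self.beta, "se": se})
        out.loc["eta"] = [self.eta, self.eta_se]
        out["ci_lo"] = out["estimate"] - _Z975 * out["se"]
        out["ci_hi"] = out["estimate"] + _Z975 * out["se"]
        return out


def fit_joint(df: pd.DataFrame, surv: pd.DataFrame,
              spec: JointSpec = JointSpec(), lmm_fit=None) -> JointFit:
    """Convenience wrapper: prepare the model and fit by maximum likelihood."""
    return JointModel(df, surv, spec).fit(lmm_fit=lmm_fit)
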