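"""Maximum-likelihood linear mixed models for log tumor growth.

The longitudinal model is a (piecewise) linear trajectory of log tumor volume
in weeks,

    y_ij = X_i(t_ij)' beta + b_i' z(t_ij) + e_ij,
    z(t) = (1, min(t, c), max(t - c, 0)),   e_ij ~ N(0, sigma^2),

with correlated mouse-level random effects ``b_i ~ N(0, G)`` on the intercept
and slope(s), and optionally an additional PDX-level random effect with
diagonal covariance on the same terms (mouse nested within PDX).  With no
changepoint the trajectory is a single line and z(t) = (1, t).

Estimation is full maximum likelihood (not REML).  Fixed effects and the
residual variance are profiled out of the marginal Gaussian likelihood by
generalized least squares, leaving a low-dimensional optimization over the
log-Cholesky factor of the scaled random-effect covariance, which guarantees
positive semi-definiteness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

_Z975 = float(stats.norm.ppf(0.975))

ON_TREATMENT = "on_treatment"
POST_TREATMENT = "post_treatment"


def piecewise_basis(t_weeks, changepoint_weeks):
    """Continuous piecewise-linear time basis (f1, f2).

    ``f1 = min(t, c)``, ``f2 = max(t - c, 0)``; with ``c=None`` the basis is
    ``(t, 0)`` (single slope).  The fitted trajectory is continuous at c.
    """
    t = np.asarray(t_weeks, dtype=float)
    if changepoint_weeks is None:
        return t, np.zeros_like(t)
    c = float(changepoint_weeks)
    if c <= 0:
        raise ValueError("changepoint must be positive")
    return np.minimum(t, c), np.maximum(t - c, 0.0)


@dataclass(frozen=True)
class LmmSpec:
    """Model specification: changepoint and random-effect structure.

    Fixed effects are built from the data's design labels: one intercept per
    subgroup and one slope per (subgroup x arm) cell and period, which
    collapses to ``intercept + slope`` for single-group data.
    """

    changepoint_weeks: float | None = None
    re_levels: str = "one_level"  # "one_level" | "two_level"

    def __post_init__(self) -> None:
        if self.re_levels not in ("one_level", "two_level"):
            raise ValueError("re_levels must be 'one_level' or 'two_level'")

    @property
    def q(self) -> int:
        return 2 if self.changepoint_weeks is None else 3

    @property
    def periods(self) -> tuple[str, ...]:
        if self.changepoint_weeks is None:
            return (ON_TREATMENT,)
        return (ON_TREATMENT, POST_TREATMENT)


@dataclass
class LmmDesign:
    """Prepared arrays for likelihood evaluation (sorted by mouse, then time)."""

    y: np.ndarray            # (N,) log volumes
    t: np.ndarray            # (N,) weeks
    X: np.ndarray            # (N, p) fixed design
    Z: np.ndarray            # (N, q) random-effect design
    col_names: list[str]
    mouse_ids: np.ndarray    # (M,)
    mouse_index: np.ndarray  # (N,) 0..M-1
    starts: np.ndarray       # (M+1,) row offsets per mouse
    pdx_index: np.ndarray    # (M,) PDX code per mouse
    pdx_ids: np.ndarray
    cells: list[tuple[str, str]]          # (subgroup, arm) per slope cell
    intercept_block: np.ndarray           # (M, p) X-row components: constant part
    slope_blocks: np.ndarray              # (n_periods, M, p) per-period slope part
    subgroup: np.ndarray                  # (M,) labels
    arm: np.ndarray                       # (M,)

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_mice(self) -> int:
        return self.mouse_ids.size

    def x_row_at(self, t_weeks, changepoint):
        """Fixed design rows at arbitrary times: (M, p) for a time per mouse."""
        f1, f2 = piecewise_basis(t_weeks, changepoint)
        rows = self.intercept_block + f1[:, None] * self.slope_blocks[0]
        if self.slope_blocks.shape[0] > 1:
            rows = rows + f2[:, None] * self.slope_blocks[1]
        return rows


def build_design(df: pd.DataFrame, spec: LmmSpec) -> LmmDesign:
    """Assemble fixed/random design matrices from a long modelling frame.

    Requires columns mouse_id, t_weeks, log_tv; pdx_id, subgroup, arm are
    optional (defaulting to a single cell).  Slopes get one free coefficient
    per (subgroup x arm) cell and period; intercepts one per subgroup.
    """
    df = df.sort_values(["mouse_id", "t_weeks"], kind="mergesort").reset_index(drop=True)
    for col, default in (("subgroup", "all"), ("arm", "all"), ("pdx_id", "P0")):
        if col not in df.columns:
            df[col] = default
    mouse_codes, mouse_ids = pd.factorize(df["mouse_id"], sort=True)
    M = len(mouse_ids)
    starts = np.searchsorted(mouse_codes, np.arange(M + 1))
    first = starts[:-1]
    sub_m = df["subgroup"].to_numpy()[first]
    arm_m = df["arm"].to_numpy()[first]
    pdx_codes, pdx_ids = pd.factorize(df["pdx_id"], sort=True)

    t = df["t_weeks"].to_numpy(dtype=float)
    y = df["log_tv"].to_numpy(dtype=float)
    f1, f2 = piecewise_basis(t, spec.changepoint_weeks)
    Z = np.column_stack([np.ones_like(t), f1, f2][: spec.q])

    subgroups = list(pd.unique(sub_m))
    arms = list(pd.unique(arm_m))
    cells = [(s, a) for s in subgroups for a in arms
             if np.any((sub_m == s) & (arm_m == a))]

    names = ["intercept"]
    cols_const_m = [np.ones(M)]
    for s in subgroups[1:]:
        names.append(f"sub[{s}]")
        cols_const_m.append((sub_m == s).astype(float))
    n_const = len(names)
    slope_names: list[list[str]] = []
    for pi, period in enumerate(spec.periods, start=1):
        pnames = []
        for s, a in cells:
            pnames.append(f"slope{pi}[{s}:{a}]" if len(cells) > 1 else f"slope{pi}")
        slope_names.append(pnames)
        names.extend(pnames)
    p = len(names)

    intercept_block = np.zeros((M, p))
    for j, col in enumerate(cols_const_m):
        intercept_block[:, j] = col
    n_periods = len(spec.periods)
    slope_blocks = np.zeros((n_periods, M, p))
    j = n_const
    for pi in range(n_periods):
        for (s, a) in cells:
            slope_blocks[pi, (sub_m == s) & (arm_m == a), j] = 1.0
            j += 1

    fbases = [f1, f2]
    X = intercept_block[mouse_codes]
    for pi in range(n_periods):
        X = X + fbases[pi][:, None] * slope_blocks[pi][mouse_codes]

    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design matrix is rank deficient")
    return LmmDesign(y=y, t=t, X=X, Z=Z, col_names=names, mouse_ids=np.asarray(mouse_ids),
                     mouse_index=mouse_codes, starts=starts, pdx_index=pdx_codes[first],
                     pdx_ids=np.asarray(pdx_ids), cells=cells,
                     intercept_block=intercept_block, slope_blocks=slope_blocks,
                     subgroup=sub_m, arm=arm_m)


# ---------------------------------------------------------------------------
# log-Cholesky parameterization

def theta_size(q: int, two_level: bool) -> int:
    return q * (q + 1) // 2 + (q if two_level else 0)


def chol_from_theta(theta: np.ndarray, q: int) -> np.ndarray:
    """Lower-triangular Cholesky factor with exponentiated diagonal."""
    L = np.zeros((q, q))
    idx = np.tril_indices(q)
    L[idx] = theta[: q * (q + 1) // 2]
    L[np.diag_indices(q)] = np.exp(np.diag(L))
    return L


def theta_from_cov(G: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    q = G.shape[0]
    L = np.linalg.cholesky(G + eps * np.eye(q))
    T = L.copy()
    T[np.diag_indices(q)] = np.log(np.diag(L))
    return T[np.tril_indices(q)]


# ---------------------------------------------------------------------------
# sufficient statistics and profiled deviance (one level)

def _suffstats(design: LmmDesign):
    Z, X, y = design.Z, design.X, design.y
    st = design.starts
    ZZ = np.add.reduceat(Z[:, :, None] * Z[:, None, :], st[:-1], axis=0)
    ZX = np.add.reduceat(Z[:, :, None] * X[:, None, :], st[:-1], axis=0)
    Zy = np.add.reduceat(Z * y[:, None], st[:-1], axis=0)
    return {"ZZ": ZZ, "ZX": ZX, "Zy": Zy, "XX": X.T @ X, "Xy": X.T @ y,
            "yy": float(y @ y), "n_i": np.diff(st)}


def _profile_one_level(theta, ss, q, N, want_details=False):
    """Profiled ML deviance for one-level models.

    The marginal covariance per mouse is sigma^2 (I + Z Gt Z') with
    Gt = G / sigma^2 = L L'; beta and sigma^2 are profiled in closed form.
    """
    L = chol_from_theta(theta, q)
    K = np.eye(q) + np.einsum("ab,mbc,cd->mad", L.T, ss["ZZ"], L)
    cK = np.linalg.cholesky(K)
    logdet = 2.0 * np.log(np.einsum("mii->mi", cK)).sum()
    CX = np.einsum("ab,mbp->map", L.T, ss["ZX"])          # (M, q, p)
    Cy = np.einsum("ab,mb->ma", L.T, ss["Zy"])            # (M, q)
    SX = np.linalg.solve(K, CX)
    Sy = np.linalg.solve(K, Cy[..., None])[..., 0]
    XVX = ss["XX"] - np.einsum("mqp,mqr->pr", CX, SX)
    XVy = ss["Xy"] - np.einsum("mqp,mq->p", CX, Sy)
    yVy = ss["yy"] - np.einsum("mq,mq->", Cy, Sy)
    beta = np.linalg.solve(XVX, XVy)
    rss = max(yVy - beta @ XVy, 1e-12)
    sigma2 = max(rss / N, 1e-12)
    deviance = N * np.log(2.0 * np.pi * sigma2) + logdet + N
    if not want_details:
        return deviance
    return {"deviance": deviance, "beta": beta, "sigma2": sigma2,
            "XVX": XVX, "L": L, "K": K, "loglik": -0.5 * deviance}


def _profile_two_level(theta, design: LmmDesign, q, N, want_details=False):
    """Profiled ML deviance with an additional diagonal PDX-level effect.

    Dense per-PDX marginal covariance; mouse-level blocks are masked to the
    within-mouse pattern, the PDX effect is shared across all rows of a PDX.
    """
    n_chol = q * (q + 1) // 2
    L = chol_from_theta(theta[:n_chol], q)
    Gm = L @ L.T
    Dp = np.diag(np.exp(2.0 * theta[n_chol:]))
    X, Z, y = design.X, design.Z, design.y
    mouse_of_row = design.mouse_index
    pdx_of_row = design.pdx_index[mouse_of_row]
    p = X.shape[1]
    XVX = np.zeros((p, p))
    XVy = np.zeros(p)
    yVy = 0.0
    logdet = 0.0
    chols = []
    for g in range(design.pdx_ids.size):
        rows = np.flatnonzero(pdx_of_row == g)
        if rows.size == 0:
            continue
        Zg = Z[rows]
        same = (mouse_of_row[rows][:, None] == mouse_of_row[rows][None, :])
        V = (Zg @ Gm @ Zg.T) * same + Zg @ Dp @ Zg.T + np.eye(rows.size)
        cv = np.linalg.cholesky(V)
        logdet += 2.0 * np.log(np.diag(cv)).sum()
        rhs = np.column_stack([X[rows], y[rows]])
        sol = np.linalg.solve(V, rhs)
        XVX += X[rows].T @ sol[:, :p]
        XVy += X[rows].T @ sol[:, p]
        yVy += float(y[rows] @ sol[:, p])
        if want_details:
            chols.append((rows, V))
    beta = np.linalg.solve(XVX, XVy)
    rss = max(yVy - beta @ XVy, 1e-12)
    sigma2 = max(rss / N, 1e-12)
    deviance = N * np.log(2.0 * np.pi * sigma2) + logdet + N
    if not want_details:
        return deviance
    return {"deviance": deviance, "beta": beta, "sigma2": sigma2, "XVX": XVX,
            "L": L, "Dp": Dp, "blocks": chols, "loglik": -0.5 * deviance}


def marginal_loglik(design: LmmDesign, beta, G, sigma2) -> float:
    """Marginal Gaussian log-likelihood at arbitrary (beta, G, sigma2).

    One-level evaluator used for cross-checks (e.g. against the joint model
    with the association switched off).
    """
    beta = np.asarray(beta, float)
    r = design.y - design.X @ beta
    st = design.starts
    q = design.Z.shape[1]
    Lg = np.linalg.cholesky(np.asarray(G, float) + 1e-14 * np.eye(q)) / np.sqrt(sigma2)
    ZZ = np.add.reduceat(design.Z[:, :, None] * design.Z[:, None, :], st[:-1], axis=0)
    Zr = np.add.reduceat(design.Z * r[:, None], st[:-1], axis=0)
    rr = np.add.reduceat(r * r, st[:-1])
    K = np.eye(q) + np.einsum("ab,mbc,cd->mad", Lg.T, ZZ, Lg)
    cK = np.linalg.cholesky(K)
    logdet = 2.0 * np.log(np.einsum("mii->mi", cK)).sum() + design.n_obs * np.log(sigma2)
    Cr = np.einsum("ab,mb->ma", Lg.T, Zr)
    quad = (rr.sum() - np.einsum("mq,mq->", Cr,
                                 np.linalg.solve(K, Cr[..., None])[..., 0])) / sigma2
    return float(-0.5 * (design.n_obs * np.log(2.0 * np.pi) + logdet + quad))


# ---------------------------------------------------------------------------
# fitting

@dataclass
class LmmFit:
    """Result of a maximum-likelihood LMM fit."""

    spec: LmmSpec
    beta: pd.Series
    vcov_beta: pd.DataFrame
    G: np.ndarray
    G_pdx: np.ndarray | None
    sigma2: float
    loglik: float
    aic: float
    n_params: int
    converged: bool
    n_obs: int
    n_mice: int
    design: LmmDesign = field(repr=False)
    theta: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)

    def summary_frame(self) -> pd.DataFrame:
        se = pd.Series(np.sqrt(np.diag(self.vcov_beta)), index=self.beta.index)
        return pd.DataFrame({"estimate": self.beta, "se": se,
                             "ci_lo": self.beta - _Z975 * se,
                             "ci_hi": self.beta + _Z975 * se})


def _numeric_hessian(f, x, h=1e-4):
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (f(x + ei + ej) - f(x + ei - ej)
                                 - f(x - ei + ej) + f(x - ei - ej)) / (4 * h * h)
    return H


def _numeric_grad(f, x, h=1e-6):
    g = np.empty(x.size)
    for i in range(x.size):
        e = np.zeros(x.size); e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def fit_lmm(df: pd.DataFrame, spec: LmmSpec = LmmSpec()) -> LmmFit:
    """Fit the (piecewise) linear mixed model by maximum likelihood.

    Variance components are optimized by L-BFGS-B over the log-Cholesky
    parameterization with fixed effects and residual variance profiled out;
    two jittered restarts are attempted on non-convergence.  The convergence
    flag requires both a small profiled-deviance gradient and a positive-
    definite observed information (numerical Hessian) for the variance
    parameters.  Non-convergence is reported, not raised.
    """
    design = build_design(df, spec)
    q = spec.q
    N = design.n_obs
    two = spec.re_levels == "two_level"
    if two:
        def obj(th):
            return _profile_two_level(th, design, q, N)

        def details(th):
            return _profile_two_level(th, design, q, N, want_details=True)
    else:
        ss = _suffstats(design)

        def obj(th):
            return _profile_one_level(th, ss, q, N)

        def details(th):
            return _profile_one_level(th, ss, q, N, want_details=True)

    n_th = theta_size(q, two)
    n_chol = q * (q + 1) // 2
    x0 = np.zeros(n_th)
    x0[:n_chol][_diag_positions(q)] = -1.0
    if two:
        x0[n_chol:] = -1.5
    bounds = []
    diag_pos = set(np.flatnonzero(_diag_positions(q)))
    for i in range(n_chol):
        bounds.append((-8.0, 4.0) if i in diag_pos else (-10.0, 10.0))
    bounds += [(-8.0, 4.0)] * (n_th - n_chol)

    best_x, best_f = None, np.inf
    converged = False
    rng = np.random.default_rng(0)
    for attempt in range(3):
        start = x0 if attempt == 0 else x0 + rng.normal(scale=0.5, size=n_th)
        res = optimize.minimize(obj, start, method="L-BFGS-B", bounds=bounds,
                                jac=lambda th: _numeric_grad(obj, th),
                                options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-7})
        x, f, ok = _polish_newton(obj, res.x, res.fun, bounds)
        if f < best_f - 1e-10:
            best_x, best_f = x, f
        if ok:
            best_x, best_f = x, f
            converged = True
            break

    det = details(best_x)
    sigma2 = det["sigma2"]
    L = det["L"]
    G = (L @ L.T) * sigma2
    G_pdx = det["Dp"] * sigma2 if two else None
    beta = pd.Series(det["beta"], index=design.col_names)
    vcov = pd.DataFrame(sigma2 * np.linalg.inv(det["XVX"]),
                        index=design.col_names, columns=design.col_names)
    p = len(design.col_names)
    n_params = p + n_th + 1
    loglik = det["loglik"]
    aic = -2.0 * loglik + 2.0 * n_params

    fitted, resid = _conditional_fitted(design, det, spec, two)
    return LmmFit(spec=spec, beta=beta, vcov_beta=vcov, G=G, G_pdx=G_pdx,
                  sigma2=sigma2, loglik=loglik, aic=aic, n_params=n_params,
                  converged=converged, n_obs=N, n_mice=design.n_mice,
                  design=design, theta=best_x, fitted=fitted, residuals=resid)


def _polish_newton(obj, x, f, bounds, max_iter=8):
    """Newton refinement of an L-BFGS-B solution; declares convergence.

    The optimum is accepted when the observed information (numerical Hessian)
    is positive definite and the Newton step is negligible, i.e. the gradient
    vanishes on the curvature scale; parameters resting on a variance lower
    bound (component estimated at zero) are treated as converged boundary
    solutions and excluded from the step criterion.
    """
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    for _ in range(max_iter):
        at_bound = (np.abs(x - lo) < 1e-8) | (np.abs(x - hi) < 1e-8)
        free = ~at_bound
        g = _numeric_grad(obj, x)
        H = _numeric_hessian(obj, x)
        if not free.any():
            return x, f, True
        Hf = H[np.ix_(free, free)]
        eigs = np.linalg.eigvalsh(Hf)
        if eigs.min() <= 0:
            return x, f, False
        step = np.linalg.solve(Hf, g[free])
        step_size = np.max(np.abs(step))
        if step_size < 3e-4:
            return x, f, True
        trial = x.copy()
        trial[free] = trial[free] - np.clip(step, -1.0, 1.0)
        trial = np.clip(trial, lo, hi)
        f_trial = obj(trial)
        if not np.isfinite(f_trial) or f_trial > f + 1e-9:
            # a rejected micro-step means we sit at the optimum within the
            # noise floor of the objective
            return x, f, step_size < 1e-2
        x, f = trial, f_trial
    return x, f, False


def _diag_positions(q: int) -> np.ndarray:
    """Boolean mask of diagonal entries within the lower-triangle vector."""
    mask = np.zeros(q * (q + 1) // 2, dtype=bool)
    rows, cols = np.tril_indices(q)
    mask[rows == cols] = True
    return mask


def _conditional_fitted(design: LmmDesign, det, spec: LmmSpec, two: bool):
    """Empirical-Bayes fitted values Xb + Z bhat and conditional residuals."""
    r = design.y - design.X @ det["beta"]
    if not two:
        st = design.starts
        q = design.Z.shape[1]
        L, K = det["L"], det["K"]
        Zr = np.add.reduceat(design.Z * r[:, None], st[:-1], axis=0)
        inner = np.linalg.solve(K, np.einsum("ab,mb->ma", L.T, Zr)[..., None])[..., 0]
        bhat = np.einsum("ab,mb->ma", L, inner)
        fitted = design.X @ det["beta"] + np.einsum("nq,nq->n", design.Z, bhat[design.mouse_index])
    else:
        fitted = design.X @ det["beta"]
        Gm, Dp = det["L"] @ det["L"].T, det["Dp"]
        contrib = np.zeros_like(r)
        mouse_of_row = design.mouse_index
        for rows, V in det["blocks"]:
            w = np.linalg.solve(V, r[rows])
            Zg = design.Z[rows]
            dhat = Dp @ (Zg.T @ w)
            contrib[rows] += Zg @ dhat
            for m in np.unique(mouse_of_row[rows]):
                mr = rows[mouse_of_row[rows] == m]
                bh = Gm @ (design.Z[mr].T @ w[mouse_of_row[rows] == m])
                contrib[mr] += design.Z[mr] @ bh
        fitted = fitted + contrib
    return fitted, design.y - fitted


# ---------------------------------------------------------------------------
# inference on slopes

@dataclass(frozen=True)
class SlopeEstimate:
    subgroup: str
    arm: str
    period: str
    estimate: float
    se: float
    ci_lo: float
    ci_hi: float


def contrast(fit: LmmFit, vector) -> tuple[float, float]:
    """Estimate and SE of a linear contrast of the fixed effects."""
    cvec = np.asarray(vector, float)
    est = float(cvec @ fit.beta.to_numpy())
    se = float(np.sqrt(cvec @ fit.vcov_beta.to_numpy() @ cvec))
    return est, se


def slope_table(fit: LmmFit, spec: LmmSpec | None = None) -> pd.DataFrame:
    """Per (subgroup, arm, period) slope estimates with 95% Wald intervals.

    With the cell-coded design each slope is a single coefficient; the SE is
    still computed through the generic contrast machinery.
    """
    spec = spec or fit.spec
    design = fit.design
    rows = []
    names = list(fit.beta.index)
    for pi, period in enumerate(spec.periods, start=1):
        for (s, a) in design.cells:
            col = f"slope{pi}[{s}:{a}]" if len(design.cells) > 1 else f"slope{pi}"
            if col not in names:
                raise KeyError(f"unknown group label: {col}")
            cvec = np.zeros(len(names))
            cvec[names.index(col)] = 1.0
            est, se = contrast(fit, cvec)
            rows.append(SlopeEstimate(s, a, period, est, se,
                                      est - _Z975 * se, est + _Z975 * se))
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def select_changepoint(df: pd.DataFrame, spec: LmmSpec = LmmSpec(),
                       candidates_weeks=(3.0, 4.0, 5.0)):
    """AIC selection of the slope changepoint among candidate weeks.

    Returns ``(best_changepoint, aic_table, fits)``; non-converged candidates
    appear in the table but are excluded from the argmin.  Ties go to the
    smaller changepoint.
    """
    rows = []
    fits = {}
    for c in sorted(candidates_weeks):
        cspec = dataclasses.replace(spec, changepoint_weeks=float(c))
        try:
            fit = fit_lmm(df, cspec)
        except ValueError:
            # e.g. no observations beyond the candidate knot (rank deficiency)
            rows.append({"changepoint_weeks": c, "loglik": np.nan,
                         "n_params": np.nan, "aic": np.nan, "converged": False})
            continue
        fits[c] = fit
        rows.append({"changepoint_weeks": c, "loglik": fit.loglik,
                     "n_params": fit.n_params, "aic": fit.aic,
                     "converged": fit.converged})
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if ok.empty:
        raise RuntimeError("no candidate changepoint model converged")
    best = float(ok.sort_values(["aic", "changepoint_weeks"]).iloc[0]["changepoint_weeks"])
    return best, table, fits
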