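"""Core data structures for mouse-clinical-trial (MCT) tumor-growth data.

An MCT pools several patient-derived xenograft (PDX) models; within each PDX,
mice are randomized between a vehicle arm and treatment arms.  Tumor volume
(mm^3) is measured by calipers on a day grid until the end of follow-up or the
death of the mouse.  Internally all models work on the natural-log scale,
``log_tv = log(tv_mm3)``, and in weeks (``t_weeks = day / 7``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

DAYS_PER_WEEK = 7.0

#: death-cause codes used by the simulator
CAUSE_NONE = "none"
CAUSE_MAR = "sacrifice_MAR"
CAUSE_MNAR = "natural_MNAR"


def weeks(day):
    """Convert study day to weeks (the internal time unit)."""
    return np.asarray(day, dtype=float) / DAYS_PER_WEEK


@dataclass(frozen=True)
class TrialDesign:
    """Design of an MCT: PDX/mouse structure, arms, subgroups and schedule.

    ``pdx_subgroup`` maps each PDX id to its subgroup label; ``mouse_arm``
    assigns arms mouse-by-mouse within PDX (randomization within PDX).
    ``mice_per_pdx`` may be a single count or one count per PDX.
    """

    n_pdx: int
    mice_per_pdx: int | Sequence[int]
    arm_labels: tuple[str, ...] = ("vehicle",)
    subgroup_labels: tuple[str, ...] = ("all",)
    pdx_subgroup: Mapping[int, str] | None = None
    follow_up_days: float = 28.0
    measurement_days: tuple[float, ...] = (0, 3, 7, 10, 14, 17, 21, 24, 28)

    def __post_init__(self) -> None:
        if self.n_pdx < 1:
            raise ValueError("empty design: n_pdx must be >= 1")
        days = np.asarray(self.measurement_days, dtype=float)
        if days[0] != 0:
            raise ValueError("measurement_days must start at 0")
        if np.any(np.diff(days) <= 0):
            raise ValueError("measurement_days must be strictly increasing")
        if days[-1] > self.follow_up_days:
            raise ValueError("measurement_days must all be <= follow_up_days")
        if self.mice_counts().sum() < 1:
            raise ValueError("empty design: no mice")

    def mice_counts(self) -> np.ndarray:
        if np.isscalar(self.mice_per_pdx):
            return np.full(self.n_pdx, int(self.mice_per_pdx))
        counts = np.asarray(self.mice_per_pdx, dtype=int)
        if counts.size != self.n_pdx:
            raise ValueError("mice_per_pdx list length must equal n_pdx")
        return counts

    @property
    def n_mice(self) -> int:
        return int(self.mice_counts().sum())

    def subgroup_of_pdx(self, pdx: int) -> str:
        if self.pdx_subgroup is not None:
            return self.pdx_subgroup[pdx]
        return self.subgroup_labels[0]

    @property
    def follow_up_weeks(self) -> float:
        return self.follow_up_days / DAYS_PER_WEEK


@dataclass(frozen=True)
class GrowthTruth:
    """True data-generating parameters of the (piecewise) log-linear model.

    Log tumor volume for mouse i follows
    ``m_i(t) = intercept + slope1*min(t,c) + slope2*max(t-c,0) + b_i' z(t)``
    (weeks), with mouse-level random effects ``b_i ~ N(0, G)`` where
    ``G = D(re_sd) R D(re_sd)``, optional PDX-level effects with diagonal
    covariance ``diag(pdx_re_sd^2)``, and i.i.d. Gaussian measurement noise
    with SD ``residual_sd`` on the log scale.  With ``changepoint_weeks=None``
    the model is single-slope and the random-effect dimension is 2
    (intercept, slope); otherwise it is 3.

    ``slope_offsets`` maps ``(subgroup, arm)`` to additive per-period slope
    offsets, so treatment effects enter as slope shifts.
    """

    intercept_mean: float = float(np.log(150.0))
    slope1: float = 0.39
    slope2: float | None = None
    changepoint_weeks: float | None = None
    slope_offsets: Mapping[tuple[str, str], tuple[float, ...]] = field(default_factory=dict)
    re_sd: tuple[float, ...] = (0.4, 0.15)
    re_corr: np.ndarray | None = None
    pdx_re_sd: tuple[float, ...] | None = None
    residual_sd: float = 0.15

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.re_sd) or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        q = self.q
        if len(self.re_sd) != q:
            raise ValueError(f"re_sd must have length {q} for this truth")
        R = self.corr_matrix()
        if R.shape != (q, q) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("re_corr must be symmetric with unit diagonal")
        if np.any(np.linalg.eigvalsh(R) < -1e-10):
            raise ValueError("re_corr must be positive semi-definite")
        if self.changepoint_weeks is not None and self.changepoint_weeks <= 0:
            raise ValueError("changepoint_weeks must be positive")

    @property
    def q(self) -> int:
        """Random-effect dimension: 2 (single slope) or 3 (piecewise)."""
        return 2 if self.changepoint_weeks is None else 3

    def corr_matrix(self) -> np.ndarray:
        if self.re_corr is None:
            R = np.eye(self.q)
            R[R == 0] = 0.2
            return R
        return np.asarray(self.re_corr, dtype=float)

    def cov_matrix(self) -> np.ndarray:
        """Mouse-level random-effect covariance G."""
        D = np.diag(self.re_sd)
        return D @ self.corr_matrix() @ D

    def pdx_cov_matrix(self) -> np.ndarray:
        if self.pdx_re_sd is None:
            return np.zeros((self.q, self.q))
        return np.diag(np.square(self.pdx_re_sd))

    def slopes_for(self, subgroup: str, arm: str) -> tuple[float, float]:
        """(slope1, slope2) for a design cell, offsets applied."""
        s2 = self.slope1 if self.slope2 is None else self.slope2
        off = self.slope_offsets.get((subgroup, arm), (0.0, 0.0))
        if np.isscalar(off):
            off = (off, off)
        return self.slope1 + off[0], s2 + (off[1] if len(off) > 1 else off[0])

    def mean_log_volume(self, t_weeks: np.ndarray, subgroup: str = "all",
                        arm: str = "vehicle") -> np.ndarray:
        """Population-mean log volume path m(t) for a design cell."""
        t = np.asarray(t_weeks, dtype=float)
        s1, s2 = self.slopes_for(subgroup, arm)
        c = self.changepoint_weeks
        if c is None:
            return self.intercept_mean + s1 * t
        return self.intercept_mean + s1 * np.minimum(t, c) + s2 * np.maximum(t - c, 0.0)


@dataclass(frozen=True)
class DropoutSpec:
    """Competing dropout mechanisms of an MCT.

    MAR: sacrifice at the first measurement whose *observed* volume reaches
    ``ethical_threshold_mm3`` (missing-at-random: the decision depends only on
    recorded data).  MNAR: a latent death hazard
    ``h(t) = h0(t) * exp(mnar_eta * m_i(t))`` driven by the *true* current log
    volume (missing-not-at-random), with Weibull baseline
    ``h0(t) = (shape/scale) * (t/scale)**(shape-1)`` in weeks.

    ``ethical_threshold_mm3 = inf`` disables MAR; ``mnar_baseline_scale = inf``
    disables MNAR.
    """

    ethical_threshold_mm3: float = np.inf
    mnar_eta: float = 1.0
    mnar_baseline_shape: float = 1.5
    mnar_baseline_scale: float = np.inf
    target_prop_mnar: float | None = None
    target_prop_mar: float | None = None

    def __post_init__(self) -> None:
        if self.ethical_threshold_mm3 <= 0:
            raise ValueError("ethical_threshold_mm3 must be > 0")
        for tgt in (self.target_prop_mnar, self.target_prop_mar):
            if tgt is not None and not 0 <= tgt <= 1:
                raise ValueError("target proportions must lie in [0, 1]")
        if (self.target_prop_mnar or 0) + (self.target_prop_mar or 0) > 1:
            raise ValueError("target proportions must sum to <= 1")

    @property
    def mnar_enabled(self) -> bool:
        return np.isfinite(self.mnar_baseline_scale)

    @property
    def mar_enabled(self) -> bool:
        return np.isfinite(self.ethical_threshold_mm3)



@dataclass
class MouseRecord:
    """One mouse: observed series, realized death, and design labels."""

    mouse_id: str
    pdx_id: str
    subgroup: str
    arm: str
    obs_days: np.ndarray
    obs_tv_mm3: np.ndarray
    death_day: float | None = None
    death_cause: str = CAUSE_NONE
    latent_re: np.ndarray | None = None  # for oracle tests only
    all_masked: bool = False

    def __post_init__(self) -> None:
        self.obs_days = np.asarray(self.obs_days, dtype=float)
        self.obs_tv_mm3 = np.asarray(self.obs_tv_mm3, dtype=float)
        if len(self.obs_days) != len(self.obs_tv_mm3):
            raise ValueError("obs_days and obs_tv_mm3 must have equal length")
        if len(self.obs_days) > 1 and np.any(np.diff(self.obs_days) <= 0):
            raise ValueError("obs_days must be strictly increasing")
        if (self.death_day is None) != (self.death_cause == CAUSE_NONE):
            raise ValueError("death_day is None iff death_cause is 'none'")
        if self.death_day is not None and len(self.obs_days) and self.obs_days[-1] > self.death_day + 1e-9:
            raise ValueError("observations must not extend past death_day")

    @property
    def n_obs(self) -> int:
        return len(self.obs_days)


@dataclass
class Cohort:
    """A simulated MCT cohort: records plus the generating configuration."""

    records: list[MouseRecord]
    design: TrialDesign
    truth: GrowthTruth
    dropout: DropoutSpec
    seed: int

    def __post_init__(self) -> None:
        ids = [r.mouse_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("mouse ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Long measurement table and per-mouse death table.

        Measurements: pdx_id, mouse_id, subgroup, arm, day, tv_mm3.
        Deaths: mouse_id, death_day (NaN if alive at end), cause.
        """
        meas = []
        deaths = []
        for r in self.records:
            for d, v in zip(r.obs_days, r.obs_tv_mm3):
                meas.append((r.pdx_id, r.mouse_id, r.subgroup, r.arm, d, v))
            deaths.append((r.mouse_id, np.nan if r.death_day is None else r.death_day,
                           r.death_cause))
        mdf = pd.DataFrame(meas, columns=["pdx_id", "mouse_id", "subgroup", "arm", "day", "tv_mm3"])
        ddf = pd.DataFrame(deaths, columns=["mouse_id", "death_day", "cause"])
        return mdf, ddf

    def write_csv(self, measurements_path, deaths_path) -> None:
        mdf, ddf = self.to_frames()
        mdf.to_csv(measurements_path, index=False)
        ddf.to_csv(deaths_path, index=False)


def modelling_frame(measurements: pd.DataFrame, deaths: pd.DataFrame | None = None,
                    follow_up_days: float | None = None) -> pd.DataFrame:
    """Long table ready for model fitting: adds t_weeks and log_tv.

    When ``deaths`` is given, per-mouse event time (weeks) and indicator are
    merged in; mice alive at the end are administratively censored at
    ``follow_up_days``.
    """
    df = measurements.copy()
    if np.any(df["tv_mm3"].to_numpy() <= 0):
        raise ValueError("tumor volumes must be positive for log transformation")
    df["t_weeks"] = df["day"].to_numpy(dtype=float) / DAYS_PER_WEEK
    df["log_tv"] = np.log(df["tv_mm3"].to_numpy(dtype=float))
    if deaths is not None:
        if follow_up_days is None:
            raise ValueError("follow_up_days required when merging deaths")
        d = deaths.copy()
        d["event"] = (~d["death_day"].isna()).astype(int)
        d["event_weeks"] = d["death_day"].fillna(follow_up_days).to_numpy(dtype=float) / DAYS_PER_WEEK
        df = df.merge(d[["mouse_id", "event", "event_weeks"]], on="mouse_id", how="left")
    return df


# ---------------------------------------------------------------------------
# declarative configuration


def _truth_from_dict(d: dict) -> GrowthTruth:
    kw = dict(d)
    if "re_corr" in kw and kw["re_corr"] is not None:
        kw["re_corr"] = np.asarray(kw["re_corr"], dtype=float)
    if "slope_offsets" in kw and kw["slope_offsets"]:
        kw["slope_offsets"] = {tuple(k.split(":")): tuple(np.atleast_1d(v))
                               for k, v in kw["slope_offsets"].items()}
    for name in ("re_sd", "pdx_re_sd"):
        if kw.get(name) is not None:
            kw[name] = tuple(kw[name])
    return GrowthTruth(**kw)


def load_config(path) -> dict:
    """Read a YAML/JSON study configuration.

    Top-level keys: ``design``, ``truth``, ``dropout`` (each mirroring the
    corresponding dataclass fields) and a mandatory ``seed``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "seed" not in raw:
        raise ValueError("configuration must set a seed")
    out = {"seed": int(raw["seed"])}
    if "design" in raw:
        dkw = dict(raw["design"])
        for name in ("arm_labels", "subgroup_labels", "measurement_days"):
            if name in dkw:
                dkw[name] = tuple(dkw[name])
        out["design"] = TrialDesign(**dkw)
    if "truth" in raw:
        out["truth"] = _truth_from_dict(raw["truth"])
    if "dropout" in raw:
        out["dropout"] = DropoutSpec(**raw["dropout"])
    return out


def replace(obj, **changes):
    """dataclasses.replace passthrough (convenience re-export)."""
    return dataclasses.replace(obj, **changes)
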