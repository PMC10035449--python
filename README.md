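# mctmodels

Statistical models for tumor-growth analysis in **mouse clinical trials
(MCTs)** of patient-derived xenografts (PDX), focused on one question: *which
longitudinal model should analyze tumor volume when mice die before the end
of follow-up?*

In an MCT, mice from several PDX models are randomized within each PDX to a
vehicle arm and treatment arms, and subcutaneous tumor volume is measured
with calipers every few days. Deaths during follow-up truncate the series
and, if ignored, bias any late-timepoint comparison toward slow-growing
survivors (survivor bias). Two model families handle the dropout, under
different missingness assumptions:

- a **linear mixed-effects model (LMM)** of log tumor volume — valid when
  dropout is *missing at random* (MAR), e.g. sacrifice triggered by a
  measured volume crossing an ethical threshold such as 1,500 mm³;
- a **joint shared-random-effects model** — the same LMM coupled to a
  proportional-hazards survival submodel through the current *true* level of
  log volume, valid when dropout is *missing not at random* (MNAR), e.g.
  natural death driven by the latent tumor burden.

This package implements both estimators from scratch, a synthetic MCT
generator with competing, calibratable MAR/MNAR mechanisms, a Monte-Carlo
study of estimator bias/coverage/convergence, and an end-to-end trial
analysis pipeline including a masking perturbation that converts MAR dropout
into MNAR while retaining death dates.

## Models

Log tumor volume for mouse *i* at week *t* follows a piecewise-linear mixed
model with changepoint *c* (single slope when *c* is absent):

```
y_ij = X_i(t_ij)'β + b_i' z(t_ij) + ε_ij,   z(t) = (1, min(t,c), max(t−c,0)),
b_i ~ N(0, G),   ε_ij ~ N(0, σ²),
```

optionally with an extra PDX-level random effect on the same terms (mouse
nested within PDX). Estimation is full maximum likelihood with fixed effects
and σ² profiled out by GLS and the scaled covariance optimized on a
log-Cholesky scale; Wald 95% intervals use normal quantiles.

The joint model shares `b_i` with a hazard

```
h_i(t) = h0(t) · exp(γ'X_Ei + η · m_i(t)),   m_i(t) = X_i(t)'β + b_i' z(t),
```

with a Weibull baseline `h0` (piecewise-constant available) and association
parameter η. The marginal likelihood integrates `b_i` out by adaptive
Gauss–Hermite quadrature (9 nodes/dimension, per-mouse mode re-centering);
cumulative hazards use 15-point Gauss–Jacobi/Legendre quadrature per
trajectory segment. Optimization runs on a smooth frozen-node objective with
an exact analytic gradient; standard errors come from the observed
information.

## Worked example

```python
import numpy as np
from mctmodels import (GrowthTruth, JointModel, JointSpec, TrialDesign,
                       calibrate_dropout, fit_lmm, simulate_cohort)
from mctmodels.simstudy import cohort_frames, scenario_design

truth = GrowthTruth()          # log-linear growth, slope 0.39 log(mm³)/week
dropout = calibrate_dropout(scenario_design(10_000), truth,
                            target_prop_mnar=0.5, target_prop_mar=0.0, seed=99)
cohort = simulate_cohort(scenario_design(300), truth, dropout, seed=1)
df, surv = cohort_frames(cohort)

lmm = fit_lmm(df)
joint = JointModel(df, surv, JointSpec()).fit(lmm_fit=lmm)
print(f"LMM slope   {lmm.beta['slope1']:.4f} "
      f"(se {np.sqrt(lmm.vcov_beta.loc['slope1','slope1']):.4f})")
print(f"joint slope {joint.beta['slope1']:.4f} "
      f"(se {np.sqrt(joint.vcov_beta.loc['slope1','slope1']):.4f}), "
      f"eta {joint.eta:.2f} (se {joint.eta_se:.2f})")
```

prints

```
LMM slope   0.3803 (se 0.0088)
joint slope 0.3832 (se 0.0089), eta 0.95 (se 0.16)
```

Half of these 300 mice die from a hazard tied to their latent growth curve
(true association η = 1). The joint model, which models exactly that
coupling, recovers the true slope 0.39 and η ≈ 1 with a valid standard
error; the plain LMM is also close here, but only the joint model's CI is
guaranteed nominal under this MNAR mechanism.

## Analysis scripts

Numbered drivers under `analysis/` reproduce the package's studies and write
their tables under `results/`:

| script | what it does |
|---|---|
| `01_make_fixture.py` | generate the synthetic 25-PDX / 225-mouse trial dataset (CSV) |
| `02_trial_analysis.py` | changepoint selection, one-/two-level LMM, joint model, slope tables, cumulative incidence by death cause, naive survivor means, and the 900 mm³ masking re-analysis |
| `03_simulation_study.py` | the bias/coverage/convergence grid over cohort sizes and MNAR:MAR splits |
| `04_perturbation_study.py` | replicate-level masking experiment showing when each estimator is closer to the truth |

Each script accepts `--seed` and `--out`; run with `--help` for options.

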