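# Methods

`fracsurv` analyzes how radiotherapy fractionation affects overall survival
in head-and-neck squamous cell carcinoma (HNSCC), combining a mechanistic
dose model with a predictive and a causal machine-learning stage. This note
records the models, the defaults and why, the numerical choices, and the
limits of what the synthetic experiments demonstrate.

## Biologically effective dose with tumor repopulation

For a schedule of `m` fractions of `d` Gy, the linear-quadratic BED without
repopulation is

    BED_simp = m d (1 + d/r),

with `r` the alpha/beta ratio (default 10 Gy for HNSCC; 7 and 13 Gy are
carried as sensitivity variants). Two repopulation-aware extensions
subtract proliferation penalties accrued over the elapsed treatment time
`T` (days):

* **Dose-independent (DI).** Accelerated repopulation starts at a fixed
  kick-off time `T_k`, regardless of treatment intensity:

      BED_DI = [m α d (d + r)/r − g T − λ max(0, T − T_k)] / α

  with α = 0.069 /Gy, λ = 0.035 /day, T_k = 28.6 days.

* **Dose-dependent (DD).** Both the onset and the rate of accelerated
  repopulation respond to the mean daily log cell kill
  `k = m α d (d + r)/(r T)`: acceleration begins once the cumulative log
  kill crosses a threshold `C` (at time `C/k`) and proceeds at rate
  `λ (1 − exp(−k))`:

      BED_DD = [m α d (d + r)/r − g T − λ (1 − e^{−k}) max(0, T − C/k)] / α

  with α = 0.224 /Gy, λ = 1.17 /day, C = 14.5.

Both reduce exactly to `BED_simp` when their repopulation terms vanish
(`g = 0` and `T ≤ T_k`, or `g = 0` and `C → ∞`), which the tests assert, and
a sympy test verifies the DD closed form algebraically against its expanded
polynomial/exponential term structure over the common denominator `r α`.

**Background rate g and the day-count convention.** The slow background
proliferation rate `g` is not part of the published parameter sets, and
elapsed days must be derived from a duration quoted in weeks. Both are
resolved by calibration against the standard 35 × 2 Gy / 7-week schedule
*only* (`calibrate_background_rate`): the models are linear in `g`, so the
anchor fit is closed-form, and the day convention is chosen by residuals on
non-anchor validation schedules. The selected convention is the exact
Monday-start weekday calendar, `T = 7⌊(D−1)/5⌋ + (D−1) mod 5` with `D`
treatment days — it coincides with the simpler `T = 7·weeks − 3` whenever
the duration is a whole number of weeks, but unlike it also places
fractional-week schedules (18 × 3 in 3.6 weeks, 21 × 2.55 in 4.2 weeks) on
the weekday grid, which is what lets a single anchor-calibrated `g`
(≈ 0.0161/day for DD, ≈ 0.0165/day for DI) reproduce every once-daily
reference schedule within 0.07 Gy (DD) and 0.28 Gy (DI). Twice-daily (BID)
schedules use no inter-fraction-interval correction.

**Shape of the DD model.** BED_DD is continuous but only piecewise smooth:
at the acceleration onset (`T = C/k`) the penalty term switches on, and in
a narrow band around it the model can *decrease* slightly with increasing
dose per fraction (the penalty initially grows faster than the LQ kill
term; the dip is a few hundredths of a Gy, e.g. for 15 fractions stretched
over 8 weeks). This is a genuine property of the model, so monotonicity is
asserted only where it holds: everywhere for BED_simp and BED_DI, and on
the clinically relevant hypofractionation range (m ≤ 35, d ≥ 1.8 Gy,
derived durations) for BED_DD; both repopulation models are globally
non-increasing in `T` at fixed schedule.

Negative BEDs (possible for pathologically protracted schedules) are
returned as-is with a logged warning; clamping would hide input errors.
Tabulated outputs are rounded half-up to 2 decimals; computation is full
precision.

## Synthetic cohort generator

`fracsurv.cohort` draws cohorts emulating the structure of a modern
definitive-radiotherapy HNSCC registry (the public RADCURE collection,
3,346 patients, 2005–2017): age ~ N(62, 11²) clipped to [25, 90], 78% male,
30% never-smokers with Gamma(2, 15) pack-years otherwise, AJCC stage
0–4 with probabilities (.02, .08, .15, .30, .45), HPV positive/negative/
unknown at (.55, .30, .15) one-hot encoded with HPV− as reference, 55%
concurrent chemotherapy, treatment year uniform on 2005–2017, and
diagnosis-site flags (oropharynx-dominant) with at most one flag per
patient. Fractionation schedules are drawn from the registry's empirical
mix (the 35 × 2 Gy standard for ~68%, then 25 × 2.4, 40 × 1.6, 20 × 2.55,
33 × 2, …), so at the reference size the modal regimen is 35 × 2 and
exactly four other regimens exceed 50 patients.

Survival uses cause-specific Weibull proportional hazards for three causes
(index cancer, other cancer, other causes); each cause has its own shape,
scale and covariate log-hazard coefficients (stage, smoking, HPV, chemo and
calendar year act on the index-cancer hazard; age dominates the non-cancer
hazard). The radiotherapy effect enters the **index-cancer hazard as a
threshold term in BED_DD** (> 61.8 Gy, log-HR −0.40 by default), so the
binary "treatment" downstream is the generator's own discontinuity and the
forest/SHAP stage has a true cut-point to rediscover. Event times are the
minimum of the three latent cause times (exact for cause-specific hazards);
censoring is covariate-independent — exponential dropout (rate 0.02/y) plus
a uniform(4, 12)-year administrative horizon capped at 12 years — so a
Kaplan–Meier censoring model is correctly specified by construction.

Because the DGP is fully parametric, `true_effects` computes the exact ATE
on RMST and survival probability by averaging counterfactual survival
curves over a 20,000-draw covariate sample (trapezoid integration, 0.02-y
grid), and `calibrate_effect` solves for the treatment log-HR that yields a
requested true RMST effect (e.g. 0.5 y at 8 years) by bisection against
that oracle. A `confounding` switch tilts regimen choice by stage so that
naive and adjusted analyses separate; with it off, regimens are randomized.

What the generator does *not* emulate: covariate-dependent censoring,
measurement error in dose records, non-proportional hazards, correlated
covariates (age and smoking are drawn independently), or institution-level
effects. Tests passing on this cohort therefore demonstrate internal
statistical correctness of the estimators under a known DGP — not that the
clinical conclusions transfer to any real registry.

## Survival-forest stage

Random survival forests (scikit-survival) with the tuned settings carried
as configuration defaults: overall survival (min_samples_leaf 30,
min_samples_split 2, 52 trees), HPV-negative subset (10, 2, 65), competing
risks (300 trees). Evaluation follows a 70:30 split with 10-fold
cross-validation *refit per fold* on the training portion plus a held-out
c-index (Harrell, ties at 0.5).

**Shapley attributions** are computed in-package on a scalar risk score:
the log ensemble cumulative hazard at the cohort's median event time
(exponentiated attributions then read as multiplicative mortality-risk
changes, so 1.1 is a 10% higher predicted risk). The value function is
interventional (marginal expectations over a background sample). Two
estimators: exact coalition enumeration (≤ 16 features; the test oracle)
and antithetic permutation sampling, whose telescoping construction makes
local accuracy (base + Σ attributions = model output) hold to floating
point for any number of permutations — sampling noise only affects the
split between features. Risk scores use per-tree leaf lookups of the
stored Nelson–Aalen node curves, which equals the library's full
cumulative-hazard prediction at the reference time but is orders of
magnitude faster under Shapley's millions of evaluations. Relative-risk
curves are exp(attribution) against feature value, smoothed by a running
median (window 21 by default).

**Competing risks** are handled cause-specifically: one forest per cause
(other causes censored) for predictions and permutation variable importance
(drop in that cause's c-index over repeated permutations of a feature), plus
nonparametric summaries — Nelson–Aalen cause-specific cumulative hazards
(lifelines) and an in-package Aalen–Johansen estimator whose construction
makes `Σ_c CIF_c(t) + S_KM(t) = 1` hold exactly on the event grid (ties
resolved events-first); lifelines' Aalen–Johansen is the independent
cross-check in the tests.

## Cut-points

Continuous BED variants are dichotomized at `value > cutpoint` (boundary
maps to 0); defaults 61.8 Gy (BED_DD), 57.6 Gy (BED_DI), 70 Gy (BED_simp).
The "visible change in the relative-risk curve" rule is operationalized as
the two-segment piecewise-constant least-squares change point (exhaustive
scan over split positions; cut at the midpoint between neighbouring support
values). A curve whose two-segment fit improves on a flat fit by less than
2% of total SSE is declared flat and falls back to a percentile rule; the
no-repopulation variant's cut-point is placed at the same percentile of its
dose distribution that the DD cut-point occupies in the DD distribution.
On the default synthetic cohort the detector recovers the generator's
61.8 Gy threshold within a fraction of a Gy (the detected cut falls in the
gap between the adjacent observed dose levels 60.95 and 62.19 Gy).

## Doubly robust causal stage

For a binary treatment W (one binarized BED variant at a time; the other
two variants are excluded from the data) with covariates
{Sex, Smoking_PY, Stage_numeric, HPV_Positive, HPV_Unknown, Chemo, RT_year,
Age}, the estimator is cross-fitted AIPW with inverse-probability-of-
censoring weighting, per horizon h (default 1–12 y, truncated at the 95th
percentile of follow-up to keep censoring weights stable):

    φ_w = m_w(X) + 1{W=w}/e_w(X) · Δ(h)/G_w(min(T,h)⁻) · (Y − m_w(X)),
    effect score = φ_1 − φ_0,   ATE = mean(score),   SE = sd(score)/√n,

where Y is `1{T > h}` (survival probability, SP) or `min(T, h)` (RMST),
Δ(h) indicates the h-horizon outcome is observed, e(X) is a probability
forest (or regularized logistic regression), G_w a per-arm Kaplan–Meier of
the censoring distribution, and m_w(h|X) comes from arm-specific random
survival forests (step-function integration for RMST). Propensities are
clipped to [0.05, 0.95] with the clipped count logged; if more than 20% of
raw propensities fall outside the bounds, estimation aborts with a
positivity error rather than extrapolate. Ten folds by default, fold
assignment seeded. SP effects are reported in percentage points and RMST
in years in all written tables.

The doubly robust property is the tested contract: replacing the outcome
model with a constant (correct propensity + censoring) or the propensity
with a constant (correct outcome model) leaves the estimate consistent on
synthetic data; on uncensored randomized data with empirical propensity
and constant outcome model, the estimate collapses *exactly* to the
difference of truncated means.

Per-patient effects (CATEs) come from a regression forest on the effect
scores, read out-of-bag to avoid own-observation bias; per-patient
uncertainty is either the spread of per-tree predictions (fast, heuristic)
or a bootstrap over refitted forests. The best linear projection (BLP) is
OLS of the scores on covariates with HC3 sandwich errors; its coefficients
measure modification of the treatment effect, not covariate main effects on
mortality. Collinear columns are rank-checked and dropped with a warning.

## Refutation battery

Pure seeded perturbations with numeric pass criteria: k independent N(0,1)
noise covariates must shift the ATE by < 1 reference SE at every horizon;
permuting treatment, or jointly permuting (time, event, cause), must leave
|ATE| < 2 SE at every horizon; shifting uncensored treated survival times
by +δ years (re-censored at the 12-year cap) must raise the RMST effect at
the longest horizon by > 2 reference SE. The 1-SE/2-SE thresholds are
package conventions for tests that the source analyses report only
qualitatively. The every-horizon criterion is strict: the per-horizon
checks are correlated but not identical, so a small false-alarm rate under
the null is inherent to it.

## Problem sizes used by the test suite

Monte-Carlo checks run at sizes chosen to make each property decisive at
sensible cost: ATE recovery and double-robustness at n = 5,000 with 10-fold
cross-fitting; null calibration over 50 zero-effect replicates at n = 600
(5 folds, small forests); logrank-p uniformity over 200 replicates at
n = 400; fake-effect detection power over 10 replicates at n = 3,000;
cut-point recovery on an n = 2,000 cohort with 150 explained patients.
Several power-sensitive tests use a balanced three-regimen mix (~50%
treated) instead of the registry mix (~90% treated), because at small n a
9:1 arm ratio leaves too few controls for stable fold-wise estimates.

## Known limitations

* The calibrated `g` is a surrogate: it reproduces the reference table but
  is not the original fitted value, which is unpublished.
* Per-patient CATE standard errors from tree spread are a heuristic; the
  bootstrap option is principled but slower. Neither matches honest-forest
  variance estimates.
* The IPCW score omits the censoring-martingale augmentation term; it is
  consistent under covariate-independent censoring (true in the generator)
  but less efficient than the fully augmented estimator and may be biased
  when censoring depends on covariates beyond the treatment arm.
* SHAP values on strongly correlated features (the three BED variants)
  split credit between them; the relative-risk curves remain readable but
  individual attributions should not be over-interpreted.
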