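# fracsurv

Radiotherapy fractionation analysis for head-and-neck squamous cell
carcinoma (HNSCC): mechanistic biologically-effective-dose (BED) models
with tumor repopulation, an exploratory random-survival-forest stage with
Shapley-value interpretation, and a targeted doubly robust causal stage
estimating the effect of high vs. low BED on restricted mean survival time
(RMST) and survival probability (SP) — exercised end to end on a synthetic
cohort generator with known ground truth.

## Who this is for

Radiation-oncology modellers and biostatisticians who want to (a) compare
fractionation schedules on a repopulation-aware dose scale, and (b) move
beyond associational survival modelling to doubly robust causal effect
estimates of dose intensity, with every stage testable against a generator
whose true effects are known in closed form.

## The models

For `m` fractions of `d` Gy with alpha/beta ratio `r` (10 Gy for HNSCC),
elapsed treatment time `T` days, the three BED variants are

    BED_simp = m d (1 + d/r)                                       (no repopulation)
    BED_DI   = [m α d (d+r)/r − g T − λ max(0, T − T_k)] / α       (fixed onset T_k)
    BED_DD   = [m α d (d+r)/r − g T − λ (1 − e^{−k}) max(0, T − C/k)] / α

where `k = m α d (d+r)/(r T)` is the mean daily log cell kill: in the
dose-dependent (DD) model, intense schedules trigger accelerated
repopulation earlier (`C/k`) and faster (`λ(1 − e^{−k})`), but also finish
sooner. Published parameters: DI α = 0.069/Gy, λ = 0.035/day, T_k = 28.6 d;
DD α = 0.224/Gy, λ = 1.17/day, C = 14.5. The background rate `g` is
calibrated on the standard 35 × 2 Gy / 7-week schedule only, and the
calibrated models then reproduce the full reference table (see
`docs/methods.md`).

The causal stage dichotomizes one BED variant at a time (BED_DD > 61.8 Gy,
BED_DI > 57.6 Gy, BED_simp > 70 Gy — cut-points read off the Shapley
relative-risk curves or re-derived by a change-point detector) and
estimates, per horizon `h`, the average treatment effect on RMST(h) and
SP(h) from cross-fitted augmented inverse-propensity-weighted (AIPW) scores
with inverse-probability-of-censoring weights; per-patient effects come
from a regression forest on the scores and effect modification from the
best linear projection (OLS with HC3 errors).

## Worked example

Calibrate the repopulation models on the standard schedule and tabulate the
dose comparison (`python analysis/01_bed_table.py`):

```
calibrated on the standard schedule only (weekday day convention):
  g_DD = 0.016108 /day, g_DI = 0.016506 /day
  worst once-daily residual vs reference: DD 0.069 Gy, DI 0.272 Gy

 fractions  dose_per_fraction  bed_dd  bed_dd_diff_standard  bed_simp  bed_simp_diff_standard
        18               3.00   63.91                  1.72     70.20                  -13.80
        25               2.40   63.28                  1.09     74.40                   -9.60
        35               2.00   62.19                  0.00     84.00                    0.00
        40               1.60   60.88                 -1.31     74.24                   -9.76
```

Hypofractionated schedules (18 × 3, 25 × 2.4 Gy) *gain* 1–2 Gy of
dose-dependent BED over the 7-week standard despite delivering 6–16 Gy less
physical dose, because they outrun tumor repopulation; the no-repopulation
BED_simp ranks them the other way round. That reversal is the reason the
two downstream stages treat BED_DD/BED_DI and BED_simp separately.

Generate the default synthetic cohort and inspect its ground truth
(`python analysis/02_simulate_cohort.py`):

```
cohort: 3346 patients, event rate 42.2%
modal regimen: 35 x 2.0 Gy (2253 patients)
non-standard regimens with >50 patients: 4

true treatment effects of BED_DD > 61.8 Gy under this generator:
 horizon  rmst_effect  sp_effect
     1.0       0.0096     0.0181
     4.0       0.1173     0.0493
     8.0       0.3473     0.0621
    12.0       0.5949     0.0603
```

The forest stage (`analysis/03_rsf_shap.py`) fits the survival forest
(70:30 split, 10-fold CV), printing fold and held-out concordances and the
mean |SHAP| ranking — age, chemotherapy, HPV and smoking dominate, and the
repopulation-aware BED variants out-rank BED_simp, matching the generator's
construction. The change-point detector (`analysis/04_cutpoints.py`) then
reads the dichotomization threshold straight off the BED_DD relative-risk
curve:

```
variant     suggested  manual default
bed_dd          61.88            61.8
bed_di          54.89            57.6
bed_simp        72.00            70.0
```

`analysis/05_causal_effects.py` estimates the causal effects per variant
(ATE tables in years and percentage points, per-patient histograms, BLP),
and `analysis/06_refutations.py` runs the robustness battery (noise
injection, placebo treatment, outcome randomization, fake-effect
injection), each judged by a numeric criterion.

Equivalent one-shot run: `fracsurv run --out results/pipeline --seed 0`.

## Layout

```
src/fracsurv/     bed, cohort, shapley, forest, cutpoints, causal, refute, pipeline
analysis/         numbered narrative drivers (01 dose table ... 06 refutations)
tests/            pytest suite incl. end-to-end acceptance checks
docs/methods.md   models, defaults, numerical choices, limitations
```
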