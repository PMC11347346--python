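"""Robustness battery for the causal stage.

Each refutation is a pure, seeded function of the cohort table: it returns
a perturbed copy, never mutates its input, and is bit-reproducible.  The
battery re-runs the doubly robust estimator on the perturbed data and
judges the result against a numeric criterion:

* noise injection — appending independent standard-normal covariates must
  shift the ATE by less than 1 reference SE;
* placebo treatment / randomized outcomes — permuting the treatment, or
  jointly permuting the (time, event) pairs, must collapse the effect to
  insignificance (|ATE| < 2 SE at every horizon);
* fake effect — adding ``delta`` years to the uncensored survival times of
  treated patients must be detected (> 2 SE above the reference estimate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .causal import CausalEffectReport, CausalTask, NuisanceConfig, estimate_effects


@dataclass
class RefutationResult:
    name: str
    criterion: str
    passed: bool
    reference: pd.DataFrame
    perturbed: pd.DataFrame
    detail: str = ""


def add_noise_variables(table: pd.DataFrame, k: int, seed: int = 0) -> pd.DataFrame:
    """Append ``k`` independent N(0,1) covariate columns ``noise_0..k-1``."""
    if k < 0:
        raise ValueError("k must be >= 0")
    out = table.copy()
    rng = np.random.default_rng(seed)
    for j in range(k):
        out[f"noise_{j}"] = rng.standard_normal(len(table))
    return out


def placebo_treatment(table: pd.DataFrame, seed: int = 0, treatment_col: str = "treatment") -> pd.DataFrame:
    """Permute the treatment assignment across patients."""
    out = table.copy()
    rng = np.random.default_rng(seed)
    out[treatment_col] = rng.permutation(out[treatment_col].to_numpy())
    return out


def randomize_outcomes(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Jointly permute (Length_FU, Status, cause) across patients."""
    out = table.copy()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(table))
    for col in ("Length_FU", "Status", "cause"):
        if col in out.columns:
            out[col] = out[col].to_numpy()[perm]
    return out


def inject_fake_effect(
    table: pd.DataFrame,
    delta: float,
    seed: int = 0,
    treatment_col: str = "treatment",
    admin_cap: float = 12.0,
) -> pd.DataFrame:
    """Shift uncensored treated survival times by ``+delta`` years.

    Times pushed past the administrative cap are re-censored there.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    out = table.copy()
    shift = (out[treatment_col] == 1) & (out["Status"] == 1)
    t = out["Length_FU"].to_numpy(dtype=float).copy()
    ev = out["Status"].to_numpy(dtype=int).copy()
    t[shift.to_numpy()] += delta
    recensor = shift.to_numpy() & (t > admin_cap)
    t[recensor] = admin_cap
    ev[recensor] = 0
    out["Length_FU"] = t
    out["Status"] = ev
    if "cause" in out.columns:
        out.loc[recensor, "cause"] = "none"
    return out


# ---------------------------------------------------------------------------
# battery


def _significant_horizons(report: CausalEffectReport, estimand: str) -> list[float]:
    sub = report.ate[report.ate.estimand == estimand]
    return [
        float(r.horizon) for r in sub.itertuples() if abs(r.estimate) >= 2 * r.se
    ]


def run_battery(
    table: pd.DataFrame,
    task: CausalTask | None = None,
    nuisance: NuisanceConfig | None = None,
    folds: int = 10,
    seed: int = 0,
    noise_k: int = 5,
    fake_delta: float = 1.0,
    reference: CausalEffectReport | None = None,
) -> list[RefutationResult]:
    """Run the full refutation battery against a reference estimate.

    Criteria (estimand = RMST unless noted):

    * noise: |ATE_perturbed - ATE_reference| < 1 reference SE at every horizon;
    * placebo / randomized outcomes: |ATE_perturbed| < 2 SE at every horizon;
    * fake effect: RMST ATE at the longest horizon exceeds the reference by
      more than 2 reference SEs.
    """
    task = task or CausalTask()
    ref = reference or estimate_effects(table, task, folds=folds, seed=seed, nuisance=nuisance)
    results: list[RefutationResult] = []

    def _run(perturbed: pd.DataFrame, cov_extra: tuple[str, ...] = ()) -> CausalEffectReport:
        t = task
        if cov_extra:
            t = CausalTask(
                treatment_col=task.treatment_col,
                covariates=task.covariates + cov_extra,
                horizons=task.horizons,
                estimands=task.estimands,
            )
        return estimate_effects(perturbed, t, folds=folds, seed=seed, nuisance=nuisance)

    # -- noise injection ----------------------------------------------------
    noisy = add_noise_variables(table, noise_k, seed=seed + 1)
    rep_noise = _run(noisy, tuple(f"noise_{j}" for j in range(noise_k)))
    ref_rmst = ref.ate[ref.ate.estimand == "rmst"].set_index("horizon")
    new_rmst = rep_noise.ate[rep_noise.ate.estimand == "rmst"].set_index("horizon")
    shifts = (new_rmst["estimate"] - ref_rmst["estimate"]).abs() / ref_rmst["se"]
    results.append(
        RefutationResult(
            name="add_noise_variables",
            criterion="ATE shift < 1 reference SE at every horizon after appending "
            f"{noise_k} independent N(0,1) covariates",
            passed=bool((shifts < 1.0).all()),
            reference=ref.ate,
            perturbed=rep_noise.ate,
            detail=f"max shift {shifts.max():.2f} SE",
        )
    )

    # -- placebo treatment ---------------------------------------------------
    rep_placebo = _run(placebo_treatment(table, seed=seed + 2, treatment_col=task.treatment_col))
    sig = _significant_horizons(rep_placebo, "rmst") + _significant_horizons(rep_placebo, "sp")
    results.append(
        RefutationResult(
            name="placebo_treatment",
            criterion="|ATE| < 2 SE at every horizon under permuted treatment",
            passed=len(sig) == 0,
            reference=ref.ate,
            perturbed=rep_placebo.ate,
            detail=f"significant horizons: {sorted(set(sig))}" if sig else "none significant",
        )
    )

    # -- randomized outcomes -------------------------------------------------
    rep_rand = _run(randomize_outcomes(table, seed=seed + 3))
    sig = _significant_horizons(rep_rand, "rmst") + _significant_horizons(rep_rand, "sp")
    results.append(
        RefutationResult(
            name="randomize_outcomes",
            criterion="|ATE| < 2 SE at every horizon under jointly permuted outcomes",
            passed=len(sig) == 0,
            reference=ref.ate,
            perturbed=rep_rand.ate,
            detail=f"significant horizons: {sorted(set(sig))}" if sig else "none significant",
        )
    )

    # -- fake effect ----------------------------------------------------------
    rep_fake = _run(inject_fake_effect(table, fake_delta, seed=seed + 4, treatment_col=task.treatment_col))
    h = ref.horizons[-1]
    ref_est, ref_se = ref.ate_at("rmst", h)
    fake_est, _ = rep_fake.ate_at("rmst", h)
    detected = fake_est - ref_est > 2 * ref_se
    results.append(
        RefutationResult(
            name="inject_fake_effect",
            criterion=f"RMST ATE at {h:g} y rises > 2 reference SE after shifting "
            f"treated event times by +{fake_delta:g} y",
            passed=bool(detected),
            reference=ref.ate,
            perturbed=rep_fake.ate,
            detail=f"reference {ref_est:.3f}±{ref_se:.3f}, perturbed {fake_est:.3f}",
        )
    )
    return results


def battery_frame(results: list[RefutationResult]) -> pd.DataFrame:
    """Aggregate pass/fail table suitable for CI gating."""
    return pd.DataFrame(
        [
            {"test": r.name, "passed": r.passed, "criterion": r.criterion, "detail": r.detail}
            for r in results
        ]
    )
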