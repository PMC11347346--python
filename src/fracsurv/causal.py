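"""Doubly robust causal effects of a binary dose indicator on survival.

Estimates the average and conditional average treatment effect of a
binarized biologically-effective-dose indicator on two estimands at a grid
of horizons h:

* RMST(h): restricted mean survival time, ``E[min(T, h)]``, in years;
* SP(h): survival probability ``P(T > h)`` (reported in percentage points
  by convention downstream).

The estimator is cross-fitted augmented inverse-propensity weighting
(AIPW) with inverse-probability-of-censoring weights (IPCW).  For each
held-out fold, nuisances fitted on the complementary folds provide

* a propensity model e(X) = P(W = 1 | X) (probability forest or logistic
  regression), clipped to [0.05, 0.95] with the clipped count logged;
* arm-specific conditional survival curves S_w(t | X) from random survival
  forests, giving outcome regressions m_w(h | X) for both estimands;
* a censoring survival curve G_w(t) (per-arm Kaplan–Meier of the censoring
  distribution).

The per-patient doubly robust score for arm w is

    phi_w = m_w(X) + 1{W = w} / e_w(X) * Delta(h) / G_w(min(T,h)-) * (Y - m_w(X))

with Delta(h) = 1 when the h-horizon outcome Y is observed (death before h
or follow-up past h).  The effect score is phi_1 - phi_0; its mean is the
ATE and its standard deviation over sqrt(n) the SE.  Consistency requires
either the propensity+censoring models or the outcome model to be correct
— the doubly robust property — which the test-suite exercises by
deliberately breaking one nuisance at a time.

Per-patient effects (CATEs) come from a regression forest fitted to the
scores (out-of-bag predictions; per-patient uncertainty from the spread of
tree predictions or a bootstrap).  Effect modification is summarized by
the best linear projection (BLP): OLS of the scores on covariates with
heteroskedasticity-robust (HC3) standard errors.  BLP coefficients measure
how covariates modulate the *treatment effect* — a large p-value does not
mean the covariate has no effect on mortality itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .forest import ForestConfig, fit_survival_forest

logger = logging.getLogger(__name__)

DEFAULT_CAUSAL_COVARIATES = [
    "Sex",
    "Smoking_PY",
    "Stage_numeric",
    "HPV_Positive",
    "HPV_Unknown",
    "Chemo",
    "RT_year",
    "Age",
]

ESTIMANDS = ("rmst", "sp")


class PositivityError(RuntimeError):
    """Propensity overlap too poor to identify the effect.

    Positivity requires every covariate stratum to have a nonzero
    probability of receiving either treatment level; when more than 20% of
    propensities fall outside the trimming bounds the estimate would rest
    on extrapolation, so estimation stops instead.
    """


@dataclass(frozen=True)
class CausalTask:
    """What to estimate: treatment column, adjustment set, horizons."""

    treatment_col: str = "treatment"
    covariates: tuple[str, ...] = tuple(DEFAULT_CAUSAL_COVARIATES)
    horizons: tuple[float, ...] = tuple(float(h) for h in range(1, 13))
    estimands: tuple[str, ...] = ESTIMANDS

    def __post_init__(self) -> None:
        hs = list(self.horizons)
        if any(h <= 0 for h in hs) or hs != sorted(hs):
            raise ValueError("horizons must be positive and sorted")
        bed_cols = {"bed_simp", "bed_di", "bed_dd"}
        overlap = bed_cols & set(self.covariates)
        if overlap:
            raise ValueError(
                f"BED variants {sorted(overlap)} may not appear in the adjustment set "
                "when another BED variant is the treatment"
            )
        for e in self.estimands:
            if e not in ESTIMANDS:
                raise ValueError(f"unknown estimand {e!r}")


@dataclass(frozen=True)
class NuisanceConfig:
    """Which nuisance models to use (and how to deliberately break them)."""

    propensity: str = "forest"  # forest | logistic | empirical | constant
    constant_propensity: float = 0.5
    outcome: str = "forest"  # forest | constant
    censoring: str = "km"  # km | none
    outcome_trees: int = 52
    outcome_min_leaf: int = 30
    propensity_trees: int = 200
    propensity_min_leaf: int = 20
    trim: tuple[float, float] = (0.05, 0.95)


@dataclass
class CausalEffectReport:
    task: CausalTask
    horizons: list[float]  # horizons actually used (capped at follow-up)
    ate: pd.DataFrame  # horizon, estimand, estimate, se, n
    fold_effects: pd.DataFrame  # fold, horizon, estimand, estimate
    scores: dict  # estimand -> DataFrame (rows = patients, cols = horizons)
    propensity: np.ndarray
    trimmed_fraction: float
    covariate_frame: pd.DataFrame = field(repr=False, default=None)
    treatment: np.ndarray = field(repr=False, default=None)

    def ate_at(self, estimand: str, horizon: float) -> tuple[float, float]:
        row = self.ate[(self.ate.estimand == estimand) & (self.ate.horizon == horizon)]
        return float(row["estimate"].iloc[0]), float(row["se"].iloc[0])


def _km_censoring(train: pd.DataFrame) -> KaplanMeierFitter:
    km = KaplanMeierFitter()
    km.fit(train["Length_FU"], 1 - train["Status"])
    return km


def _surv_left_limit(km: KaplanMeierFitter, times: np.ndarray) -> np.ndarray:
    return km.survival_function_at_times(np.maximum(times - 1e-9, 0.0)).to_numpy()


def _step_rmst(surv: np.ndarray, grid: np.ndarray, horizon: float) -> np.ndarray:
    """Integrate right-continuous step survival curves from 0 to horizon."""
    edges = np.concatenate([[0.0], np.minimum(grid, horizon)])
    widths = np.diff(edges)
    vals = np.concatenate([np.ones((surv.shape[0], 1)), surv[:, :-1]], axis=1)
    head = vals[:, : len(widths)] @ widths
    # tail beyond the last grid time, if the horizon extends past it
    tail = max(horizon - min(grid[-1], horizon), 0.0) * surv[:, -1]
    return head + tail


def estimate_effects(
    table: pd.DataFrame,
    task: CausalTask | None = None,
    folds: int = 10,
    seed: int = 0,
    nuisance: NuisanceConfig | None = None,
    horizon_cap_quantile: float = 0.95,
) -> CausalEffectReport:
    """Cross-fitted doubly robust ATE of a binary treatment on RMST and SP.

    Horizons beyond the ``horizon_cap_quantile`` quantile of follow-up are
    dropped (censoring weights explode there).  Raises
    :class:`PositivityError` when more than 20% of propensities need
    trimming.
    """
    task = task or CausalTask()
    nuis = nuisance or NuisanceConfig()
    W = table[task.treatment_col].to_numpy(dtype=int)
    if W.sum() == 0 or W.sum() == len(W):
        raise PositivityError("one treatment arm is empty")
    X = table[list(task.covariates)].copy()
    time = table["Length_FU"].to_numpy(dtype=float)
    event = table["Status"].to_numpy(dtype=int)
    n = len(table)

    cap = float(np.quantile(time, horizon_cap_quantile))
    horizons = [h for h in task.horizons if h <= cap]
    if not horizons:
        raise ValueError(f"no horizon lies below the follow-up cap {cap:.2f} y")
    dropped = [h for h in task.horizons if h > cap]
    if dropped:
        logger.info("dropping horizons beyond %.2f y of follow-up: %s", cap, dropped)

    if folds == 1:
        idx = np.arange(n)
        splits = [(idx, idx)]  # no cross-fitting: fit and score on everything
    else:
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(kf.split(table))
    prop = np.empty(n)
    raw_outside = 0
    scores = {e: np.full((n, len(horizons)), np.nan) for e in task.estimands}
    fold_ids = np.empty(n, dtype=int)

    for fold, (tr_idx, te_idx) in enumerate(splits):
        fold_ids[te_idx] = fold
        tr = table.iloc[tr_idx]
        Xtr, Xte = X.iloc[tr_idx], X.iloc[te_idx]
        Wtr = W[tr_idx]

        # -- propensity ---------------------------------------------------
        if nuis.propensity == "forest":
            clf = RandomForestClassifier(
                n_estimators=nuis.propensity_trees,
                min_samples_leaf=nuis.propensity_min_leaf,
                random_state=seed + fold,
                n_jobs=1,
            ).fit(Xtr, Wtr)
            e_raw = clf.predict_proba(Xte)[:, list(clf.classes_).index(1)]
        elif nuis.propensity == "logistic":
            clf = LogisticRegression(max_iter=2000).fit(
                (Xtr - Xtr.mean()) / Xtr.std().replace(0, 1), Wtr
            )
            e_raw = clf.predict_proba((Xte - Xtr.mean()) / Xtr.std().replace(0, 1))[:, 1]
        elif nuis.propensity == "empirical":
            e_raw = np.full(len(te_idx), Wtr.mean())
        elif nuis.propensity == "constant":
            e_raw = np.full(len(te_idx), nuis.constant_propensity)
        else:
            raise ValueError(f"unknown propensity model {nuis.propensity!r}")
        lo, hi = nuis.trim
        raw_outside += int(np.sum((e_raw < lo) | (e_raw > hi)))
        e = np.clip(e_raw, lo, hi)
        prop[te_idx] = e

        # -- censoring ----------------------------------------------------
        km_cens = {}
        for w in (0, 1):
            arm = tr[Wtr == w]
            km_cens[w] = _km_censoring(arm) if nuis.censoring == "km" and len(arm) else None

        # -- outcome ------------------------------------------------------
        m_hat = {w: {e_: np.zeros((len(te_idx), len(horizons))) for e_ in task.estimands} for w in (0, 1)}
        if nuis.outcome == "forest":
            for w in (0, 1):
                arm = tr[Wtr == w]
                cfg = ForestConfig(
                    min_samples_leaf=min(nuis.outcome_min_leaf, max(2, len(arm) // 10)),
                    min_samples_split=2,
                    n_estimators=nuis.outcome_trees,
                    seed=seed + fold,
                )
                m = fit_survival_forest(arm, cfg, list(task.covariates))
                grid = m.model.unique_times_
                surv = m.model.predict_survival_function(
                    Xte.to_numpy(dtype=float), return_array=True
                )
                for j, h in enumerate(horizons):
                    if "sp" in task.estimands:
                        i = int(np.searchsorted(grid, h, side="right")) - 1
                        m_hat[w]["sp"][:, j] = 1.0 if i < 0 else surv[:, i]
                    if "rmst" in task.estimands:
                        m_hat[w]["rmst"][:, j] = _step_rmst(surv, grid, h)
        elif nuis.outcome == "constant":
            km_all = KaplanMeierFitter().fit(tr["Length_FU"], tr["Status"])
            for j, h in enumerate(horizons):
                sp_const = float(km_all.survival_function_at_times(h).iloc[0])
                grid_h = np.linspace(0, h, 200)
                rmst_const = float(
                    np.trapezoid(km_all.survival_function_at_times(grid_h).to_numpy(), grid_h)
                )
                for w in (0, 1):
                    if "sp" in task.estimands:
                        m_hat[w]["sp"][:, j] = sp_const
                    if "rmst" in task.estimands:
                        m_hat[w]["rmst"][:, j] = rmst_const
        else:
            raise ValueError(f"unknown outcome model {nuis.outcome!r}")

        # -- doubly robust scores ----------------------------------------
        t_te, ev_te, w_te = time[te_idx], event[te_idx], W[te_idx]
        for j, h in enumerate(horizons):
            observed = ((ev_te == 1) & (t_te <= h)) | (t_te >= h)
            t_min = np.minimum(t_te, h)
            g = np.ones(len(te_idx))
            if nuis.censoring == "km":
                for w in (0, 1):
                    sel = w_te == w
                    if km_cens[w] is not None and sel.any():
                        g[sel] = _surv_left_limit(km_cens[w], t_min[sel])
            g = np.clip(g, 0.05, None)
            ipcw = observed / g
            y = {"sp": (t_te > h).astype(float), "rmst": t_min}
            for est in task.estimands:
                phi1 = m_hat[1][est][:, j] + (w_te / e) * ipcw * (y[est] - m_hat[1][est][:, j])
                phi0 = m_hat[0][est][:, j] + ((1 - w_te) / (1 - e)) * ipcw * (
                    y[est] - m_hat[0][est][:, j]
                )
                scores[est][te_idx, j] = phi1 - phi0

    trimmed_fraction = raw_outside / n
    if trimmed_fraction > 0.20:
        raise PositivityError(
            f"{trimmed_fraction:.0%} of propensities lie outside {nuis.trim}; "
            "positivity (a nonzero chance of either treatment in every covariate "
            "stratum) is violated too strongly to proceed"
        )
    if raw_outside:
        logger.info("trimmed %d of %d propensities to %s", raw_outside, n, nuis.trim)

    ate_rows, fold_rows = [], []
    for est in task.estimands:
        for j, h in enumerate(horizons):
            s = scores[est][:, j]
            ate_rows.append(
                {
                    "horizon": h,
                    "estimand": est,
                    "estimate": float(np.mean(s)),
                    "se": float(np.std(s, ddof=1) / np.sqrt(n)),
                    "n": n,
                }
            )
            for fold in range(folds):
                sel = fold_ids == fold
                fold_rows.append(
                    {
                        "fold": fold,
                        "horizon": h,
                        "estimand": est,
                        "estimate": float(np.mean(s[sel])),
                    }
                )
    return CausalEffectReport(
        task=task,
        horizons=horizons,
        ate=pd.DataFrame(ate_rows),
        fold_effects=pd.DataFrame(fold_rows),
        scores={e: pd.DataFrame(scores[e], columns=horizons) for e in task.estimands},
        propensity=prop,
        trimmed_fraction=trimmed_fraction,
        covariate_frame=X,
        treatment=W,
    )


# ---------------------------------------------------------------------------
# per-patient effects


@dataclass
class PerPatientEffects:
    estimand: str
    horizon: float
    cate: np.ndarray
    cate_se: np.ndarray
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    positive_share: float


def per_patient_effects(
    report: CausalEffectReport,
    estimand: str = "sp",
    horizon: float | None = None,
    n_trees: int = 200,
    min_samples_leaf: int = 20,
    se_method: str = "forest",
    n_bootstrap: int = 50,
    bins: int = 30,
    seed: int = 0,
) -> PerPatientEffects:
    """Per-patient CATEs from a regression forest on the doubly robust scores.

    ``horizon=None`` picks the horizon where the mean effect for the chosen
    estimand peaks.  Out-of-bag predictions avoid own-observation bias.
    ``se_method`` is either "forest" (spread of per-tree predictions) or
    "bootstrap" (refit on resampled score vectors).
    """
    if horizon is None:
        sub = report.ate[report.ate.estimand == estimand]
        horizon = float(sub.loc[sub["estimate"].idxmax(), "horizon"])
    s = report.scores[estimand][horizon].to_numpy()
    X = report.covariate_frame.to_numpy(dtype=float)
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        min_samples_leaf=min_samples_leaf,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    ).fit(X, s)
    cate = rf.oob_prediction_

    if se_method == "forest":
        per_tree = np.stack([t.predict(X) for t in rf.estimators_])
        cate_se = per_tree.std(axis=0) / np.sqrt(len(rf.estimators_) / 10.0)
    elif se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty((n_bootstrap, len(s)))
        for b in range(n_bootstrap):
            idx = rng.integers(0, len(s), len(s))
            rb = RandomForestRegressor(
                n_estimators=max(n_trees // 4, 25),
                min_samples_leaf=min_samples_leaf,
                random_state=seed + b + 1,
                n_jobs=1,
            ).fit(X[idx], s[idx])
            boots[b] = rb.predict(X)
        cate_se = boots.std(axis=0, ddof=1)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")

    counts, edges = np.histogram(cate, bins=bins)
    return PerPatientEffects(
        estimand=estimand,
        horizon=horizon,
        cate=cate,
        cate_se=cate_se,
        hist_counts=counts,
        hist_edges=edges,
        positive_share=float(np.mean(cate > 0)),
    )


# ---------------------------------------------------------------------------
# best linear projection


def blp(
    report: CausalEffectReport,
    estimand: str = "rmst",
    horizon: float | None = None,
    covariates: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Best linear projection of the doubly robust scores onto covariates.

    OLS with HC3 heteroskedasticity-robust standard errors.  Coefficients
    quantify treatment-effect *modification*: a nonsignificant coefficient
    says the covariate does not modulate the causal effect, not that it is
    unrelated to mortality.  Collinear columns are dropped with a warning.
    """
    if horizon is None:
        sub = report.ate[report.ate.estimand == estimand]
        horizon = float(sub.loc[sub["estimate"].idxmax(), "horizon"])
    s = report.scores[estimand][horizon].to_numpy()
    cols = list(covariates) if covariates is not None else list(report.task.covariates)
    Xf = report.covariate_frame[cols] if cols else report.covariate_frame.iloc[:, :0]

    keep: list[str] = []
    design = np.ones((len(s), 1))
    for c in cols:
        candidate = np.column_stack([design, Xf[c].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(candidate) == candidate.shape[1]:
            design = candidate
            keep.append(c)
        else:
            logger.warning("blp: dropping collinear covariate %r", c)
    model = sm.OLS(s, design).fit(cov_type="HC3")
    names = ["intercept"] + keep
    return pd.DataFrame(
        {
            "covariate": names,
            "estimate": model.params,
            "se_robust": model.bse,
            "p_value": model.pvalues,
            "estimand": estimand,
            "horizon": horizon,
        }
    )


# ---------------------------------------------------------------------------
# univariate comparison


def km_logrank(table: pd.DataFrame, W: np.ndarray) -> tuple[pd.DataFrame, float, float]:
    """Kaplan–Meier curves per arm and the two-sided logrank test.

    Returns ``(curves, chi2, p)``.  Raises if either arm has no events.
    """
    W = np.asarray(W, dtype=int)
    frames = []
    for w in (0, 1):
        sub = table[W == w]
        if len(sub) == 0:
            raise ValueError(f"treatment arm {w} is empty")
        if sub["Status"].sum() == 0:
            raise ValueError(f"treatment arm {w} has no events")
        km = KaplanMeierFitter().fit(sub["Length_FU"], sub["Status"], label=f"arm_{w}")
        sf = km.survival_function_
        frames.append(
            pd.DataFrame({"arm": w, "time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})
        )
    res = logrank_test(
        table.loc[W == 1, "Length_FU"],
        table.loc[W == 0, "Length_FU"],
        table.loc[W == 1, "Status"],
        table.loc[W == 0, "Status"],
    )
    return pd.concat(frames, ignore_index=True), float(res.test_statistic), float(res.p_value)
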