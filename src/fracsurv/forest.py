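"""Exploratory survival-forest stage: fitting, concordance, KM overlays,
Shapley interpretation, and competing-risks summaries.

The forest is a right-censoring-aware random survival forest
(scikit-survival).  Model interpretation reduces the forest to a scalar
risk score — the log of the ensemble cumulative hazard at a reference time
(default: the cohort's median event time) — and attributes it to features
with Shapley values; exponentiating an attribution then reads as a
multiplicative change in predicted mortality risk, which is the
"relative risk" scale used for the cut-point curves.

Competing-risks analysis is cause-specific: one forest per cause of death
(other causes treated as censoring) for predictions and permutation
variable importance, plus nonparametric cause-specific Nelson–Aalen
cumulative hazards and Aalen–Johansen cumulative incidence functions that
satisfy ``sum_c CIF_c(t) = 1 - S(t)`` exactly on the event grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter, NelsonAalenFitter
from sklearn.model_selection import KFold, train_test_split
from sksurv.ensemble import RandomSurvivalForest
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from .cohort import CAUSES, COVARIATE_COLUMNS
from .shapley import normalize_to_relative_risk, running_median, shap_permutation

logger = logging.getLogger(__name__)

DEFAULT_FEATURES = COVARIATE_COLUMNS + ["bed_simp", "bed_di", "bed_dd"]


class UnfitError(RuntimeError):
    """Training data cannot support a survival fit."""


@dataclass(frozen=True)
class SplitPlan:
    """70:30 train/test split with 10-fold CV on the training portion."""

    train_fraction: float = 0.70
    cv_folds: int = 10
    seed: int = 0


@dataclass(frozen=True)
class ForestConfig:
    """Survival-forest hyperparameters.

    The defaults are the tuned overall-survival settings; ``hpv_negative``
    and ``competing_risks`` give the settings used for the HPV- subset and
    the cause-specific analysis.
    """

    min_samples_leaf: int = 30
    min_samples_split: int = 2
    n_estimators: int = 52
    seed: int = 0

    @classmethod
    def os_full(cls, seed: int = 0) -> "ForestConfig":
        return cls(30, 2, 52, seed)

    @classmethod
    def hpv_negative(cls, seed: int = 0) -> "ForestConfig":
        return cls(10, 2, 65, seed)

    @classmethod
    def competing_risks(cls, seed: int = 0) -> "ForestConfig":
        return cls(30, 2, 300, seed)


def _surv_y(table: pd.DataFrame, event_col: str = "Status", time_col: str = "Length_FU"):
    return Surv.from_arrays(
        event=table[event_col].to_numpy(dtype=bool),
        time=table[time_col].to_numpy(dtype=float),
    )


@dataclass
class SurvivalForestModel:
    """A fitted forest plus the feature list and reference time it uses."""

    model: RandomSurvivalForest
    features: list[str]
    reference_time: float

    def _matrix(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(table, pd.DataFrame):
            return table[self.features].to_numpy(dtype=float)
        return np.asarray(table, dtype=float)

    def predict_survival(self, table, times: np.ndarray) -> np.ndarray:
        X = self._matrix(table)
        surv = self.model.predict_survival_function(X, return_array=True)
        grid = self.model.unique_times_
        idx = np.searchsorted(grid, times, side="right") - 1
        out = np.empty((len(X), len(times)))
        for j, i in enumerate(idx):
            out[:, j] = 1.0 if i < 0 else surv[:, i]
        return out

    def risk_score(self, table) -> np.ndarray:
        """Log ensemble cumulative hazard at the reference time.

        Uses per-tree leaf lookups (each survival tree stores its
        Nelson-Aalen curve per node), which agrees exactly with the full
        cumulative-hazard prediction at that time but avoids materializing
        the whole time grid — Shapley attribution makes millions of calls.
        """
        X = self._matrix(table).astype(np.float32)
        grid = self.model.unique_times_
        i = max(int(np.searchsorted(grid, self.reference_time, side="right")) - 1, 0)
        acc = np.zeros(len(X))
        for tree in self.model.estimators_:
            leaves = tree.apply(X)
            acc += tree.tree_.value[leaves, i, 0]
        return np.log(acc / len(self.model.estimators_) + 1e-12)

    def predict_risk(self, table) -> np.ndarray:
        return self.model.predict(self._matrix(table))


def fit_survival_forest(
    train: pd.DataFrame,
    cfg: ForestConfig | None = None,
    features: Sequence[str] | None = None,
    event_col: str = "Status",
    time_col: str = "Length_FU",
) -> SurvivalForestModel:
    """Fit a random survival forest on the training table."""
    cfg = cfg or ForestConfig()
    features = list(features or DEFAULT_FEATURES)
    if train[event_col].sum() == 0:
        raise UnfitError("training data contain no events; cannot fit a survival forest")
    rsf = RandomSurvivalForest(
        n_estimators=cfg.n_estimators,
        min_samples_leaf=cfg.min_samples_leaf,
        min_samples_split=cfg.min_samples_split,
        random_state=cfg.seed,
        n_jobs=1,
    )
    rsf.fit(train[features].to_numpy(dtype=float), _surv_y(train, event_col, time_col))
    ref_time = float(np.median(train.loc[train[event_col] == 1, time_col]))
    return SurvivalForestModel(rsf, features, ref_time)


def concordance(
    event: np.ndarray, time: np.ndarray, risk: np.ndarray
) -> float:
    """Harrell's c-index (ties in risk count 0.5)."""
    event = np.asarray(event, dtype=bool)
    if event.sum() < 2:
        raise UnfitError("concordance undefined with fewer than 2 events")
    c, *_ = concordance_index_censored(event, np.asarray(time, dtype=float), np.asarray(risk, dtype=float))
    return float(c)


@dataclass
class ConcordanceReport:
    c_train_folds: list[float]
    c_test_folds: list[float]
    c_holdout: float

    def summary(self) -> dict[str, float]:
        return {
            "c_index_train_fold_mean": float(np.mean(self.c_train_folds)),
            "c_index_train_fold_sd": float(np.std(self.c_train_folds, ddof=1)),
            "c_index_test_fold_mean": float(np.mean(self.c_test_folds)),
            "c_index_test_fold_sd": float(np.std(self.c_test_folds, ddof=1)),
            "c_index_holdout": self.c_holdout,
        }


def evaluate_concordance(
    table: pd.DataFrame,
    cfg: ForestConfig | None = None,
    plan: SplitPlan | None = None,
    features: Sequence[str] | None = None,
) -> tuple[ConcordanceReport, SurvivalForestModel, pd.DataFrame, pd.DataFrame]:
    """70:30 split, refit-per-fold CV on train, and held-out evaluation.

    Returns ``(report, model_fit_on_full_train, train_table, test_table)``.
    """
    plan = plan or SplitPlan()
    cfg = cfg or ForestConfig()
    features = list(features or DEFAULT_FEATURES)
    train, test = train_test_split(
        table, train_size=plan.train_fraction, random_state=plan.seed, shuffle=True
    )
    kf = KFold(n_splits=plan.cv_folds, shuffle=True, random_state=plan.seed)
    c_tr, c_te = [], []
    for fold_train_idx, fold_test_idx in kf.split(train):
        ft = train.iloc[fold_train_idx]
        fv = train.iloc[fold_test_idx]
        m = fit_survival_forest(ft, cfg, features)
        c_tr.append(concordance(ft["Status"], ft["Length_FU"], m.predict_risk(ft)))
        c_te.append(concordance(fv["Status"], fv["Length_FU"], m.predict_risk(fv)))
    model = fit_survival_forest(train, cfg, features)
    c_hold = concordance(test["Status"], test["Length_FU"], model.predict_risk(test))
    report = ConcordanceReport(c_tr, c_te, c_hold)
    return report, model, train.reset_index(drop=True), test.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Kaplan-Meier by group with model overlay


def km_by_group(
    table: pd.DataFrame,
    group: pd.Series | np.ndarray,
    model: SurvivalForestModel | None = None,
    times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Kaplan–Meier curves (Greenwood 95% CI) per group, with the mean
    model-predicted survival curve overlaid when a model is given.

    Empty groups and groups without events are skipped with a warning.
    """
    group = pd.Series(np.asarray(group), index=table.index, name="group")
    frames = []
    for g, sub in table.groupby(group):
        if len(sub) == 0 or sub["Status"].sum() == 0:
            logger.warning("km_by_group: skipping group %r (no events)", g)
            continue
        km = KaplanMeierFitter()
        km.fit(sub["Length_FU"], sub["Status"])
        grid = times if times is not None else km.survival_function_.index.to_numpy()
        sf = km.survival_function_at_times(grid).to_numpy()
        ci = km.confidence_interval_survival_function_
        lo = np.interp(grid, ci.index.to_numpy(), ci.iloc[:, 0].to_numpy())
        hi = np.interp(grid, ci.index.to_numpy(), ci.iloc[:, 1].to_numpy())
        frame = pd.DataFrame(
            {"group": g, "time": grid, "km": sf, "km_lo": lo, "km_hi": hi}
        )
        if model is not None:
            frame["model_mean"] = model.predict_survival(sub, grid).mean(axis=0)
        frames.append(frame)
    if not frames:
        raise UnfitError("no group had any events")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Shapley interpretation


def shap_values(
    model: SurvivalForestModel,
    table: pd.DataFrame,
    background: pd.DataFrame | None = None,
    n_background: int = 20,
    n_permutations: int = 12,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Shapley attributions of the forest's log-risk score.

    Returns ``(shap_frame, base_value)``; ``shap_frame`` has one column per
    feature and satisfies base + row-sum = risk score for every patient.
    A constant-output model yields all-zero attributions.
    """
    bg_src = background if background is not None else table
    rng = np.random.default_rng(seed)
    take = rng.choice(len(bg_src), size=min(n_background, len(bg_src)), replace=False)
    bg = bg_src.iloc[take][model.features].to_numpy(dtype=float)
    X = table[model.features].to_numpy(dtype=float)
    phi, base = shap_permutation(
        model.risk_score, X, bg, n_permutations=n_permutations, seed=seed
    )
    return pd.DataFrame(phi, columns=model.features, index=table.index), base


def normalize_shap(
    shap_frame: pd.DataFrame,
    table: pd.DataFrame,
    feature: str,
    window: int = 21,
) -> pd.DataFrame:
    """Relative-risk curve of a feature: exp(attribution) vs feature value.

    1.0 means no change from the population-average prediction; 1.1 a 10%
    higher predicted mortality risk.  Points are sorted by feature value and
    smoothed with a running median.
    """
    order = np.argsort(table[feature].to_numpy())
    x = table[feature].to_numpy()[order]
    rr = normalize_to_relative_risk(shap_frame[feature].to_numpy()[order])
    return pd.DataFrame(
        {"value": x, "relative_risk": rr, "smoothed": running_median(rr, window)}
    )


def shap_feature_correlations(shap_frame: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each feature with every SHAP column."""
    feats = list(shap_frame.columns)
    out = np.zeros((len(feats), len(feats)))
    for i, f in enumerate(feats):
        x = table[f].to_numpy(dtype=float)
        for j, g in enumerate(feats):
            s = shap_frame[g].to_numpy()
            if np.std(x) == 0 or np.std(s) == 0:
                out[i, j] = np.nan
            else:
                out[i, j] = np.corrcoef(x, s)[0, 1]
    return pd.DataFrame(out, index=feats, columns=[f"shap_{f}" for f in feats])


# ---------------------------------------------------------------------------
# competing risks


def aalen_johansen(
    time: np.ndarray,
    event: np.ndarray,
    cause: np.ndarray,
    causes: Sequence[str] = CAUSES,
) -> pd.DataFrame:
    """Aalen–Johansen cumulative incidence per cause on the event grid.

    Ties between events and censorings at the same time are resolved
    events-first.  By construction ``sum_c CIF_c(t) + S(t) = 1`` at every
    grid time, with S the all-cause Kaplan–Meier.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    cause = np.asarray(cause, dtype=object)
    grid = np.unique(time[event == 1])
    n = len(time)
    surv_prev = 1.0
    at_risk_all = n
    rows = []
    cif = {c: 0.0 for c in causes}
    for t in grid:
        at_risk = int(np.sum(time >= t))
        d_by_cause = {c: int(np.sum((time == t) & (event == 1) & (cause == c))) for c in causes}
        d_tot = sum(d_by_cause.values())
        for c in causes:
            cif[c] += surv_prev * d_by_cause[c] / at_risk
        surv = surv_prev * (1.0 - d_tot / at_risk)
        rows.append({"time": t, "survival": surv, **{f"cif_{c}": cif[c] for c in causes}})
        surv_prev = surv
    out = pd.DataFrame(rows)
    zero_causes = [c for c in causes if out[f"cif_{c}"].iloc[-1] == 0.0] if len(out) else list(causes)
    for c in zero_causes:
        logger.warning("aalen_johansen: cause %r has zero events; its CIF is identically 0", c)
    return out


@dataclass
class CompetingRisksReport:
    cschf: pd.DataFrame  # Nelson-Aalen cause-specific cumulative hazards
    cif: pd.DataFrame  # Aalen-Johansen cumulative incidences + overall survival
    vimp: pd.DataFrame  # permutation importance per feature per cause
    models: dict = field(default_factory=dict)
    c_index: dict = field(default_factory=dict)


def competing_risks_analysis(
    table: pd.DataFrame,
    cfg: ForestConfig | None = None,
    features: Sequence[str] | None = None,
    causes: Sequence[str] = CAUSES,
    vimp_repeats: int = 3,
    eval_table: pd.DataFrame | None = None,
    seed: int = 0,
) -> CompetingRisksReport:
    """Cause-specific forests plus nonparametric CSCHF/CIF and VIMP.

    For each cause a survival forest is fitted treating deaths from other
    causes as censored.  VIMP for a feature is the drop in that cause's
    c-index (on ``eval_table``, default the training table) after permuting
    the feature, averaged over ``vimp_repeats`` permutations.
    """
    cfg = cfg or ForestConfig.competing_risks()
    features = list(features or DEFAULT_FEATURES)
    eval_tab = eval_table if eval_table is not None else table
    rng = np.random.default_rng(seed)

    # nonparametric summaries
    cif = aalen_johansen(table["Length_FU"], table["Status"], table["cause"], causes)
    na_frames = []
    for c in causes:
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(table["Length_FU"], (table["Status"] == 1) & (table["cause"] == c))
        h = naf.cumulative_hazard_
        na_frames.append(
            pd.DataFrame({"time": h.index.to_numpy(), "cschf": h.iloc[:, 0].to_numpy(), "cause": c})
        )
    cschf = pd.concat(na_frames, ignore_index=True)

    models, cidx = {}, {}
    vimp_rows = []
    for c in causes:
        sub = table.copy()
        sub["Status"] = ((table["Status"] == 1) & (table["cause"] == c)).astype(int)
        if sub["Status"].sum() == 0:
            logger.warning("competing_risks_analysis: no events for cause %r; skipping forest", c)
            continue
        m = fit_survival_forest(sub, cfg, features)
        models[c] = m
        ev = eval_tab.copy()
        ev_event = ((ev["Status"] == 1) & (ev["cause"] == c)).astype(int)
        risk = m.predict_risk(ev)
        c0 = concordance(ev_event, ev["Length_FU"], risk)
        cidx[c] = c0
        for f in features:
            drops = []
            for _ in range(vimp_repeats):
                perm = ev.copy()
                perm[f] = rng.permutation(perm[f].to_numpy())
                drops.append(c0 - concordance(ev_event, ev["Length_FU"], m.predict_risk(perm)))
            vimp_rows.append({"cause": c, "feature": f, "vimp": float(np.mean(drops))})
    vimp = pd.DataFrame(vimp_rows)
    return CompetingRisksReport(cschf=cschf, cif=cif, vimp=vimp, models=models, c_index=cidx)
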