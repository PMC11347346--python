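"""Synthetic HNSCC radiotherapy cohort generator with known ground truth.

Emulates the covariate structure of a modern definitive-radiotherapy
head-and-neck cohort (the public RADCURE collection): demographics, smoking,
AJCC stage, HPV status with a missing category, concurrent chemotherapy,
treatment calendar year, the empirical fractionation-regimen mix, and a
survival process with competing causes of death.

The data-generating process is a cause-specific proportional-hazards Weibull
model.  Each cause of death (index cancer, other cancer, other causes) has a
Weibull baseline hazard and a linear predictor in the covariates; the
radiotherapy effect enters the index-cancer hazard as a *threshold* term in
the dose-dependent biologically effective dose (BED_DD > 61.8 Gy by
default), so the downstream forest/SHAP stage should rediscover the
cut-point and the causal stage should recover the configured effect.
Because the model is fully specified, the true average treatment effect on
restricted mean survival time and survival probability is available by
numerical integration (:func:`true_effects`), which downstream tests use as
an oracle.

Censoring is independent of covariates: an exponential dropout time plus a
uniform administrative horizon capped at 12 years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .bed import RADCURE_REGIMEN_COUNTS, bed_columns_for

logger = logging.getLogger(__name__)

SITE_COLUMNS = [
    "Esophagus",
    "Hypopharynx",
    "Larynx",
    "Lip_Oral_Cavity",
    "Nasal_Cavity",
    "Oropharynx",
]

CAUSES = ["index_cancer", "other_cancer", "other_causes"]

COVARIATE_COLUMNS = [
    "Age",
    "Sex",
    "Smoking_PY",
    "Stage_numeric",
    "HPV_Positive",
    "HPV_Unknown",
    "Chemo",
    "RT_year",
]

REQUIRED_COLUMNS = (
    COVARIATE_COLUMNS
    + ["fractions", "dose_per_fraction", "fractions_per_day"]
    + ["bed_simp", "bed_di", "bed_dd", "Status", "Length_FU", "cause"]
    + SITE_COLUMNS
)


class CohortSpecError(ValueError):
    """Invalid cohort specification."""


class SchemaError(ValueError):
    """Cohort table fails schema validation."""


def _default_regimen_weights() -> dict[tuple[int, float, int], float]:
    """Empirical fractionation mix: (fractions, dose/fraction, fx/day) -> prob."""
    total = sum(n for _, _, n in RADCURE_REGIMEN_COUNTS)
    weights = {}
    for m, total_dose, n in RADCURE_REGIMEN_COUNTS:
        fpd = 2 if m >= 50 else 1  # only the 60-fraction schedule is BID
        weights[(m, round(total_dose / m, 4), fpd)] = n / total
    return weights


@dataclass(frozen=True)
class WeibullCause:
    """Cause-specific Weibull proportional-hazards component.

    Cumulative hazard ``H(t | X) = (t / scale)**shape * exp(eta(X))``.
    """

    shape: float
    scale: float
    #: log-hazard coefficients on centered covariates
    coefs: Mapping[str, float] = field(default_factory=dict)
    #: additional log-hazard when the treatment indicator is 1
    tx_loghr: float = 0.0
    #: effect modification: tx log-HR += interaction * (stage - 2)
    tx_stage_interaction: float = 0.0
    #: hard effect modification: no treatment effect above this stage
    tx_stage_max: float = float("inf")


#: Centering constants applied before multiplying by coefficients.
COVARIATE_CENTERS = {
    "Age": 62.0,
    "Sex": 0.0,
    "Smoking_PY": 20.0,
    "Stage_numeric": 2.4,
    "HPV_Positive": 0.0,
    "HPV_Unknown": 0.0,
    "Chemo": 0.0,
    "RT_year": 2011.0,
}


def _default_causes() -> dict[str, WeibullCause]:
    return {
        "index_cancer": WeibullCause(
            shape=0.95,
            scale=16.0,
            coefs={
                "Age": 0.015,
                "Sex": 0.10,
                "Smoking_PY": 0.006,
                "Stage_numeric": 0.35,
                "HPV_Positive": -0.80,
                "HPV_Unknown": -0.20,
                "Chemo": -0.35,
                "RT_year": -0.02,
            },
            tx_loghr=-0.40,
        ),
        "other_cancer": WeibullCause(
            shape=1.2,
            scale=45.0,
            coefs={"Age": 0.05, "Sex": 0.15, "Smoking_PY": 0.012},
        ),
        "other_causes": WeibullCause(
            shape=1.5,
            scale=32.0,
            coefs={"Age": 0.08, "Sex": 0.20, "Smoking_PY": 0.008},
        ),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of the synthetic cohort's data-generating process."""

    n_patients: int = 3346
    seed: int = 0
    regimen_weights: Mapping[tuple[int, float, int], float] = field(
        default_factory=_default_regimen_weights
    )
    causes: Mapping[str, WeibullCause] = field(default_factory=_default_causes)
    #: BED_DD threshold defining the binary radiotherapy "treatment"
    bed_threshold: float = 61.8
    #: confounding strength: log-odds shift of the high-BED regimen group per
    #: unit of (stage - 2.4); 0 disables confounding (randomized regimens)
    confounding: float = 0.0
    #: exponential dropout rate (1/years)
    censor_rate: float = 0.02
    #: administrative censoring drawn Uniform(admin_low, admin_high) years
    admin_low: float = 4.0
    admin_high: float = 12.0
    #: hard follow-up cap in years
    max_followup: float = 12.0
    hpv_probs: tuple[float, float, float] = (0.55, 0.30, 0.15)  # +, -, unknown
    stage_probs: tuple[float, ...] = (0.02, 0.08, 0.15, 0.30, 0.45)
    site_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "Oropharynx": 0.50,
            "Larynx": 0.20,
            "Lip_Oral_Cavity": 0.12,
            "Hypopharynx": 0.08,
            "Nasal_Cavity": 0.04,
            "Esophagus": 0.03,
            # remaining mass: site unknown, no flag set
        }
    )
    male_prob: float = 0.78
    never_smoker_prob: float = 0.30
    chemo_prob: float = 0.55
    age_mean: float = 62.0
    age_sd: float = 11.0
    rt_years: tuple[int, int] = (2005, 2017)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise CohortSpecError(f"n_patients must be >= 1, got {self.n_patients}")
        w = np.array(list(self.regimen_weights.values()), dtype=float)
        if np.any(w < 0) or np.any(w > 1):
            raise CohortSpecError("regimen weights must lie in [0, 1]")
        if abs(w.sum() - 1.0) > 1e-8:
            raise CohortSpecError(f"regimen weights must sum to 1, got {w.sum():.6f}")
        for probs, name in [
            (self.hpv_probs, "hpv_probs"),
            (self.stage_probs, "stage_probs"),
        ]:
            p = np.array(probs, dtype=float)
            if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-8:
                raise CohortSpecError(f"{name} must be probabilities summing to 1")
        sp = np.array(list(self.site_probs.values()), dtype=float)
        if np.any(sp < 0) or sp.sum() > 1 + 1e-9:
            raise CohortSpecError("site_probs must be non-negative with sum <= 1")

    # -- convenience constructors ------------------------------------------

    def with_effect(
        self,
        tx_loghr: float,
        stage_interaction: float = 0.0,
        stage_max: float = float("inf"),
    ) -> "CohortSpec":
        """Return a spec whose index-cancer treatment log-HR is replaced."""
        causes = dict(self.causes)
        causes["index_cancer"] = replace(
            causes["index_cancer"],
            tx_loghr=tx_loghr,
            tx_stage_interaction=stage_interaction,
            tx_stage_max=stage_max,
        )
        return replace(self, causes=causes)

    def null_effect(self) -> "CohortSpec":
        return self.with_effect(0.0)


# ---------------------------------------------------------------------------
# covariate sampling


def _sample_covariates(spec: CohortSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 25.0, 90.0)
    sex = rng.binomial(1, spec.male_prob, n)
    never = rng.random(n) < spec.never_smoker_prob
    smoking = np.where(never, 0.0, rng.gamma(2.0, 15.0, n))
    smoking = np.clip(smoking, 0.0, 150.0)
    stage = rng.choice(len(spec.stage_probs), size=n, p=np.asarray(spec.stage_probs))
    hpv = rng.choice(3, size=n, p=np.asarray(spec.hpv_probs))  # 0=+, 1=-, 2=unknown
    chemo = rng.binomial(1, spec.chemo_prob, n)
    rt_year = rng.integers(spec.rt_years[0], spec.rt_years[1] + 1, n)
    df = pd.DataFrame(
        {
            "Age": np.round(age, 1),
            "Sex": sex,
            "Smoking_PY": np.round(smoking, 1),
            "Stage_numeric": stage.astype(int),
            "HPV_Positive": (hpv == 0).astype(int),
            "HPV_Unknown": (hpv == 2).astype(int),
            "Chemo": chemo,
            "RT_year": rt_year.astype(int),
        }
    )
    # diagnosis site: at most one flag set
    site_names = list(spec.site_probs)
    probs = np.array([spec.site_probs[s] for s in site_names])
    p_full = np.append(probs, max(0.0, 1.0 - probs.sum()))
    site_idx = rng.choice(len(p_full), size=n, p=p_full)
    for j, s in enumerate(SITE_COLUMNS):
        if s in site_names:
            df[s] = (site_idx == site_names.index(s)).astype(int)
        else:
            df[s] = 0
    return df


def _sample_regimens(
    spec: CohortSpec, stage: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    keys = list(spec.regimen_weights)
    weights = np.array([spec.regimen_weights[k] for k in keys], dtype=float)
    beds = bed_columns_for(
        [k[0] for k in keys], [k[1] for k in keys], [k[2] for k in keys]
    )
    high = beds["bed_dd"].to_numpy() > spec.bed_threshold
    n = len(stage)

    if spec.confounding == 0.0:
        idx = rng.choice(len(keys), size=n, p=weights)
    else:
        # stage tilts the odds of landing in the high-BED regimen group,
        # then a regimen is drawn within the group by renormalized weights
        p_high_base = weights[high].sum()
        logit = np.log(p_high_base / (1 - p_high_base)) + spec.confounding * (
            stage - COVARIATE_CENTERS["Stage_numeric"]
        )
        p_high = 1.0 / (1.0 + np.exp(-logit))
        take_high = rng.random(n) < p_high
        w_high = np.where(high, weights, 0.0)
        w_high = w_high / w_high.sum()
        w_low = np.where(~high, weights, 0.0)
        w_low = w_low / w_low.sum()
        idx_high = rng.choice(len(keys), size=n, p=w_high)
        idx_low = rng.choice(len(keys), size=n, p=w_low)
        idx = np.where(take_high, idx_high, idx_low)

    out = pd.DataFrame(
        {
            "fractions": [keys[i][0] for i in idx],
            "dose_per_fraction": [keys[i][1] for i in idx],
            "fractions_per_day": [keys[i][2] for i in idx],
        }
    )
    for col in ("bed_simp", "bed_di", "bed_dd"):
        out[col] = beds[col].to_numpy()[idx]
    return out


# ---------------------------------------------------------------------------
# survival process


def _linear_predictor(cause: WeibullCause, X: pd.DataFrame, W: np.ndarray) -> np.ndarray:
    eta = np.zeros(len(X))
    for name, coef in cause.coefs.items():
        eta += coef * (X[name].to_numpy(dtype=float) - COVARIATE_CENTERS[name])
    if cause.tx_loghr != 0.0 or cause.tx_stage_interaction != 0.0:
        stage = X["Stage_numeric"].to_numpy(dtype=float)
        loghr = cause.tx_loghr + cause.tx_stage_interaction * (stage - 2.0)
        loghr = np.where(stage <= cause.tx_stage_max, loghr, 0.0)
        eta += W * loghr
    return eta


def sample_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a full synthetic cohort; bit-reproducible given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    X = _sample_covariates(spec, spec.n_patients, rng)
    reg = _sample_regimens(spec, X["Stage_numeric"].to_numpy(), rng)
    df = pd.concat([X, reg], axis=1)
    W = (df["bed_dd"].to_numpy() > spec.bed_threshold).astype(float)

    # latent cause-specific event times by inverse-transform sampling
    latent = {}
    for name, cause in spec.causes.items():
        eta = _linear_predictor(cause, df, W)
        e = rng.exponential(1.0, spec.n_patients)
        latent[name] = cause.scale * (e / np.exp(eta)) ** (1.0 / cause.shape)
    times = np.column_stack([latent[c] for c in spec.causes])
    cause_idx = times.argmin(axis=1)
    t_event = times.min(axis=1)

    c_drop = rng.exponential(1.0 / spec.censor_rate, spec.n_patients) if spec.censor_rate > 0 else np.full(spec.n_patients, np.inf)
    c_admin = rng.uniform(spec.admin_low, spec.admin_high, spec.n_patients)
    t_cens = np.minimum(np.minimum(c_drop, c_admin), spec.max_followup)

    event = (t_event <= t_cens).astype(int)
    time = np.minimum(t_event, t_cens)
    time = np.maximum(time, 1e-4)  # guard: strictly positive follow-up
    cause_names = np.array(list(spec.causes))
    cause = np.where(event == 1, cause_names[cause_idx], "none")

    df["Status"] = event
    df["Length_FU"] = time
    df["cause"] = cause
    # column order: covariates, regimen, BEDs, outcome, cause, sites
    return df[REQUIRED_COLUMNS].copy()


def treatment_indicator(table: pd.DataFrame, threshold: float = 61.8, column: str = "bed_dd") -> np.ndarray:
    return (table[column].to_numpy(dtype=float) > threshold).astype(int)


# ---------------------------------------------------------------------------
# ground-truth effects by numerical integration


def _all_cause_survival(
    spec: CohortSpec, X: pd.DataFrame, W: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """S(t | X, W) on ``grid`` for each row of X; shape (n, len(grid))."""
    H = np.zeros((len(X), len(grid)))
    for cause in spec.causes.values():
        eta = _linear_predictor(cause, X, W)
        base = (grid[None, :] / cause.scale) ** cause.shape
        H += base * np.exp(eta)[:, None]
    return np.exp(-H)


def true_effects(
    spec: CohortSpec,
    horizons: Sequence[float],
    n_mc: int = 20000,
    grid_step: float = 0.02,
) -> pd.DataFrame:
    """True ATE of the BED threshold treatment on RMST and SP.

    Monte-Carlo averages the counterfactual survival functions over a large
    covariate sample (seeded from ``spec.seed``), integrating numerically
    for RMST.  Returns one row per horizon with columns ``rmst_effect``
    (years) and ``sp_effect`` (probability difference).
    """
    horizons = np.asarray(sorted(horizons), dtype=float)
    rng = np.random.default_rng(np.uint32(spec.seed) ^ np.uint32(0x5EED))
    X = _sample_covariates(spec, n_mc, rng)
    grid = np.arange(0.0, horizons.max() + grid_step, grid_step)
    s1 = _all_cause_survival(spec, X, np.ones(n_mc), grid).mean(axis=0)
    s0 = _all_cause_survival(spec, X, np.zeros(n_mc), grid).mean(axis=0)
    diff = s1 - s0
    # cumulative trapezoid for the RMST integrand
    cum = np.concatenate([[0.0], np.cumsum((diff[1:] + diff[:-1]) / 2.0 * grid_step)])
    rows = []
    for h in horizons:
        i = int(round(h / grid_step))
        i = min(i, len(grid) - 1)
        rows.append({"horizon": h, "rmst_effect": cum[i], "sp_effect": diff[i]})
    return pd.DataFrame(rows)


def calibrate_effect(
    spec: CohortSpec,
    target_rmst_effect: float,
    horizon: float = 8.0,
    n_mc: int = 20000,
) -> CohortSpec:
    """Return a spec whose true RMST effect at ``horizon`` equals the target.

    Solves for the index-cancer treatment log-hazard-ratio by bisection
    against the :func:`true_effects` oracle.
    """

    def objective(loghr: float) -> float:
        s = spec.with_effect(loghr)
        eff = true_effects(s, [horizon], n_mc=n_mc)
        return float(eff["rmst_effect"].iloc[0]) - target_rmst_effect

    loghr = brentq(objective, -3.0, 3.0, xtol=1e-4)
    return spec.with_effect(float(loghr))


# ---------------------------------------------------------------------------
# I/O


def write_cohort(table: pd.DataFrame, path) -> None:
    validate_cohort(table)
    table.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    validate_cohort(table)
    extra = [c for c in table.columns if c not in REQUIRED_COLUMNS]
    if extra:
        logger.info("cohort file has %d extra columns (preserved): %s", len(extra), extra)
    return table


def validate_cohort(table: pd.DataFrame) -> None:
    """Schema check; raises :class:`SchemaError` naming offending columns."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table missing mandatory columns: {missing}")
    onehot = ["Sex", "HPV_Positive", "HPV_Unknown", "Chemo", "Status"] + SITE_COLUMNS
    bad = [c for c in onehot if not table[c].isin([0, 1]).all()]
    if bad:
        raise SchemaError(f"non-binary one-hot columns: {bad}")
    if (table["HPV_Positive"] & table["HPV_Unknown"]).any():
        raise SchemaError("HPV_Positive and HPV_Unknown are both 1 for some rows")
    if (table[SITE_COLUMNS].sum(axis=1) > 1).any():
        raise SchemaError("more than one diagnosis-site flag set for some rows")
    if not (table["Length_FU"] > 0).all():
        raise SchemaError("Length_FU must be strictly positive")
    censored_with_cause = (table["Status"] == 0) & (table["cause"] != "none")
    if censored_with_cause.any():
        raise SchemaError("censored rows must have cause 'none'")
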