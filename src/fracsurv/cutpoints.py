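"""Dichotomization of continuous BED variants into binary treatment
indicators, with SHAP-guided cut-point suggestion.

The published cut-points (BED_DD 61.8 Gy, BED_DI 57.6 Gy, BED_simp 70 Gy)
are retained as defaults.  ``suggest_cutpoint`` formalizes the visual
"clear change in the relative-risk curve" rule as the two-segment
piecewise-constant least-squares change-point; for features whose curve is
flat (no change point), it falls back to a percentile of the dose
distribution, mirroring how the no-repopulation variant was dichotomized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_CUTPOINTS = {"bed_dd": 61.8, "bed_di": 57.6, "bed_simp": 70.0}


class DegenerateTreatmentWarning(UserWarning):
    """Binarization produced a single class (positivity violation ahead)."""


class FlatCurveWarning(UserWarning):
    """No change point detectable; percentile fallback used."""


@dataclass(frozen=True)
class CutpointSpec:
    variant: str  # bed_dd | bed_di | bed_simp
    cutpoint: float
    provenance: str = "manual"  # manual | shap_changepoint | percentile

    def __post_init__(self) -> None:
        if self.variant not in DEFAULT_CUTPOINTS:
            raise ValueError(f"unknown BED variant {self.variant!r}")


def binarize(values, spec: CutpointSpec) -> np.ndarray:
    """Map dose values to {0, 1}: 1 iff value is strictly above the cut-point.

    Values equal to the cut-point map to 0.  Emits a
    :class:`DegenerateTreatmentWarning` when the output is all-0 or all-1.
    """
    values = np.asarray(values, dtype=float)
    out = (values > spec.cutpoint).astype(int)
    if len(out) and (out.all() or not out.any()):
        warnings.warn(
            f"binarize at {spec.cutpoint} Gy produced a degenerate (all-"
            f"{int(out[0]) if len(out) else 0}) treatment variable",
            DegenerateTreatmentWarning,
            stacklevel=2,
        )
    return out


def _two_segment_sse_split(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Best split of (x, y) into two constant segments by least squares.

    Returns ``(cut, sse_best, sse_flat)`` where ``cut`` is the midpoint
    between the last x of the left segment and the first of the right.
    Evaluated by exhaustive scan over all n-1 split positions.
    """
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    n = len(ys)
    csum = np.cumsum(ys)
    csq = np.cumsum(ys**2)
    total_sum, total_sq = csum[-1], csq[-1]
    best = (np.inf, 0.0)
    for i in range(1, n):  # left = [0, i), right = [i, n)
        left_sse = csq[i - 1] - csum[i - 1] ** 2 / i
        rs = total_sum - csum[i - 1]
        rq = total_sq - csq[i - 1]
        right_sse = rq - rs**2 / (n - i)
        sse = left_sse + right_sse
        if sse < best[0]:
            best = (sse, (xs[i - 1] + xs[i]) / 2.0)
    sse_flat = total_sq - total_sum**2 / n
    return best[1], best[0], sse_flat


def suggest_cutpoint(
    curve_x: np.ndarray,
    curve_y: np.ndarray,
    method: str = "changepoint",
    percentile: float | None = None,
    dose_values: np.ndarray | None = None,
    flat_tol: float = 0.02,
) -> float:
    """Suggest a dichotomization cut-point from a relative-risk curve.

    Parameters
    ----------
    curve_x, curve_y : arrays
        Feature values (sorted or not) and the normalized relative-risk
        curve evaluated there; at least 10 support points.
    method : {"changepoint", "percentile"}
    percentile : float, optional
        Percentile in [0, 100] for the percentile mode (and the flat-curve
        fallback).  Defaults to 50.
    dose_values : array, optional
        Dose distribution used for the percentile mode; defaults to
        ``curve_x``.
    flat_tol : float
        Minimum relative SSE improvement of the two-segment fit over a flat
        fit for a change point to count.  Below it the curve is declared
        flat and the percentile fallback is used (with a warning).
    """
    x = np.asarray(curve_x, dtype=float)
    y = np.asarray(curve_y, dtype=float)
    if len(x) < 10:
        raise ValueError(f"curve needs >= 10 support points, got {len(x)}")
    doses = np.asarray(dose_values if dose_values is not None else x, dtype=float)
    p = 50.0 if percentile is None else float(percentile)

    if method == "percentile":
        return float(np.percentile(doses, p))
    if method != "changepoint":
        raise ValueError(f"unknown method {method!r}")

    cut, sse_split, sse_flat = _two_segment_sse_split(x, y)
    if sse_flat <= 0 or (sse_flat - sse_split) / sse_flat < flat_tol:
        warnings.warn(
            "relative-risk curve is flat; falling back to percentile cut-point",
            FlatCurveWarning,
            stacklevel=2,
        )
        return float(np.percentile(doses, p))
    return float(cut)


def percentile_of(value: float, distribution) -> float:
    """Empirical percentile (0-100) of ``value`` within ``distribution``."""
    d = np.asarray(distribution, dtype=float)
    return float(100.0 * np.mean(d <= value))


def transfer_cutpoint_by_percentile(
    reference_cut: float, reference_doses, target_doses
) -> float:
    """Apply the reference variant's cut-point percentile to another variant.

    E.g. the no-repopulation BED has no change point of its own, so its
    cut-point is placed at the same percentile of its distribution as the
    dose-dependent variant's cut-point occupies in its distribution.
    """
    p = percentile_of(reference_cut, reference_doses)
    return float(np.percentile(np.asarray(target_doses, dtype=float), p))
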