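"""Shapley-value attributions for tabular prediction functions.

Attributions use the *interventional* (marginal) value function: the payoff
of a coalition S for row x is ``E_b[f(x_S, b_{~S})]`` with the expectation
over a background sample b.  Two estimators are provided:

``shap_exact``
    Full enumeration of all 2^p coalitions with the Shapley kernel weights.
    Exact but exponential in the number of features; intended for small p
    and as the oracle against which the sampler is tested.

``shap_permutation``
    Antithetic permutation sampling.  Each sampled permutation contributes
    a telescoping sum of marginal contributions that adds up *exactly* to
    ``f(x) - E_b[f(b)]``, so local accuracy (base value + sum of
    attributions = model output) holds to floating-point precision for any
    number of permutations; sampling only affects how the total is divided
    among features.

Both operate on a plain ``predict(X) -> scores`` callable, so any model
(including a survival forest reduced to a scalar risk score) can be
explained.
"""

from __future__ import annotations

import itertools
import math
from typing import Callable

import numpy as np

Predictor = Callable[[np.ndarray], np.ndarray]


def _coalition_matrix(x: np.ndarray, background: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Rows of background with features in ``mask`` replaced by x's values."""
    out = background.copy()
    out[:, mask] = x[mask]
    return out


def shap_exact(
    predict: Predictor,
    X: np.ndarray,
    background: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Exact interventional Shapley values by coalition enumeration.

    Returns ``(phi, base_value)`` where ``phi`` has shape (n, p) and
    ``base_value = mean(predict(background))``.
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    n, p = X.shape
    if p > 16:
        raise ValueError(f"exact enumeration limited to 16 features, got {p}")
    nb = len(background)

    # payoff v(S) for every coalition, for every explained row
    subsets = list(itertools.product([False, True], repeat=p))
    payoff = np.empty((n, len(subsets)))
    for si, mask in enumerate(subsets):
        mask_a = np.array(mask)
        if not mask_a.any():
            payoff[:, si] = predict(background).mean()
            continue
        stacked = np.vstack([_coalition_matrix(X[i], background, mask_a) for i in range(n)])
        preds = predict(stacked).reshape(n, nb)
        payoff[:, si] = preds.mean(axis=1)

    index = {mask: si for si, mask in enumerate(subsets)}
    phi = np.zeros((n, p))
    fact = math.factorial
    for j in range(p):
        for mask in subsets:
            if mask[j]:
                continue
            s = sum(mask)
            w = fact(s) * fact(p - s - 1) / fact(p)
            with_j = tuple(m or (k == j) for k, m in enumerate(mask))
            phi[:, j] += w * (payoff[:, index[with_j]] - payoff[:, index[mask]])
    base = float(predict(background).mean())
    return phi, base


def shap_permutation(
    predict: Predictor,
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 16,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Permutation-sampling Shapley values (antithetic pairs).

    For each permutation the marginal contributions telescope to
    ``f(x) - base``, so the average over permutations satisfies local
    accuracy exactly.  ``n_permutations`` counts forward permutations; each
    is paired with its reverse.

    Returns ``(phi, base_value)``.
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    n, p = X.shape
    nb = len(background)
    rng = np.random.default_rng(seed)

    perms = []
    for _ in range(n_permutations):
        fwd = rng.permutation(p)
        perms.append(fwd)
        perms.append(fwd[::-1])

    # Build every coalition evaluation in one batch per permutation step to
    # keep the number of predict() calls small (forest predictions dominate).
    phi = np.zeros((n, p))
    base = float(predict(background).mean())
    full = predict(X)

    for perm in perms:
        prev = np.full(n, base)
        mask = np.zeros(p, dtype=bool)
        # evaluate all intermediate coalitions of this permutation in one call
        stacks = []
        masks = []
        running = mask.copy()
        for j in perm[:-1]:
            running = running.copy()
            running[j] = True
            masks.append(running)
        for m in masks:
            stacks.append(np.vstack([_coalition_matrix(X[i], background, m) for i in range(n)]))
        if stacks:
            preds = predict(np.vstack(stacks)).reshape(len(masks), n, nb).mean(axis=2)
        for step, j in enumerate(perm):
            cur = full if step == p - 1 else preds[step]
            phi[:, j] += (cur - prev) / len(perms)
            prev = cur
    return phi, base


def normalize_to_relative_risk(phi_column: np.ndarray) -> np.ndarray:
    """Map log-risk attributions to a multiplicative relative-risk scale.

    Zero attribution maps to 1.0 (population average); log(1.1) maps to a
    10% increase in predicted risk.
    """
    return np.exp(np.asarray(phi_column, dtype=float))


def running_median(y: np.ndarray, window: int = 11) -> np.ndarray:
    """Centered running median with edge shrinkage (odd window)."""
    y = np.asarray(y, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    half = window // 2
    out = np.empty_like(y)
    for i in range(len(y)):
        lo, hi = max(0, i - half), min(len(y), i + half + 1)
        out[i] = np.median(y[lo:hi])
    return out
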