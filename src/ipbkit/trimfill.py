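"""Duval-Tweedie trim-and-fill, oriented for inverse publication bias.

For adverse events the suppressed studies are the ones showing significant
harm, i.e. the *right* side of the funnel (log OR > 0), so the default is
``side="right"``: the algorithm trims the surplus of extreme low effects,
re-centres, and imputes mirror-image studies on the right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .core import InvalidInputError, PooledResult, StudyEffect, pool_fixed, pool_random
from .bias_tests import InsufficientStudiesError


@dataclass(frozen=True)
class TrimFillResult:
    k0: int
    side: str  # "right" | "left"
    estimator: str  # "L0" | "R0"
    filled_studies: tuple[StudyEffect, ...]
    pooled_adjusted: PooledResult
    pooled_observed: PooledResult
    iterations: int
    stabilized: bool


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def _midranks(a: np.ndarray) -> np.ndarray:
    """Ascending midranks with tolerance-based ties.

    Mirror-imputed effects reproduce |y - mu| only to floating-point
    accuracy, so exact-equality ranking would break such ties arbitrarily;
    values within a relative 1e-8 of the group leader share a midrank.
    """
    k = a.size
    order = np.argsort(a, kind="stable")
    ranks = np.empty(k)
    tol = 1e-8 * max(1.0, float(a.max()))
    i = 0
    while i < k:
        j = i
        while j + 1 < k and a[order[j + 1]] - a[order[i]] <= tol:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        ranks[order[i:j + 1]] = mid
        i = j + 1
    return ranks


def estimate_k0(centered: Sequence[float], estimator: str = "L0") -> int:
    """Estimate the number of suppressed studies from centred effects.

    ``centered`` are y_i - mu, oriented so the side with the *observed
    surplus* (opposite the suspected-missing side) is positive.  Absolute
    values are ranked ascending with midranks for ties; T is the rank sum of
    the strictly positive values.  L0 = (4T - k(k+1)) / (2k - 1); R0 is one
    less than the length of the run of largest absolute values that all lie
    on the positive side.  Estimates are floored at zero.
    """
    c = np.asarray(centered, dtype=float)
    k = c.size
    if k < 3:
        raise InsufficientStudiesError(f"trim-and-fill needs k >= 3, got {k}")
    ranks = _midranks(np.abs(c))
    if estimator == "L0":
        t_sum = float(np.sum(ranks[c > 0]))
        l0 = (4.0 * t_sum - k * (k + 1)) / (2.0 * k - 1.0)
        return max(0, _round_half_away(l0))
    if estimator == "R0":
        order = np.argsort(ranks, kind="stable")  # ascending |c|
        run = 0
        for idx in order[::-1]:
            if c[idx] > 0:
                run += 1
            else:
                break
        return max(0, run - 1)
    raise InvalidInputError(f"unknown estimator {estimator!r}")


def _pool(studies: Sequence[StudyEffect], pooling: str) -> PooledResult:
    if pooling == "fixed" or len(studies) < 2:
        return pool_fixed(studies)
    return pool_random(studies)


def trim_and_fill(
    studies: Sequence[StudyEffect],
    side: str = "right",
    estimator: str = "L0",
    pooling: str = "random",
    max_iter: int = 20,
) -> TrimFillResult:
    """Iterative trim-and-fill with mirror-image imputation.

    Each pass pools the untrimmed studies, centres all observed effects at
    that estimate, re-estimates k0, and trims the k0 most extreme effects on
    the observed-surplus side; iteration stops when k0 stabilizes.  Filling
    mirrors each trimmed study about the final centre (y_fill = 2*mu - y,
    se unchanged) onto the missing side and re-pools observed + filled.
    Ties in the trimming order are broken by input order.
    """
    k = len(studies)
    if k < 3:
        raise InsufficientStudiesError(f"trim-and-fill needs k >= 3, got {k}")
    if side not in ("right", "left"):
        raise InvalidInputError(f"side must be 'right' or 'left', got {side!r}")
    sign = -1.0 if side == "right" else 1.0  # orient surplus side positive
    y_or = sign * np.array([s.y for s in studies], dtype=float)
    # trimming order: descending oriented effect, ties by input order
    trim_order = sorted(range(k), key=lambda i: (-y_or[i], i))

    pooled_observed = _pool(studies, pooling)
    k0, iterations, stabilized = 0, 0, False
    for iterations in range(1, max_iter + 1):
        keep = [i for i in range(k) if i not in set(trim_order[:k0])]
        if len(keep) < 1:
            break
        mu_or = sign * _pool([studies[i] for i in keep], pooling).mu
        k0_new = min(estimate_k0(y_or - mu_or, estimator), k - 1)
        if k0_new == k0:
            stabilized = True
            break
        k0 = k0_new

    keep = [i for i in range(k) if i not in set(trim_order[:k0])]
    mu_final = _pool([studies[i] for i in keep], pooling).mu  # original scale
    filled = tuple(
        replace(
            studies[i],
            study_id=f"{studies[i].study_id}+fill",
            y=2.0 * mu_final - studies[i].y,
        )
        for i in trim_order[:k0]
    )
    pooled_adjusted = _pool(list(studies) + list(filled), pooling)
    return TrimFillResult(
        k0=k0,
        side=side,
        estimator=estimator,
        filled_studies=filled,
        pooled_adjusted=pooled_adjusted,
        pooled_observed=pooled_observed,
        iterations=iterations,
        stabilized=stabilized,
    )
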