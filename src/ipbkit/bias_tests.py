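"""Funnel-asymmetry regression tests with direction-aware one-sided p-values.

Inverse publication bias (IPB) in safety outcomes suppresses small studies
that show *significant harm*, so the published small studies sit closer to
the null than the large ones.  With harm coded as log OR > 0, both Egger's
and Peters' asymmetry coefficients are then expected to be *negative* —
the opposite direction from classic publication bias in efficacy outcomes.
Each test therefore reports a conventional two-sided p-value and a
one-sided p-value under the chosen IPB alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .core import InvalidInputError, StudyEffect


class InsufficientStudiesError(InvalidInputError):
    """Fewer than three studies: the regression has no residual df."""


class DegenerateDesignError(InvalidInputError):
    """The regressor is constant, so the asymmetry slope is not identified."""


class Direction(str, Enum):
    """Which side of the funnel the missing studies are suspected to be on.

    ``SUPPRESS_HIGH``: studies with large (harmful, log OR > 0) effects are
    suppressed — the IPB alternative, asymmetry coefficient < 0.
    ``SUPPRESS_LOW``: classic publication bias, coefficient > 0.
    """

    SUPPRESS_HIGH = "suppress_high"
    SUPPRESS_LOW = "suppress_low"


@dataclass(frozen=True)
class AsymmetryTestResult:
    method: str  # "egger" | "peters"
    coef: float
    se_coef: float
    t: float
    df: int
    p_two: float
    p_one: float
    direction: Direction
    k_used: int


@dataclass(frozen=True)
class SignificanceCall:
    significant: bool
    alpha: float
    sidedness: str  # "one" | "two"


def one_sided_p(t: float, df: int, alternative_sign: int) -> float:
    """One-sided p-value from a Student-t statistic.

    ``alternative_sign`` < 0 tests H1: coefficient < 0 (p = P(T <= t));
    positive tests H1: coefficient > 0 (p = P(T >= t)).
    """
    if df < 1:
        raise InvalidInputError("one-sided p needs df >= 1")
    if alternative_sign < 0:
        return float(stats.t.cdf(t, df))
    return float(stats.t.sf(t, df))


def _finalize(method, coef, se_coef, df, direction, k) -> AsymmetryTestResult:
    if se_coef == 0:  # exact fit: the t ratio degenerates to 0 or +/-inf
        t = 0.0 if coef == 0 else math.copysign(math.inf, coef)
    else:
        t = coef / se_coef
    p_two = float(2.0 * stats.t.sf(abs(t), df))
    sign = -1 if direction is Direction.SUPPRESS_HIGH else +1
    p_one = one_sided_p(t, df, sign)
    return AsymmetryTestResult(
        method=method, coef=float(coef), se_coef=float(se_coef), t=float(t),
        df=int(df), p_two=p_two, p_one=p_one, direction=direction, k_used=k,
    )


def egger_test(
    studies: Sequence[StudyEffect],
    direction: Direction = Direction.SUPPRESS_HIGH,
) -> AsymmetryTestResult:
    """Egger's regression test for small-study effects.

    Ordinary least squares of the standardized effect z_i = y_i / se_i on
    precision 1 / se_i; the *intercept* is the asymmetry coefficient
    (algebraically identical to the slope on se_i in the weighted form of
    the regression).  Inference uses Student t with k - 2 df.
    """
    k = len(studies)
    if k < 3:
        raise InsufficientStudiesError(f"Egger's test needs k >= 3, got {k}")
    se = np.array([s.se for s in studies], dtype=float)
    y = np.array([s.y for s in studies], dtype=float)
    if np.ptp(se) == 0:
        raise DegenerateDesignError("all standard errors identical: precision has no spread")
    z = y / se
    prec = 1.0 / se
    fit = sm.OLS(z, sm.add_constant(prec)).fit()
    return _finalize("egger", fit.params[0], fit.bse[0], int(fit.df_resid), direction, k)


def peters_test(
    studies: Sequence[StudyEffect],
    direction: Direction = Direction.SUPPRESS_HIGH,
) -> AsymmetryTestResult:
    """Peters' test for binary outcomes.

    Weighted least squares of the log OR on 1/N with weights
    1 / (1/S + 1/F), where N, S, F are a study's total sample size, total
    events and total non-events.  Regressing on inverse sample size rather
    than the standard error avoids the built-in correlation between a log OR
    and its standard error that inflates Egger's test for rare events.
    The asymmetry coefficient is the slope on 1/N.
    """
    k = len(studies)
    if k < 3:
        raise InsufficientStudiesError(f"Peters' test needs k >= 3, got {k}")
    n = np.array([s.n_total for s in studies], dtype=float)
    s_ev = np.array([s.events_total for s in studies], dtype=float)
    f_ev = np.array([s.nonevents_total for s in studies], dtype=float)
    y = np.array([s.y for s in studies], dtype=float)
    if np.any(s_ev <= 0) or np.any(f_ev <= 0):
        raise InvalidInputError("Peters' weights need positive event and non-event totals")
    if np.ptp(n) == 0:
        raise DegenerateDesignError("all sample sizes identical: 1/N has no spread")
    x = 1.0 / n
    w = 1.0 / (1.0 / s_ev + 1.0 / f_ev)
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    return _finalize("peters", fit.params[1], fit.bse[1], int(fit.df_resid), direction, k)


def classify(
    result: AsymmetryTestResult,
    alpha: float = 0.1,
    sidedness: str = "one",
) -> SignificanceCall:
    """Dichotomize a test result at the IPB significance threshold (default 0.1)."""
    if sidedness not in ("one", "two"):
        raise InvalidInputError(f"sidedness must be 'one' or 'two', got {sidedness!r}")
    p = result.p_one if sidedness == "one" else result.p_two
    return SignificanceCall(significant=bool(p < alpha), alpha=alpha, sidedness=sidedness)
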