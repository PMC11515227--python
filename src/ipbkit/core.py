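"""Effect sizes and pooling for meta-analyses of binary safety outcomes.

This module covers the per-trial layer of an adverse-event meta-analysis:
2x2 contingency tables, the continuity-correction / exclusion rules for
zero event counts, the log odds ratio and its large-sample standard error,
and fixed- and random-effects inverse-variance pooling.  Between-study
variance is estimated by restricted maximum likelihood (Fisher scoring)
with an automatic DerSimonian-Laird fallback when the scoring iteration
fails to converge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np


class InvalidInputError(ValueError):
    """Raised for inputs that violate a documented precondition."""


class ZeroCellError(InvalidInputError):
    """A 2x2 cell is zero: zero handling must be applied before the log OR."""


class ZeroStatus(str, Enum):
    """What zero handling did to a trial's 2x2 table."""

    UNMODIFIED = "unmodified"
    CONTINUITY_CORRECTED = "continuity_corrected"
    EXCLUDED_DOUBLE_ZERO = "excluded_double_zero"


@dataclass(frozen=True)
class ContingencyTable:
    """One trial's 2x2 adverse-event table.

    Cells are events / totals per arm; non-events are derived.  Counts are
    stored as floats so that continuity-corrected tables (with 0.5 cells)
    share the type of raw integer tables.
    """

    events_trt: float
    total_trt: float
    events_ctl: float
    total_ctl: float

    def __post_init__(self) -> None:
        for name in ("events_trt", "total_trt", "events_ctl", "total_ctl"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidInputError(f"{name} must be a finite non-negative count, got {v!r}")
        if self.total_trt < 1 or self.total_ctl < 1:
            raise InvalidInputError("each arm must have at least one participant")
        if self.events_trt > self.total_trt or self.events_ctl > self.total_ctl:
            raise InvalidInputError("events cannot exceed the arm total")

    @property
    def nonevents_trt(self) -> float:
        return self.total_trt - self.events_trt

    @property
    def nonevents_ctl(self) -> float:
        return self.total_ctl - self.events_ctl

    @property
    def n_total(self) -> float:
        return self.total_trt + self.total_ctl

    def cells(self) -> tuple[float, float, float, float]:
        """(a, b, c, d) = (events_trt, nonevents_trt, events_ctl, nonevents_ctl)."""
        return (self.events_trt, self.nonevents_trt, self.events_ctl, self.nonevents_ctl)


@dataclass(frozen=True)
class ZeroHandlingOutcome:
    status: ZeroStatus
    corrected_table: Optional[ContingencyTable] = None


def apply_zero_handling(table: ContingencyTable) -> ZeroHandlingOutcome:
    """Apply the zero-event rules to a trial's 2x2 table.

    Trials with zero events in both arms carry no information about the odds
    ratio and are excluded.  If exactly one arm has zero events, 0.5 is added
    to all four cells (so each arm total grows by 1).  A zero *non-events*
    cell (every participant in an arm had the event) equally makes the log OR
    undefined and receives the same all-cells correction.
    """
    a, b, c, d = table.cells()
    if a == 0 and c == 0:
        return ZeroHandlingOutcome(ZeroStatus.EXCLUDED_DOUBLE_ZERO)
    if 0 in (a, b, c, d):
        corrected = ContingencyTable(
            events_trt=a + 0.5,
            total_trt=table.total_trt + 1.0,
            events_ctl=c + 0.5,
            total_ctl=table.total_ctl + 1.0,
        )
        return ZeroHandlingOutcome(ZeroStatus.CONTINUITY_CORRECTED, corrected)
    return ZeroHandlingOutcome(ZeroStatus.UNMODIFIED, table)


def log_odds_ratio(table: ContingencyTable) -> tuple[float, float]:
    """Log odds ratio ln[(a*d)/(b*c)] and its standard error sqrt(sum of 1/cell).

    All four cells must be positive; apply :func:`apply_zero_handling` first.
    """
    a, b, c, d = table.cells()
    if min(a, b, c, d) <= 0:
        raise ZeroCellError("table contains a zero cell; apply zero handling first")
    y = math.log((a * d) / (b * c))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return y, se


@dataclass(frozen=True)
class StudyEffect:
    """A trial's log odds ratio with the covariates the asymmetry tests need.

    ``n_total``, ``events_total`` and ``nonevents_total`` are the *observed*
    integer counts (uncorrected): sample sizes are measured quantities, while
    the continuity correction is purely an effect-estimation device.
    """

    study_id: str
    y: float
    se: float
    n_total: float
    events_total: float
    nonevents_total: float
    zero_status: ZeroStatus = ZeroStatus.UNMODIFIED

    def __post_init__(self) -> None:
        if not (self.se > 0 and math.isfinite(self.se)):
            raise InvalidInputError(f"se must be positive and finite, got {self.se!r}")
        if not math.isfinite(self.y):
            raise InvalidInputError(f"y must be finite, got {self.y!r}")


def study_effect(table: ContingencyTable, study_id: str = "") -> Optional[StudyEffect]:
    """Turn a raw 2x2 table into a :class:`StudyEffect`, or ``None`` if excluded.

    Zero handling is applied internally; the corrected cells feed ``y`` and
    ``se`` while the raw counts feed the sample-size covariates.
    """
    outcome = apply_zero_handling(table)
    if outcome.status is ZeroStatus.EXCLUDED_DOUBLE_ZERO:
        return None
    y, se = log_odds_ratio(outcome.corrected_table)
    return StudyEffect(
        study_id=study_id,
        y=y,
        se=se,
        n_total=table.n_total,
        events_total=table.events_trt + table.events_ctl,
        nonevents_total=table.nonevents_trt + table.nonevents_ctl,
        zero_status=outcome.status,
    )


@dataclass(frozen=True)
class PooledResult:
    mu: float
    se_mu: float
    tau2: float
    model: str  # "fixed" | "random"
    tau2_method: str  # "REML" | "DL" | "none"
    converged: bool
    k: int


def _arrays(studies: Sequence[StudyEffect]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([s.y for s in studies], dtype=float)
    v = np.array([s.se**2 for s in studies], dtype=float)
    return y, v


def pool_fixed(studies: Sequence[StudyEffect]) -> PooledResult:
    """Fixed-effect inverse-variance pooling."""
    if len(studies) < 1:
        raise InvalidInputError("pooling needs at least one study")
    y, v = _arrays(studies)
    w = 1.0 / v
    mu = float(np.sum(w * y) / np.sum(w))
    se_mu = float(1.0 / math.sqrt(np.sum(w)))
    return PooledResult(mu, se_mu, 0.0, "fixed", "none", True, len(studies))


def tau2_dl(studies: Sequence[StudyEffect]) -> float:
    """DerSimonian-Laird moment estimator of the between-study variance."""
    if len(studies) < 2:
        raise InvalidInputError("tau2 estimation needs at least two studies")
    y, v = _arrays(studies)
    w = 1.0 / v
    ybar = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - ybar) ** 2))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    k = len(studies)
    return max(0.0, (q - (k - 1)) / denom)


def tau2_reml(
    studies: Sequence[StudyEffect],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[float, bool]:
    """REML estimate of tau^2 by Fisher scoring on the random-effects model.

    Model: y_i ~ Normal(mu, v_i + tau^2).  The scoring update uses the
    restricted score and expected information; tau^2 is floored at zero after
    every step.  Returns ``(tau2, converged)``; non-convergence (step size
    above ``tol`` after ``max_iter`` iterations, or non-finite iterates) is a
    reported state, not an error, so callers can fall back to DL.
    """
    if len(studies) < 2:
        raise InvalidInputError("tau2 estimation needs at least two studies")
    y, v = _arrays(studies)
    tau2 = tau2_dl(studies)  # moment start
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        sw = np.sum(w)
        mu = np.sum(w * y) / sw
        resid2 = (y - mu) ** 2
        # restricted score and expected information in tau^2
        score = 0.5 * (np.sum(w**2 * resid2) - np.sum(w) + np.sum(w**2) / sw)
        info = 0.5 * (np.sum(w**2) - 2.0 * np.sum(w**3) / sw + (np.sum(w**2) / sw) ** 2)
        if not np.isfinite(score) or not np.isfinite(info) or info <= 0:
            return float(tau2), False
        new = max(0.0, tau2 + score / info)
        delta = abs(new - tau2)
        tau2 = new
        if not np.isfinite(tau2):
            return float(tau2), False
        if delta <= tol:
            return float(tau2), True
    return float(tau2), False


def pool_random(
    studies: Sequence[StudyEffect],
    tau2_method: str = "REML",
    tol: float = 1e-10,
    max_iter: int = 100,
) -> PooledResult:
    """Random-effects pooling with REML tau^2 and automatic DL fallback.

    ``tau2_method="REML"`` (default) tries Fisher-scoring REML first and
    silently falls back to DerSimonian-Laird when scoring does not converge,
    recording the method actually used.  ``tau2_method="DL"`` requests the
    moment estimator directly.
    """
    if len(studies) < 2:
        raise InvalidInputError("random-effects pooling needs at least two studies")
    if tau2_method not in ("REML", "DL"):
        raise InvalidInputError(f"unknown tau2_method {tau2_method!r}")
    converged = True
    if tau2_method == "REML":
        tau2, converged = tau2_reml(studies, tol=tol, max_iter=max_iter)
        method = "REML"
        if not converged:
            tau2 = tau2_dl(studies)
            method = "DL"
    else:
        tau2 = tau2_dl(studies)
        method = "DL"
    y, v = _arrays(studies)
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se_mu = float(1.0 / math.sqrt(np.sum(w)))
    return PooledResult(mu, se_mu, float(tau2), "random", method, bool(converged), len(studies))
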