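"""Synthetic meta-analyses of binary adverse events with selective publication.

The generator emulates the structure of trial-level safety data: per trial a
2x2 table of adverse events, with between-study heterogeneity on the log OR
scale, log-uniform sample sizes, and control-arm event probabilities low
enough that zero cells occur.  Inverse publication bias is modelled as a
significance-based suppression rule: a study whose own one-sided Wald test
shows significant harm is published only with probability gamma; all other
studies are always published.

All randomness flows through a single seeded numpy Generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .core import (
    ContingencyTable,
    InvalidInputError,
    StudyEffect,
    ZeroStatus,
    apply_zero_handling,
    log_odds_ratio,
    study_effect,
)
from . import bias_tests
from .bias_tests import Direction


@dataclass(frozen=True)
class SelectionModel:
    """Publication rule applied to each simulated study.

    ``significance_based``: if the study's one-sided Wald p-value for harm
    (log OR > 0) falls below ``alpha_sel``, the study is published with
    probability ``gamma``; otherwise it is always published.
    """

    mechanism: str = "none"  # "none" | "significance_based"
    alpha_sel: float = 0.05
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.mechanism not in ("none", "significance_based"):
            raise InvalidInputError(f"unknown selection mechanism {self.mechanism!r}")
        if not (0.0 <= self.gamma <= 1.0):
            raise InvalidInputError("gamma must be in [0, 1]")
        if not (0.0 < self.alpha_sel < 1.0):
            raise InvalidInputError("alpha_sel must be in (0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic meta-analysis generator.

    Defaults describe a typical adverse-event meta-analysis: 13 published
    trials (the median size in large safety corpora), rare events
    (control-arm risk 10%), sample sizes log-uniform on [50, 1000], equal
    allocation, and no heterogeneity or selection unless requested.
    """

    k_published: int = 13
    theta: float = 0.0  # true pooled log OR (harm > 0)
    tau2: float = 0.0  # between-study variance of the log OR
    n_min: int = 50
    n_max: int = 1000
    alloc_ratio: float = 1.0  # treatment : control participants
    p0: Union[float, tuple[float, float]] = 0.1  # control risk, or loguniform range
    selection: SelectionModel = field(default_factory=SelectionModel)
    n_meta: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k_published < 3:
            raise InvalidInputError("k_published must be >= 3")
        if self.tau2 < 0:
            raise InvalidInputError("tau2 must be >= 0")
        if not (1 <= self.n_min <= self.n_max):
            raise InvalidInputError("need 1 <= n_min <= n_max")
        lo, hi = (self.p0, self.p0) if np.isscalar(self.p0) else self.p0
        if not (0.0 < lo <= hi < 1.0):
            raise InvalidInputError("p0 must lie in (0, 1)")


@dataclass(frozen=True)
class StudyTruth:
    theta_i: float
    p0: float
    p1: float
    n_trt: int
    n_ctl: int
    published: bool


@dataclass(frozen=True)
class SimulatedMeta:
    meta_id: str
    tables: tuple[ContingencyTable, ...]  # published trials only
    truth: tuple[StudyTruth, ...]  # all generated trials, published or not
    n_generated: int
    config: SimulationConfig

    def effects(self) -> list[StudyEffect]:
        """Published trials as StudyEffects, double-zero trials dropped."""
        out = []
        for i, t in enumerate(self.tables):
            eff = study_effect(t, study_id=f"{self.meta_id}:{i + 1}")
            if eff is not None:
                out.append(eff)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Published trials in the trial-table layout the pipeline reads."""
        return pd.DataFrame(
            {
                "meta_id": self.meta_id,
                "events_trt": [t.events_trt for t in self.tables],
                "total_trt": [t.total_trt for t in self.tables],
                "events_ctl": [t.events_ctl for t in self.tables],
                "total_ctl": [t.total_ctl for t in self.tables],
            }
        )


def _draw_p0(config: SimulationConfig, rng: np.random.Generator) -> float:
    if np.isscalar(config.p0):
        return float(config.p0)
    lo, hi = config.p0
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def simulate_study(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[ContingencyTable, StudyTruth]:
    """Draw one trial: sample size, risks, study effect, binomial counts."""
    n_total = int(round(np.exp(rng.uniform(np.log(config.n_min), np.log(config.n_max)))))
    n_total = max(n_total, 2)
    n_trt = max(1, int(round(n_total * config.alloc_ratio / (1.0 + config.alloc_ratio))))
    n_ctl = max(1, n_total - n_trt)
    p0 = _draw_p0(config, rng)
    theta_i = float(rng.normal(config.theta, math.sqrt(config.tau2)))
    p1 = float(expit(logit(p0) + theta_i))
    e_trt = int(rng.binomial(n_trt, p1))
    e_ctl = int(rng.binomial(n_ctl, p0))
    table = ContingencyTable(e_trt, n_trt, e_ctl, n_ctl)
    truth = StudyTruth(theta_i, p0, p1, n_trt, n_ctl, published=True)
    return table, truth


def harm_p_one_sided(table: ContingencyTable) -> float:
    """The study's own one-sided Wald p-value for harm (log OR > 0).

    Double-zero tables carry no evidence of harm and score p = 1.
    """
    outcome = apply_zero_handling(table)
    if outcome.status is ZeroStatus.EXCLUDED_DOUBLE_ZERO:
        return 1.0
    y, se = log_odds_ratio(outcome.corrected_table)
    return float(stats.norm.sf(y / se))


def publish_decision(
    table: ContingencyTable, selection: SelectionModel, rng: np.random.Generator
) -> bool:
    """Apply the significance-based suppression rule to one study."""
    if selection.mechanism == "none":
        return True
    if harm_p_one_sided(table) < selection.alpha_sel:
        return bool(rng.random() < selection.gamma)
    return True


_MAX_GENERATED = 1_000_000


def simulate_meta(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    meta_id: str = "meta_1",
) -> SimulatedMeta:
    """Generate studies until ``k_published`` survive the publication rule.

    The truth record keeps every generated study (with its publication flag)
    so the induced suppression fraction is known exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tables: list[ContingencyTable] = []
    truths: list[StudyTruth] = []
    generated = 0
    while len(tables) < config.k_published:
        generated += 1
        if generated > _MAX_GENERATED:
            raise RuntimeError(
                "selection acceptance rate pathologically low: "
                f"> {_MAX_GENERATED} studies generated for k={config.k_published}"
            )
        table, truth = simulate_study(config, rng)
        published = publish_decision(table, config.selection, rng)
        truths.append(replace(truth, published=published))
        if published:
            tables.append(table)
    return SimulatedMeta(meta_id, tuple(tables), tuple(truths), generated, config)


def simulate_corpus(config: SimulationConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Simulate ``config.n_meta`` meta-analyses as one pipeline-ready trial table."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frames = [
        simulate_meta(config, rng, meta_id=f"meta_{i + 1}").to_frame()
        for i in range(config.n_meta)
    ]
    return pd.concat(frames, ignore_index=True)


def operating_characteristics(
    config_grid: Sequence[tuple[str, SimulationConfig]],
    n_reps: int = 200,
    alpha: float = 0.1,
    direction: Direction = Direction.SUPPRESS_HIGH,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Empirical rejection rates of the four test variants over a scenario grid.

    For each labelled configuration, ``n_reps`` meta-analyses are simulated
    and the one- and two-sided Egger and Peters tests are run at level
    ``alpha``; the table reports the rejection proportion, its Monte-Carlo
    standard error, and the number of analysable replicates (a replicate is
    skipped when fewer than three studies survive double-zero exclusion or
    the regression design is degenerate — skipped cells never abort the grid).
    """
    rng = np.random.default_rng(seed)
    rows = []
    variants = [("egger", "one"), ("egger", "two"), ("peters", "one"), ("peters", "two")]
    for label, config in config_grid:
        rejections = {v: 0 for v in variants}
        usable = {v: 0 for v in variants}
        for _ in range(n_reps):
            meta = simulate_meta(config, rng)
            effects = meta.effects()
            if len(effects) < 3:
                continue
            for method in ("egger", "peters"):
                fn = bias_tests.egger_test if method == "egger" else bias_tests.peters_test
                try:
                    res = fn(effects, direction=direction)
                except InvalidInputError:
                    continue
                for sided in ("one", "two"):
                    usable[(method, sided)] += 1
                    if bias_tests.classify(res, alpha=alpha, sidedness=sided).significant:
                        rejections[(method, sided)] += 1
        for (method, sided) in variants:
            n_ok = usable[(method, sided)]
            rate = rejections[(method, sided)] / n_ok if n_ok else float("nan")
            mc_se = math.sqrt(rate * (1 - rate) / n_ok) if n_ok else float("nan")
            rows.append(
                {
                    "scenario": label,
                    "test": method,
                    "sidedness": sided,
                    "alpha": alpha,
                    "rejection_rate": rate,
                    "mc_se": mc_se,
                    "n_usable": n_ok,
                    "n_reps": n_reps,
                }
            )
    return pd.DataFrame(rows)
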