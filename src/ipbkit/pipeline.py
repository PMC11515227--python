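"""End-to-end assessment of inverse publication bias over a trial-level table.

Reads delimited trial tables (one row per trial: meta-analysis id plus the
2x2 cells), applies the eligibility rules (drop rows with missing cells,
drop double-zero trials, require at least ``min_k`` analysable trials),
runs the four asymmetry-test variants and trim-and-fill per meta-analysis,
and aggregates the results into the summary statistics of interest:
per-test significance counts, one- vs two-sided concordance and kappas,
direction-of-change splits, and Venn region counts of the significant sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import agreement, bias_tests, trimfill
from .bias_tests import Direction
from .core import (
    ContingencyTable,
    InvalidInputError,
    StudyEffect,
    ZeroStatus,
    pool_random,
    study_effect,
)

logger = logging.getLogger("ipbkit")

#: Default column names of the trial table; override via ``column_map``.
DEFAULT_COLUMNS = {
    "meta_id": "meta_id",
    "events_trt": "events_trt",
    "total_trt": "total_trt",
    "events_ctl": "events_ctl",
    "total_ctl": "total_ctl",
}

TEST_VARIANTS = ("egger_one", "egger_two", "peters_one", "peters_two")


class SchemaError(InvalidInputError):
    """The trial table lacks required columns."""


@dataclass
class MetaAnalysis:
    """One meta-analysis: its trial tables plus processing state."""

    meta_id: str
    tables: list[Optional[ContingencyTable]]  # None marks a missing-cell row
    effects: list[StudyEffect] = field(default_factory=list)

    @property
    def n_rows_raw(self) -> int:
        return len(self.tables)

    @property
    def n_missing(self) -> int:
        return sum(t is None for t in self.tables)


@dataclass(frozen=True)
class EligibilityReport:
    meta_id: str
    n_rows_raw: int
    n_dropped_missing: int
    n_dropped_double_zero: int
    k_final: int
    eligible: bool
    pooling_method_used: Optional[str] = None


def read_trials(
    path,
    column_map: Optional[dict] = None,
    sep: str = ",",
) -> list[MetaAnalysis]:
    """Read a delimited trial table into per-meta-analysis groups.

    Rows with any missing or unparseable 2x2 cell are retained and flagged
    (``tables`` entry None) so eligibility accounting is exact, never
    silently dropped.
    """
    cols = {**DEFAULT_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path, sep=sep)
    missing_cols = [v for v in cols.values() if v not in df.columns]
    if missing_cols:
        raise SchemaError(f"trial table is missing columns: {missing_cols}")
    metas: list[MetaAnalysis] = []
    count_cols = [cols[c] for c in ("events_trt", "total_trt", "events_ctl", "total_ctl")]
    for meta_id, grp in df.groupby(cols["meta_id"], sort=False):
        tables: list[Optional[ContingencyTable]] = []
        for _, row in grp.iterrows():
            vals = [pd.to_numeric(row[c], errors="coerce") for c in count_cols]
            if any(pd.isna(v) for v in vals):
                tables.append(None)
                continue
            try:
                tables.append(ContingencyTable(*[float(v) for v in vals]))
            except InvalidInputError as err:
                logger.warning("meta %s: unusable row (%s); flagged missing", meta_id, err)
                tables.append(None)
        metas.append(MetaAnalysis(meta_id=str(meta_id), tables=tables))
    return metas


def write_trials(metas: Sequence[MetaAnalysis], path, sep: str = ",") -> None:
    """Write meta-analyses back to the delimited trial-table layout."""
    rows = []
    for meta in metas:
        for t in meta.tables:
            if t is None:
                rows.append({"meta_id": meta.meta_id, "events_trt": None, "total_trt": None,
                             "events_ctl": None, "total_ctl": None})
            else:
                rows.append({"meta_id": meta.meta_id, "events_trt": t.events_trt,
                             "total_trt": t.total_trt, "events_ctl": t.events_ctl,
                             "total_ctl": t.total_ctl})
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def apply_eligibility(
    metas: Sequence[MetaAnalysis],
    min_k: int = 10,
    double_zero_before_threshold: bool = True,
) -> tuple[list[MetaAnalysis], list[EligibilityReport]]:
    """Filter meta-analyses to those with at least ``min_k`` analysable trials.

    Default ordering: drop missing-cell rows, then double-zero trials, then
    apply the threshold — eligibility reflects the trials that can actually
    enter an asymmetry assessment.  Set ``double_zero_before_threshold=False``
    to threshold on the post-missing count instead.
    """
    eligible, reports = [], []
    for meta in metas:
        effects: list[StudyEffect] = []
        n_dz = 0
        for i, table in enumerate(meta.tables):
            if table is None:
                continue
            eff = study_effect(table, study_id=f"{meta.meta_id}:{i + 1}")
            if eff is None:
                n_dz += 1
            else:
                effects.append(eff)
        k_final = len(effects)
        k_for_threshold = k_final if double_zero_before_threshold else k_final + n_dz
        ok = k_for_threshold >= min_k
        reports.append(
            EligibilityReport(
                meta_id=meta.meta_id,
                n_rows_raw=meta.n_rows_raw,
                n_dropped_missing=meta.n_missing,
                n_dropped_double_zero=n_dz,
                k_final=k_final,
                eligible=ok,
            )
        )
        if ok:
            meta.effects = effects
            eligible.append(meta)
    return eligible, reports


def assess_all(
    metas: Sequence[MetaAnalysis],
    alpha: float = 0.1,
    direction: Direction = Direction.SUPPRESS_HIGH,
    trimfill_side: str = "right",
) -> pd.DataFrame:
    """Run the four asymmetry-test variants and trim-and-fill per meta-analysis.

    Returns one row per meta-analysis with pooled results, p-values,
    significance calls and trim-and-fill k0.  Per-meta computational
    failures are recorded in the ``error`` column and never abort the batch.
    """
    rows = []
    for meta in metas:
        row: dict = {"meta_id": meta.meta_id, "k": len(meta.effects), "error": ""}
        try:
            pooled = pool_random(meta.effects)
            row.update(
                mu=pooled.mu, se_mu=pooled.se_mu, tau2=pooled.tau2,
                tau2_method=pooled.tau2_method, reml_converged=pooled.converged,
            )
            for method, fn in (("egger", bias_tests.egger_test),
                               ("peters", bias_tests.peters_test)):
                res = fn(meta.effects, direction=direction)
                row[f"{method}_coef"] = res.coef
                row[f"{method}_p_one"] = res.p_one
                row[f"{method}_p_two"] = res.p_two
                row[f"{method}_one_sig"] = bias_tests.classify(res, alpha, "one").significant
                row[f"{method}_two_sig"] = bias_tests.classify(res, alpha, "two").significant
            tf = trimfill.trim_and_fill(meta.effects, side=trimfill_side)
            row["trimfill_k0"] = tf.k0
            row["mu_adjusted"] = tf.pooled_adjusted.mu
        except Exception as err:  # noqa: BLE001 — per-meta failures are data
            logger.warning("meta %s: assessment failed (%s)", meta.meta_id, err)
            row["error"] = str(err)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["alpha"] = alpha
    df.attrs["direction"] = direction.value
    return df


def _sig_col(method: str, sided: str) -> str:
    return f"{method}_{sided}_sig"


def summarize(rows: pd.DataFrame) -> dict:
    """Aggregate an assessment table into the headline summary statistics.

    Counts and proportions of significant calls per test variant; pairwise
    concordance counts and Cohen's kappas (one- vs two-sided within each
    test, and Egger vs Peters within each sidedness); the split of
    changed calls by direction of change; Venn region counts of the four
    significant sets; and the median number of studies.
    """
    ok = rows[rows["error"] == ""].copy()
    n = len(ok)
    out: dict = {
        "n_meta": n,
        "n_failed": int((rows["error"] != "").sum()),
        "median_k": float(ok["k"].median()) if n else float("nan"),
        "n_dl_fallback": int((ok["tau2_method"] == "DL").sum()) if n else 0,
    }
    sig: dict[str, pd.Series] = {}
    for method in ("egger", "peters"):
        for sided in ("one", "two"):
            s = ok[_sig_col(method, sided)].astype(bool)
            sig[f"{method}_{sided}"] = s
            out[f"n_sig_{method}_{sided}"] = int(s.sum())
            out[f"prop_sig_{method}_{sided}"] = float(s.mean()) if n else float("nan")
    pairs = {
        "egger_one_vs_two": ("egger_one", "egger_two"),
        "peters_one_vs_two": ("peters_one", "peters_two"),
        "one_sided_egger_vs_peters": ("egger_one", "peters_one"),
        "two_sided_egger_vs_peters": ("egger_two", "peters_two"),
    }
    for name, (a, b) in pairs.items():
        agree = (sig[a] == sig[b])
        out[f"n_agree_{name}"] = int(agree.sum())
        out[f"n_change_{name}"] = int(n - agree.sum())
        if n and sig[a].nunique() + sig[b].nunique() > 0:
            out[f"kappa_{name}"] = agreement.cohen_kappa(
                sig[a].tolist(), sig[b].tolist()
            ).kappa
        else:
            out[f"kappa_{name}"] = float("nan")
    # direction of change when moving from the two-sided to the one-sided test
    for method in ("egger", "peters"):
        a, b = sig[f"{method}_one"], sig[f"{method}_two"]
        out[f"n_{method}_sig_to_nonsig"] = int((b & ~a).sum())
        out[f"n_{method}_nonsig_to_sig"] = int((~b & a).sum())
    ids = ok["meta_id"]
    out["venn_significant"] = agreement.venn_counts(
        {name: set(ids[s]) for name, s in sig.items()}, universe=set(ids)
    )
    return out
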