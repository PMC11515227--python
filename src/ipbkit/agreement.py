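"""Inter-rater and inter-test agreement: Cohen's kappa, level collapsing, Venn counts.

Visual funnel-plot grades are human judgments supplied as data (a labels
file of meta_id, rater, grade); this module only quantifies how well two
raters — or two statistical tests dichotomized at the same alpha — agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core import InvalidInputError

#: Ordered four-level visual grade of inverse publication bias.
IPB_GRADES = ("no", "mild", "moderate", "severe")

#: Binary collapse: no/mild -> bias absent, moderate/severe -> bias present.
BINARY_COLLAPSE = {"no": "absent", "mild": "absent", "moderate": "present", "severe": "present"}


@dataclass(frozen=True)
class AgreementSummary:
    contingency: pd.DataFrame  # joint label counts, rows = rater A, cols = rater B
    kappa: float
    n: int


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> AgreementSummary:
    """Unweighted Cohen's kappa between two equal-length label sequences.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and p_e
    the chance agreement from the marginals.  When both raters are constant
    and identical (p_e = 1, p_o = 1) kappa is defined as 1.
    """
    if len(labels_a) != len(labels_b):
        raise InvalidInputError(
            f"label sequences differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    n = len(labels_a)
    if n < 1:
        raise InvalidInputError("kappa needs at least one rated item")
    a = pd.Categorical(list(labels_a), categories=sorted(set(labels_a) | set(labels_b)))
    b = pd.Categorical(list(labels_b), categories=a.categories)
    table = pd.crosstab(a, b, dropna=False)
    table.index.name, table.columns.name = "rater_a", "rater_b"
    p_o = sum(table.values[i][i] for i in range(len(table))) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if p_e >= 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementSummary(contingency=table, kappa=float(kappa), n=n)


def collapse_to_binary(grades: Iterable[str]) -> list[str]:
    """Collapse four-level IPB grades to present/absent."""
    out = []
    for g in grades:
        if g not in BINARY_COLLAPSE:
            raise InvalidInputError(f"unknown IPB grade {g!r}; expected one of {IPB_GRADES}")
        out.append(BINARY_COLLAPSE[g])
    return out


def read_grades(path, sep: str = ",") -> pd.DataFrame:
    """Read a visual-grades labels file with columns meta_id, rater, grade."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"meta_id", "rater", "grade"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"labels file is missing columns: {sorted(missing)}")
    bad = set(df["grade"]) - set(IPB_GRADES)
    if bad:
        raise InvalidInputError(f"unknown grades in labels file: {sorted(bad)}")
    return df


def venn_counts(
    sig_sets: Mapping[str, set],
    universe: Optional[set] = None,
) -> dict[str, int]:
    """Cardinalities of all exclusive intersection regions of named sets.

    Keys are '&'-joined sorted set names (e.g. ``"egger_one&peters_one"``);
    the empty-membership region (items in the universe but in no set) is
    keyed ``"none"``.  Regions partition the universe, which defaults to the
    union of the sets.
    """
    names = sorted(sig_sets)
    union = set().union(*sig_sets.values()) if sig_sets else set()
    univ = set(universe) if universe is not None else union
    if not union <= univ:
        raise InvalidInputError("universe does not contain all set members")
    counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            region = set(univ)
            for nm in combo:
                region &= sig_sets[nm]
            for nm in names:
                if nm not in combo:
                    region -= sig_sets[nm]
            counts["&".join(combo)] = len(region)
    counts["none"] = len(univ - union)
    return counts
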