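"""Descriptive statistics and two-group comparisons for lipid cohorts.

Continuous analytes are summarized as median (Q1, Q3) with type-7
(linearly interpolated) quartiles, compared between groups with the
Wilcoxon rank-sum test; categorical splits use the uncorrected Pearson
chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .lipids import LipidPanel, Sex, estimate_all, LdlMethod

__all__ = ["GroupSummary", "summarize", "rank_sum_test", "chi_square_2x2", "lipid_table"]

#: above this combined sample size the rank-sum p switches from exact
#: enumeration to the tie-corrected normal approximation
_EXACT_N_LIMIT = 12


@dataclass(frozen=True)
class GroupSummary:
    n: int
    median: float
    q1: float
    q3: float

    def __str__(self) -> str:
        return f"{self.median:.2f} ({self.q1:.2f}, {self.q3:.2f})"


def summarize(values) -> GroupSummary:
    """Median and quartiles (type-7 linear interpolation) of a sample."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    return GroupSummary(n=int(x.size), median=float(med), q1=float(q1), q3=float(q3))


def rank_sum_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two independent samples.

    Uses exact enumeration when the combined sample size is at most 12 and
    there are no ties; otherwise the normal approximation with midranks,
    tie correction, and continuity correction.  Returns (statistic, p) where
    the statistic is the Mann-Whitney U of the first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # all observations identical: no evidence of separation
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= _EXACT_N_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(table) -> tuple[float, float]:
    """Uncorrected Pearson chi-square test (1 df) on a 2x2 count table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin: expected counts undefined")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


_ANALYTES = [
    ("TG [mg/dL]", lambda p, e: p.tg),
    ("TC [mg/dL]", lambda p, e: p.tc),
    ("HDL [mg/dL]", lambda p, e: p.hdl),
    ("non-HDL [mg/dL]", lambda p, e: p.non_hdl),
    ("LDL-D [mg/dL]", lambda p, e: p.ldl_direct),
    ("LDL-C Friedewald [mg/dL]", lambda p, e: e[LdlMethod.FRIEDEWALD]),
    ("LDL-C Sampson-NIH [mg/dL]", lambda p, e: e[LdlMethod.SAMPSON]),
]


def lipid_table(
    panels: Iterable[LipidPanel],
    grouping: Literal["sex", "age_lt_13"] = "sex",
) -> pd.DataFrame:
    """Per-analyte summary table with two-group comparison.

    One row per analyte (TG, TC, HDL, non-HDL, direct LDL, Friedewald LDL,
    Sampson-NIH LDL) with overall and per-group median/Q1/Q3 plus the
    rank-sum p-value.  ``grouping`` is either by sex or by the age-13 split.
    Analytes missing for a subject (absent direct LDL) are dropped pairwise.
    """
    panels = list(panels)
    if grouping == "sex":
        labels = ("boy", "girl")
        group_of = lambda p: "boy" if p.sex is Sex.BOY else "girl"
    elif grouping == "age_lt_13":
        labels = ("<13", ">=13")
        group_of = lambda p: "<13" if p.age_years < 13 else ">=13"
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    values: dict[str, dict[str, list[float]]] = {
        name: {"all": [], labels[0]: [], labels[1]: []} for name, _ in _ANALYTES
    }
    for panel in panels:
        ests = {e.method: e.value for e in estimate_all(panel)}
        g = group_of(panel)
        for name, getter in _ANALYTES:
            v = getter(panel, ests)
            if v is None:
                continue
            values[name]["all"].append(v)
            values[name][g].append(v)

    rows = []
    for name, _ in _ANALYTES:
        v = values[name]
        for lab in labels:
            if len(v[lab]) < 2:
                raise ValueError(f"group {lab!r} has fewer than 2 values for {name}")
        overall = summarize(v["all"])
        s1, s2 = summarize(v[labels[0]]), summarize(v[labels[1]])
        _, p = rank_sum_test(v[labels[0]], v[labels[1]])
        rows.append(
            {
                "analyte": name,
                "n": overall.n,
                "median": overall.median,
                "q1": overall.q1,
                "q3": overall.q3,
                f"median_{labels[0]}": s1.median,
                f"q1_{labels[0]}": s1.q1,
                f"q3_{labels[0]}": s1.q3,
                f"median_{labels[1]}": s2.median,
                f"q1_{labels[1]}": s2.q1,
                f"q3_{labels[1]}": s2.q3,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
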