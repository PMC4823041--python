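"""Cohort-level statistical utilities.

Fisher's exact independence tests for 2x2 cohort-composition tables,
Wilcoxon rank-sum class contrasts and Benjamini-Hochberg adjustment —
the standard tests wrapped behind small, validated interfaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of a binary category (rows) across two cohorts (columns)."""

    a: int  # category +, cohort 1
    b: int  # category +, cohort 2
    c: int  # category -, cohort 1
    d: int  # category -, cohort 2

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def degenerate(self) -> bool:
        t = self.as_array()
        return (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any()


def fisher_independence(table: ContingencyTable2x2,
                        ) -> tuple[float, float]:
    """Two-sided Fisher exact test (point-probability method).

    Returns ``(p_value, odds_ratio)`` with the sample odds ratio
    ``ad/bc`` (infinite when ``bc == 0`` and ``ad > 0``).
    """
    if table.degenerate:
        warnings.warn("degenerate contingency margins; p = 1",
                      stacklevel=2)
        return 1.0, float("nan")
    res = sps.fisher_exact(table.as_array(), alternative="two-sided")
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return float(res.pvalue), odds


def wilcoxon_class_diff(values, classes) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two labelled groups.

    Exact enumeration when both groups have <= 10 samples and the pooled
    values are tie-free; otherwise the normal approximation with tie
    correction.  Constant pooled values give p = 1.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    labels = np.unique(classes)
    if labels.size != 2:
        raise ValueError(f"need exactly two class labels, got {labels}")
    x = values[classes == labels[0]]
    y = values[classes == labels[1]]
    if x.size < 3 or y.size < 3:
        raise ValueError("need >= 3 samples per class")
    if np.ptp(values) == 0:
        return 1.0
    tie_free = np.unique(values).size == values.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and tie_free) \
        else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(min(res.pvalue, 1.0))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohort_composition_table(categories: pd.DataFrame,
                             cohort_col: str = "cohort") -> pd.DataFrame:
    """Table-1-style summary of binary categories across two cohorts.

    ``categories`` has one row per sample, a cohort column and one column
    per binary category ('+'/'-', with missing values excluded per
    category).  Returns counts, percentages and the Fisher p-value per
    category.
    """
    cohorts = sorted(categories[cohort_col].dropna().unique())
    if len(cohorts) != 2:
        raise ValueError("exactly two cohorts required")
    rows = []
    for col in categories.columns:
        if col == cohort_col:
            continue
        sub = categories[[cohort_col, col]].dropna()
        counts = {}
        for level in ("+", "-"):
            for coh in cohorts:
                counts[(level, coh)] = int(
                    ((sub[col] == level)
                     & (sub[cohort_col] == coh)).sum())
        t = ContingencyTable2x2(counts[("+", cohorts[0])],
                                counts[("+", cohorts[1])],
                                counts[("-", cohorts[0])],
                                counts[("-", cohorts[1])])
        p, odds = fisher_independence(t)
        n0 = counts[("+", cohorts[0])] + counts[("-", cohorts[0])]
        n1 = counts[("+", cohorts[1])] + counts[("-", cohorts[1])]
        rows.append({
            "category": col,
            f"{cohorts[0]}_pos": counts[("+", cohorts[0])],
            f"{cohorts[0]}_pct": 100 * counts[("+", cohorts[0])]
            / n0 if n0 else float("nan"),
            f"{cohorts[1]}_pos": counts[("+", cohorts[1])],
            f"{cohorts[1]}_pct": 100 * counts[("+", cohorts[1])]
            / n1 if n1 else float("nan"),
            "p_value": p, "odds_ratio": odds,
        })
    return pd.DataFrame(rows)
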