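"""Descriptive cohort-comparison statistics.

Pearson chi-square on 2x2 trait-by-cohort tables (uncorrected by default,
Yates optional), the Mann-Whitney rank-sum test reported as a signed,
tie-corrected normal z statistic, and tidy per-node summary tables
(mean +/- sd, median and interquartile-range width).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, norm, rankdata

__all__ = [
    "ContingencyTable2x2",
    "pearson_chi2",
    "mann_whitney_z",
    "group_summaries",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a, b / c, d: rows are cohorts, columns trait present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @classmethod
    def from_proportions(cls, yes_a: int, n_a: int, yes_b: int, n_b: int):
        return cls(yes_a, n_a - yes_a, yes_b, n_b - yes_b)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def pearson_chi2(
    table: ContingencyTable2x2, correction: bool = False
) -> tuple[float, float]:
    """Pearson X^2 = sum (O-E)^2/E on a 2x2 table, with 1-df p-value.

    Uncorrected by default; ``correction=True`` applies Yates' continuity
    correction.  A zero row or column margin is an error.
    """
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    stat, p, _, _ = chi2_contingency(arr, correction=correction)
    return float(stat), float(p)


def mann_whitney_z(
    sample_a: Iterable[float], sample_b: Iterable[float]
) -> tuple[float, float]:
    """Mann-Whitney rank-sum test as a signed normal z with tie correction.

    The sign follows the location of ``sample_a`` relative to ``sample_b``:
    z > 0 when a is stochastically larger.  p is the two-sided normal tail.
    """
    a = np.asarray(list(sample_a), float)
    b = np.asarray(list(sample_b), float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    ranks = rankdata(np.concatenate([a, b]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2  # U statistic of sample a
    mu = n1 * n2 / 2
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    n = n1 + n2
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12 * (n + 1 - tie_term)
    if var <= 0:
        raise ValueError("all values tied across both samples")
    z = (u - mu) / np.sqrt(var)
    return float(z), float(2 * norm.sf(abs(z)))


def group_summaries(
    data: pd.DataFrame,
    columns: Sequence[str],
    by: str = "node",
) -> pd.DataFrame:
    """Tidy per-group summary: mean, sd, median and IQR width per column.

    The IQR is reported as the width of the interquartile range
    (75th - 25th percentile), the convention of the cohort tables.
    """
    missing = [c for c in list(columns) + [by] if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    rows = []
    for group, sub in data.groupby(by):
        if sub.empty:
            raise ValueError(f"empty group {group!r}")
        for col in columns:
            vals = sub[col].dropna().to_numpy(float)
            if vals.size == 0:
                continue
            q75, q25 = np.percentile(vals, [75, 25])
            rows.append(
                {
                    by: group,
                    "variable": col,
                    "n": vals.size,
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
                    "median": float(np.median(vals)),
                    "iqr": float(q75 - q25),
                }
            )
    return pd.DataFrame(rows)
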