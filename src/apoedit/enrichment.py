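"""Contingency and overlap statistics for editing-event sets.

Thin, explicit wrappers over scipy's exact/asymptotic tests with the
conventions used throughout the package: Pearson chi-squared without
continuity correction by default, two-sided Fisher exact by the
point-probability rule, and a retention statistic comparing the
composition of a filtered site set against its pre-filter superset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "chi2_2x2",
    "fisher_exact_2x2",
    "retention_test",
    "overlap_sites",
    "pearson_corr",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("2x2 table entries must be non-negative integers")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def _coerce(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    arr = np.asarray(table).reshape(4)
    return ContingencyTable2x2(*(int(v) for v in arr))


def chi2_2x2(table, continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, df=1, upper-tail p.

    No Yates continuity correction by default.
    """
    t = _coerce(table).as_array()
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-squared undefined: zero row or column margin")
    res = stats.chi2_contingency(t, correction=continuity)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table, method: str = "point") -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    ``method='point'`` sums all margin-fixed tables with hypergeometric
    point probability <= that of the observed table (the common default);
    ``method='central'`` doubles the smaller one-sided tail, capped at 1.
    """
    t = _coerce(table).as_array()
    if method == "point":
        return float(stats.fisher_exact(t, alternative="two-sided").pvalue)
    if method == "central":
        less = stats.fisher_exact(t, alternative="less").pvalue
        greater = stats.fisher_exact(t, alternative="greater").pvalue
        return float(min(1.0, 2.0 * min(less, greater)))
    raise ValueError(f"unknown method {method!r}")


def retention_test(
    retained_overlap: int,
    retained_nonoverlap: int,
    prefilter_overlap: int,
    prefilter_nonoverlap: int,
    continuity: bool = False,
) -> dict:
    """Chi-squared comparison of a retained set's composition vs its
    pre-filter superset.

    Builds the 2x2 table [[retained_overlap, retained_nonoverlap],
    [prefilter_overlap, prefilter_nonoverlap]] and applies
    :func:`chi2_2x2`.  Note the rows are *not* disjoint (the retained set
    is a subset of the pre-filter set); the construction deliberately
    compares compositions, and the returned metadata records this.
    """
    if retained_overlap > prefilter_overlap or retained_nonoverlap > prefilter_nonoverlap:
        raise ValueError("retained counts must not exceed pre-filter counts")
    table = ContingencyTable2x2(
        retained_overlap, retained_nonoverlap, prefilter_overlap, prefilter_nonoverlap
    )
    stat, p = chi2_2x2(table, continuity=continuity)
    return {
        "test": "chi2_2x2",
        "table": [table.a, table.b, table.c, table.d],
        "rows_overlap": True,
        "statistic": stat,
        "p_value": p,
    }


def overlap_sites(
    set_a: Iterable[Hashable], set_b: Iterable[Hashable]
) -> tuple[int, int, int]:
    """(n shared, n in a only, n in b only) for two site-key sets."""
    a, b = set(set_a), set(set_b)
    return len(a & b), len(a - b), len(b - a)


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
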