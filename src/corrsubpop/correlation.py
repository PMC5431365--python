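"""Pearson correlation with significance, and cohort summary statistics.

p-values use the exact Student-t reference distribution
``t = r * sqrt((n-2) / (1-r^2))`` with ``n-2`` degrees of freedom rather
than a normal approximation; several cohort pairs have only a few hundred
pairwise-complete subjects.  Significance is flagged at p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocessing import VariablePair, pairwise_complete
from .tabular_io import BiomarkerTable

#: Two-sided significance level for correlation flags.
ALPHA = 0.01


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson coefficient r with pair count n and two-sided p-value."""

    x_name: str
    y_name: str
    r: float
    n: int
    p: float

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass(frozen=True)
class SummaryStats:
    """Range, sample SD and mean of one variable's non-missing values."""

    variable: str
    n: int
    min: float
    max: float
    mean: float
    sd: float


def pearson(pair: VariablePair) -> CorrelationResult:
    """Pearson correlation of a pairwise-complete variable pair.

    Raises
    ------
    ValueError
        When fewer than 3 pairs are available or a coordinate is constant.
    """
    n = len(pair)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    for name, v in ((pair.x_name, pair.x), (pair.y_name, pair.y)):
        if np.ptp(v) == 0:
            raise ValueError(f"variable {name!r} is constant; correlation undefined")
    dx = pair.x - pair.x.mean()
    dy = pair.y - pair.y.mean()
    slope = (dx * dy).sum() / (dx * dx).sum()
    if np.array_equal(dy, slope * dx):  # exact collinearity: t statistic diverges
        return CorrelationResult(pair.x_name, pair.y_name, float(np.sign(slope)), n, 0.0)
    r, p = stats.pearsonr(pair.x, pair.y)
    return CorrelationResult(pair.x_name, pair.y_name, float(r), n, float(p))


def correlation_table(
    table: BiomarkerTable, pairs: list[tuple[str, str]]
) -> list[CorrelationResult | Exception]:
    """One :func:`pearson` result per requested pair.

    Each pair is evaluated on its own pairwise-complete subject subset, so
    the per-row n values differ when missingness differs.  A failing pair
    (constant variable, too few subjects) yields the exception object in its
    row rather than aborting the whole table.
    """
    out: list[CorrelationResult | Exception] = []
    for x_name, y_name in pairs:
        try:
            out.append(pearson(pairwise_complete(table, x_name, y_name)))
        except (ValueError, KeyError) as exc:
            out.append(exc)
    return out


def summarize(table: BiomarkerTable, variable: str) -> SummaryStats:
    """n, min, max, mean and sample SD (n-1 denominator) of one variable."""
    v = table.column(variable)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError(f"variable {variable!r} has no non-missing values")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return SummaryStats(
        variable=variable,
        n=int(v.size),
        min=float(v.min()),
        max=float(v.max()),
        mean=float(v.mean()),
        sd=sd,
    )
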