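"""Long-term trend statistics: OLS annual rates, block means, percent change.

These are the summary statistics used to report multi-year behaviour of
yields, incomes, soil carbon and the net ecosystem economic budget:
ordinary least-squares slopes against calendar year (so that missing
years are handled naturally), multi-year block means with percent
changes between consecutive blocks, and simple percent change.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError

#: Default block edges: four five-year windows covering a 2003–2022 study.
DEFAULT_BLOCKS: tuple[tuple[int, int], ...] = (
    (2003, 2007),
    (2008, 2012),
    (2013, 2017),
    (2018, 2022),
)


@dataclass(frozen=True)
class TrendResult:
    """An ordinary least-squares linear trend against calendar year."""

    slope: float
    intercept: float
    n: int
    r_squared: float


@dataclass(frozen=True)
class BlockSummary:
    """Mean of one year-block and its percent change vs the previous block."""

    label: str
    start: int
    end: int
    n: int
    mean: float
    pct_change_vs_previous: float | None


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (report-table convention, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def ols_trend(years: Sequence[int], values: Sequence[float]) -> TrendResult:
    """Least-squares slope and intercept of ``values`` against year.

    Years must be strictly increasing; gaps are allowed and enter the
    fit at their true calendar position.  Requires n ≥ 3.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.shape != values.shape or years.ndim != 1:
        raise ValidationError("years and values must be 1-D and equal length")
    if len(years) < 3:
        raise InsufficientDataError(f"need >= 3 years, got {len(years)}")
    if np.any(np.diff(years) <= 0):
        raise ValidationError("years must be strictly increasing (no duplicates)")
    fit = stats.linregress(years, values)
    r2 = fit.rvalue**2
    if not np.isfinite(r2):  # constant series: slope 0, r^2 undefined
        r2 = 0.0
    return TrendResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(years),
        r_squared=float(r2),
    )


def pct_change(a: float, b: float) -> float:
    """Percent change from ``a`` to ``b``: (b/a − 1) × 100.  Needs a > 0."""
    if a <= 0:
        raise ValidationError(f"baseline must be > 0, got {a}")
    return (b / a - 1.0) * 100.0


def block_means(
    years: Sequence[int],
    values: Sequence[float],
    block_edges: Sequence[tuple[int, int]] = DEFAULT_BLOCKS,
) -> list[BlockSummary]:
    """Arithmetic means over year blocks with consecutive percent changes.

    ``block_edges`` is a chronologically ordered list of inclusive
    (start, end) year ranges; every block must contain at least one
    observed year.  The percent change of block k vs block k−1 is
    (mean_k / mean_{k−1} − 1) × 100, reported unrounded (round for
    display with :func:`round_half_up`).
    """
    years = np.asarray(years, dtype=int)
    values = np.asarray(values, dtype=float)
    if years.shape != values.shape:
        raise ValidationError("years and values must have equal length")
    edges = [(int(s), int(e)) for s, e in block_edges]
    for (s1, e1), (s2, e2) in zip(edges, edges[1:]):
        if s2 <= e1:
            raise ValidationError("blocks must be disjoint and ordered")
    out: list[BlockSummary] = []
    prev_mean: float | None = None
    for start, end in edges:
        mask = (years >= start) & (years <= end)
        if not mask.any():
            raise ValidationError(f"block {start}-{end} contains no observations")
        mean = float(values[mask].mean())
        change = None if prev_mean is None else pct_change(prev_mean, mean)
        out.append(
            BlockSummary(
                label=f"{start}-{end}",
                start=start,
                end=end,
                n=int(mask.sum()),
                mean=mean,
                pct_change_vs_previous=change,
            )
        )
        prev_mean = mean
    return out
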