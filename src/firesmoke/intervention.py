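"""Before/after comparison of exposure and burden around the burning ban.

Period membership is by calendar year (the ban's enforcement year closes
the "before" period); comparisons are descriptive annual means, not causal
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PeriodComparison:
    metric: str
    before_annual_mean: float
    after_annual_mean: float
    absolute_change: float
    percent_change: float


def split_periods(
    series: pd.DataFrame | pd.Series,
    before_years: tuple[int, ...],
    after_years: tuple[int, ...],
    date_col: str = "date",
):
    """Partition a dated series into the pre-ban and post-ban periods.

    Membership is by calendar year against the configured period
    definitions. Either side being empty is an error: the series must span
    the intervention.
    """
    if isinstance(series, pd.Series):
        years = pd.DatetimeIndex(series.index).year
        before = series[np.isin(years, before_years)]
        after = series[np.isin(years, after_years)]
    else:
        years = series[date_col].dt.year
        before = series[years.isin(before_years)]
        after = series[years.isin(after_years)]
    if len(before) == 0 or len(after) == 0:
        raise ValueError("series does not cover both sides of the ban")
    return before, after


def compare(
    metric_by_year: dict[int, float] | pd.Series,
    before_years: tuple[int, ...],
    after_years: tuple[int, ...],
    metric: str = "",
) -> PeriodComparison:
    """Annual means per period and their absolute/percent change.

    Annual means are unweighted means of the per-year values (no
    day-weighting). Every configured year must have a value.
    """
    values = pd.Series(metric_by_year, dtype=float)
    missing = [y for y in (*before_years, *after_years) if y not in values.index]
    if missing:
        raise ValueError(f"no value for year(s) {missing}")
    before = float(values.loc[list(before_years)].mean())
    after = float(values.loc[list(after_years)].mean())
    change = after - before
    pct = 100.0 * change / before if before != 0 else float("nan")
    return PeriodComparison(metric, before, after, change, pct)


def comparison_table(
    metrics: dict[str, dict[int, float] | pd.Series],
    before_years: tuple[int, ...],
    after_years: tuple[int, ...],
) -> pd.DataFrame:
    """Stack :func:`compare` over named metrics into one tidy table."""
    rows = [
        compare(values, before_years, after_years, metric=name)
        for name, values in metrics.items()
    ]
    return pd.DataFrame([r.__dict__ for r in rows])
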