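"""Health-burden attribution: from fire-originated PM10 to attributable visits.

The concentration–response function gives a relative risk per 10 μg/m³;
per province-day the relative risk is RR = exp(β · PM10_fire) with
β = ln(RR_10)/10, the population attributable fraction is (RR − 1)/RR, and
attributable cases are daily visits × PAF, summed over burning days.
Uncertainty ranges re-run the attribution at the CRF's 95% CI bounds; only
CRF uncertainty is propagated.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import CRF

logger = logging.getLogger(__name__)


def beta_from_rr(rr: float, per: float = 10.0) -> float:
    """Per-μg/m³ log-relative-risk implied by a relative risk per ``per`` μg/m³."""
    if rr <= 0:
        raise ValueError("relative risk must be positive")
    return float(np.log(rr) / per)


def relative_risk(fire_pm10, beta: float):
    """RR = exp(β · PM10_fire); elementwise on arrays."""
    return np.exp(beta * np.asarray(fire_pm10, dtype=float))


def paf(rr):
    """Population attributable fraction (RR − 1)/RR."""
    rr = np.asarray(rr, dtype=float)
    return (rr - 1.0) / rr


def attributable_cases(hv, rr):
    """Daily attributable visits HV × (RR − 1)/RR.

    ``rr`` below 1 is an error: it cannot arise with non-negative exposure
    and a non-negative coefficient.
    """
    hv = np.asarray(hv, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if (hv < 0).any():
        raise ValueError("visit counts must be non-negative")
    if (rr < 1).any():
        raise ValueError("relative risk below 1")
    return hv * (rr - 1.0) / rr


def daily_attribution(
    fire_series: pd.DataFrame,
    visits: pd.DataFrame,
    rr_table: dict[str, CRF],
) -> pd.DataFrame:
    """Attributable visits per (province, burning day, age group).

    Joins the fire-originated PM10 series with the daily visit counts and
    applies each age group's CRF at its central RR and 95% CI bounds.
    Returns one row per province-day-age_group with ``fire_pm10, count,
    rr, paf, attributable, attributable_low, attributable_high``.
    """
    merged = visits.merge(
        fire_series[["province", "date", "fire_pm10"]],
        on=["province", "date"],
        how="inner",
    )
    frames = []
    for group, crf in rr_table.items():
        sub = merged[merged["age_group"] == group].copy()
        if sub.empty:
            continue
        betas = {
            "": beta_from_rr(crf.rr_per_10, crf.per),
            "_low": beta_from_rr(crf.ci_low, crf.per),
            "_high": beta_from_rr(crf.ci_high, crf.per),
        }
        rr = relative_risk(sub["fire_pm10"], betas[""])
        sub["rr"] = rr
        sub["paf"] = paf(rr)
        for suffix, beta in betas.items():
            sub[f"attributable{suffix}"] = attributable_cases(
                sub["count"], relative_risk(sub["fire_pm10"], beta)
            )
        frames.append(sub)
    if not frames:
        raise ValueError("no visit rows match the fire series and CRF table")
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["province", "date", "age_group"], kind="mergesort").reset_index(
        drop=True
    )


def aggregate_burden(
    daily: pd.DataFrame,
    visits: pd.DataFrame,
    population: pd.DataFrame,
    calendar: pd.DataFrame,
) -> pd.DataFrame:
    """Sum attributable cases per (province, year, age group) with context.

    ``proportion_of_total`` is attributable cases as a percentage of all
    visits in the stratum over the period; ``proportion_of_burning_days``
    uses burning-day visits only. ``incidence_per_100k`` uses the province
    population of the configured reference year; a zero population leaves
    incidence missing with a warning.
    """
    daily = daily.copy()
    daily["period"] = daily["date"].dt.year.astype(str)
    visits = visits.copy()
    visits["period"] = visits["date"].dt.year.astype(str)

    burning_dates = calendar.loc[calendar["label"] == "burning", ["province", "date"]]
    burning_visits = visits.merge(burning_dates, on=["province", "date"])

    agg = (
        daily.groupby(["province", "period", "age_group"])
        .agg(
            attributable=("attributable", "sum"),
            attributable_low=("attributable_low", "sum"),
            attributable_high=("attributable_high", "sum"),
            paf_mean=("paf", "mean"),
            n_burning_days=("date", "nunique"),
        )
        .reset_index()
    )
    total = (
        visits.groupby(["province", "period", "age_group"])["count"]
        .sum()
        .rename("total_visits")
    )
    burn = (
        burning_visits.groupby(["province", "period", "age_group"])["count"]
        .sum()
        .rename("burning_day_visits")
    )
    agg = agg.merge(total, on=["province", "period", "age_group"], how="left")
    agg = agg.merge(burn, on=["province", "period", "age_group"], how="left")
    agg["proportion_of_total"] = 100.0 * agg["attributable"] / agg["total_visits"]
    agg["proportion_of_burning_days"] = (
        100.0 * agg["attributable"] / agg["burning_day_visits"]
    )

    pop = population.groupby("province")["population"].sum()
    agg["population"] = agg["province"].map(pop)
    zero_pop = agg["population"].isna() | (agg["population"] <= 0)
    if zero_pop.any():
        logger.warning(
            "%d stratum/strata with zero or unknown population; incidence left missing",
            int(zero_pop.sum()),
        )
    agg["incidence_per_100k"] = np.where(
        zero_pop, np.nan, 1e5 * agg["attributable"] / agg["population"]
    )
    return agg.sort_values(
        ["province", "period", "age_group"], kind="mergesort"
    ).reset_index(drop=True)


def region_totals(annual: pd.DataFrame) -> pd.DataFrame:
    """Whole-region totals per (period, age group) from the province table."""
    out = (
        annual.groupby(["period", "age_group"])
        .agg(
            attributable=("attributable", "sum"),
            attributable_low=("attributable_low", "sum"),
            attributable_high=("attributable_high", "sum"),
            total_visits=("total_visits", "sum"),
            burning_day_visits=("burning_day_visits", "sum"),
        )
        .reset_index()
    )
    out["proportion_of_total"] = 100.0 * out["attributable"] / out["total_visits"]
    out["proportion_of_burning_days"] = (
        100.0 * out["attributable"] / out["burning_day_visits"]
    )
    return out


def uncertainty_range(
    fire_series: pd.DataFrame, visits: pd.DataFrame, crf: CRF
) -> tuple[float, float]:
    """Total attributable cases recomputed at the CRF's 95% CI bounds."""
    table = daily_attribution(fire_series, visits, {crf.age_group: crf})
    return float(table["attributable_low"].sum()), float(table["attributable_high"].sum())
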