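"""From hourly monitor records and hotspot points to fire-originated PM10.

The chain is: completeness-filtered station daily means → nearest-monitor
district concentrations → population-weighted province daily PM10 →
burning-day classification from regional hotspot counts and a concentration
cut-point → seasonality/day-of-week-adjusted background per province →
fire-originated PM10 as the excess of the daily value over background on
burning days.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

LABEL_BURNING = "burning"
LABEL_BACKGROUND = "background"
LABEL_OTHER = "other"


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in kilometres between coordinate pairs."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


# ---------------------------------------------------------------------------
# daily means and population weighting


def daily_average(hourly: pd.DataFrame, min_valid: int = 18) -> pd.DataFrame:
    """Collapse hourly records to station-day means under a completeness rule.

    A daily mean is reported only when at least ``min_valid`` (default 18,
    i.e. 75% of 24) hourly values are present; otherwise the day is missing.
    Missing is a value, not an error.

    Returns columns ``station_id, province, date, pm10_daily, n_valid_hours``.
    """
    df = hourly.copy()
    df["date"] = df["timestamp"].dt.normalize()
    grouped = df.groupby(["station_id", "province", "date"], sort=True)["pm10"]
    out = grouped.agg(pm10_daily="mean", n_valid_hours="count").reset_index()
    out["pm10_daily"] = out["pm10_daily"].where(out["n_valid_hours"] >= min_valid)
    out["n_valid_hours"] = out["n_valid_hours"].astype(int)
    return out


def population_weight(district_conc: dict[str, float], population: pd.DataFrame) -> float:
    """Population-weighted mean concentration over a province's districts.

    Computes Σ C_i·P_i / P_tot with P_i the district populations. The
    result is missing (NaN) when any district lacks a concentration, with a
    warning; a zero total population is an error.
    """
    pop = population.set_index("district_id")["population"]
    p_tot = float(pop.sum())
    if p_tot <= 0:
        raise ValueError("total population must be positive")
    conc = pd.Series(district_conc, dtype=float).reindex(pop.index)
    if conc.isna().any():
        missing = list(conc.index[conc.isna()])
        logger.warning("missing concentration for district(s) %s", missing)
        return float("nan")
    return float((conc * pop).sum() / p_tot)


def assign_station_to_districts(
    stations: pd.DataFrame, districts: pd.DataFrame
) -> pd.Series:
    """Map each district to its nearest same-province monitoring station.

    ``stations`` needs ``station_id, province, lat, lon``; ``districts``
    needs ``district_id, province, lat, lon``. Distance is great-circle;
    ties break to the lexicographically smaller station id. A province with
    no station is an error.
    """
    out: dict[str, str] = {}
    stations = stations.drop_duplicates(subset="station_id")
    by_prov = dict(tuple(stations.groupby("province")))
    for _, d in districts.iterrows():
        prov = d["province"]
        if prov not in by_prov:
            raise ValueError(f"province {prov!r} has no monitoring station")
        cand = by_prov[prov]
        dist = haversine_km(
            d["lat"], d["lon"], cand["lat"].to_numpy(), cand["lon"].to_numpy()
        )
        order = sorted(zip(dist, cand["station_id"]), key=lambda x: (x[0], x[1]))
        out[d["district_id"]] = order[0][1]
    return pd.Series(out, name="station_id")


def province_daily_series(
    station_daily: pd.DataFrame,
    population: pd.DataFrame,
    district_station: pd.Series | None = None,
) -> pd.DataFrame:
    """Population-weighted daily PM10 per province.

    Each district carries its assigned station's daily value; the province
    value is the population-weighted mean. When ``district_station`` is
    None (no coordinates available) every district takes the unweighted
    mean of its province's stations for that day. ``pm10_weighted`` is
    present only when every district in the province has a value.

    Returns ``province, date, pm10_daily, pm10_weighted, n_stations_valid``
    where ``pm10_daily`` is the unweighted mean over stations.
    """
    dates = station_daily["date"].drop_duplicates().sort_values()
    frames = []
    for prov, pop in population.groupby("province", sort=True):
        p = pop.set_index("district_id")["population"]
        p_tot = float(p.sum())
        if p_tot <= 0:
            raise ValueError(f"province {prov!r} has zero total population")
        sd = station_daily[station_daily["province"] == prov]
        wide = sd.pivot(index="date", columns="station_id", values="pm10_daily")
        wide = wide.reindex(dates)
        if district_station is not None:
            cols = district_station.loc[p.index]
            conc = wide.reindex(columns=cols.to_numpy())
            conc.columns = p.index
        else:
            mean = wide.mean(axis=1).where(wide.notna().all(axis=1))
            conc = pd.DataFrame({d: mean for d in p.index})
        weighted = (conc * (p / p_tot)).sum(axis=1, min_count=len(p))
        weighted = weighted.where(conc.notna().all(axis=1))
        frames.append(
            pd.DataFrame(
                {
                    "province": prov,
                    "date": dates.to_numpy(),
                    "pm10_daily": wide.mean(axis=1).to_numpy(),
                    "pm10_weighted": weighted.to_numpy(),
                    "n_stations_valid": wide.notna().sum(axis=1).to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# hotspots and burning-day classification


def filter_hotspots(hotspots: pd.DataFrame, confidence_min: float = 20.0) -> pd.DataFrame:
    """Drop low-confidence detections; strictly below the cut is excluded."""
    return hotspots[hotspots["confidence"] >= confidence_min].reset_index(drop=True)


def daily_hotspot_counts(
    hotspots: pd.DataFrame, start: pd.Timestamp, end: pd.Timestamp
) -> pd.Series:
    """Daily region-wide hotspot counts, zero-filled over the study period."""
    idx = pd.date_range(start, end, freq="D")
    counts = hotspots.groupby("date").size().reindex(idx, fill_value=0)
    counts.index.name = "date"
    return counts.rename("hotspot_count")


def hotspot_threshold(daily_counts: pd.Series, percentile: float = 0.90) -> int:
    """Nearest-rank empirical percentile of daily regional hotspot counts.

    With n sorted counts the threshold is the value at rank ⌈p·n⌉
    (1-based). Burning-day classification uses strict "exceeds", so a
    constant series yields a threshold no day exceeds.
    """
    n = len(daily_counts)
    if n == 0:
        raise ValueError("empty hotspot count series")
    rank = math.ceil(percentile * n)
    return int(np.sort(daily_counts.to_numpy())[rank - 1])


def classify_days(
    series: pd.DataFrame,
    daily_counts: pd.Series,
    threshold: int,
    cutoff: float,
) -> pd.DataFrame:
    """Label every province-day as burning, background, or other.

    burning: regional count strictly exceeds the threshold AND the
    province's population-weighted PM10 strictly exceeds the cut-point.
    background: zero regional hotspots (the background-eligible set).
    other: everything else — days with some but sub-threshold fire
    activity, supra-threshold days that miss the concentration criterion,
    and candidate days with missing PM10 (logged).
    """
    df = series[["province", "date", "pm10_weighted"]].copy()
    df["regional_hotspot_count"] = (
        df["date"].map(daily_counts).fillna(0).astype(int)
    )
    count = df["regional_hotspot_count"]
    pm = df["pm10_weighted"]

    label = np.full(len(df), LABEL_OTHER, dtype=object)
    label[count == 0] = LABEL_BACKGROUND
    label[(count > threshold) & (pm > cutoff)] = LABEL_BURNING

    missing_candidate = (count > threshold) & pm.isna()
    if missing_candidate.any():
        logger.warning(
            "%d candidate burning day(s) have missing PM10; labelled 'other'",
            int(missing_candidate.sum()),
        )
    df["label"] = label
    return df[["province", "date", "label", "regional_hotspot_count"]]


# ---------------------------------------------------------------------------
# background model


@dataclass
class BackgroundModel:
    """Fitted spline + day-of-week background regression for one province.

    ``background_mean`` is the seasonality/DOW-adjusted average PM10 on
    zero-hotspot days: the mean residual over the fit days (zero for an
    ordinary least-squares fit) plus the mean of the model's predictions
    over every calendar day of the study period, so that seasonal
    under-sampling of background days does not bias the scalar.
    """

    province: str
    df_per_year: int
    total_df: int
    dow_effects: pd.Series
    spline_coefficients: np.ndarray
    background_mean: float
    aic: float
    n_days_fit: int
    candidate_aic: dict[int, float] = field(default_factory=dict)
    fitted_daily: pd.Series | None = None  # diagnostic, not used downstream


def _fit_one(bg: pd.DataFrame, total_df: int):
    model = smf.ols(f"pm10 ~ cr(t, df={total_df}) + C(dow)", data=bg)
    # the natural spline basis spans the intercept, so exactly one redundant
    # dimension is expected (resolved by the pseudoinverse); anything beyond
    # that means a genuinely singular design
    design_rank = np.linalg.matrix_rank(model.exog)
    if design_rank < model.exog.shape[1] - 1:
        raise ValueError("singular design matrix in background fit")
    return model.fit()


def fit_background(
    series: pd.DataFrame,
    province: str | None = None,
    df_candidates: tuple[int, ...] = (4, 5, 6),
    min_days: int = 30,
    alpha: float = 0.05,
    all_dates: pd.DatetimeIndex | None = None,
) -> BackgroundModel:
    """Fit the background PM10 model on zero-hotspot (background) days.

    ``series`` holds the background-day rows for one province with columns
    ``date`` and ``pm10_weighted`` (or ``pm10``). For each per-year degrees
    of freedom candidate, an OLS regression of PM10 on a natural cubic
    spline of time (quantile knots, total df = candidate × study years,
    rounded) plus day-of-week indicators is fitted. The minimal adequate
    model is the smallest candidate that no richer candidate improves
    significantly (nested F-test at ``alpha``); its AIC is reported.

    ``all_dates`` (default: every calendar day spanning the series) is the
    grid over which predictions are averaged for ``background_mean``.
    """
    col = "pm10_weighted" if "pm10_weighted" in series.columns else "pm10"
    bg = series.dropna(subset=[col]).copy()
    if len(bg) < min_days:
        raise ValueError(
            f"only {len(bg)} background days with data; need at least {min_days}"
        )
    if province is None:
        province = str(bg["province"].iloc[0]) if "province" in bg.columns else ""

    if all_dates is None:
        all_dates = pd.date_range(bg["date"].min(), bg["date"].max(), freq="D")
    t0 = all_dates[0]
    n_years = len(all_dates) / 365.25
    bg["t"] = (bg["date"] - t0).dt.days.astype(float)
    bg["dow"] = bg["date"].dt.dayofweek
    bg["pm10"] = bg[col].astype(float)

    candidates = sorted(set(df_candidates))
    fits = {}
    for d in candidates:
        total_df = max(3, round(d * n_years))
        fits[d] = (total_df, _fit_one(bg, total_df))

    # minimal adequate model: smallest df whose richer alternatives do not
    # significantly improve the fit
    selected = candidates[-1]
    for i, d in enumerate(candidates):
        improved = False
        for d_big in candidates[i + 1 :]:
            if fits[d_big][0] == fits[d][0]:
                continue
            tab = anova_lm(fits[d][1], fits[d_big][1])
            pval = float(tab["Pr(>F)"].iloc[-1])
            if np.isfinite(pval) and pval < alpha:
                improved = True
                break
        if not improved:
            selected = d
            break

    total_df, fit = fits[selected]
    grid = pd.DataFrame(
        {"t": (all_dates - t0).days.astype(float), "dow": all_dates.dayofweek}
    )
    # predict only over day-of-week levels seen during the fit
    grid = grid[grid["dow"].isin(bg["dow"].unique())]
    fitted_all = fit.predict(grid)
    background_mean = float(fit.resid.mean() + fitted_all.mean())

    params = fit.params
    dow_raw = pd.Series(0.0, index=range(7))
    for name, value in params.items():
        if name.startswith("C(dow)"):
            level = int(name.split("T.")[1].rstrip("]"))
            dow_raw[level] = value
    dow_effects = dow_raw - dow_raw[sorted(bg["dow"].unique())].mean()
    spline_coefficients = params[
        [n for n in params.index if n.startswith("cr(")]
    ].to_numpy()

    return BackgroundModel(
        province=province,
        df_per_year=selected,
        total_df=total_df,
        dow_effects=dow_effects,
        spline_coefficients=spline_coefficients,
        background_mean=background_mean,
        aic=float(fit.aic),
        n_days_fit=len(bg),
        candidate_aic={d: float(f.aic) for d, (_, f) in fits.items()},
        fitted_daily=pd.Series(fitted_all.to_numpy(), index=all_dates[grid.index]),
    )


# ---------------------------------------------------------------------------
# fire-originated PM10


def fire_pm10(
    series: pd.DataFrame,
    model: BackgroundModel,
    calendar: pd.DataFrame,
) -> pd.DataFrame:
    """Fire-originated PM10 on burning days: daily minus background, floored at 0.

    The excess of the population-weighted daily PM10 over the province's
    scalar background concentration; a (pathological) negative excess is
    clamped to zero with a logged warning, and burning days with missing
    PM10 are dropped with a warning.
    """
    burning = calendar[calendar["label"] == LABEL_BURNING]
    merged = burning.merge(
        series[["province", "date", "pm10_weighted"]], on=["province", "date"], how="left"
    )
    missing = merged["pm10_weighted"].isna()
    if missing.any():
        logger.warning(
            "dropping %d burning day(s) with missing PM10 in %s",
            int(missing.sum()),
            model.province,
        )
        merged = merged[~missing]
    excess = merged["pm10_weighted"] - model.background_mean
    clamped = excess < 0
    if clamped.any():
        logger.warning(
            "clamping %d negative fire PM10 value(s) to 0 in %s",
            int(clamped.sum()),
            model.province,
        )
    out = merged[["province", "date"]].copy()
    out["fire_pm10"] = excess.clip(lower=0.0).to_numpy()
    return out.reset_index(drop=True)
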