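"""Synthetic generator for all four pipeline inputs with known ground truth.

Emulates the study design: seasonal PM10 with a weekly cycle, episodic
dry-season fire spikes shared across a region and mirrored by satellite
hotspot counts, district populations, and Poisson hospital-visit counts
whose log-rate rises linearly with fire-originated PM10. The defaults are
calibrated to the study's printed magnitudes (background ≈ 23.2 μg/m³,
fire-originated PM10 ≈ 106.5 μg/m³, a regional burning season of order
30 province-days per year before the burning ban and roughly a third of
that after it) so synthetic outputs are magnitude-plausible; this is a
calibration of the scenario, not a reproduction of the study's data.

Every stochastic draw descends from ``SimScenario.seed`` through named
``numpy`` seed sequences, so each component (and the whole bundle) is
reproducible per seed.
"""

from __future__ import annotations

import calendar as _calendar
import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .burden import beta_from_rr

AGE_COMPONENTS = ("children", "older_adults", "other")


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for the synthetic region.

    Concentrations are μg/m³; visit rates are expected visits per province
    per day in each age component ("all" counts are the sum of the three
    components, so child + older-adult counts never exceed the all-ages
    count by construction). ``beta_true`` is the per-μg/m³ log-rate
    increase applied to every component on burning days.
    """

    n_provinces: int = 8
    n_districts_per_province: int = 4
    n_stations_per_province: int = 2
    years: tuple[int, int] = (2014, 2018)
    background_mean: float = 23.2
    background_province_spread: float = 2.0
    seasonal_amplitude: float = 12.0
    seasonal_peak_doy: int = 45
    dow_offsets: tuple[float, ...] = (2.0, 1.0, 0.5, 0.0, -0.5, -1.0, -2.0)
    fire_season: tuple[int, int] = (1, 4)
    n_fire_days_per_year: int = 30
    fire_days_after_ban_factor: float = 0.35
    ban_year: int = 2017
    fire_pm10_mean: float = 106.5
    fire_pm10_sd: float = 20.0
    hotspot_lambda_fire: float = 40.0
    hotspot_lambda_quiet: float = 1.5
    baseline_visit_rate: dict[str, float] = field(
        default_factory=lambda: {"children": 45.0, "older_adults": 14.0, "other": 33.0}
    )
    beta_true: float = beta_from_rr(1.020)
    noise_sd: float = 5.0
    missing_day_fraction: float = 0.02
    region_origin: tuple[float, float] = (18.0, 98.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_provinces < 1 or self.n_districts_per_province < 1:
            raise ValueError("need at least one province and district")
        if self.fire_pm10_mean < 0 or self.noise_sd < 0:
            raise ValueError("rates and scales must be non-negative")
        if any(v < 0 for v in self.baseline_visit_rate.values()):
            raise ValueError("visit rates must be non-negative")
        if not 1 <= self.fire_season[0] <= self.fire_season[1] <= 12:
            raise ValueError("fire_season must be an ordered month range")

    def replace(self, **kwargs) -> "SimScenario":
        return dataclasses.replace(self, **kwargs)

    @property
    def provinces(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_provinces)]

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(
            f"{self.years[0]}-01-01", f"{self.years[1]}-12-31", freq="D"
        )

    def province_background(self) -> pd.Series:
        """Per-province mean background level (evenly spread around the mean)."""
        s = self.background_province_spread
        offsets = (
            np.linspace(-s, s, self.n_provinces) if self.n_provinces > 1 else [0.0]
        )
        return pd.Series(self.background_mean + np.asarray(offsets), index=self.provinces)


@dataclass
class GroundTruth:
    """Per province-day truth the pipeline is asked to recover.

    ``exposure`` has columns ``province, date, true_background_daily,
    true_background_scalar, true_fire_pm10, true_burning_flag``;
    ``visits`` has ``province, date, age_group, expected_visits,
    expected_excess`` where expected_excess = expected_visits ×
    (1 − exp(−β_true · true_fire_pm10)).
    """

    exposure: pd.DataFrame
    visits: pd.DataFrame

    def expected_excess_total(self, age_group: str = "all") -> float:
        v = self.visits
        return float(
            v.loc[v["age_group"] == age_group, "expected_excess"].sum()
        )


def _seed_for(scenario: SimScenario, stream: str) -> np.random.Generator:
    # crc32 is stable across processes, unlike the salted builtin hash
    ss = np.random.SeedSequence(
        scenario.seed, spawn_key=(zlib.crc32(stream.encode()) % (2**31),)
    )
    return np.random.default_rng(ss)


def _fire_dates(scenario: SimScenario, rng: np.random.Generator) -> pd.DatetimeIndex:
    """Regional fire days: sampled within the fire season, thinned after the ban."""
    chosen = []
    m0, m1 = scenario.fire_season
    for year in range(scenario.years[0], scenario.years[1] + 1):
        n = scenario.n_fire_days_per_year
        if year >= scenario.ban_year:
            n = int(round(n * scenario.fire_days_after_ban_factor))
        last_day = _calendar.monthrange(year, m1)[1]
        season = pd.date_range(
            f"{year}-{m0:02d}-01", f"{year}-{m1:02d}-{last_day:02d}", freq="D"
        )
        n = min(n, len(season))
        picks = rng.choice(len(season), size=n, replace=False)
        chosen.append(season[np.sort(picks)])
    return pd.DatetimeIndex(np.concatenate([c.to_numpy() for c in chosen]))


def _seasonal(scenario: SimScenario, dates: pd.DatetimeIndex) -> np.ndarray:
    phase = (
        2 * np.pi * (dates.dayofyear.to_numpy() - scenario.seasonal_peak_doy) / 365.25
    )
    return scenario.seasonal_amplitude * np.cos(phase)


def ground_truth_exposure(scenario: SimScenario) -> pd.DataFrame:
    """True daily background, fire-originated PM10 and burning flags."""
    rng = _seed_for(scenario, "fire")
    dates = scenario.dates
    fire_dates = _fire_dates(scenario, rng)
    seasonal = _seasonal(scenario, dates)
    dow = np.asarray(scenario.dow_offsets)[dates.dayofweek]
    prov_bg = scenario.province_background()

    frames = []
    for prov in scenario.provinces:
        bg_daily = prov_bg[prov] + seasonal + dow
        is_fire = dates.isin(fire_dates)
        fire = np.zeros(len(dates))
        fire[is_fire] = np.clip(
            rng.normal(scenario.fire_pm10_mean, scenario.fire_pm10_sd, is_fire.sum()),
            0.0,
            None,
        )
        frames.append(
            pd.DataFrame(
                {
                    "province": prov,
                    "date": dates,
                    "true_background_daily": bg_daily,
                    "true_background_scalar": prov_bg[prov]
                    + seasonal.mean()
                    + dow.mean(),
                    "true_fire_pm10": fire,
                    "true_burning_flag": is_fire,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_pm10(
    scenario: SimScenario, truth: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hourly monitor records: daily truth plus hourly noise.

    A ``missing_day_fraction`` of station-days keeps fewer than 18 hourly
    records to exercise the completeness rule. Returns (hourly records,
    ground-truth exposure frame).
    """
    if truth is None:
        truth = ground_truth_exposure(scenario)
    rng = _seed_for(scenario, "pm10")
    hours = np.arange(24)
    frames = []
    for prov in scenario.provinces:
        t = truth[truth["province"] == prov]
        daily = (t["true_background_daily"] + t["true_fire_pm10"]).to_numpy()
        n_days = len(daily)
        for s in range(scenario.n_stations_per_province):
            station = f"{prov}S{s + 1}"
            values = np.clip(
                daily[:, None] + rng.normal(0.0, scenario.noise_sd, (n_days, 24)),
                0.0,
                None,
            )
            keep = np.ones((n_days, 24), dtype=bool)
            gap_days = rng.random(n_days) < scenario.missing_day_fraction
            for di in np.flatnonzero(gap_days):
                n_keep = rng.integers(0, 18)
                drop = rng.choice(24, size=24 - n_keep, replace=False)
                keep[di, drop] = False
            ts = (
                t["date"].to_numpy()[:, None]
                + hours[None, :] * np.timedelta64(1, "h")
            )
            frames.append(
                pd.DataFrame(
                    {
                        "station_id": station,
                        "province": prov,
                        "timestamp": ts[keep],
                        "pm10": values[keep],
                    }
                )
            )
    hourly = pd.concat(frames, ignore_index=True)
    coords = station_locations(scenario).set_index("station_id")
    hourly["lat"] = hourly["station_id"].map(coords["lat"])
    hourly["lon"] = hourly["station_id"].map(coords["lon"])
    return hourly, truth


def station_locations(scenario: SimScenario) -> pd.DataFrame:
    """Deterministic station coordinates: a small cluster per province."""
    lat0, lon0 = scenario.region_origin
    rows = []
    for i, prov in enumerate(scenario.provinces):
        clat, clon = lat0 + 0.5 * (i // 4), lon0 + 0.7 * (i % 4)
        for s in range(scenario.n_stations_per_province):
            rows.append(
                {
                    "station_id": f"{prov}S{s + 1}",
                    "province": prov,
                    "lat": clat + 0.05 * s,
                    "lon": clon - 0.05 * s,
                }
            )
    return pd.DataFrame(rows)


def simulate_population(scenario: SimScenario) -> pd.DataFrame:
    """District populations with centroids near their province's stations."""
    rng = _seed_for(scenario, "population")
    lat0, lon0 = scenario.region_origin
    rows = []
    for i, prov in enumerate(scenario.provinces):
        clat, clon = lat0 + 0.5 * (i // 4), lon0 + 0.7 * (i % 4)
        for d in range(scenario.n_districts_per_province):
            rows.append(
                {
                    "district_id": f"{prov}D{d + 1}",
                    "province": prov,
                    "population": float(np.round(rng.lognormal(np.log(5e4), 0.4))),
                    "lat": clat + 0.1 * np.cos(2 * np.pi * d / scenario.n_districts_per_province),
                    "lon": clon + 0.1 * np.sin(2 * np.pi * d / scenario.n_districts_per_province),
                }
            )
    return pd.DataFrame(rows)


def simulate_hotspots(
    scenario: SimScenario, truth: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Satellite hotspot points: Poisson counts, uniform confidences.

    Daily regional counts are Poisson with mean ``hotspot_lambda_fire`` on
    fire days and ``hotspot_lambda_quiet`` otherwise; detection confidences
    are uniform on [0, 100], so the <20% exclusion removes about a fifth
    of the points.
    """
    if truth is None:
        truth = ground_truth_exposure(scenario)
    rng = _seed_for(scenario, "hotspots")
    flags = (
        truth.groupby("date")["true_burning_flag"].any().sort_index()
    )
    lam = np.where(
        flags.to_numpy(), scenario.hotspot_lambda_fire, scenario.hotspot_lambda_quiet
    )
    counts = rng.poisson(lam)
    lat0, lon0 = scenario.region_origin
    n_total = int(counts.sum())
    dates = np.repeat(flags.index.to_numpy(), counts)
    return pd.DataFrame(
        {
            "date": dates,
            "lat": lat0 + rng.uniform(-0.3, 1.3, n_total),
            "lon": lon0 + rng.uniform(-0.3, 2.4, n_total),
            "confidence": rng.uniform(0.0, 100.0, n_total),
        }
    )


def expected_visits(scenario: SimScenario, truth: pd.DataFrame) -> pd.DataFrame:
    """Expected visit rates and excesses per province-day-age_group (incl. all)."""
    frames = []
    base = truth[["province", "date", "true_fire_pm10", "true_burning_flag"]].copy()
    fire = np.where(base["true_burning_flag"], base["true_fire_pm10"], 0.0)
    rr = np.exp(scenario.beta_true * fire)
    for group in AGE_COMPONENTS:
        lam = scenario.baseline_visit_rate[group] * rr
        f = base[["province", "date"]].copy()
        f["age_group"] = group
        f["expected_visits"] = lam
        f["expected_excess"] = lam * (1.0 - np.exp(-scenario.beta_true * fire))
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    allg = (
        out.groupby(["province", "date"], sort=False)[
            ["expected_visits", "expected_excess"]
        ]
        .sum()
        .reset_index()
    )
    allg["age_group"] = "all"
    return pd.concat([out, allg], ignore_index=True)


def simulate_visits(
    scenario: SimScenario,
    truth: pd.DataFrame | None = None,
    fire_override: np.ndarray | None = None,
) -> pd.DataFrame:
    """Daily visit counts ~ Poisson(baseline × exp(β_true × fire PM10)).

    Counts are drawn by inverting shared uniforms, so regenerating with
    ``fire_override`` (e.g. all zeros for the no-fire counterfactual)
    couples the two draws through common random numbers. The reported
    ``all`` series is the sum of the three component series.
    """
    if truth is None:
        truth = ground_truth_exposure(scenario)
    rng = _seed_for(scenario, "visits")
    base = truth.sort_values(["province", "date"], kind="mergesort").reset_index(drop=True)
    fire = np.where(base["true_burning_flag"], base["true_fire_pm10"], 0.0)
    if fire_override is not None:
        fire = np.asarray(fire_override, dtype=float)
        if fire.shape != (len(base),):
            raise ValueError("fire_override must match the province-day grid")
    rr = np.exp(scenario.beta_true * fire)
    u = rng.random((len(base), len(AGE_COMPONENTS)))
    frames = []
    for j, group in enumerate(AGE_COMPONENTS):
        lam = scenario.baseline_visit_rate[group] * rr
        counts = stats.poisson.ppf(u[:, j], lam).astype(int)
        f = base[["province", "date"]].copy()
        f["age_group"] = group
        f["count"] = counts
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    allg = (
        out.groupby(["province", "date"], sort=False)["count"].sum().reset_index()
    )
    allg["age_group"] = "all"
    # only the reported strata leave the generator; the "other" component is
    # internal and appears solely through the all-ages sum
    out = pd.concat(
        [out[out["age_group"] != "other"], allg], ignore_index=True
    )
    return out.sort_values(
        ["province", "date", "age_group"], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class InputBundle:
    """The four synthetic input tables plus their generating truth."""

    hourly: pd.DataFrame
    hotspots: pd.DataFrame
    population: pd.DataFrame
    visits: pd.DataFrame
    truth: GroundTruth
    scenario: SimScenario


def simulate_inputs(scenario: SimScenario) -> InputBundle:
    """Generate all four inputs coherently from one scenario."""
    truth_exp = ground_truth_exposure(scenario)
    hourly, _ = simulate_pm10(scenario, truth_exp)
    hotspots = simulate_hotspots(scenario, truth_exp)
    population = simulate_population(scenario)
    visits = simulate_visits(scenario, truth_exp)
    truth = GroundTruth(exposure=truth_exp, visits=expected_visits(scenario, truth_exp))
    return InputBundle(hourly, hotspots, population, visits, truth, scenario)


def write_inputs(bundle: InputBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the four inputs as CSV in the exact dialects the readers accept.

    Hotspots are written in the FIRMS archive dialect (``latitude,
    longitude, acq_date, confidence``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "monitors": out_dir / "monitors_hourly.csv",
        "hotspots": out_dir / "hotspots.csv",
        "population": out_dir / "district_population.csv",
        "visits": out_dir / "hospital_visits.csv",
    }
    bundle.hourly.to_csv(paths["monitors"], index=False)
    firms = bundle.hotspots.rename(
        columns={"lat": "latitude", "lon": "longitude", "date": "acq_date"}
    )
    firms["acq_date"] = pd.to_datetime(firms["acq_date"]).dt.strftime("%Y-%m-%d")
    firms.to_csv(paths["hotspots"], index=False)
    bundle.population.to_csv(paths["population"], index=False)
    visits = bundle.visits.copy()
    visits["date"] = visits["date"].dt.strftime("%Y-%m-%d")
    visits.to_csv(paths["visits"], index=False)
    return paths
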