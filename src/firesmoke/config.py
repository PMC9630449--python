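"""Run configuration: every analysis threshold in one versioned, human-readable file.

The sensitivity analysis (lowering the burning-day PM10 cut-point from
100 to 50 μg/m³) is a config change, never a code change.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import yaml

AGE_GROUPS = ("all", "children", "older_adults")

CONFIG_VERSION = 1


@dataclass(frozen=True)
class CRF:
    """Concentration–response function: relative risk per 10 μg/m³ PM10.

    ``beta`` is the implied per-μg/m³ log-relative-risk, ln(rr)/10.
    """

    age_group: str
    rr_per_10: float
    ci_low: float
    ci_high: float
    per: float = 10.0

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {self.age_group!r}")
        if self.rr_per_10 <= 0:
            raise ValueError("relative risk must be positive")
        if not (self.ci_low <= self.rr_per_10 <= self.ci_high):
            raise ValueError("CI must bracket the central relative risk")

    @property
    def beta(self) -> float:
        from .burden import beta_from_rr

        return beta_from_rr(self.rr_per_10, per=self.per)


#: Risks of respiratory hospital visits per 10 μg/m³ PM10 from regional
#: epidemiological studies: all ages 1.020 (1.012–1.028), children <15
#: 1.009 (1.001–1.017), older adults ≥65 1.021 (1.007–1.035, chronic lower
#: respiratory outpatient visits — applied to all-respiratory counts as a
#: documented caveat).
DEFAULT_CRF_TABLE = {
    "all": CRF("all", 1.020, 1.012, 1.028),
    "children": CRF("children", 1.009, 1.001, 1.017),
    "older_adults": CRF("older_adults", 1.021, 1.007, 1.035),
}


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline.

    Parameters
    ----------
    pm10_cutoff
        Daily population-weighted PM10 (μg/m³) a province must exceed for a
        burning day. Default 100; the sensitivity run uses 50.
    hotspot_percentile
        Fraction for the nearest-rank percentile of daily regional hotspot
        counts defining the count threshold (default 0.90).
    hotspot_count_override
        If set, pins the count threshold (e.g. 10) instead of computing the
        percentile.
    confidence_min
        Minimum satellite detection confidence (%) retained; points below
        are excluded (default 20, strict ``< 20`` removed).
    spline_df_candidates
        Per-year degrees of freedom tried for the natural cubic spline of
        time in the background model; the minimal adequate model is chosen
        by nested F-tests with AIC reported.
    spline_df_per_year
        Preferred default within the candidate set (5).
    ban_date
        Date the open-burning ban took force; period membership is by
        calendar year via ``before_years``/``after_years``.
    """

    pm10_cutoff: float = 100.0
    hotspot_percentile: float = 0.90
    hotspot_count_override: int | None = None
    confidence_min: float = 20.0
    spline_df_candidates: tuple[int, ...] = (4, 5, 6)
    spline_df_per_year: int = 5
    ban_date: dt.date = dt.date(2016, 1, 1)
    before_years: tuple[int, ...] = (2014, 2015, 2016)
    after_years: tuple[int, ...] = (2017, 2018)
    rr_table: dict[str, CRF] = field(
        default_factory=lambda: dict(DEFAULT_CRF_TABLE)
    )
    incidence_population_year: int = 2015
    min_valid_hours: int = 18
    min_background_days: int = 30
    rng_seed: int = 0
    version: int = CONFIG_VERSION

    def __post_init__(self) -> None:
        if self.pm10_cutoff <= 0:
            raise ValueError("pm10_cutoff must be > 0")
        if not 0 < self.hotspot_percentile < 1:
            raise ValueError("hotspot_percentile must be in (0, 1)")
        if not self.spline_df_candidates:
            raise ValueError("spline_df_candidates must be non-empty")
        if self.spline_df_per_year not in self.spline_df_candidates:
            raise ValueError("spline_df_per_year must be a candidate")
        if not 0 <= self.confidence_min <= 100:
            raise ValueError("confidence_min must be a percentage")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ban_date"] = self.ban_date.isoformat()
        d["spline_df_candidates"] = list(self.spline_df_candidates)
        d["before_years"] = list(self.before_years)
        d["after_years"] = list(self.after_years)
        d["rr_table"] = {
            g: {
                "rr_per_10": c.rr_per_10,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "per": c.per,
            }
            for g, c in self.rr_table.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "ban_date" in d and isinstance(d["ban_date"], str):
            d["ban_date"] = dt.date.fromisoformat(d["ban_date"])
        for key in ("spline_df_candidates", "before_years", "after_years"):
            if key in d:
                d[key] = tuple(d[key])
        if "rr_table" in d:
            d["rr_table"] = {
                g: c if isinstance(c, CRF) else CRF(age_group=g, **c)
                for g, c in d["rr_table"].items()
            }
        version = d.pop("version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise ValueError(
                f"config version {version} not supported (expected {CONFIG_VERSION})"
            )
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
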