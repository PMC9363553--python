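"""Subnational historical human-development index (SHIHD) construction.

A composite development index on the [0, 1] scale is built from three
components — health (life expectancy at birth), education (a literacy ×
enrollment composite, in percent) and income (GDP per capita in
Geary-Khamis 1990 $) — each mapped onto [0, 1] by a logarithmic goalpost
transform and combined by a geometric mean.  National historical series
(observed roughly every five years) are linearly interpolated to an annual
grid; subnational series, observed only in recent decades, are extended
backwards by scaling the national series with the subnational-to-national
ratio of the earliest jointly observed year.  Finally, each region-year
analysis cell reads the index at a cohort-lagged year: the calendar year in
which the cell's respondents averaged the median childbearing age (19 for
women, 24 for men).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._util import round_half_up

#: goalposts (lower, upper) per raw indicator
LIFE_EXPECTANCY_GOALPOSTS = (20.0, 85.0)
EDUCATION_GOALPOSTS = (0.0, 100.0)
INCOME_GOALPOSTS = (100.0, 46949.0)

COMPONENTS = ("overall", "education", "health", "income")


class DomainError(ValueError):
    """Raw indicator outside the well-defined transform domain."""


class ExtrapolationError(ValueError):
    """Year requested outside the observed span of a series."""


@dataclass
class LagRule:
    """Cohort-lag target ages: the median childbearing ages by sex."""

    target_age_female: float = 19.0
    target_age_male: float = 24.0

    def target_age(self, sex: str) -> float:
        if sex == "female":
            return self.target_age_female
        if sex == "male":
            return self.target_age_male
        raise ValueError(f"unknown sex {sex!r}")


@dataclass
class DevSeries:
    """One development-index time series (year -> value).

    ``level`` is 'national' or 'subnational'; ``component`` one of
    ``COMPONENTS``.  ``values`` is a pandas Series indexed by integer year.
    ``country_id`` identifies the parent country for subnational units.
    """

    unit_id: str
    level: str
    component: str
    values: pd.Series
    country_id: str | None = field(default=None)

    def __post_init__(self):
        self.values = self.values.sort_index()
        if self.values.index.has_duplicates:
            raise ValueError(f"duplicate years in series {self.unit_id}/{self.component}")

    @property
    def years(self) -> np.ndarray:
        return self.values.index.to_numpy()


def transform_life_expectancy(le):
    """Map life expectancy at birth (years) onto [0, 1].

    Logarithmic goalpost transform with bounds 20 and 85; the log makes an
    absolute gain count for more at higher starting levels.
    """
    le = np.asarray(le, dtype=float)
    lo, hi = LIFE_EXPECTANCY_GOALPOSTS
    if np.any(le < lo) or np.any(le > hi - 1.0):
        raise DomainError(f"life expectancy outside [{lo}, {hi - 1.0}]")
    out = (np.log(hi - lo) - np.log(hi - le)) / np.log(hi - lo)
    return out if out.ndim else float(out)


def transform_education(edu):
    """Map the education composite (percent) onto [0, 1] (goalposts 0/100)."""
    edu = np.asarray(edu, dtype=float)
    lo, hi = EDUCATION_GOALPOSTS
    if np.any(edu < lo) or np.any(edu > hi - 1.0):
        raise DomainError(f"education outside [{lo}, {hi - 1.0}]")
    out = (np.log(hi - lo) - np.log(hi - edu)) / np.log(hi - lo)
    return out if out.ndim else float(out)


def transform_income(gdp_pc):
    """Map GDP per capita (G-K 1990 $) onto [0, 1] (goalposts 100/46949)."""
    gdp_pc = np.asarray(gdp_pc, dtype=float)
    lo, hi = INCOME_GOALPOSTS
    if np.any(gdp_pc < lo) or np.any(gdp_pc > hi):
        raise DomainError(f"income outside [{lo}, {hi}]")
    out = (np.log(gdp_pc) - np.log(lo)) / (np.log(hi) - np.log(lo))
    return out if out.ndim else float(out)


def composite_index(edu_idx, health_idx, income_idx):
    """Geometric mean of the three transformed component indices."""
    e, h, i = (np.asarray(v, dtype=float) for v in (edu_idx, health_idx, income_idx))
    for v in (e, h, i):
        if np.any(v < 0) or np.any(v > 1):
            raise DomainError("component index outside [0, 1]")
    out = np.cbrt(e * h * i)
    return out if out.ndim else float(out)


def interpolate_series(series: DevSeries, years: Iterable[int]) -> DevSeries:
    """Linearly interpolate a series onto the requested years.

    Observed years are returned exactly; requests outside the observed
    span raise :class:`ExtrapolationError` — backcasting, not
    extrapolation, is the mechanism for earlier years.
    """
    if len(series.values) < 2:
        raise ValueError("need at least two observations to interpolate")
    years = np.asarray(list(years))
    obs_years = series.years.astype(float)
    if years.min() < obs_years.min() or years.max() > obs_years.max():
        raise ExtrapolationError(
            f"years outside observed span [{obs_years.min():.0f}, {obs_years.max():.0f}] "
            f"for {series.unit_id}/{series.component}"
        )
    vals = np.interp(years.astype(float), obs_years, series.values.to_numpy(dtype=float))
    return DevSeries(
        unit_id=series.unit_id,
        level=series.level,
        component=series.component,
        values=pd.Series(vals, index=years),
        country_id=series.country_id,
    )


def backcast_subnational(sub_earliest: float, nat_earliest: float, nat_hist) -> float:
    """Scale a national historical value by the subnational/national ratio.

    ``sub_earliest`` and ``nat_earliest`` are the subnational and national
    index values of the earliest jointly observed year; ``nat_hist`` is the
    national value in the target historical year.  Assumes the ratio is
    constant through time.
    """
    if nat_earliest <= 0:
        raise ZeroDivisionError("national earliest-year index is zero; ratio undefined")
    nat_hist = np.asarray(nat_hist, dtype=float)
    out = (sub_earliest / nat_earliest) * nat_hist
    return out if out.ndim else float(out)


def lag_year(survey_year: int, mean_age: float, sex: str, rule: LagRule | None = None) -> int:
    """Calendar year in which the cell's respondents averaged the target age.

    Rounded half-up to the nearest integer year.
    """
    rule = rule or LagRule()
    target = rule.target_age(sex)
    if mean_age < target:
        raise ValueError(f"mean age {mean_age} below target age {target}")
    return round_half_up(survey_year - (mean_age - target))


def build_shihd(
    national: Iterable[DevSeries],
    subnational: Iterable[DevSeries],
    years: tuple[int, int] = (1938, 2017),
) -> pd.DataFrame:
    """Assemble annual subnational historical series for every region/component.

    For years at or after a region's earliest subnational observation the
    (interpolated) subnational values pass through; earlier years are
    backcast from the interpolated national series using the earliest-year
    ratio.  Years before the national span starts are left missing (they
    flow to imputation downstream).

    Returns a tidy frame with columns
    ``(level, unit_id, country_id, component, year, value)``.
    """
    nat = {(s.unit_id, s.component): s for s in national}
    rows = []
    year_grid = np.arange(years[0], years[1] + 1)
    for sub in subnational:
        country = sub.country_id or sub.unit_id.split(".")[0]
        key = (country, sub.component)
        if key not in nat:
            raise KeyError(f"no national series for {key}")
        nat_s = nat[key]
        nat_lo, nat_hi = nat_s.years.min(), nat_s.years.max()
        sub_lo, sub_hi = sub.years.min(), sub.years.max()
        # ratio at the earliest jointly covered subnational year
        anchor_year = max(sub_lo, nat_lo)
        sub_anchor = float(sub.values.loc[sub_lo]) if anchor_year == sub_lo else float(
            interpolate_series(sub, [anchor_year]).values.iloc[0]
        )
        nat_anchor = float(interpolate_series(nat_s, [anchor_year]).values.iloc[0])
        for yr in year_grid:
            if yr >= sub_lo:
                if yr <= sub_hi:
                    v = float(interpolate_series(sub, [yr]).values.iloc[0])
                else:
                    v = np.nan  # beyond the subnational series; no forward extrapolation
            elif nat_lo <= yr <= nat_hi:
                nat_v = float(interpolate_series(nat_s, [yr]).values.iloc[0])
                v = backcast_subnational(sub_anchor, nat_anchor, nat_v)
            else:
                v = np.nan  # national coverage gap, reported missing
            rows.append((sub.level, sub.unit_id, country, sub.component, int(yr), v))
    return pd.DataFrame(
        rows, columns=["level", "unit_id", "country_id", "component", "year", "value"]
    )


def series_from_frame(df: pd.DataFrame) -> list[DevSeries]:
    """Parse the tidy CSV schema (level, unit_id, country_id, component, year, value)."""
    out = []
    for (level, unit, country, comp), g in df.groupby(
        ["level", "unit_id", "country_id", "component"], dropna=False
    ):
        g = g.dropna(subset=["value"])
        out.append(
            DevSeries(
                unit_id=str(unit),
                level=str(level),
                component=str(comp),
                values=pd.Series(g["value"].to_numpy(), index=g["year"].astype(int).to_numpy()),
                country_id=None if pd.isna(country) else str(country),
            )
        )
    return out


def frame_from_series(series: Iterable[DevSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for yr, v in s.values.items():
            rows.append((s.level, s.unit_id, s.country_id, s.component, int(yr), float(v)))
    return pd.DataFrame(
        rows, columns=["level", "unit_id", "country_id", "component", "year", "value"]
    )


def lookup(shihd: pd.DataFrame, unit_id: str, component: str, year: int) -> float:
    """Read one value from a tidy SHIHD frame; NaN when absent."""
    m = shihd[
        (shihd["unit_id"] == unit_id)
        & (shihd["component"] == component)
        & (shihd["year"] == year)
    ]
    if m.empty:
        return float("nan")
    return float(m["value"].iloc[0])
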