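"""Synthetic survey-microdata and covariate-series generator.

Emulates the statistical structure of pooled DHS-style data for testing
with known ground truth: countries containing subnational regions, repeated
survey rounds, individual parity/preference/marital variables, a latent
development trajectory per region that drives type-specific childlessness
probabilities (involuntary decreasing in development, voluntary and
circumstantial increasing), plus national/subnational development series
with exactly constant subnational-to-national ratios, HIV series,
population counts, and controllable missingness in aggregate covariates.

Latent childlessness types are assigned per individual by a categorical
draw whose probabilities are logit-linear in the region's development
level at the survey year.  Questionnaire variables are then generated
consistently with the drawn type, so the decision-tree classifier can
recover every latent type exactly.

Default levels are calibrated to the magnitudes observed in pooled
sub-Saharan African survey data: type prevalences of a few percent at a
development level around 0.18, development indices in the 0.05-0.45 band,
and sex ratios near 100 women per 100 men.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import typology
from ._util import substream
from .devindex import DevSeries


class ConfigurationError(ValueError):
    pass


@dataclass
class TypeLink:
    """Logit-linear links from development to type probabilities.

    P(type | dev) = expit(intercept + slope * dev); the undecided share is
    a small fixed fraction independent of development.
    """

    involuntary: tuple[float, float] = (-3.28, -5.0)
    voluntary: tuple[float, float] = (-7.54, 5.0)
    circumstantial: tuple[float, float] = (-5.96, 5.0)
    undecided_frac: float = 0.002

    def probabilities(self, dev: np.ndarray) -> np.ndarray:
        """(n, 4) array: involuntary, voluntary, circumstantial, undecided."""
        dev = np.asarray(dev, dtype=float)
        p = np.column_stack(
            [
                expit(self.involuntary[0] + self.involuntary[1] * dev),
                expit(self.voluntary[0] + self.voluntary[1] * dev),
                expit(self.circumstantial[0] + self.circumstantial[1] * dev),
                np.full(dev.shape, self.undecided_frac),
            ]
        )
        return p


@dataclass
class DevTrajectory:
    """Per-country linear development path with per-region ratio scaling.

    National overall index: start + annual_increment * (year - 1990),
    starts drawn uniformly from ``start_range`` per country.  Each region's
    path is its country's path times a region ratio drawn from
    ``region_ratio_range`` — constant through time, so the ratio-backcasting
    assumption holds exactly in the generator.
    """

    start_range: tuple[float, float] = (0.10, 0.25)
    annual_increment: float = 0.005
    region_ratio_range: tuple[float, float] = (0.75, 1.25)
    base_year: int = 1990


@dataclass
class SimConfig:
    n_countries: int = 5
    regions_per_country: int = 4
    survey_years: Sequence[int] = (1995, 2005, 2015)
    respondents_per_region_survey: int = 350
    sex: str = "female"
    interview_age_bounds: tuple[int, int] = (15, 59)
    dev_trajectory: DevTrajectory = field(default_factory=DevTrajectory)
    type_link: TypeLink = field(default_factory=TypeLink)
    missing_rate: float = 0.0
    seed: int = 20260101

    def __post_init__(self):
        if min(self.n_countries, self.regions_per_country,
               self.respondents_per_region_survey) <= 0:
            raise ConfigurationError("counts must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Generator state stored alongside simulated data; never an analysis input."""

    region_dev: pd.DataFrame  # country_id, region_id, year, dev
    latent_type: pd.Series  # per respondent_id; 'parent' for non-childless
    link: TypeLink
    region_ratio: pd.DataFrame | None = None  # constant sub/national ratios


def _region_paths(config: SimConfig, years: np.ndarray) -> pd.DataFrame:
    """Deterministic per-region overall development values on a year grid."""
    rng = substream(config.seed, "dev_paths")
    tr = config.dev_trajectory
    rows = []
    for c in range(config.n_countries):
        start = rng.uniform(*tr.start_range)
        ratios = rng.uniform(*tr.region_ratio_range, size=config.regions_per_country)
        for r in range(config.regions_per_country):
            nat = start + tr.annual_increment * (years - tr.base_year)
            dev = np.clip(ratios[r] * nat, 0.01, 0.99)
            for yr, d, n in zip(years, dev, nat):
                rows.append((f"C{c:02d}", f"C{c:02d}.R{r:02d}", int(yr), float(d),
                             float(np.clip(n, 0.01, 0.99)), float(ratios[r])))
    return pd.DataFrame(
        rows, columns=["country_id", "region_id", "year", "dev", "national_dev", "ratio"]
    )


def _check_links(config: SimConfig, paths: pd.DataFrame) -> None:
    p = config.type_link.probabilities(paths["dev"].to_numpy())
    total = p.sum(axis=1)
    bad = total >= 1.0
    if bad.any():
        i = int(np.argmax(bad))
        raise ConfigurationError(
            "type probabilities exceed 1 for region-year "
            f"{paths['region_id'].iloc[i]}/{paths['year'].iloc[i]}"
        )


def simulate_microdata(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw DHS-like individual records plus the generating ground truth."""
    years = np.asarray(sorted(set(config.survey_years)), dtype=int)
    paths = _region_paths(config, years)
    _check_links(config, paths)
    rng = substream(config.seed, "microdata")

    lo, hi = config.interview_age_bounds
    frames = []
    latent = []
    rid = 0
    for _, cell in paths.iterrows():
        n = config.respondents_per_region_survey
        p_types = config.type_link.probabilities(np.array([cell["dev"]]))[0]
        probs = np.append(p_types, 1.0 - p_types.sum())  # last = parent
        draw = rng.choice(5, size=n, p=probs)
        lab = np.array(
            [typology.INVOLUNTARY, typology.VOLUNTARY, typology.CIRCUMSTANTIAL,
             typology.UNDECIDED, "parent"], dtype=object
        )[draw]
        age = np.floor(rng.uniform(lo, hi + 1, size=n))
        childless = lab != "parent"
        ceb = np.where(
            childless, 0, 1 + rng.poisson(4.0, size=n)  # truncated Poisson, >=1
        )
        pref = np.empty(n, dtype=object)
        marital = np.empty(n, dtype=object)
        ideal = np.empty(n, dtype=object)
        # parents: mostly done childbearing, in union
        parent = lab == "parent"
        pref[parent] = rng.choice(
            ["wants_no_children", "wants_children"], p=[0.8, 0.2], size=parent.sum()
        )
        marital[parent] = rng.choice(
            ["in_union", "divorced_separated", "widowed", "never_married"],
            p=[0.85, 0.08, 0.06, 0.01], size=parent.sum(),
        )
        ideal[parent] = rng.integers(2, 8, size=parent.sum()).astype(object)

        inv = lab == typology.INVOLUNTARY
        n_inv = inv.sum()
        infecund = rng.random(n_inv) < 0.6
        pref[inv] = np.where(infecund, "declared_infecund", "wants_children")
        marital[inv] = "in_union"
        ideal[inv] = rng.integers(1, 6, size=n_inv).astype(object)

        vol = lab == typology.VOLUNTARY
        pref[vol] = "wants_no_children"
        marital[vol] = rng.choice(
            ["in_union", "never_married"], p=[0.6, 0.4], size=vol.sum()
        )
        ideal[vol] = 0

        cir = lab == typology.CIRCUMSTANTIAL
        pref[cir] = "wants_children"
        marital[cir] = rng.choice(
            ["never_married", "divorced_separated", "widowed"],
            p=[0.5, 0.3, 0.2], size=cir.sum(),
        )
        ideal[cir] = rng.integers(1, 6, size=cir.sum()).astype(object)

        und = lab == typology.UNDECIDED
        pref[und] = "dont_know"
        marital[und] = rng.choice(
            ["in_union", "never_married"], p=[0.5, 0.5], size=und.sum()
        )
        ideal[und] = "non_numeric"

        in_union = marital == "in_union"
        poly = np.where(
            in_union,
            np.where(rng.random(n) < 0.25, "yes", "no"),
            "not_applicable",
        )
        dev = float(cell["dev"])
        urban = np.where(
            rng.random(n) < np.clip(0.15 + 0.8 * dev, 0, 1), "urban", "rural"
        )
        # postponement ages rise with development
        afs = np.round(rng.normal(16.5 + 4 * dev, 1.5, size=n), 1)
        afu = np.round(afs + np.abs(rng.normal(2.0, 1.0, size=n)), 1)
        afb = np.where(childless, np.nan,
                       np.round(afu + np.abs(rng.normal(1.5, 1.0, size=n)), 1))
        afu = np.where(marital == "never_married", np.nan, afu)

        frames.append(pd.DataFrame({
            "respondent_id": np.arange(rid, rid + n),
            "sex": config.sex,
            "survey_id": f"{cell['country_id']}-{cell['year']}",
            "country_id": cell["country_id"],
            "region_id": cell["region_id"],
            "survey_year": int(cell["year"]),
            "age": age.astype(int),
            "children_ever_born": ceb.astype(int),
            "currently_pregnant": "no",
            "fertility_preference": pref,
            "ideal_children": ideal,
            "marital_status": marital,
            "polygynous": poly,
            "age_first_sex": afs,
            "age_first_union": afu,
            "age_first_birth": afb,
            "urban": urban,
        }))
        latent.append(pd.Series(lab, index=np.arange(rid, rid + n)))
        rid += n

    micro = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        region_dev=paths[["country_id", "region_id", "year", "dev"]].copy(),
        latent_type=pd.concat(latent).rename("latent_type"),
        link=config.type_link,
        region_ratio=paths[["country_id", "region_id", "ratio"]].drop_duplicates(),
    )
    return micro, truth


def simulate_dev_series(
    config: SimConfig,
    national_years: Sequence[int] | None = None,
    subnational_span: tuple[int, int] = (1990, 2017),
) -> tuple[list[DevSeries], list[DevSeries], GroundTruth]:
    """National series on a 5-year grid plus annual subnational series.

    Subnational/national ratios are constant through time by construction,
    so ratio backcasting recovers the generator's truth exactly.  Component
    series (education, health, income) are the overall path times fixed
    multipliers whose product is one, keeping the overall index the
    geometric mean of its components.
    """
    if national_years is None:
        national_years = np.arange(1950, 2016, 5)
    national_years = np.asarray(sorted(national_years), dtype=int)
    sub_years = np.arange(subnational_span[0], subnational_span[1] + 1)
    all_years = np.union1d(national_years, sub_years)
    paths = _region_paths(config, all_years)

    # component multipliers (education, health, income), geometric mean 1
    raw = np.array([0.68, 0.83, 1.99])
    mult = dict(zip(["education", "health", "income"], raw / np.cbrt(raw.prod())))
    mult["overall"] = 1.0

    national, subnational = [], []
    truth_rows = []
    nat_paths = paths.drop_duplicates(["country_id", "year"])
    for comp, m in mult.items():
        for cid, g in nat_paths.groupby("country_id"):
            g = g.set_index("year")
            vals = np.clip(g.loc[national_years, "national_dev"].to_numpy() * m, 0.005, 0.995)
            national.append(DevSeries(
                unit_id=cid, level="national", component=comp,
                values=pd.Series(vals, index=national_years), country_id=cid,
            ))
        for (cid, rgn), g in paths.groupby(["country_id", "region_id"]):
            g = g.set_index("year")
            ratio = float(g["ratio"].iloc[0])
            sub_vals = np.clip(g.loc[sub_years, "national_dev"].to_numpy() * ratio * m,
                               0.005, 0.995)
            subnational.append(DevSeries(
                unit_id=rgn, level="subnational", component=comp,
                values=pd.Series(sub_vals, index=sub_years), country_id=cid,
            ))
            for yr in all_years:
                truth_rows.append((cid, rgn, comp, int(yr),
                                   float(np.clip(g.loc[yr, "national_dev"] * ratio * m,
                                                 0.005, 0.995))))
    truth = GroundTruth(
        region_dev=pd.DataFrame(
            truth_rows, columns=["country_id", "region_id", "component", "year", "dev"]
        ),
        latent_type=pd.Series(dtype=object),
        link=config.type_link,
        region_ratio=paths[["country_id", "region_id", "ratio"]].drop_duplicates(),
    )
    return national, subnational, truth


def simulate_hiv_series(config: SimConfig, span: tuple[int, int] = (1990, 2017)):
    """National annual HIV prevalence (%) per country plus subnational anchors.

    A logistic epidemic curve per country with peak prevalence between 0.5
    and 8 percent; each region gets one anchor observation in 2010 at a
    region-specific multiple of the national level.
    """
    rng = substream(config.seed, "hiv")
    years = np.arange(span[0], span[1] + 1)
    national = {}
    anchors = {}
    for c in range(config.n_countries):
        cid = f"C{c:02d}"
        peak = rng.uniform(0.5, 8.0)
        vals = peak * expit((years - 2005) / 5.0)
        national[cid] = pd.Series(vals, index=years)
        for r in range(config.regions_per_country):
            rgn = f"{cid}.R{r:02d}"
            ratio = rng.uniform(0.5, 1.5)
            anchors[rgn] = (2010, float(ratio * national[cid].loc[2010]))
    return national, anchors


def simulate_pop_counts(config: SimConfig, span: tuple[int, int] = (1950, 2017)) -> pd.DataFrame:
    """Sex-specific 15-24 population counts per country-year."""
    rng = substream(config.seed, "pop")
    years = np.arange(span[0], span[1] + 1)
    rows = []
    for c in range(config.n_countries):
        cid = f"C{c:02d}"
        base = rng.uniform(2e5, 2e6)
        growth = rng.uniform(0.01, 0.03)
        ratio = rng.normal(1.0, 0.03, size=len(years))
        for yr, rt in zip(years, ratio):
            men = base * np.exp(growth * (yr - span[0]))
            rows.append((cid, int(yr), float(men * rt), float(men)))
    return pd.DataFrame(rows, columns=["country_id", "year", "women_15_24", "men_15_24"])


def simulate_model_panel(
    n_countries: int = 200,
    regions_per_country: int = 10,
    n_years: int = 4,
    gamma: dict | None = None,
    re_sd: tuple[float, float] = (0.01, 0.005),
    re_corr: float = 0.3,
    resid_sd: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a region-year panel directly from the hierarchical model.

    The outcome is built from the same fixed-effect structure the models
    module fits — intercept, orthogonal time polynomials, orthogonal
    development polynomials — plus a correlated country-level random
    intercept and random slope on the first development term, and i.i.d.
    Gaussian noise.  The returned truth dictionary holds the generating
    coefficients *with respect to the orthonormal bases computed on the
    generated panel*, which is exactly the basis the fitting code rebuilds.

    ``re_sd`` gives the random-intercept and random-slope standard
    deviations on the outcome scale: the slope deviation multiplies the
    *unit-variance* (standardised) first development term, so a slope sd
    of 0.05 perturbs the outcome by about ±0.05 per standard deviation of
    development.  On the unit-norm basis the fitting code uses, the
    implied slope variance is ``re_sd[1]**2 * n``.
    """
    from .models import ortho_poly  # deferred: avoid cycle at import time

    gamma = dict(gamma or {})
    gamma.setdefault("intercept", 0.035)
    gamma.setdefault("time_op1", -0.05)
    gamma.setdefault("time_op2", 0.05)
    gamma.setdefault("shihd_op1", 0.4)
    gamma.setdefault("shihd_op2", 0.4)
    rng = substream(seed, "model_panel")

    n = n_countries * regions_per_country * n_years
    country = np.repeat(np.arange(n_countries), regions_per_country * n_years)
    region = np.repeat(np.arange(n_countries * regions_per_country), n_years)
    year = np.tile(np.arange(n_years), n_countries * regions_per_country)

    base = rng.uniform(0.05, 0.40, size=n_countries * regions_per_country)
    shihd = np.clip(base[region] + 0.01 * year + rng.normal(0, 0.01, n), 0.01, 0.99)
    time = year * 5.0

    sb = ortho_poly(shihd, 2)
    tb = ortho_poly(time, 2)
    cov = np.array(
        [[re_sd[0] ** 2, re_corr * re_sd[0] * re_sd[1]],
         [re_corr * re_sd[0] * re_sd[1], re_sd[1] ** 2]]
    )
    u = rng.multivariate_normal(np.zeros(2), cov, size=n_countries)
    y = (
        gamma["intercept"]
        + gamma["time_op1"] * tb.columns[:, 0]
        + gamma["time_op2"] * tb.columns[:, 1]
        + gamma["shihd_op1"] * sb.columns[:, 0]
        + gamma["shihd_op2"] * sb.columns[:, 1]
        + u[country, 0]
        + u[country, 1] * (sb.columns[:, 0] * np.sqrt(n))
        + rng.normal(0, resid_sd, size=n)
    )
    panel = pd.DataFrame({
        "country_id": [f"C{c:03d}" for c in country],
        "region_id": [f"R{r:04d}" for r in region],
        "survey_year": 2000 + year * 5,
        "sex": "female",
        "time": time,
        "shihd_overall": shihd,
        "childless_pct": 100.0 * y,
    })
    truth = {
        "gamma": gamma,
        "re_sd": re_sd,
        "re_corr": re_corr,
        "resid_sd": resid_sd,
        "random_effects": u,
    }
    return panel, truth


def inject_missingness(
    panel: pd.DataFrame,
    rate: float,
    columns: Sequence[str],
    mechanism: str = "MCAR",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank ``round(rate * n)`` cells per targeted column; return panel + mask.

    MCAR picks cells uniformly; MAR-on-year picks them with probability
    increasing in the survey year (weighted sampling without replacement),
    emulating questions absent from older survey rounds.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = substream(seed, "missingness")
    out = panel.copy()
    mask = pd.DataFrame(False, index=panel.index, columns=list(columns))
    n = len(panel)
    k = int(round(rate * n))
    for col in columns:
        if k == 0:
            continue
        if mechanism == "MCAR":
            idx = rng.choice(n, size=k, replace=False)
        elif mechanism == "MAR-on-year":
            yr = panel["survey_year"].to_numpy(dtype=float)
            z = (yr - yr.mean()) / (yr.std() or 1.0)
            w = np.exp(1.5 * z)
            idx = rng.choice(n, size=k, replace=False, p=w / w.sum())
        else:
            raise ValueError(f"unknown mechanism {mechanism!r}")
        pos = panel.index[idx]
        out.loc[pos, col] = np.nan
        mask.loc[pos, col] = True
    return out, mask
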