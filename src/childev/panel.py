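"""Aggregation of classified microdata to region-year analysis cells.

The unit of analysis is a (subnational region, survey year, sex) cell.
Respondents aged 40+ with a usable parity variable enter; percentages are
unweighted (no age adjustment, no country-size weights).  Development,
HIV prevalence and the marriage-market sex ratio are attached at the
cohort-lagged year — the calendar year in which the cell's respondents
averaged the median childbearing age.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import covariates, typology
from .devindex import COMPONENTS, LagRule, lag_year

SHIHD_COLUMNS = {c: f"shihd_{c}" for c in COMPONENTS}

PANEL_COLUMNS = [
    "country_id", "region_id", "survey_year", "sex", "n", "mean_age",
    "childless_pct", "involuntary_pct", "voluntary_pct",
    "circumstantial_pct", "undecided_pct", "urban_pct",
    "never_married_pct", "in_union_pct", "divorced_separated_pct",
    "widowed_pct", "mean_age_first_sex", "mean_age_first_union",
    "mean_age_first_birth", "polygyny_pct", "polygyny_uncertain",
    "hiv_pct", "women_per_100_men",
    "shihd_overall", "shihd_education", "shihd_health", "shihd_income",
    "time",
]


def aggregate(
    classified: pd.DataFrame,
    sex: str | None = None,
    postponement_sample: str = "40plus",
) -> pd.DataFrame:
    """One row per (region, survey year) cell of 40+ respondents.

    ``classified`` is microdata carrying the ``childlessness_type`` column
    from :func:`childev.typology.classify`.  Respondents flagged
    ineligible (under 40 or missing parity) are excluded from numerator
    and denominator alike.  ``postponement_sample`` chooses whether the
    mean ages at first sex/union/birth are taken over the 40+ analysis
    sample (default, consistent with the unit of analysis) or over all
    interviewed respondents in the cell (``"all"``).
    """
    if postponement_sample not in ("40plus", "all"):
        raise ValueError("postponement_sample must be '40plus' or 'all'")
    full = classified if sex is None else classified[classified["sex"] == sex]
    df = full[full["childlessness_type"] != typology.INELIGIBLE]
    post_groups = None
    if postponement_sample == "all":
        post_groups = dict(iter(full.groupby(
            ["country_id", "region_id", "survey_year", "sex"], sort=True
        )))
    rows = []
    for (country, region, year, sx), g in df.groupby(
        ["country_id", "region_id", "survey_year", "sex"], sort=True
    ):
        post_g = post_groups.get((country, region, year, sx), g) \
            if post_groups is not None else g
        n = len(g)
        types = g["childlessness_type"]
        pct = {
            f"{t}_pct": 100.0 * (types == t).sum() / n for t in typology.TYPES
        }
        childless = 100.0 * (types != typology.NOT_CHILDLESS).sum() / n
        poly_pct, poly_unc = covariates.polygyny_prevalence(g)
        row = {
            "country_id": country,
            "region_id": region,
            "survey_year": int(year),
            "sex": sx,
            "n": n,
            "mean_age": float(pd.to_numeric(g["age"]).mean()),
            "childless_pct": childless,
            **pct,
            "urban_pct": 100.0 * (g["urban"] == "urban").sum() / n,
            **covariates.marital_shares(g),
            **covariates.postponement_ages(post_g),
            "polygyny_pct": poly_pct,
            "polygyny_uncertain": poly_unc,
        }
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    # secular time variable, relative to this (sex-specific) sample's minimum
    out["time"] = out["survey_year"] - out["survey_year"].min()
    return out


def attach_lagged(
    cells: pd.DataFrame,
    shihd: pd.DataFrame | None = None,
    hiv: dict[str, pd.Series] | None = None,
    pop_counts: pd.DataFrame | None = None,
    rule: LagRule | None = None,
) -> pd.DataFrame:
    """Join cohort-lagged development, HIV and sex-ratio columns onto cells.

    ``shihd`` is the tidy frame from :func:`childev.devindex.build_shihd`;
    ``hiv`` maps region_id -> annual prevalence Series (falling back to the
    country_id key when a region is absent); ``pop_counts`` has columns
    (country_id, year, women_15_24, men_15_24).  Missing series values
    remain missing and flow to imputation.
    """
    rule = rule or LagRule()
    out = cells.copy()
    out["lag_year"] = [
        lag_year(int(r.survey_year), float(r.mean_age), str(r.sex), rule)
        for r in out.itertuples()
    ]

    if shihd is not None:
        idx = shihd.set_index(["unit_id", "component", "year"])["value"]
        for comp, col in SHIHD_COLUMNS.items():
            vals = []
            for r in out.itertuples():
                key = (r.region_id, comp, int(r.lag_year))
                vals.append(float(idx[key]) if key in idx.index else np.nan)
            out[col] = vals

    if hiv is not None:
        vals = []
        for r in out.itertuples():
            series = hiv.get(r.region_id, hiv.get(r.country_id))
            if series is not None and int(r.lag_year) in series.index:
                vals.append(float(series.loc[int(r.lag_year)]))
            else:
                vals.append(np.nan)
        out["hiv_pct"] = vals

    if pop_counts is not None:
        idx = pop_counts.set_index(["country_id", "year"])
        vals = []
        for r in out.itertuples():
            key = (r.country_id, int(r.lag_year))
            if key in idx.index:
                rec = idx.loc[key]
                vals.append(covariates.sex_ratio(
                    float(rec["women_15_24"]), float(rec["men_15_24"])
                ))
            else:
                vals.append(np.nan)
        out["women_per_100_men"] = vals

    return out
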