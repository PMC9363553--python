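"""Non-development region-year covariates.

HIV prevalence histories are reconstructed subnationally by ratio scaling
of national series, with an exponential epidemic back-projection between
1970 and 1990 (prevalence set to zero before 1970, when the virus had not
yet been identified).  Marriage-market sex balance is the number of women
per 100 men aged 15-24 (national level only).  Polygyny prevalence treats
respondents not in a union as monogynous and falls back to the male cell
when the female cell is missing or mostly uncertain.  Marital-status
shares and mean ages at first sex/union/birth are simple cell aggregates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: default anchor prevalence (percentage points) at the 1970 epidemic origin;
#: an exponential cannot start at literal zero, so a small floor stands in.
HIV_EPSILON = 0.001

HIV_ZERO_BEFORE = 1970
HIV_SPLICE_YEAR = 1990


def sex_ratio(women_15_24: float, men_15_24: float) -> float:
    """Women per 100 men in the 15-24 age group."""
    if men_15_24 <= 0:
        raise ZeroDivisionError("male population count must be positive")
    return 100.0 * women_15_24 / men_15_24


def backcast_hiv(
    national: pd.Series,
    subnational_anchor: tuple[int, float] | None = None,
    span: tuple[int, int] = (1960, 2017),
    eps: float = HIV_EPSILON,
) -> pd.Series:
    """Annual subnational HIV prevalence (%) over ``span``.

    For years covered by the national series the subnational value is the
    anchor-year subnational/national ratio times the national value (ratio
    1 when no subnational anchor exists, i.e. national values are used for
    all regions).  Between 1970 and the first national year the series
    follows exponential growth v(t) = v(1990) * exp(r (t - 1990)) with r
    chosen so v(1970) = ``eps``; before 1970 prevalence is zero.
    """
    national = national.sort_index()
    if HIV_SPLICE_YEAR not in national.index:
        raise ValueError("national HIV series must cover 1990")
    if subnational_anchor is None:
        ratio = 1.0
    else:
        anchor_year, anchor_value = subnational_anchor
        nearest = national.index[np.argmin(np.abs(national.index.to_numpy() - anchor_year))]
        nat_at_anchor = float(national.loc[nearest])
        if nat_at_anchor <= 0:
            ratio = 1.0  # ratio undefined; fall back to national series
        else:
            ratio = anchor_value / nat_at_anchor

    years = np.arange(span[0], span[1] + 1)
    out = pd.Series(0.0, index=years)
    nat_lo = int(national.index.min())
    covered = (years >= nat_lo) & (years <= int(national.index.max()))
    interp = np.interp(
        years[covered], national.index.to_numpy(dtype=float),
        national.to_numpy(dtype=float),
    )
    out.loc[years[covered]] = ratio * interp

    v_splice = ratio * float(national.loc[HIV_SPLICE_YEAR])
    pre = (years >= HIV_ZERO_BEFORE) & (years < nat_lo)
    if v_splice > eps:
        r = np.log(v_splice / eps) / (HIV_SPLICE_YEAR - HIV_ZERO_BEFORE)
        out.loc[years[pre]] = v_splice * np.exp(r * (years[pre] - HIV_SPLICE_YEAR))
    else:
        out.loc[years[pre]] = v_splice  # flat: splice level already at/below the floor
    return out


def polygyny_prevalence(records: pd.DataFrame) -> tuple[float, bool]:
    """Cell polygyny prevalence (%) and an uncertainty flag.

    Respondents not in a union count as monogynous.  In-union respondents
    with a yes/no flag enter directly; the cell is *uncertain* when more
    than half of in-union respondents lack a usable flag, and *missing*
    (NaN) when no in-union respondent has one at all.
    """
    marital = records["marital_status"].astype("object")
    flag = records["polygynous"].astype("object")
    in_union = marital == "in_union"
    usable = in_union & flag.isin(["yes", "no"])
    not_in_union = marital.isin(["never_married", "divorced_separated", "widowed"])
    if in_union.sum() > 0 and usable.sum() == 0:
        return float("nan"), True
    n = usable.sum() + not_in_union.sum()
    if n == 0:
        return float("nan"), True
    pct = 100.0 * (usable & (flag == "yes")).sum() / n
    uncertain = in_union.sum() > 0 and (usable.sum() / in_union.sum()) < 0.5
    return float(pct), bool(uncertain)


def impute_polygyny_from_male(
    female_panel: pd.DataFrame, male_panel: pd.DataFrame
) -> pd.DataFrame:
    """Replace missing/mostly-uncertain female cell values with the male cell.

    Never overwrites a valid (non-missing, certain) female value; cells
    without a matching male value stay missing and flow to imputation.
    """
    out = female_panel.copy()
    male = male_panel.set_index(["region_id", "survey_year"])["polygyny_pct"]
    needs = out["polygyny_pct"].isna() | out.get(
        "polygyny_uncertain", pd.Series(False, index=out.index)
    ).fillna(False).astype(bool)
    for i in out.index[needs]:
        key = (out.at[i, "region_id"], out.at[i, "survey_year"])
        if key in male.index and not pd.isna(male.loc[key]):
            out.at[i, "polygyny_pct"] = float(male.loc[key])
    return out


MARITAL_SHARE_COLUMNS = {
    "never_married": "never_married_pct",
    "in_union": "in_union_pct",
    "divorced_separated": "divorced_separated_pct",
    "widowed": "widowed_pct",
}


def marital_shares(records: pd.DataFrame) -> dict[str, float]:
    """Four marital-status shares summing to 100% of non-missing responses."""
    status = records["marital_status"].astype("object")
    valid = status.isin(list(MARITAL_SHARE_COLUMNS))
    n = valid.sum()
    out = {}
    for cat, col in MARITAL_SHARE_COLUMNS.items():
        out[col] = 100.0 * (status == cat).sum() / n if n else float("nan")
    return out


def postponement_ages(records: pd.DataFrame) -> dict[str, float]:
    """Mean ages at first sex, union (cohabitation proxies included) and birth."""
    out = {}
    for src, col in [
        ("age_first_sex", "mean_age_first_sex"),
        ("age_first_union", "mean_age_first_union"),
        ("age_first_birth", "mean_age_first_birth"),
    ]:
        vals = pd.to_numeric(records[src], errors="coerce") if src in records else None
        if src == "age_first_union" and (vals is None or not vals.notna().any()):
            # surveys without a marriage-age question: cohabitation age proxies
            if "age_first_cohabitation" in records:
                vals = pd.to_numeric(records["age_first_cohabitation"], errors="coerce")
        out[col] = float(vals.mean()) if vals is not None and vals.notna().any() else float("nan")
    return out
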