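"""Childlessness status and type classification.

Permanent childlessness is defined as having borne no live children by the
time of interview at age 40 or older.  Eligible childless respondents are
assigned exactly one of four types from their questionnaire responses:

* **involuntary** — declared infecund, or wanting children while in a
  union yet never having achieved a live birth;
* **voluntary** — stating a preference for no children;
* **circumstantial** — fecund and wanting children but currently
  unpartnered (never married, divorced/separated or widowed);
* **undecided** — unable to state a preference and a numeric ideal family
  size; retained in overall childlessness but excluded from type-specific
  outcomes.

Fecundity is checked first, then the stated preference, then marital
status; classification of a record depends only on that record.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# classification outcomes
NOT_CHILDLESS = "not_childless"
INVOLUNTARY = "involuntary"
VOLUNTARY = "voluntary"
CIRCUMSTANTIAL = "circumstantial"
UNDECIDED = "undecided"
INELIGIBLE = "ineligible"

TYPES = (INVOLUNTARY, VOLUNTARY, CIRCUMSTANTIAL, UNDECIDED)
ALL_OUTCOMES = (NOT_CHILDLESS,) + TYPES + (INELIGIBLE,)

UNPARTNERED = ("never_married", "divorced_separated", "widowed")

#: minimum interview age for the permanent-childlessness definition
ELIGIBILITY_AGE = 40

MICRODATA_COLUMNS = [
    "respondent_id", "sex", "survey_id", "country_id", "region_id",
    "survey_year", "age", "children_ever_born", "currently_pregnant",
    "fertility_preference", "ideal_children", "marital_status",
    "polygynous", "age_first_sex", "age_first_union", "age_first_birth",
    "urban",
]


def classify(df: pd.DataFrame, min_age: int = ELIGIBILITY_AGE) -> pd.DataFrame:
    """Classify every respondent; returns the frame plus two columns.

    ``childlessness_type`` holds one of :data:`ALL_OUTCOMES`;
    ``reason_code`` explains ineligible/undecided routings.  Records with
    missing parity cannot be classified and are routed to ``ineligible``
    with reason ``missing_parity`` (excluded from cells downstream).
    """
    out = df.copy()
    age = pd.to_numeric(out["age"], errors="coerce")
    ceb = pd.to_numeric(out["children_ever_born"], errors="coerce")
    def _as_str(col, fill):
        s = out[col].astype("object")
        return s.where(s.notna(), fill)

    preg = _as_str("currently_pregnant", "unknown")
    pref = _as_str("fertility_preference", "missing")
    marital = _as_str("marital_status", "missing")
    ideal = _as_str("ideal_children", "missing")
    ideal_num = pd.to_numeric(ideal, errors="coerce")

    eligible = age >= min_age
    parity_ok = ceb.notna()
    childless = eligible & parity_ok & (ceb == 0) & (preg != "yes")

    unpartnered = marital.isin(UNPARTNERED)
    in_union = marital == "in_union"

    # decision tree, first matching branch wins
    conds = [
        ~parity_ok,
        ~eligible,
        ~childless,
        pref == "declared_infecund",
        pref == "wants_no_children",
        (pref == "wants_children") & in_union,
        (pref == "wants_children") & unpartnered,
        pref == "wants_children",  # marital status missing: branch not printed
        ideal_num == 0,  # preference dont_know/missing: ideal-number tiebreaker
        ideal == "non_numeric",
    ]
    choices = [
        INELIGIBLE, INELIGIBLE, NOT_CHILDLESS,
        INVOLUNTARY, VOLUNTARY, INVOLUNTARY, CIRCUMSTANTIAL,
        UNDECIDED, VOLUNTARY, UNDECIDED,
    ]
    out["childlessness_type"] = np.select(conds, choices, default=UNDECIDED)

    reasons = [
        "missing_parity", "under_40", "", "", "", "", "",
        "marital_status_missing", "ideal_zero_tiebreak", "non_numeric_ideal",
    ]
    out["reason_code"] = np.select(conds, reasons, default="preference_unresolved")
    return out


def _classify_one(rec, min_age: int = ELIGIBILITY_AGE) -> str:
    row = pd.DataFrame([dict(rec)])
    return classify(row, min_age=min_age)["childlessness_type"].iloc[0]


def is_permanently_childless(rec, min_age: int = ELIGIBILITY_AGE):
    """True/False for a 40+ respondent; ``'ineligible'`` below the age cutoff.

    ``children_ever_born`` counts live births only (stillbirths and
    terminations are never counted — input contract).
    """
    outcome = _classify_one(rec, min_age=min_age)
    if outcome == INELIGIBLE:
        if pd.isna(pd.to_numeric(pd.Series([rec.get("children_ever_born")]))[0]):
            raise ValueError("children_ever_born missing; respondent excluded")
        return INELIGIBLE
    return outcome != NOT_CHILDLESS


def classify_type(rec, min_age: int = ELIGIBILITY_AGE) -> str:
    """Type for a single permanently childless respondent."""
    outcome = _classify_one(rec, min_age=min_age)
    if outcome in (NOT_CHILDLESS, INELIGIBLE):
        raise ValueError("classify_type expects a permanently childless respondent")
    return outcome
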