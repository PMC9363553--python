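"""End-to-end orchestration on synthetic or pre-extracted inputs.

The analysis proceeds in four steps: descriptive statistics of the
region-year panel; bivariate childlessness-development fits at national
and subnational aggregation; pooled hierarchical models M1–M5; and
bivariate type-by-component fits.  Every output table is written as CSV
into one run directory, stamped with the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates, models, panel as panel_mod, simulate, typology
from .devindex import LagRule, build_shihd
from .imputation import choose_M, mice
from .simulate import SimConfig, inject_missingness

log = logging.getLogger("childev")

#: aggregate covariates eligible for missingness injection / imputation
IMPUTABLE_COLUMNS = [
    "urban_pct", "never_married_pct", "in_union_pct",
    "divorced_separated_pct", "widowed_pct", "mean_age_first_sex",
    "mean_age_first_union", "mean_age_first_birth", "polygyny_pct",
    "hiv_pct", "women_per_100_men",
    "shihd_overall", "shihd_education", "shihd_health", "shihd_income",
]

DESCRIPTIVE_ROWS = [
    "n", "mean_age_first_birth", "mean_age_first_union", "mean_age_first_sex",
    "hiv_pct", "women_per_100_men", "urban_pct", "polygyny_pct",
    "survey_year", "mean_age",
    "shihd_overall", "shihd_education", "shihd_health", "shihd_income",
    "childless_pct", "voluntary_pct", "involuntary_pct", "circumstantial_pct",
    "in_union_pct", "never_married_pct", "divorced_separated_pct", "widowed_pct",
]


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    sexes: tuple[str, ...] = ("female", "male")
    lag_rule: LagRule = field(default_factory=LagRule)
    mice_iterations: int = 5
    max_imputations: int | None = 5
    model_labels: tuple[str, ...] = ("M1", "M2", "M3", "M4", "M5")
    ic_mode: str = "mean"
    outdir: str = "run_output"
    seed: int = 20260101
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def descriptives(cells: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/min/max summary per panel variable (one row each)."""
    rows = []
    for var in DESCRIPTIVE_ROWS:
        if var not in cells.columns:
            continue
        v = pd.to_numeric(cells[var], errors="coerce")
        rows.append({
            "variable": var, "mean": v.mean(), "sd": v.std(),
            "min": v.min(), "max": v.max(), "n_cells": int(v.notna().sum()),
        })
    return pd.DataFrame(rows)


def build_synthetic_panel(config: RunConfig, sex: str):
    """Simulate, classify, aggregate and attach lagged series for one sex."""
    sim = dataclasses.replace(config.sim, sex=sex, seed=config.sim.seed)
    micro, truth = simulate.simulate_microdata(sim)
    national, subnational, _ = simulate.simulate_dev_series(sim)
    hiv_nat, hiv_anchor = simulate.simulate_hiv_series(sim)
    pop = simulate.simulate_pop_counts(sim)

    classified = typology.classify(micro)
    cells = panel_mod.aggregate(classified, sex=sex)
    shihd = build_shihd(national, subnational)
    hiv = {
        region: covariates.backcast_hiv(hiv_nat[region.split(".")[0]], anchor)
        for region, anchor in hiv_anchor.items()
    }
    cells = panel_mod.attach_lagged(cells, shihd, hiv, pop, config.lag_rule)
    return cells, truth, classified


def national_aggregate(cells: pd.DataFrame) -> pd.DataFrame:
    """Collapse region-year cells to country-year (respondent-weighted)."""
    rows = []
    for (country, year), g in cells.groupby(["country_id", "survey_year"]):
        w = g["n"].to_numpy(dtype=float)
        row = {"country_id": country, "survey_year": int(year), "n": int(w.sum())}
        for col in ["childless_pct", "shihd_overall", "shihd_education",
                    "shihd_health", "shihd_income", "mean_age", "time"]:
            v = g[col].to_numpy(dtype=float)
            ok = ~np.isnan(v)
            row[col] = float(np.average(v[ok], weights=w[ok])) if ok.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _bivariate_overall(cells: pd.DataFrame, level: str) -> pd.DataFrame:
    tab, _ = models.fit_bivariate_types(
        cells.dropna(subset=["shihd_overall", "childless_pct"]),
        outcomes=("childless",), components=("overall",),
    )
    tab.insert(0, "level", level)
    return tab


def run_pipeline(config: RunConfig) -> dict:
    """Execute all four analysis steps; returns paths of written outputs."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    written: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame):
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        written[name] = str(path)

    for sex in config.sexes:
        t0 = time.time()
        cells, truth, classified = build_synthetic_panel(config, sex)
        log.info("%s: %d respondents -> %d cells", sex,
                 len(classified), len(cells))
        emit(f"panel_{sex}", cells)

        # Step 1: descriptives
        emit(f"descriptives_{sex}", descriptives(cells))

        # Step 2: bivariate fits at both aggregation levels
        nat = national_aggregate(cells)
        biv = pd.concat([
            _bivariate_overall(nat, "national"),
            _bivariate_overall(cells, "subnational"),
        ], ignore_index=True)
        emit(f"bivariate_overall_{sex}", biv)

        # Step 3: missingness, imputation, hierarchical models
        cols = [c for c in IMPUTABLE_COLUMNS if c in cells.columns]
        if config.sim.missing_rate > 0:
            cells_missing, _ = inject_missingness(
                cells, config.sim.missing_rate, cols,
                mechanism="MCAR", seed=config.seed,
            )
        else:
            cells_missing = cells
        M = choose_M(cells_missing, cols)
        if config.max_imputations is not None:
            M = min(M, config.max_imputations)
        imputed = mice(cells_missing, M=M, iterations=config.mice_iterations,
                       seed=config.seed, columns=cols)
        fits = models.fit_all_models(
            imputed, sex, labels=config.model_labels, ic_mode=config.ic_mode
        )
        coef_tables = []
        for label, fit in fits.items():
            t = fit.table().reset_index(names="term")
            t.insert(0, "model", label)
            t["aic"], t["bic"], t["loglik"] = fit.aic, fit.bic, fit.loglik
            coef_tables.append(t)
        emit(f"hierarchical_{sex}", pd.concat(coef_tables, ignore_index=True))
        best_label = min(fits, key=lambda k: fits[k].aic)
        emit(f"fitted_curve_{sex}",
             models.fitted_curve(fits[best_label], imputed.copies[0]))

        # Step 4: type-by-component bivariate fits
        tab, lines = models.fit_bivariate_types(cells)
        emit(f"type_component_{sex}", tab)
        emit(f"type_component_lines_{sex}", lines)

        meta["stages"][sex] = {
            "n_respondents": int(len(classified)),
            "n_cells": int(len(cells)),
            "M": int(imputed.M),
            "seconds": round(time.time() - t0, 2),
        }

    (outdir / "run_meta.json").write_text(json.dumps(meta, indent=2))
    written["run_meta"] = str(outdir / "run_meta.json")
    return written
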