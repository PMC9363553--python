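# childev

Tools for studying how **permanent childlessness** relates to
**socioeconomic development** across subnational regions, built for
demographers working with pooled DHS-style survey microdata.

The scientific question: does childlessness follow a *U-shape* in
development — declining as development lifts poverty-driven infertility,
then rising as voluntary and circumstantial childlessness spread with
education, income and later family formation? Answering it requires
several non-trivial pieces, each of which this package implements as a
tested, reusable stage:

1. **Typology** — classify each respondent aged 40+ with zero live births
   as involuntarily (infecund, or wanting children while partnered),
   voluntarily (wants no children), circumstantially (fecund and wanting
   children but unpartnered) childless, or undecided, by a deterministic
   decision tree.
2. **Development index** — build a subnational *historical* human
   development index: logarithmic goalpost transforms of life expectancy
   (bounds 20/85), education (0/100) and GDP per capita (100/46949 G-K
   1990 $), composited by a geometric mean; annual interpolation of
   national historical series; and ratio backcasting of subnational
   series before 1990, e.g. `0.304 / 0.348 × 0.055 = 0.048`.
3. **Panel assembly** — aggregate to region-year cells and attach
   development, HIV prevalence and marriage-market sex balance at the
   *cohort-lagged* year, when the cell's respondents averaged the median
   childbearing age (19 for women, 24 for men): a 2014 survey with mean
   age 43.8 reads its covariates in `2014 − (43.8 − 19) ≈ 1989`.
4. **Imputation** — chained-equation multiple imputation (predictive mean
   matching) with M equal to the percentage of incomplete rows, and
   Rubin's-rules pooling with Barnard–Rubin degrees of freedom.
5. **Models** — two-level linear mixed models (regions in countries) of
   the childlessness proportion on orthogonal polynomials of development
   and time, with a country random intercept and random development
   slope, estimated by full ML and compared by a ΔAIC > 9 evidence rule;
   plus linear bivariate models of each childlessness type on each
   development component.
6. **Synthetic data** — a generator with known ground truth (logit-linear
   type links in development, exactly constant subnational/national
   ratios, controllable MCAR/MAR missingness) so every stage is testable
   without access-restricted survey data.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import childev as cv
from childev import models, simulate
from childev.pipeline import RunConfig, build_synthetic_panel

# index construction: transforms, backcasting, cohort lag
cv.transform_life_expectancy(52.5)          # 0.16605
cv.backcast_subnational(0.304, 0.348, 0.055)  # 0.04805 -> 0.048 at 3 d.p.
cv.lag_year(2014, 43.8, "female")           # 1989

# a synthetic study: 6 countries x 4 regions x 3 survey rounds,
# involuntary childlessness falling with development, voluntary and
# circumstantial rising
cfg = simulate.SimConfig(
    n_countries=6, regions_per_country=4, survey_years=(1995, 2005, 2015),
    respondents_per_region_survey=1500,
    dev_trajectory=simulate.DevTrajectory(start_range=(0.08, 0.45)),
    type_link=simulate.TypeLink(involuntary=(-2.6, -6.0),
                                voluntary=(-7.5, 6.0),
                                circumstantial=(-6.2, 6.0)),
    seed=13,
)
cells, truth, classified = build_synthetic_panel(RunConfig(sim=cfg), "female")
# 108,000 respondents -> 72 region-year cells; mean childlessness 3.9%

sel = models.select_functional_form(cells, "female")
# quadratic (AIC -489.6 vs -441.1 linear: the U-shape wins by >> 9)

fit = models.fit_hierarchical(cells, models.ModelSpec(label="M1", shihd_degree=2))
fit.params["shihd_op2"], fit.pvalues["shihd_op2"]
# (0.0712, <0.001): positive, significant convexity in development

tab, _ = models.fit_bivariate_types(cells, components=("education",))
# involuntary slope -0.123 (falling with education),
# voluntary +0.044 and circumstantial +0.167 (rising), all p < 0.001 —
# the type-level links whose superposition produces the U-shape
```

The same stages run from the shell:

```bash
childev simulate --sex female --seed 13 --out run/
childev classify  --microdata run/microdata.csv --out run/classified.csv
childev aggregate --classified run/classified.csv --sex female --out run/panel.csv
childev build-index --national run/dev_national.csv \
                    --subnational run/dev_subnational.csv --out run/shihd.csv
childev report --seed 13 --out run/report   # all four analysis steps
```

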