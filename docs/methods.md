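# Methods

`childev` implements an analysis pipeline for studying how permanent
childlessness relates to socioeconomic development across subnational
regions, using pooled cross-national survey microdata of the DHS type.
This note documents the models and procedures, the choices made where the
design was genuinely open, and what the synthetic-data tests do and do not
demonstrate.

## Unit of analysis and eligibility

The unit of analysis is a region-year cell: one subnational region
observed in one survey round, separately by sex. Permanent childlessness
is defined as zero live births by the interview at age 40 or older;
respondents under 40 are ineligible, and respondents with a missing
children-ever-born count are excluded from numerator and denominator with
a logged reason code. Cell percentages are unweighted: no age adjustment
and no country-size weighting.

## Childlessness typology

Eligible childless respondents are classified by a deterministic decision
tree, fecundity first, then stated preference, then marital status:

1. declared infecund → **involuntary**;
2. wants no children → **voluntary**;
3. wants children and in union → **involuntary** (wanting, partnered, yet
   never a live birth);
4. wants children and never married / divorced–separated / widowed →
   **circumstantial**;
5. otherwise the ideal-family-size question breaks the tie: a numeric
   ideal of zero → voluntary; a non-numeric ideal → **undecided**.

Open branches resolved here (configurable, logged via reason codes):
"wants children" with missing marital status goes to undecided; a
"don't know" preference with a positive numeric ideal also goes to
undecided rather than being treated as wanting children; pregnancy status
"unknown" is treated as not pregnant (pregnancy at 40+ with zero parity
is rare). Undecided respondents stay in overall childlessness but are
excluded from type-specific outcomes.

## Development index

Health (life expectancy at birth, years), education (a literacy ×
enrollment composite, percent) and income (GDP per capita, Geary-Khamis
1990 $) are mapped onto [0, 1] by logarithmic goalpost transforms —
bounds 20/85, 0/100 and 100/46949 respectively — and combined by an
unweighted geometric mean. The log form makes a fixed absolute raw gain
count for more at higher levels; the health and education transforms are
well defined up to 84 and 99, and inputs outside the domain raise rather
than clip.

National historical series observed on a roughly 5-year grid are linearly
interpolated to an annual grid, never extrapolated: years before the
first national observation are left missing and flow to imputation.
Subnational series, observed annually only from about 1990, are extended
backwards by ratio backcasting — the subnational/national ratio of the
earliest jointly observed year scales the national series, assuming that
ratio is constant through time. The overall index is backcast with the
overall-index ratio directly (not recomposited from backcast components);
each component uses its own ratio. The backcast series is continuous at
the splice year by construction.

Every covariate that acts around family formation (development, HIV,
sex balance) is attached to a cell at its **cohort-lagged year**: the
calendar year in which the cell's respondents averaged the median
childbearing age, 19 for women and 24 for men, i.e.
`round(survey_year − (mean_age − target_age))`, rounded half-up so the
worked arithmetic is deterministic.

## Other covariates

* **HIV prevalence (15–24, %)** — subnational series are national series
  scaled by the subnational/national ratio of the nearest jointly
  observed year (regions without subnational data use national values).
  Between 1970 and 1990 the series follows exponential growth
  `v(t) = v(1990)·exp(r(t−1990))` with `r` set so `v(1970) = ε`; an
  exponential cannot start at literal zero, so a configurable floor
  (default ε = 0.001 percentage points) stands in. Prevalence is zero
  before 1970.
* **Marriage-market sex balance** — women per 100 men aged 15–24,
  national level only, lagged like development.
* **Polygyny prevalence** — share of respondents flagged polygynous,
  counting respondents not in a union as monogynous. A female cell whose
  in-union respondents are more than half missing/uncertain on the
  polygyny question (threshold our construct, configurable) — or that has
  no usable response at all — is replaced by the matching male cell when
  available; a valid female value is never overwritten.
* **Marital shares** — four categories summing to 100% of non-missing
  responses. **Postponement** — cell means of ages at first sex, first
  union (cohabitation age proxies where marriage age was not asked) and
  first birth, computed over the 40+ analysis sample (a flag switches to
  all interviewed ages).

## Missing data

Missing aggregates are filled by chained-equation multiple imputation:
predictive mean matching with 5 donors, all other panel covariates as
predictors, 10 cycles (backed by `statsmodels`' MICE machinery). The
imputation count M equals the percentage of incomplete rows, rounded
half-up with a floor of 2 so the pooling formulas stay defined.
Coefficients estimated on the M completed panels are combined by Rubin's
rules — total variance `T = W + (1 + 1/M)B` — with Barnard–Rubin degrees
of freedom for the t reference. Information criteria are pooled by their
mean across imputations, which keeps AIC differences on the single-fit
scale that the evidence rule below assumes; a literal summed mode is
available behind a flag. Limitations: the imputation model ignores the
country clustering, and congenial joint-model imputation is out of scope.

## Hierarchical models

The outcome is the cell childlessness percentage analysed as a proportion
in [0, 1] with Gaussian errors (no logit transform). Development and
time enter through orthonormal polynomial terms built by the three-term
recurrence (the construction behind R's `poly()`), computed per fitted
dataset; raw powers of an index confined to roughly [0.05, 0.45] are
nearly collinear, and the orthogonal basis spans the same column space —
fitted values are identical — while keeping standard errors honest.

Two-level linear mixed models nest regions within countries with a
random intercept and a random slope on the first-degree development term
(unstructured covariance). A random slope on the second-degree term is
available behind a flag but off by default, matching the fitted models
this pipeline reproduces. The sex-balance covariate enters the fixed part
as a main effect; cross-level interaction terms with the development
polynomials exist behind a flag. Estimation is full maximum likelihood
(not REML) so AIC comparisons across fixed-effect sets are valid;
non-convergence triggers an optimizer switch and then a simplified
covariance restart, degenerate optima (collapsed residual variance) are
rejected, and fits that still fail are excluded from pooling with a
warning. Single-country inputs reduce to ordinary least squares.

Five nested covariate sets are fitted per sex — M1 time trends only, M2
adds mean age and urban share, M3 marital shares and postponement ages,
M4 polygyny, HIV and sex balance, M5 everything — quadratic in
development for women, linear for men by default, with the degree also
selectable from the data: one model is preferred over another only when
the AIC difference exceeds nine, and the linear form is the default when
the evidence is inconclusive. Type-by-component associations are
estimated as linear bivariate regressions of each childlessness type on
each development component (there is no a-priori reason to expect
curvature within a type-component pair; the U-shape is expected to emerge
from their superposition).

## Synthetic data

The generator emulates the statistical structure the pipeline is built
for, with known ground truth stored beside every dataset and never read
by analysis stages. Latent childlessness types are drawn per individual
from logit-linear links in the region's development level — involuntary
decreasing, voluntary and circumstantial increasing, undecided a small
constant — and questionnaire variables are then generated consistently
with the drawn type, so the classifier can recover every latent type
exactly. Default link intercepts are calibrated so type prevalences at a
development level of 0.18 sit near the few-percent magnitudes seen in
pooled sub-Saharan African survey data; ages are uniform over the
interview bounds; parity for parents is a truncated Poisson (only
zero/nonzero matters downstream). Development paths are linear per
country with constant per-region ratios, so ratio backcasting holds
exactly and recovery tests can demand exactness. Missingness injection
blanks an exact count of cells per column, uniformly (MCAR) or with
probability increasing in survey year (MAR-on-year). All randomness
derives from one root seed with named substreams per stage.

A second generator simulates region-year panels directly from the
hierarchical-model equations (fixed polynomial structure plus correlated
country random effects plus noise) for parameter-recovery and calibration
tests. Its random-slope standard deviation is parameterised per standard
deviation of development, which keeps effect sizes interpretable and
identifiable.

What passing tests show: the classifier, index construction, lagging,
imputation and estimation machinery are correct and calibrated under the
stated generating mechanisms. What they do not show: robustness to
survey-design features deliberately out of scope (sampling weights,
clustering, nonresponse), to boundary harmonization of real subnational
regions, or to misreported fertility in real interviews.

## Problem sizes and numerics

Statistical tests use sizes chosen to give adequate power at interactive
runtimes: parameter recovery at 200 countries × 10 regions × 4 years over
20 replicates; null calibration (false-positive rate of the curvature
term) over 400 replicates at 60 countries × 4 regions × 3 years;
prevalence calibration at 10⁵ respondents in a single cell. Worked-value
comparisons are made at the printed precision (3 decimals); internal
computation is full double precision. Mixed-model convergence tolerance
follows the statsmodels defaults with a 200-iteration cap and a
deterministic start.
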