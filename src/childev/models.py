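"""Hierarchical U-shape models of childlessness on development.

The outcome is a region-year childlessness percentage analysed on the
proportion scale with Gaussian errors.  Development enters through
orthogonal polynomial terms (raw powers of an index confined to a narrow
band are nearly collinear; an orthogonal basis keeps the standard errors
honest without changing the fitted surface).  Two-level linear mixed
models nest subnational regions within countries, with a random intercept
and a random slope on the first-degree development term by country
(unstructured covariance), estimated by full maximum likelihood so that
AIC comparisons across fixed-effect sets are valid.  Model selection uses
an AIC difference of nine as the evidence threshold.

Five nested covariate sets are fitted: M1 time trends only, M2 adds
composition (mean age, urban share), M3 adds marriage and postponement,
M4 adds polygyny, HIV and the marriage-market sex ratio, M5 everything.
By default the models are quadratic in development for women and linear
for men.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .imputation import ImputedPanel, PooledEstimate, pool_estimates, pool_ic

AIC_EVIDENCE_THRESHOLD = 9.0

#: extra fixed-effect covariates per model label (beyond time + development)
MODEL_COVARIATES: dict[str, list[str]] = {
    "M1": [],
    "M2": ["mean_age", "urban_pct"],
    "M3": [
        "never_married_pct", "divorced_separated_pct", "widowed_pct",
        "mean_age_first_birth", "mean_age_first_union", "mean_age_first_sex",
    ],
    "M4": ["polygyny_pct", "hiv_pct", "women_per_100_men"],
}
MODEL_COVARIATES["M5"] = MODEL_COVARIATES["M2"] + MODEL_COVARIATES["M3"] + MODEL_COVARIATES["M4"]

#: percentage-scale covariates converted to proportions before fitting
_PERCENT_COVARIATES = {
    "urban_pct", "never_married_pct", "divorced_separated_pct", "widowed_pct",
    "polygyny_pct", "hiv_pct",
}


class RankError(ValueError):
    pass


@dataclass
class OrthoBasis:
    """Discrete orthonormal polynomial basis over a set of source values.

    Built by the three-term recurrence (the construction behind R's
    ``poly()``): each column is orthogonal to the constant and to every
    other column, with unit norm.  ``alpha``/``norm2`` store the recurrence
    coefficients so the same polynomials can be evaluated on new values.
    """

    degree: int
    alpha: np.ndarray
    norm2: np.ndarray  # norms of the unnormalised columns, starting at degree 0
    source: np.ndarray = field(repr=False)
    columns: np.ndarray = field(repr=False)

    def transform(self, x) -> np.ndarray:
        """Evaluate the basis polynomials at new values."""
        x = np.asarray(x, dtype=float)
        F = np.empty((len(x), self.degree + 1))
        F[:, 0] = 1.0
        for k in range(1, self.degree + 1):
            f = (x - self.alpha[k - 1]) * F[:, k - 1]
            if k >= 2:
                f -= (self.norm2[k - 1] / self.norm2[k - 2]) * F[:, k - 2]
            F[:, k] = f
        return F[:, 1:] / np.sqrt(self.norm2[1:])


def ortho_poly(values, degree: int) -> OrthoBasis:
    """Orthonormal polynomial basis of the given degree over ``values``.

    The degree-1 column is an increasing affine map of the input.  Raises
    :class:`RankError` when there are fewer than ``degree + 1`` distinct
    values (a constant input has no degree-1 term).
    """
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < degree + 1:
        raise RankError(
            f"need at least {degree + 1} distinct values for degree {degree}"
        )
    n = len(x)
    alpha = np.empty(degree)
    norm2 = np.empty(degree + 1)
    F = np.empty((n, degree + 1))
    F[:, 0] = 1.0
    norm2[0] = float(n)
    for k in range(1, degree + 1):
        fprev = F[:, k - 1]
        alpha[k - 1] = float((x * fprev**2).sum() / norm2[k - 1])
        f = (x - alpha[k - 1]) * fprev
        if k >= 2:
            f -= (norm2[k - 1] / norm2[k - 2]) * F[:, k - 2]
        F[:, k] = f
        norm2[k] = float((f**2).sum())
        if norm2[k] <= 0:
            raise RankError("input is numerically rank-deficient for this degree")
    cols = F[:, 1:] / np.sqrt(norm2[1:])
    return OrthoBasis(degree=degree, alpha=alpha, norm2=norm2, source=x, columns=cols)


@dataclass
class ModelSpec:
    """One hierarchical model specification."""

    outcome: str = "childless"  # childless | involuntary | voluntary | circumstantial
    label: str = "M1"
    shihd_degree: int = 2
    random_op2: bool = False
    sex_balance_interactions: bool = False

    @classmethod
    def for_sex(cls, sex: str, **kw) -> "ModelSpec":
        """Default functional form: quadratic for women, linear for men."""
        return cls(shihd_degree=2 if sex == "female" else 1, **kw)


@dataclass
class FitResult:
    """One maximum-likelihood fit on one completed panel."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    aic: float
    bic: float
    cov_re: pd.DataFrame
    n: int
    k_fixed: int
    converged: bool
    method: str

    @property
    def df_resid(self) -> float:
        return self.n - self.k_fixed


@dataclass
class PooledFit:
    """Rubin-pooled coefficients and mean information criteria over M fits."""

    label: str
    outcome: str
    coefficients: dict[str, PooledEstimate]
    aic: float
    bic: float
    loglik: float
    M: int
    cov_re: pd.DataFrame
    spec: ModelSpec

    def table(self) -> pd.DataFrame:
        rows = {
            name: {
                "estimate": e.estimate, "se": e.se, "p_value": e.p_value,
                "df": e.df, "between_var": e.between_var,
            }
            for name, e in self.coefficients.items()
        }
        return pd.DataFrame(rows).T


def _design(panel: pd.DataFrame, spec: ModelSpec):
    """Fixed-effect design matrix, random-effect design, outcome, names."""
    d = spec.shihd_degree
    y = panel[f"{spec.outcome}_pct"].to_numpy(dtype=float) / 100.0
    shihd_basis = ortho_poly(panel["shihd_overall"].to_numpy(dtype=float), d)
    time_basis = ortho_poly(panel["time"].to_numpy(dtype=float), d)
    cols = {"intercept": np.ones(len(panel))}
    for j in range(d):
        cols[f"time_op{j + 1}"] = time_basis.columns[:, j]
    for j in range(d):
        cols[f"shihd_op{j + 1}"] = shihd_basis.columns[:, j]
    for cov in MODEL_COVARIATES[spec.label]:
        v = panel[cov].to_numpy(dtype=float)
        if cov in _PERCENT_COVARIATES:
            v = v / 100.0
        cols[cov] = v
    if spec.sex_balance_interactions and "women_per_100_men" in cols:
        w = cols["women_per_100_men"]
        for j in range(d):
            cols[f"w_x_shihd_op{j + 1}"] = w * cols[f"shihd_op{j + 1}"]
    X = pd.DataFrame(cols, index=panel.index)
    n_re = 2 + (1 if (spec.random_op2 and d >= 2) else 0)
    Z = np.column_stack(
        [np.ones(len(panel))]
        + [shihd_basis.columns[:, j] for j in range(n_re - 1)]
    )
    re_names = ["re_intercept"] + [f"re_shihd_op{j + 1}" for j in range(n_re - 1)]
    return y, X, Z, re_names, shihd_basis


def fit_hierarchical(panel: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit one two-level mixed model on one completed panel copy.

    Regions nested in countries: random intercept plus random slope(s) on
    the development polynomial term(s), unstructured covariance, full ML.
    Non-convergence triggers a retry ladder (alternative optimizer, then a
    random-intercept-only covariance); single-country data reduce to an
    ordinary least-squares fit.
    """
    y, X, Z, re_names, _ = _design(panel, spec)
    groups = panel["country_id"].to_numpy()
    if len(np.unique(groups)) < 2:
        res = sm.OLS(y, X).fit()
        return FitResult(
            params=res.params, bse=res.bse, pvalues=res.pvalues,
            llf=float(res.llf), aic=float(res.aic), bic=float(res.bic),
            cov_re=pd.DataFrame(np.zeros((len(re_names),) * 2),
                                index=re_names, columns=re_names),
            n=len(y), k_fixed=X.shape[1], converged=True, method="ols",
        )

    attempts = [
        (Z, re_names, "lbfgs"),
        (Z, re_names, "cg"),
        (Z[:, :1], re_names[:1], "lbfgs"),  # simplified covariance restart
    ]
    candidates = []
    for z, names, method in attempts:
        model = MixedLM(y, X, groups=groups, exog_re=z)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            try:
                res = model.fit(reml=False, method=method, maxiter=200)
            except (np.linalg.LinAlgError, ValueError):
                continue
        if not np.isfinite(res.llf):
            continue  # degenerate optimum (residual variance collapsed)
        candidates.append((res, names, method))
        if res.converged:
            break
    if not candidates:
        raise RuntimeError("mixed-model estimation failed on every restart")
    # first formally converged attempt, else the best finite-likelihood one
    converged = [c for c in candidates if c[0].converged]
    res, names, method = converged[0] if converged else max(
        candidates, key=lambda c: c[0].llf
    )
    cov_re = pd.DataFrame(
        np.asarray(res.cov_re), index=names, columns=names
    )
    k = X.shape[1]
    return FitResult(
        params=res.fe_params, bse=res.bse_fe, pvalues=res.pvalues.iloc[:k],
        llf=float(res.llf), aic=float(res.aic), bic=float(res.bic),
        cov_re=cov_re, n=len(y), k_fixed=k,
        converged=bool(res.converged), method=method,
    )


def pool_fits(fits: list[FitResult], spec: ModelSpec, ic_mode: str = "mean") -> PooledFit:
    """Rubin-pool coefficients and average ICs over per-imputation fits."""
    converged = [f for f in fits if f.converged]
    if converged:
        if len(converged) < len(fits):
            warnings.warn(
                f"{len(fits) - len(converged)} of {len(fits)} imputation fits "
                "did not converge and are excluded from pooling"
            )
        fits = converged
    else:
        warnings.warn("no imputation fit formally converged; pooling best attempts")
    if not fits:
        raise RuntimeError("no fits to pool")
    names = list(fits[0].params.index)
    df_com = fits[0].df_resid
    coefs = {
        nm: pool_estimates(
            [f.params[nm] for f in fits],
            [f.bse[nm] ** 2 for f in fits],
            df_com=df_com,
        )
        for nm in names
    }
    cov_re = sum(f.cov_re for f in fits) / len(fits)
    return PooledFit(
        label=spec.label, outcome=spec.outcome, coefficients=coefs,
        aic=pool_ic([f.aic for f in fits], ic_mode),
        bic=pool_ic([f.bic for f in fits], ic_mode),
        loglik=pool_ic([f.llf for f in fits], ic_mode),
        M=len(fits), cov_re=cov_re, spec=spec,
    )


def fit_all_models(
    imputed: ImputedPanel,
    sex: str,
    outcome: str = "childless",
    labels: tuple[str, ...] = ("M1", "M2", "M3", "M4", "M5"),
    ic_mode: str = "mean",
    **spec_kw,
) -> dict[str, PooledFit]:
    """Pooled fits for the nested covariate sets M1–M5."""
    out = {}
    for label in labels:
        spec = ModelSpec.for_sex(sex, outcome=outcome, label=label, **spec_kw)
        fits = [fit_hierarchical(copy, spec) for copy in imputed.copies]
        out[label] = pool_fits(fits, spec, ic_mode=ic_mode)
    return out


def compare_models(fit_a: PooledFit, fit_b: PooledFit,
                   threshold: float = AIC_EVIDENCE_THRESHOLD) -> str:
    """Prefer the lower-AIC model only when the difference exceeds nine."""
    if fit_a.outcome != fit_b.outcome:
        raise ValueError("models estimate different outcomes")
    delta = fit_a.aic - fit_b.aic
    if abs(delta) <= threshold:
        return "indistinguishable"
    return fit_b.label if delta > 0 else fit_a.label


@dataclass
class FormSelection:
    selected: str  # linear | quadratic
    comparison: str  # winner label or 'indistinguishable'
    aic_linear: float
    aic_quadratic: float


def select_functional_form(panel: pd.DataFrame, sex: str,
                           outcome: str = "childless") -> FormSelection:
    """Fit degree-1 and degree-2 development terms; pick by the AIC rule.

    The linear form is the default when the evidence is inconclusive.
    """
    lin = fit_hierarchical(panel, ModelSpec(outcome=outcome, label="M1", shihd_degree=1))
    qua = fit_hierarchical(panel, ModelSpec(outcome=outcome, label="M1", shihd_degree=2))
    delta = lin.aic - qua.aic
    if delta > AIC_EVIDENCE_THRESHOLD:
        comparison = "quadratic"
    elif delta < -AIC_EVIDENCE_THRESHOLD:
        comparison = "linear"
    else:
        comparison = "indistinguishable"
    selected = "quadratic" if comparison == "quadratic" else "linear"
    return FormSelection(selected, comparison, float(lin.aic), float(qua.aic))


BIVARIATE_COMPONENTS = ("health", "education", "income")
BIVARIATE_OUTCOMES = ("childless", "involuntary", "voluntary", "circumstantial")


def fit_bivariate_types(
    panel: pd.DataFrame,
    outcomes=BIVARIATE_OUTCOMES,
    components=BIVARIATE_COMPONENTS,
    grid_points: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Linear bivariate fits of each childlessness type on each component.

    Returns (coefficient table, fitted-line table).  Outcomes are on the
    proportion scale; components are the lagged index columns.  Pairs with
    degenerate component variance are skipped with a note in the table.
    """
    rows, lines = [], []
    for outc in outcomes:
        for comp in components:
            sub = panel[[f"{outc}_pct", f"shihd_{comp}"]].dropna()
            x = sub[f"shihd_{comp}"].to_numpy(dtype=float)
            y = sub[f"{outc}_pct"].to_numpy(dtype=float) / 100.0
            if len(sub) < 3 or np.ptp(x) == 0:
                rows.append({"outcome": outc, "component": comp, "n": len(sub),
                             "slope": np.nan, "intercept": np.nan,
                             "slope_p": np.nan, "r_squared": np.nan,
                             "note": "degenerate"})
                continue
            X = sm.add_constant(x)
            res = sm.OLS(y, X).fit()
            rows.append({
                "outcome": outc, "component": comp, "n": len(sub),
                "slope": float(res.params[1]), "intercept": float(res.params[0]),
                "slope_p": float(res.pvalues[1]),
                "r_squared": float(res.rsquared), "note": "",
            })
            grid = np.linspace(x.min(), x.max(), grid_points)
            fit = res.params[0] + res.params[1] * grid
            for g, f in zip(grid, fit):
                lines.append({"outcome": outc, "component": comp,
                              "x": float(g), "fitted": float(f)})
    return pd.DataFrame(rows), pd.DataFrame(lines)


def fitted_curve(pooled: PooledFit, panel: pd.DataFrame,
                 grid_points: int = 100) -> pd.DataFrame:
    """Marginal development curve implied by a pooled fit.

    All non-development covariates are held at their sample means; the
    development polynomial basis is rebuilt from the panel's observed
    values (the basis the coefficients refer to).
    """
    spec = pooled.spec
    y, X, _, _, basis = _design(panel, spec)
    grid = np.linspace(panel["shihd_overall"].min(), panel["shihd_overall"].max(),
                       grid_points)
    ops = basis.transform(grid)
    means = X.mean()
    est = {nm: e.estimate for nm, e in pooled.coefficients.items()}
    base = sum(est[nm] * means[nm] for nm in est
               if not nm.startswith("shihd_op"))
    vals = base + sum(est[f"shihd_op{j + 1}"] * ops[:, j]
                      for j in range(spec.shihd_degree))
    return pd.DataFrame({"shihd_overall": grid, "fitted": vals})
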