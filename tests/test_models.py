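"""Orthogonal polynomials, hierarchical fits, model selection, bivariates."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from childev import models as m
from childev.imputation import ImputedPanel
from childev.simulate import simulate_model_panel


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="module")
def model_panel():
    panel, truth = simulate_model_panel(
        n_countries=40, regions_per_country=5, n_years=3, seed=21
    )
    return panel, truth


class TestOrthoPoly:
    def test_three_point_degree_one(self):
        b = m.ortho_poly([1, 2, 3], 1)
        assert np.allclose(b.columns.ravel(), [-np.sqrt(0.5), 0, np.sqrt(0.5)])

    def test_columns_orthonormal_and_centered(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, size=200)
        b = m.ortho_poly(x, 3)
        G = b.columns.T @ b.columns
        assert np.allclose(G, np.eye(3), atol=1e-10)
        assert np.allclose(b.columns.sum(axis=0), 0, atol=1e-10)

    def test_degree_one_column_increasing_in_input(self):
        x = np.array([0.3, 0.1, 0.9, 0.5])
        b = m.ortho_poly(x, 1)
        order = np.argsort(x)
        assert np.all(np.diff(b.columns[order, 0]) > 0)

    def test_transform_reproduces_columns_on_source(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, size=50)
        b = m.ortho_poly(x, 2)
        assert np.allclose(b.transform(x), b.columns, atol=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(m.RankError):
            m.ortho_poly([2.0, 2.0, 2.0], 1)

    def test_fitted_values_match_raw_polynomial_regression(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, size=120)
        y = 1 + 2 * x - 3 * x**2 + rng.normal(0, 0.1, size=120)
        b = m.ortho_poly(x, 2)
        fit_o = sm.OLS(y, sm.add_constant(b.columns)).fit()
        fit_r = sm.OLS(y, sm.add_constant(np.column_stack([x, x**2]))).fit()
        assert np.allclose(fit_o.fittedvalues, fit_r.fittedvalues, atol=1e-8)


class TestHierarchicalFit:
    def test_single_country_reduces_to_ols(self, model_panel):
        panel, _ = model_panel
        one = panel[panel["country_id"] == "C000"].copy()
        fit = m.fit_hierarchical(one, m.ModelSpec(label="M1", shihd_degree=2))
        y, X, _, _, _ = m._design(one, m.ModelSpec(label="M1", shihd_degree=2))
        ols = sm.OLS(y, X).fit()
        assert np.allclose(fit.params.to_numpy(), ols.params.to_numpy(), atol=1e-6)

    def test_recovers_generating_coefficients(self, model_panel):
        panel, truth = model_panel
        fit = m.fit_hierarchical(panel, m.ModelSpec(label="M1", shihd_degree=2))
        for name, val in truth["gamma"].items():
            assert fit.params[name] == pytest.approx(val, abs=4 * fit.bse[name])

    def test_aic_ordering_invariant_to_outcome_shift(self, model_panel):
        panel, _ = model_panel
        shifted = panel.copy()
        shifted["childless_pct"] = shifted["childless_pct"] + 100.0
        aics, aics_shift = [], []
        for deg in (1, 2):
            spec = m.ModelSpec(label="M1", shihd_degree=deg)
            aics.append(m.fit_hierarchical(panel, spec).aic)
            aics_shift.append(m.fit_hierarchical(shifted, spec).aic)
        assert (aics[0] < aics[1]) == (aics_shift[0] < aics_shift[1])

    def test_random_effect_variance_recovered(self):
        panel, truth = simulate_model_panel(
            n_countries=150, regions_per_country=8, n_years=3,
            re_sd=(0.02, 0.01), seed=31,
        )
        fit = m.fit_hierarchical(panel, m.ModelSpec(label="M1", shihd_degree=2))
        # the generator's slope sd is per standard deviation of development;
        # the fitted basis column has unit norm, hence the sqrt(n) rescale
        est_sd = np.sqrt(
            fit.cov_re.loc["re_shihd_op1", "re_shihd_op1"] / len(panel)
        )
        assert est_sd == pytest.approx(0.01, rel=0.2)
        est_int = np.sqrt(fit.cov_re.loc["re_intercept", "re_intercept"])
        assert est_int == pytest.approx(0.02, rel=0.2)


class TestModelStructure:
    def _imputed(self, panel):
        rng = np.random.default_rng(0)
        n = len(panel)
        full = panel.copy()
        for cov in set(sum(m.MODEL_COVARIATES.values(), [])):
            if cov not in full:
                full[cov] = rng.uniform(10, 30, size=n)
        return ImputedPanel(M=1, copies=[full], mask=full.isna(), seed=0)

    def test_men_m1_terms(self, model_panel):
        panel, _ = model_panel
        fits = m.fit_all_models(self._imputed(panel), "male", labels=("M1",))
        assert list(fits["M1"].coefficients) == ["intercept", "time_op1", "shihd_op1"]

    def test_women_m1_adds_second_order_terms(self, model_panel):
        panel, _ = model_panel
        fits = m.fit_all_models(self._imputed(panel), "female", labels=("M1",))
        assert list(fits["M1"].coefficients) == [
            "intercept", "time_op1", "time_op2", "shihd_op1", "shihd_op2",
        ]

    def test_m5_terms_are_union_of_m2_to_m4(self, model_panel):
        panel, _ = model_panel
        imputed = self._imputed(panel)
        fits = m.fit_all_models(imputed, "female", labels=("M2", "M3", "M4", "M5"))
        union = set()
        for lab in ("M2", "M3", "M4"):
            union |= set(fits[lab].coefficients)
        assert set(fits["M5"].coefficients) == union


class TestCompare:
    def _stub(self, aic, outcome="childless", label="A"):
        return m.PooledFit(
            label=label, outcome=outcome, coefficients={}, aic=aic, bic=aic,
            loglik=0.0, M=1, cov_re=pd.DataFrame(), spec=m.ModelSpec(label="M1"),
        )

    def test_large_difference_prefers_lower_aic(self):
        assert m.compare_models(self._stub(-5000, label="A"),
                                self._stub(-5020, label="B")) == "B"

    def test_small_difference_indistinguishable(self):
        assert m.compare_models(self._stub(-5000), self._stub(-5005)) == \
            "indistinguishable"

    def test_equal_aics_indistinguishable(self):
        assert m.compare_models(self._stub(-10), self._stub(-10)) == \
            "indistinguishable"

    def test_different_outcomes_rejected(self):
        with pytest.raises(ValueError):
            m.compare_models(self._stub(0), self._stub(0, outcome="voluntary"))


class TestFunctionalForm:
    def test_convex_data_selects_quadratic(self):
        panel, _ = simulate_model_panel(
            n_countries=40, regions_per_country=5, n_years=3,
            gamma={"shihd_op2": 0.5}, seed=41,
        )
        sel = m.select_functional_form(panel, "female")
        assert sel.selected == "quadratic"

    def test_linear_data_defaults_to_linear(self):
        panel, _ = simulate_model_panel(
            n_countries=40, regions_per_country=5, n_years=3,
            gamma={"shihd_op2": 0.0}, seed=42,
        )
        sel = m.select_functional_form(panel, "female")
        assert sel.selected == "linear"


class TestBivariates:
    def test_perfect_linear_data_r_squared_one(self):
        x = np.linspace(0.1, 0.5, 60)
        panel = pd.DataFrame({
            "childless_pct": 100 * (0.01 + 0.1 * x),
            "shihd_health": x,
        })
        tab, lines = m.fit_bivariate_types(
            panel, outcomes=("childless",), components=("health",)
        )
        assert tab["r_squared"].iloc[0] == pytest.approx(1.0, abs=1e-10)
        assert tab["slope"].iloc[0] == pytest.approx(0.1, abs=1e-10)
        assert len(lines) == 50

    def test_degenerate_component_skipped(self):
        panel = pd.DataFrame({
            "childless_pct": [1.0, 2.0, 3.0],
            "shihd_health": [0.2, 0.2, 0.2],
        })
        tab, _ = m.fit_bivariate_types(
            panel, outcomes=("childless",), components=("health",)
        )
        assert tab["note"].iloc[0] == "degenerate"
        assert np.isnan(tab["slope"].iloc[0])

    def test_slope_signs_match_generator_links(self):
        from childev import simulate as s
        from childev.pipeline import RunConfig, build_synthetic_panel

        cfg = s.SimConfig(
            n_countries=6, regions_per_country=4,
            survey_years=(1995, 2005, 2015),
            respondents_per_region_survey=1500,
            dev_trajectory=s.DevTrajectory(start_range=(0.08, 0.45)),
            type_link=s.TypeLink(
                involuntary=(-2.6, -6.0), voluntary=(-7.5, 6.0),
                circumstantial=(-6.2, 6.0),
            ),
            seed=13,
        )
        cells, _, _ = build_synthetic_panel(RunConfig(sim=cfg), "female")
        tab, _ = m.fit_bivariate_types(cells)
        tab = tab.set_index(["outcome", "component"])
        for comp in ("health", "education", "income"):
            assert tab.loc[("involuntary", comp), "slope"] < 0
            assert tab.loc[("voluntary", comp), "slope"] > 0
            assert tab.loc[("circumstantial", comp), "slope"] > 0
            assert tab.loc[("involuntary", comp), "slope_p"] < 0.05
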