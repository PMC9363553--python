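"""Synthetic-data generator: determinism, calibration, link structure."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from childev import simulate as s
from childev import typology


class TestDeterminism:
    def test_same_seed_identical_microdata(self, sim_config):
        a, _ = s.simulate_microdata(sim_config)
        b, _ = s.simulate_microdata(sim_config)
        pd.testing.assert_frame_equal(a, b)

    def test_same_seed_identical_dev_series(self, sim_config):
        na, sa, _ = s.simulate_dev_series(sim_config)
        nb, sb, _ = s.simulate_dev_series(sim_config)
        for x, y in zip(na + sa, nb + sb):
            pd.testing.assert_series_equal(x.values, y.values)

    def test_different_seed_differs(self, sim_config):
        import dataclasses
        a, _ = s.simulate_microdata(sim_config)
        b, _ = s.simulate_microdata(dataclasses.replace(sim_config, seed=99))
        assert not a.equals(b)


class TestTypeConsistency:
    def test_voluntary_childless_want_no_children(self, microdata):
        micro, truth = microdata
        vol = micro[truth.latent_type.to_numpy() == typology.VOLUNTARY]
        assert (vol["children_ever_born"] == 0).all()
        assert (vol["fertility_preference"] == "wants_no_children").all()

    def test_circumstantial_are_unpartnered(self, microdata):
        micro, truth = microdata
        cir = micro[truth.latent_type.to_numpy() == typology.CIRCUMSTANTIAL]
        assert cir["marital_status"].isin(typology.UNPARTNERED).all()
        assert (cir["children_ever_born"] == 0).all()


class TestPrevalenceCalibration:
    def test_large_cell_matches_configured_probabilities(self):
        cfg = s.SimConfig(
            n_countries=1, regions_per_country=1, survey_years=(2010,),
            respondents_per_region_survey=100_000, seed=5,
        )
        micro, truth = s.simulate_microdata(cfg)
        dev = truth.region_dev["dev"].iloc[0]
        p = cfg.type_link.probabilities(np.array([dev]))[0]
        n = len(micro)
        for i, tp in enumerate(
            [typology.INVOLUNTARY, typology.VOLUNTARY, typology.CIRCUMSTANTIAL]
        ):
            obs = (truth.latent_type == tp).mean()
            se = np.sqrt(p[i] * (1 - p[i]) / n)
            assert abs(obs - p[i]) < 3 * se

    def test_zero_slope_link_gives_flat_prevalence(self):
        link = s.TypeLink(voluntary=(-5.5, 0.0))
        cfg = s.SimConfig(
            n_countries=8, regions_per_country=4,
            survey_years=(1995, 2005, 2015),
            respondents_per_region_survey=2000, type_link=link, seed=6,
        )
        micro, truth = s.simulate_microdata(cfg)
        lat = truth.latent_type.to_numpy()
        cells = micro.assign(vol=(lat == typology.VOLUNTARY)).groupby(
            ["region_id", "survey_year"]
        ).agg(prev=("vol", "mean")).reset_index()
        dev = truth.region_dev.set_index(["region_id", "year"])["dev"]
        x = dev.loc[list(zip(cells.region_id, cells.survey_year))].to_numpy()
        res = sm.OLS(cells["prev"], sm.add_constant(x)).fit()
        # slope of prevalence on development within Monte-Carlo error of zero
        assert abs(res.params.iloc[1]) < 3 * res.bse.iloc[1]

    def test_u_shape_config_gives_interior_minimum(self):
        cfg = s.SimConfig(
            n_countries=12, regions_per_country=4,
            survey_years=(1995, 2005, 2015),
            respondents_per_region_survey=3000,
            dev_trajectory=s.DevTrajectory(start_range=(0.05, 0.60)),
            type_link=s.TypeLink(
                involuntary=(-1.5, -8.0), voluntary=(-8.0, 8.0),
                circumstantial=(-7.0, 8.0),
            ),
            seed=7,
        )
        micro, truth = s.simulate_microdata(cfg)
        lat = truth.latent_type.to_numpy()
        cells = micro.assign(cl=(lat != "parent")).groupby(
            ["region_id", "survey_year"]
        ).agg(prev=("cl", "mean")).reset_index()
        dev = truth.region_dev.set_index(["region_id", "year"])["dev"]
        x = dev.loc[list(zip(cells.region_id, cells.survey_year))].to_numpy()
        X = np.column_stack([np.ones_like(x), x, x**2])
        res = sm.OLS(cells["prev"].to_numpy(), X).fit()
        # convex with an interior minimum over the configured range
        assert res.params[2] > 0
        xmin = -res.params[1] / (2 * res.params[2])
        assert x.min() < xmin < x.max()


class TestConfigValidation:
    def test_probabilities_escaping_unit_interval_rejected(self):
        cfg = s.SimConfig(
            type_link=s.TypeLink(
                involuntary=(2.0, 1.0), voluntary=(2.0, 1.0),
                circumstantial=(2.0, 1.0),
            )
        )
        with pytest.raises(s.ConfigurationError, match="region-year"):
            s.simulate_microdata(cfg)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(s.ConfigurationError):
            s.SimConfig(n_countries=0)


class TestDevSeriesConstruction:
    def test_subnational_is_constant_ratio_of_national(self, sim_config):
        national, subnational, truth = s.simulate_dev_series(sim_config)
        nat = {(x.unit_id, x.component): x for x in national}
        ratios = truth.region_ratio.set_index("region_id")["ratio"]
        for sub in subnational:
            n = nat[(sub.country_id, sub.component)]
            joint = np.intersect1d(sub.years, n.years)
            if len(joint) == 0:
                continue
            r = sub.values.loc[joint].to_numpy() / n.values.loc[joint].to_numpy()
            clipped = (sub.values.loc[joint] <= 0.005) | (sub.values.loc[joint] >= 0.995)
            assert np.allclose(r[~clipped.to_numpy()], ratios.loc[sub.unit_id], rtol=1e-9)

    def test_overall_is_geometric_mean_of_components(self, sim_config):
        national, _, _ = s.simulate_dev_series(sim_config)
        by = {(x.unit_id, x.component): x.values for x in national}
        for cid in {x.unit_id for x in national}:
            prod = (by[(cid, "education")] * by[(cid, "health")] * by[(cid, "income")]) ** (1 / 3)
            ok = np.ones(len(prod), dtype=bool)
            for comp in ("education", "health", "income", "overall"):
                v = by[(cid, comp)]
                ok &= (v > 0.005).to_numpy() & (v < 0.995).to_numpy()
            assert np.allclose(prod[ok], by[(cid, "overall")][ok], rtol=1e-9)


class TestDevSeriesTrivialCases:
    def test_constant_national_unit_ratio_passes_through(self):
        cfg = s.SimConfig(
            n_countries=1, regions_per_country=1,
            dev_trajectory=s.DevTrajectory(
                start_range=(0.2, 0.2), annual_increment=0.0,
                region_ratio_range=(1.0, 1.0),
            ),
            seed=1,
        )
        national, subnational, _ = s.simulate_dev_series(cfg)
        sub_overall = [x for x in subnational if x.component == "overall"][0]
        assert np.allclose(sub_overall.values.to_numpy(), 0.2)

    def test_half_ratio_halves_true_history(self):
        cfg = s.SimConfig(
            n_countries=1, regions_per_country=1,
            dev_trajectory=s.DevTrajectory(
                start_range=(0.1, 0.1), annual_increment=0.0,
                region_ratio_range=(0.5, 0.5),
            ),
            seed=1,
        )
        _, _, truth = s.simulate_dev_series(cfg)
        t = truth.region_dev.set_index(["component", "year"])
        assert t.loc[("overall", 1950), "dev"].item() == pytest.approx(0.05)


class TestInjectMissingness:
    def _panel(self, n=100):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "survey_year": rng.choice([1995, 2000, 2005, 2010, 2015], size=n),
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
        })

    def test_rate_zero_is_identity(self):
        p = self._panel()
        out, mask = s.inject_missingness(p, 0.0, ["a", "b"], seed=1)
        pd.testing.assert_frame_equal(out, p)
        assert not mask.to_numpy().any()

    def test_exact_count_blanked(self):
        p = self._panel(100)
        out, mask = s.inject_missingness(p, 0.2, ["a", "b"], seed=1)
        assert out["a"].isna().sum() == 20
        assert out["b"].isna().sum() == 20
        assert mask["a"].sum() == 20

    def test_mask_marks_blanked_positions(self):
        p = self._panel(50)
        out, mask = s.inject_missingness(p, 0.3, ["a"], seed=2)
        assert (out["a"].isna() == mask["a"]).all()

    def test_mar_on_year_blanking_increases_with_year(self):
        p = self._panel(4000)
        _, mask = s.inject_missingness(p, 0.3, ["a"], mechanism="MAR-on-year", seed=3)
        res = sm.Logit(mask["a"].astype(float),
                       sm.add_constant(p["survey_year"].astype(float))).fit(disp=0)
        assert res.params.iloc[1] > 0
        assert res.pvalues.iloc[1] < 0.01

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            s.inject_missingness(self._panel(), 1.2, ["a"])
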