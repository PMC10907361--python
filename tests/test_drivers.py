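"""Predictor assembly, standardisation and the comparison/driver models."""

import numpy as np
import pandas as pd
import pytest

import thermoshift as ts

PRED = ts.PREDICTORS


def simulate_site_results(seed, n_study=30, per=10, beta=None, sd_u=0.02,
                          sd_e=0.03, n_taxa=3, realm_offset=None):
    """Draw site-level results directly from the driver-model data process."""
    rng = np.random.default_rng(seed)
    n = n_study * per
    g = np.repeat(np.arange(n_study), per)
    taxon = g % n_taxa
    df = pd.DataFrame({p: rng.normal(size=n) for p in PRED})
    y = rng.normal(0, sd_e, n) + rng.normal(0, sd_u, n_study)[g] \
        + rng.normal(0, 0.005, n_taxa)[taxon]
    if beta:
        for term, b in beta.items():
            v = np.ones(n)
            for c in term.split(":"):
                v = v * df[c]
            y = y + b * v
    df["rate"] = y
    df["study_id"] = [f"st{i}" for i in g]
    df["taxon_group"] = [f"tx{i}" for i in taxon]
    df["realm"] = np.where(rng.random(n) < 0.5, "terrestrial", "freshwater")
    if realm_offset:
        df.loc[df["realm"] == "freshwater", "rate"] += realm_offset
    df["latitude"] = rng.uniform(40, 50, n)
    df["longitude"] = rng.uniform(0, 10, n)
    return df


class TestSiteTemperatureTrend:
    def test_two_point_slope(self):
        assert ts.site_temperature_trend([2000, 2010], [10.0, 11.0]) \
            == pytest.approx(0.1)

    def test_constant_series(self):
        assert ts.site_temperature_trend(range(2000, 2010), [5.0] * 10) \
            == pytest.approx(0.0)

    def test_noiseless_landscape_recovers_rate_exactly(self):
        sc = ts.SimulationScenario(warming_rate=0.05, rng_seed=0)
        land = ts.generate_landscape(sc, 5, 5)
        years, temps = land.grid.annual_series(1, 1)
        assert ts.site_temperature_trend(years, temps) \
            == pytest.approx(0.05, abs=1e-12)


class TestAssemblePredictors:
    def test_assembled_values_from_constructed_inputs(self, toy_grid):
        for i, year in enumerate(range(1990, 2004)):
            toy_grid.layers[("annual_mean", year)] = \
                toy_grid.layers["bio01"] + 0.1 * i
        obs = pd.DataFrame([
            {"site_id": "s1", "study_id": "st1", "taxon_group": "plants",
             "realm": "terrestrial", "latitude": 9.5, "longitude": 0.5,
             "year": y, "sample_id": "a", "species": sp, "abundance": np.nan}
            for y in (1990, 1995, 2003) for sp in ("A", "B", "C")])
        rates = pd.DataFrame([{"site_id": "s1", "rate": 0.02}])
        profiles = pd.DataFrame({"species": ["A", "B"], "sti": [8.0, 10.0],
                                 "niche_breadth": [10.0, 16.0],
                                 "n_records": 9, "provenance": "species"})
        traits = pd.DataFrame({"species": ["A", "B"],
                               "body_size_m": [0.1, 0.3]})
        out = ts.assemble_predictors(rates, toy_grid, profiles, traits, obs,
                                     baseline_window=(1990, 2003))
        row = out.iloc[0]
        assert row["series_length"] == 13
        assert row["richness"] == 3
        assert row["mean_niche_breadth"] == pytest.approx(13.0)
        assert row["mean_body_size"] == pytest.approx(0.2)
        assert row["trait_coverage"] == pytest.approx(2 / 3)
        assert row["temp_change"] == pytest.approx(0.1, abs=1e-12)
        # baseline: mean over the 14 annual layers at the site's cell
        assert row["baseline_temp"] == pytest.approx(5.0 + 0.1 * 13 / 2)

    def test_low_trait_coverage_warns(self, toy_grid, caplog):
        for year in (2000, 2006):
            toy_grid.layers[("annual_mean", year)] = toy_grid.layers["bio01"]
        obs = pd.DataFrame([
            {"site_id": "s1", "study_id": "st1", "taxon_group": "plants",
             "realm": "terrestrial", "latitude": 9.5, "longitude": 0.5,
             "year": y, "sample_id": "a", "species": sp, "abundance": np.nan}
            for y in (2000, 2006) for sp in ("A", "B", "C")])
        rates = pd.DataFrame([{"site_id": "s1", "rate": 0.0}])
        profiles = pd.DataFrame({"species": ["A"], "sti": [8.0],
                                 "niche_breadth": [10.0], "n_records": 9,
                                 "provenance": "species"})
        traits = pd.DataFrame({"species": ["A"], "body_size_m": [0.1]})
        with caplog.at_level("WARNING", logger="thermoshift"):
            ts.assemble_predictors(rates, toy_grid, profiles, traits, obs)
        assert "trait coverage" in caplog.text


class TestZscore:
    def test_sample_sd_convention(self):
        np.testing.assert_allclose(ts.zscore([1, 2, 3]), [-1, 0, 1])

    def test_idempotent_on_standardised_input(self):
        z = ts.zscore([3.0, 9.0, 1.0, 4.0])
        np.testing.assert_allclose(ts.zscore(z), z, atol=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            ts.zscore([5.0, 5.0])

    def test_zscore_predictors_names_offender(self):
        df = pd.DataFrame({p: [1.0, 2.0, 3.0] for p in PRED})
        df["richness"] = 4.0
        with pytest.raises(ValueError, match="richness"):
            ts.zscore_predictors(df)


class TestPredictorCorrelations:
    def test_duplicated_column_warned(self):
        df = simulate_site_results(0, n_study=10)
        df["mean_body_size"] = df["temp_change"]
        corr, warnings = ts.predictor_correlations(df)
        assert corr.loc["temp_change", "mean_body_size"] == pytest.approx(1.0)
        assert any("temp_change" in w for w in warnings)

    def test_independent_columns_uncorrelated(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({p: rng.normal(size=1000) for p in PRED})
        corr, warnings = ts.predictor_correlations(df)
        off = corr.to_numpy()[~np.eye(len(PRED), dtype=bool)]
        assert np.abs(off).max() < 0.12
        assert warnings == []

    def test_constant_column_flagged(self):
        df = simulate_site_results(2, n_study=10)
        df["richness"] = 1.0
        _, warnings = ts.predictor_correlations(df)
        assert any("constant" in w for w in warnings)


class TestRealmComparison:
    def test_null_realms_give_small_coefficient(self):
        df = simulate_site_results(3, n_study=40)
        fits = ts.realm_comparison(df, spatial="none")
        fit = fits["realm"]
        i = [j for j, t in enumerate(fit.terms) if "realm" in t][0]
        assert abs(fit.params[i]) <= 2 * fit.se[i]

    def test_offset_realm_detected(self):
        df = simulate_site_results(4, n_study=40, realm_offset=0.02)
        fits = ts.realm_comparison(df, spatial="none")
        fit = fits["realm"]
        i = [j for j, t in enumerate(fit.terms) if "realm" in t][0]
        # freshwater is the reference level; terrestrial coefficient < 0
        assert fit.pvalues[i] < 0.05
        assert "interaction" in fits
        assert any(":" in t for t in fits["interaction"].terms)

    def test_single_realm_is_error(self):
        df = simulate_site_results(5, n_study=10)
        df["realm"] = "terrestrial"
        with pytest.raises(ValueError):
            ts.realm_comparison(df, spatial="none")


class TestTaxonComparison:
    def test_identical_groups_usually_not_significant(self):
        # joint F test under the null; a single realisation, so only a
        # weak assertion is made here (calibration is checked in the
        # acceptance suite)
        df = simulate_site_results(6, n_study=42, n_taxa=3)
        out = ts.taxon_comparison(df)
        for realm in out.values():
            assert realm["p_value"] > 0.001

    def test_offset_taxon_detected(self):
        df = simulate_site_results(7, n_study=30, n_taxa=3)
        df.loc[df["taxon_group"] == "tx0", "rate"] += 0.05
        out = ts.taxon_comparison(df)
        assert all(realm["p_value"] < 0.01 for realm in out.values())

    def test_single_taxon_realm_dropped_with_warning(self, caplog):
        df = simulate_site_results(8, n_study=10, n_taxa=1)
        with caplog.at_level("WARNING", logger="thermoshift"):
            out = ts.taxon_comparison(df)
        assert out == {}


class TestDriverModel:
    def test_recovers_programmed_temperature_effect(self):
        df = simulate_site_results(9, n_study=40,
                                   beta={"temp_change": 0.05})
        fit = ts.driver_model(df, scope="realm", spatial="none")
        i = fit.terms.index("temp_change")
        assert abs(fit.params[i] - 0.05) <= 2 * fit.se[i]
        # interaction terms stay near zero
        for j, t in enumerate(fit.terms):
            if ":" in t:
                assert abs(fit.params[j]) <= 3 * fit.se[j]

    def test_outlier_refit_is_applied(self):
        df = simulate_site_results(10, n_study=30)
        df.loc[3, "rate"] += 5.0
        fit = ts.driver_model(df, scope="realm", spatial="none")
        assert 3 in fit.excluded

    def test_formula_contains_expected_terms(self):
        df = simulate_site_results(11, n_study=30)
        fit = ts.driver_model(df, scope="taxon", spatial="none")
        assert "temp_change:mean_body_size:mean_niche_breadth" in fit.terms
        assert "mean_body_size:mean_niche_breadth" in fit.terms
        assert "temp_change:series_length" not in fit.terms

    def test_end_to_end_pipeline_recovers_warming_sign(self, warming_pipeline):
        # simulate -> thermal profiles -> rarefy -> rates -> driver model:
        # the programmed positive warming effect must come out positive
        fit = ts.driver_model(warming_pipeline["site_results"], scope="taxon",
                              spatial="gaussian", n_rho=8)
        i = fit.terms.index("temp_change")
        assert fit.params[i] > 0
        assert fit.pvalues[i] < 0.05
        assert fit.rho is not None and fit.rho > 0
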