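"""Shared fixtures: toy grids and session-scoped simulated datasets.

The heavier simulations (null landscape with 500 sites, the default
warming pipeline) are session-scoped so the stochastic checks in several
modules reuse one realisation instead of re-simulating.
"""

import numpy as np
import pandas as pd
import pytest

import thermoshift as ts


@pytest.fixture
def toy_grid() -> ts.TemperatureGrid:
    """3x3 one-degree grid, bio01 rows {5, 7, 9}, seasonal range 16."""
    bio01 = np.array([[5.0, 5.0, 5.0], [7.0, 7.0, 7.0], [9.0, 9.0, 9.0]])
    return ts.TemperatureGrid(
        origin_lat=10.0, origin_lon=0.0, cell_size=1.0, n_rows=3, n_cols=3,
        layers={"bio01": bio01, "bio10": bio01 + 8.0, "bio11": bio01 - 8.0})


def occurrence_frame(rows):
    """rows: (species, lat, lon[, year[, basis]]) tuples."""
    full = [tuple(r) + (np.nan,) * (5 - len(r)) for r in rows]
    return pd.DataFrame(full, columns=["species", "latitude", "longitude",
                                       "year", "basis"])


@pytest.fixture
def sti_lookup():
    return {"A": 8.0, "B": 10.0, "C": 12.0, "D": 14.0}


def pooled_cti_rates(observations: pd.DataFrame, sti: dict) -> pd.DataFrame:
    """Per-site thermophilisation rates from pooled (unrarefied) yearly sets."""
    series = [ts.cti_series_for_site(grp, sti).assign(site_id=site)
              for site, grp in observations.groupby("site_id")]
    return ts.site_rates(pd.concat(series, ignore_index=True))


@pytest.fixture(scope="session")
def null_simulation():
    """500 sites, zero warming, stationary climate: the null landscape."""
    scenario = ts.SimulationScenario(n_sites=500, n_species=150,
                                     warming_rate=0.0, rng_seed=0)
    data = ts.simulate_dataset(scenario, n_records_per_species=0,
                               landscape_shape=(25, 25))
    truth = dict(zip(data["pool"]["species"], data["pool"]["true_sti"]))
    rates = pooled_cti_rates(data["observations"], truth)
    return {"scenario": scenario, **data, "true_sti": truth, "rates": rates}


@pytest.fixture(scope="session")
def warming_pipeline():
    """Default warming scenario run through the full pipeline.

    Simulate -> clean occurrences -> estimate thermal profiles -> filter
    -> rarefy -> rates -> per-site predictors. Per-site warming rates are
    drawn from 0-0.06 deg C/yr with realistic interannual noise so the
    temperature-change predictor varies across sites.
    """
    scenario = ts.SimulationScenario(n_sites=250, n_species=150,
                                     warming_rate=(0.0, 0.06),
                                     interannual_noise_sd=0.3, rng_seed=0)
    data = ts.simulate_dataset(scenario, n_records_per_species=200,
                               landscape_shape=(20, 20))
    occ, _ = ts.clean_occurrences(data["occurrences"])
    profiles, _ = ts.build_thermal_profiles(occ, data["landscape"].grid)
    lut = ts.profile_lookup(profiles)
    config = ts.AnalysisConfig()
    kept, exclusions = ts.filter_communities(data["observations"], lut, config)
    prepped = ts.rarefy_timeseries(kept, config, seed=1, sti=lut)
    rates = ts.site_rates(prepped)
    sites = ts.assemble_predictors(
        rates, data["landscape"].grid, profiles,
        data["pool"][["species", "body_size_m"]], kept, config,
        baseline_window=(scenario.year_start, scenario.year_end))
    return {"scenario": scenario, **data, "profiles": profiles, "lut": lut,
            "config": config, "kept": kept, "exclusions": exclusions,
            "prepped": prepped, "rates": rates, "site_results": sites}
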