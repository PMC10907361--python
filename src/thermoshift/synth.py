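"""Virtual-species warming simulation with known ground truth.

Every downstream stage of the pipeline (thermal-affinity estimation,
effort standardisation, community-temperature-index trends, turnover
decomposition, driver models) gets its recovery test from here: species
are given true thermal optima (STI) and niche breadths, the landscape a
known baseline gradient and warming slope, and occupancy follows a
Gaussian function of the mismatch between a site's temperature and the
species' optimum, with width ``breadth / occupancy_width_factor``. That
makes thermal generalists literally more tolerant of warming in the
simulation, and gives the realised community temperature index an
expected trend with the sign of the programmed warming.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import SimulationScenario, TemperatureGrid

logger = logging.getLogger("thermoshift")

GENUS_BLOCK = 5  # species per synthetic genus


def generate_species_pool(n_species: int,
                          sti_mean: float = 12.0, sti_sd: float = 4.0,
                          breadth_meanlog: float = np.log(16.0),
                          breadth_sdlog: float = 0.2,
                          size_meanlog: float = np.log(0.2),
                          size_sdlog: float = 0.8,
                          seed: int = 0) -> pd.DataFrame:
    """Draw a virtual species pool.

    True STIs are normal, niche breadths and body sizes log-normal.
    Genera are assigned in blocks of five consecutive species so that
    genus-level aggregation has known membership.

    Returns a DataFrame with columns species, genus, true_sti,
    true_breadth, body_size_m.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if sti_sd < 0 or breadth_sdlog < 0 or size_sdlog < 0:
        raise ValueError("distribution scales must be non-negative")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_species)
    return pd.DataFrame({
        "species": [f"sp{i:04d}" for i in idx],
        "genus": [f"gen{i // GENUS_BLOCK:03d}" for i in idx],
        "true_sti": rng.normal(sti_mean, sti_sd, n_species),
        "true_breadth": rng.lognormal(breadth_meanlog, breadth_sdlog, n_species),
        "body_size_m": rng.lognormal(size_meanlog, size_sdlog, n_species),
    })


@dataclass
class Landscape:
    """A generated temperature grid plus its per-cell ground truth."""

    grid: TemperatureGrid
    baseline: np.ndarray       # deg C, the bio01 climatology
    warming_slope: np.ndarray  # deg C / yr, per cell

    def truth_frame(self) -> pd.DataFrame:
        rows, cols = np.indices(self.grid.shape)
        return pd.DataFrame({
            "row": rows.ravel(), "col": cols.ravel(),
            "baseline_temp": self.baseline.ravel(),
            "true_warming": self.warming_slope.ravel(),
        })


def generate_landscape(scenario: SimulationScenario,
                       n_rows: int = 20, n_cols: int = 20,
                       origin_lat: float = 50.0, origin_lon: float = 0.0,
                       cell_size: float = 0.25) -> Landscape:
    """Build a warming landscape on a regular grid.

    The baseline (bio01) runs linearly from the cold to the warm end of
    ``scenario.baseline_temp_range`` along rows (north cold, south warm).
    Each year's annual-mean layer is baseline + warming * (year - start)
    plus optional i.i.d. interannual noise. bio10/bio11 are the baseline
    plus/minus the seasonal half-amplitude, so niche breadth measured on
    this landscape equals ``2 * seasonal_amplitude`` everywhere.
    """
    rng = np.random.default_rng(scenario.rng_seed)
    lo, hi = scenario.baseline_temp_range
    row_temp = np.linspace(lo, hi, n_rows)
    baseline = np.repeat(row_temp[:, None], n_cols, axis=1)

    w = scenario.warming_rate
    if isinstance(w, tuple):
        warming = rng.uniform(w[0], w[1], size=(n_rows, n_cols))
    else:
        warming = np.full((n_rows, n_cols), float(w))

    amp = scenario.seasonal_amplitude
    if isinstance(amp, tuple):
        # vary seasonality along the axis orthogonal to the baseline
        # gradient, so niche breadth is not a pure proxy for baseline
        amp = np.repeat(np.linspace(amp[0], amp[1], n_cols)[None, :],
                        n_rows, axis=0)
    layers: dict = {
        "bio01": baseline.copy(),
        "bio10": baseline + amp,
        "bio11": baseline - amp,
    }
    for year in scenario.years:
        t = year - scenario.year_start
        layer = baseline + warming * t
        if scenario.interannual_noise_sd > 0:
            layer = layer + rng.normal(0.0, scenario.interannual_noise_sd,
                                       size=baseline.shape)
        layers[("annual_mean", int(year))] = layer
    grid = TemperatureGrid(origin_lat, origin_lon, cell_size,
                           n_rows, n_cols, layers)
    return Landscape(grid, baseline, warming)


def _suitability(temp: np.ndarray, sti: float, breadth: float,
                 width_factor: float) -> np.ndarray:
    width = breadth / width_factor
    return np.exp(-((temp - sti) ** 2) / (2.0 * width ** 2))


def generate_occurrences(pool: pd.DataFrame, grid: TemperatureGrid,
                         n_records_per_species: int = 200,
                         width_factor: float = 4.0,
                         duplicate_fraction: float = 0.0,
                         invalid_fraction: float = 0.0,
                         seed: int = 0) -> pd.DataFrame:
    """Place occurrence records across the landscape.

    Cells are sampled with probability proportional to the Gaussian
    suitability exp(-(bio01 - STI)^2 / (2 (breadth/k)^2)); when the grid
    carries bio10/bio11, a second Gaussian factor matches the cell's
    seasonal range (bio10 - bio11) to the species' true niche breadth
    (with width 2 breadth / k), so that range-based breadth estimates
    have a recoverable ground truth. Within a cell the position is
    uniform. A configurable fraction of exact duplicates and of
    invalid-coordinate rows is appended to exercise cleaning.
    """
    rng = np.random.default_rng(seed)
    bio01 = grid.layers["bio01"]
    flat = bio01.ravel()
    seas = None
    if "bio10" in grid.layers and "bio11" in grid.layers:
        seas = (grid.layers["bio10"] - grid.layers["bio11"]).ravel()
    valid = np.isfinite(flat)
    records = []
    for sp in pool.itertuples(index=False):
        suit = np.where(valid,
                        _suitability(flat, sp.true_sti, sp.true_breadth,
                                     width_factor), 0.0)
        if seas is not None:
            suit = suit * np.where(
                np.isfinite(seas),
                _suitability(seas, sp.true_breadth,
                             2.0 * sp.true_breadth, width_factor), 0.0)
        total = suit.sum()
        if total <= 0 or not np.isfinite(total):
            logger.warning("species %s has ~zero suitability everywhere; "
                           "no records generated", sp.species)
            continue
        cells = rng.choice(flat.size, size=n_records_per_species,
                           p=suit / total)
        rows, cols = np.unravel_index(cells, bio01.shape)
        lat = grid.origin_lat - (rows + rng.random(rows.size)) * grid.cell_size
        lon = grid.origin_lon + (cols + rng.random(cols.size)) * grid.cell_size
        records.append(pd.DataFrame({
            "species": sp.species, "latitude": lat, "longitude": lon,
            "year": rng.integers(1980, 2020, size=rows.size),
            "basis": "HUMAN_OBSERVATION",
        }))
    df = pd.concat(records, ignore_index=True) if records else pd.DataFrame(
        columns=["species", "latitude", "longitude", "year", "basis"])

    extras = []
    if duplicate_fraction > 0 and len(df):
        n_dup = int(round(duplicate_fraction * len(df)))
        extras.append(df.iloc[rng.integers(0, len(df), n_dup)])
    if invalid_fraction > 0 and len(df):
        n_bad = int(round(invalid_fraction * len(df)))
        bad = pd.DataFrame({
            "species": df["species"].iloc[
                rng.integers(0, len(df), n_bad)].to_numpy(),
            "latitude": rng.choice([95.0, -95.0, 0.0], n_bad),
            "longitude": rng.choice([200.0, -200.0, 0.0], n_bad),
            "year": 2000, "basis": "HUMAN_OBSERVATION",
        })
        # the (0,0) pair is itself an invalid-coordinate marker; make the
        # out-of-range rows consistent
        bad.loc[bad["latitude"] == 0.0, "longitude"] = 0.0
        extras.append(bad)
    if extras:
        df = pd.concat([df, *extras], ignore_index=True)
    return df


def generate_community_timeseries(pool: pd.DataFrame, landscape: Landscape,
                                  scenario: SimulationScenario
                                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate monitored communities on the landscape.

    Species *s* is present at site *i* in year *t* with probability
    ``detection_prob * exp(-(T_it - STI_s)^2 / (2 (breadth_s/k)^2))``
    where ``T_it`` is the cell's annual-mean temperature. Presences are
    split across the year's sample ids (each present species lands in a
    random non-empty subset of samples), so pooling a year's samples
    recovers the realised community while sub-sampling loses species —
    the situation effort standardisation must fix. With
    ``scenario.with_abundance`` a shifted-Poisson abundance proportional
    to occupancy is attached.

    Returns
    -------
    (observations, sites) — the long-format observation table and a
    per-site ground-truth table (coordinates, cell, baseline temperature,
    true warming slope, study id).
    """
    rng = np.random.default_rng(scenario.rng_seed + 1)
    grid = landscape.grid
    n_rows, n_cols = grid.shape
    n_cells = n_rows * n_cols
    if scenario.n_sites > n_cells:
        raise ValueError("more sites than landscape cells")
    cells = rng.choice(n_cells, size=scenario.n_sites, replace=False)
    rows, cols = np.unravel_index(cells, grid.shape)
    lat = grid.origin_lat - (rows + 0.5) * grid.cell_size
    lon = grid.origin_lon + (cols + 0.5) * grid.cell_size
    studies = rng.integers(0, scenario.n_studies, size=scenario.n_sites)

    sti = pool["true_sti"].to_numpy()
    width = pool["true_breadth"].to_numpy() / scenario.occupancy_width_factor
    years = scenario.years
    # temperatures per site-year
    temps = np.stack([grid.layers[("annual_mean", int(y))][rows, cols]
                      for y in years], axis=1)  # (n_sites, n_years)

    species_names = pool["species"].to_numpy()
    col_site, col_study, col_lat, col_lon = [], [], [], []
    col_year, col_sample, col_species, col_ab = [], [], [], []
    sites = []
    lo_s, hi_s = scenario.samples_per_year
    for i in range(scenario.n_sites):
        if not np.all(np.isfinite(temps[i])):
            logger.warning("site %d falls in a no-data cell; skipped", i)
            continue
        site_id = f"site{i:04d}"
        study_id = f"study{studies[i]:03d}"
        sites.append({
            "site_id": site_id, "study_id": study_id,
            "latitude": lat[i], "longitude": lon[i],
            "row": int(rows[i]), "col": int(cols[i]),
            "baseline_temp": landscape.baseline[rows[i], cols[i]],
            "true_warming": landscape.warming_slope[rows[i], cols[i]],
        })
        # random contiguous observation window for this site
        lo_len, hi_len = scenario.series_length_range
        span = int(rng.integers(min(lo_len, len(years)),
                                min(hi_len, len(years)) + 1))
        start = int(rng.integers(0, len(years) - span + 1))
        observed = np.zeros(len(years), bool)
        observed[start:start + span] = True
        # (n_years, n_species) occupancy probabilities
        p = scenario.detection_prob * np.exp(
            -((temps[i][:, None] - sti[None, :]) ** 2)
            / (2.0 * width[None, :] ** 2))
        present = rng.random(p.shape) < p
        n_samples = rng.integers(lo_s, hi_s + 1, size=len(years))
        for j, year in enumerate(years):
            if not observed[j]:
                continue
            sp_idx = np.nonzero(present[j])[0]
            if sp_idx.size == 0:
                continue
            m = int(n_samples[j])
            # random non-empty subset of samples per present species
            member = rng.random((sp_idx.size, m)) < 0.5
            none = ~member.any(axis=1)
            member[none, rng.integers(0, m, none.sum())] = True
            for s in range(m):
                hit = sp_idx[member[:, s]]
                if hit.size == 0:
                    continue
                if scenario.with_abundance:
                    ab = 1.0 + rng.poisson(scenario.abundance_scale
                                           * p[j, hit])
                else:
                    ab = np.full(hit.size, np.nan)
                k = hit.size
                col_site.append(np.repeat(site_id, k))
                col_study.append(np.repeat(study_id, k))
                col_lat.append(np.full(k, lat[i]))
                col_lon.append(np.full(k, lon[i]))
                col_year.append(np.full(k, int(year)))
                col_sample.append(np.repeat(f"s{s}", k))
                col_species.append(species_names[hit])
                col_ab.append(ab)
    if col_site:
        obs = pd.DataFrame({
            "site_id": np.concatenate(col_site),
            "study_id": np.concatenate(col_study),
            "taxon_group": scenario.taxon_group,
            "realm": scenario.realm,
            "latitude": np.concatenate(col_lat),
            "longitude": np.concatenate(col_lon),
            "year": np.concatenate(col_year),
            "sample_id": np.concatenate(col_sample),
            "species": np.concatenate(col_species),
            "abundance": np.concatenate(col_ab),
        })
    else:
        obs = pd.DataFrame(columns=["site_id", "study_id", "taxon_group",
                                    "realm", "latitude", "longitude",
                                    "year", "sample_id", "species",
                                    "abundance"])
    return obs, pd.DataFrame(sites)


def simulate_dataset(scenario: SimulationScenario,
                     n_records_per_species: int = 200,
                     landscape_shape: tuple[int, int] = (20, 20)) -> dict:
    """One-call convenience: pool, landscape, occurrences, communities.

    Returns a dict with keys pool, landscape, occurrences, observations,
    sites — the full set of inputs the analysis stages consume, plus the
    ground truth needed to score them.
    """
    pool = generate_species_pool(scenario.n_species, seed=scenario.rng_seed)
    landscape = generate_landscape(scenario, *landscape_shape)
    occ = generate_occurrences(pool, landscape.grid, n_records_per_species,
                               width_factor=scenario.occupancy_width_factor,
                               seed=scenario.rng_seed + 2)
    obs, sites = generate_community_timeseries(pool, landscape, scenario)
    return {"pool": pool, "landscape": landscape, "occurrences": occ,
            "observations": obs, "sites": sites}
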