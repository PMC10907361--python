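"""Per-site predictors and the thermophilisation driver models.

Each filtered community contributes one row: its thermophilisation rate
plus the hypothesised drivers — local temperature trend over the
observation window, baseline temperature, community mean body size and
thermal niche breadth, species richness and series length. Realm and
taxon contrasts and the interaction driver model are restricted-maximum-
likelihood mixed models (study nested in taxonomic group as random
intercepts, optional Gaussian spatial residual correlation), z-scored
predictors, and a single refit after removing residual outliers beyond
``outlier_sd`` standard deviations.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io import locate_cell
from .lmm import fit_lmm, refit_without_outliers
from .types import AnalysisConfig, ModelFit, TemperatureGrid

logger = logging.getLogger("thermoshift")

PREDICTORS = ["temp_change", "mean_body_size", "mean_niche_breadth",
              "baseline_temp", "series_length", "richness"]

#: Fixed-effects structure of the driver model: all main effects,
#: temperature-change interactions with every driver except series
#: length, the body-size x niche-breadth interaction, and the three-way
#: temperature x size x breadth term.
DRIVER_FORMULA = (
    "rate ~ temp_change + mean_body_size + mean_niche_breadth"
    " + baseline_temp + series_length + richness"
    " + temp_change:mean_body_size + temp_change:mean_niche_breadth"
    " + temp_change:baseline_temp + temp_change:richness"
    " + mean_body_size:mean_niche_breadth"
    " + temp_change:mean_body_size:mean_niche_breadth"
)


def site_temperature_trend(years, temps) -> float:
    """OLS slope (deg C/yr) of mean annual temperature on year."""
    years = np.asarray(years, dtype=float)
    temps = np.asarray(temps, dtype=float)
    ok = np.isfinite(temps)
    if ok.sum() < 2 or np.unique(years[ok]).size < 2:
        raise ValueError("temperature trend needs >= 2 distinct years")
    return float(np.polyfit(years[ok], temps[ok], 1)[0])


def _baseline_temp(grid: TemperatureGrid, row: int, col: int,
                   window: tuple[int, int]) -> float:
    years = [y for y in grid.years() if window[0] <= y <= window[1]]
    if years:
        vals = np.array([grid.layers[("annual_mean", y)][row, col]
                         for y in years])
        if np.isfinite(vals).any():
            return float(np.nanmean(vals))
    return float(grid.layers["bio01"][row, col])


def assemble_predictors(rates: pd.DataFrame, grid: TemperatureGrid,
                        profiles: pd.DataFrame,
                        traits: Optional[pd.DataFrame],
                        observations: pd.DataFrame,
                        config: Optional[AnalysisConfig] = None,
                        baseline_window: tuple[int, int] = (1980, 2010),
                        trait_coverage_warn: float = 0.7
                        ) -> pd.DataFrame:
    """Build the per-site driver table (one row per community).

    - ``temp_change``: slope of the site's mean annual temperature over
      the community's own observation window.
    - ``baseline_temp``: mean annual temperature over ``baseline_window``
      (the climatology layer when no annual layers fall in the window).
    - ``mean_body_size`` / ``mean_niche_breadth``: unweighted means over
      the recorded species with trait/profile data; trait coverage below
      ``trait_coverage_warn`` is flagged.
    - ``richness``: distinct species over the whole series;
      ``series_length``: last minus first observed year.
    """
    config = config or AnalysisConfig()
    breadth = (dict(zip(profiles["species"], profiles["niche_breadth"]))
               if "niche_breadth" in profiles.columns else {})
    sizes = (dict(zip(traits["species"], traits["body_size_m"]))
             if traits is not None else {})
    rows = []
    for site, grp in observations.groupby("site_id"):
        rate_row = rates[rates["site_id"] == site]
        if rate_row.empty:
            continue
        rate_row = rate_row.iloc[0]
        lat = float(grp["latitude"].iloc[0])
        lon = float(grp["longitude"].iloc[0])
        cell = locate_cell(grid, lat, lon)
        if cell is None:
            logger.warning("site %s outside the temperature grid; dropped",
                           site)
            continue
        y0, y1 = int(grp["year"].min()), int(grp["year"].max())
        yrs = [y for y in grid.years() if y0 <= y <= y1]
        temps = [grid.layers[("annual_mean", y)][cell] for y in yrs]
        try:
            trend = site_temperature_trend(yrs, temps)
        except ValueError:
            logger.warning("site %s lacks temperature overlap; dropped", site)
            continue
        species = grp["species"].unique()
        b_vals = [breadth[s] for s in species
                  if s in breadth and np.isfinite(breadth[s])]
        s_vals = [sizes[s] for s in species if s in sizes]
        trait_cov = len(s_vals) / len(species) if len(species) else 0.0
        if sizes and 0 < trait_cov < trait_coverage_warn:
            logger.warning("site %s trait coverage %.2f below %.2f", site,
                           trait_cov, trait_coverage_warn)
        rows.append({
            "site_id": site,
            "realm": grp["realm"].iloc[0],
            "taxon_group": grp["taxon_group"].iloc[0],
            "study_id": grp["study_id"].iloc[0],
            "latitude": lat, "longitude": lon,
            "rate": float(rate_row["rate"]),
            "temp_change": trend,
            "baseline_temp": _baseline_temp(grid, *cell, baseline_window),
            "mean_body_size": float(np.mean(s_vals)) if s_vals else np.nan,
            "trait_coverage": trait_cov,
            "mean_niche_breadth": float(np.mean(b_vals)) if b_vals else np.nan,
            "richness": int(len(species)),
            "series_length": y1 - y0,
        })
    return pd.DataFrame(rows)


def zscore(values) -> np.ndarray:
    """Standardise to mean 0, sample sd 1 (n - 1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if np.unique(arr[np.isfinite(arr)]).size < 2:
        raise ValueError("zscore needs >= 2 distinct values")
    sd = np.nanstd(arr, ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    return (arr - np.nanmean(arr)) / sd


def zscore_predictors(data: pd.DataFrame,
                      columns=PREDICTORS) -> pd.DataFrame:
    """z-score the predictor columns in place (copy), naming any that fail."""
    out = data.copy()
    for col in columns:
        if col not in out.columns:
            continue
        try:
            out[col] = zscore(out[col])
        except ValueError as err:
            raise ValueError(f"predictor {col!r}: {err}") from err
    return out


def predictor_correlations(data: pd.DataFrame, columns=PREDICTORS,
                           warn_threshold: float = 0.7
                           ) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson correlations among predictors, with warnings.

    Constant columns yield NaN correlations and are flagged explicitly;
    any |r| above ``warn_threshold`` is reported.
    """
    cols = [c for c in columns if c in data.columns]
    sub = data[cols].astype(float)
    corr = sub.corr()
    warnings = []
    for c in cols:
        if sub[c].nunique(dropna=True) < 2:
            warnings.append(f"predictor {c!r} is constant; correlation undefined")
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > warn_threshold:
                warnings.append(f"|r({a}, {b})| = {abs(r):.3f} exceeds "
                                f"{warn_threshold}")
    for w in warnings:
        logger.warning("%s", w)
    return corr, warnings


def realm_comparison(sites: pd.DataFrame, spatial: str = "gaussian",
                     **lmm_kwargs) -> dict[str, ModelFit]:
    """Realm contrast models: rate ~ realm and rate ~ temp_change x realm.

    Random intercepts for taxonomic group and study nested within it,
    with the spatial residual structure of :func:`fit_lmm`.
    """
    if sites["realm"].nunique() < 2:
        raise ValueError("realm contrast needs both realms")
    groups = lmm_kwargs.pop("groups", ("taxon_group", "study_id"))
    return {
        "realm": fit_lmm(sites, "rate ~ realm", groups=groups,
                         spatial=spatial, **lmm_kwargs),
        "interaction": fit_lmm(sites, "rate ~ temp_change * realm",
                               groups=groups, spatial=spatial, **lmm_kwargs),
    }


def wald_factor_test(fit: ModelFit, prefix: str) -> tuple[float, int, int, float]:
    """Joint Wald F test of all terms whose name starts with ``prefix``."""
    idx = [i for i, t in enumerate(fit.terms) if t.startswith(prefix)]
    if not idx:
        raise ValueError(f"no terms match {prefix!r}")
    R = np.zeros((len(idx), len(fit.terms)))
    for r, i in enumerate(idx):
        R[r, i] = 1.0
    rb = R @ fit.params
    rcr = R @ fit.cov_params @ R.T
    F = float(rb @ np.linalg.solve(rcr, rb) / len(idx))
    df1, df2 = len(idx), fit.df_resid
    p = float(stats.f.sf(F, df1, df2))
    return F, df1, df2, p


def taxon_comparison(sites: pd.DataFrame, spatial: str = "none",
                     **lmm_kwargs) -> dict[str, dict]:
    """Per-realm taxon contrast: rate ~ taxon_group, study random intercept.

    Returns, per realm, the fit plus a joint F-style test of the taxon
    factor. Realms with a single taxonomic group are skipped with a
    warning.
    """
    out = {}
    for realm, grp in sites.groupby("realm"):
        if grp["taxon_group"].nunique() < 2:
            logger.warning("realm %s has one taxon group; factor dropped",
                           realm)
            continue
        fit = fit_lmm(grp, "rate ~ taxon_group", groups=("study_id",),
                      nested=False, spatial=spatial, **lmm_kwargs)
        F, df1, df2, p = wald_factor_test(fit, "taxon_group")
        out[realm] = {"fit": fit, "F": F, "df": (df1, df2), "p_value": p}
    return out


def driver_model(sites: pd.DataFrame, scope: str = "realm",
                 config: Optional[AnalysisConfig] = None,
                 spatial: str = "gaussian", standardize: bool = True,
                 trim_outliers: bool = True, **lmm_kwargs) -> ModelFit:
    """The interaction driver model for one realm (or one taxon group).

    Fixed effects follow :data:`DRIVER_FORMULA`; predictors are z-scored
    first. ``scope="realm"`` uses taxonomic group and nested study random
    intercepts, ``scope="taxon"`` study only. After the REML fit,
    residual outliers beyond ``config.outlier_sd`` standard deviations
    are removed and the model refit once; ``trim_outliers=False`` skips
    that normality-protection step (note that trimming truncates the
    residual distribution, so trimmed fits are mildly anti-conservative
    under a pure-noise null).
    """
    config = config or AnalysisConfig()
    data = sites.dropna(subset=["rate", *PREDICTORS]).reset_index(drop=True)
    if standardize:
        data = zscore_predictors(data)
    if scope == "realm":
        groups: tuple = ("taxon_group", "study_id")
    elif scope == "taxon":
        groups = ("study_id",)
    else:
        raise ValueError("scope must be 'realm' or 'taxon'")
    fit = fit_lmm(data, DRIVER_FORMULA, groups=groups, spatial=spatial,
                  **lmm_kwargs)
    if not trim_outliers:
        return fit
    return refit_without_outliers(fit, data, config.outlier_sd)
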