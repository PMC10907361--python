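"""Community temperature index (CTI) and thermophilisation rates.

CTI at a time point is the unweighted mean STI of the species present;
thermophilisation is the ordinary-least-squares slope of CTI on calendar
year — positive means a shift toward warm-affinity species,
negative (cryophilisation) toward cold-affinity species. An
abundance-weighted variant is provided for the occurrence-vs-abundance
comparison; occurrence is the primary currency throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CTIPoint:
    """CTI at one site-year: value, species used, profile coverage."""
    cti: Optional[float]
    n_used: int
    coverage: float
    ok: bool


def profile_lookup(profiles: pd.DataFrame) -> dict[str, float]:
    """species -> STI mapping from a profile table (all provenances)."""
    return dict(zip(profiles["species"], profiles["sti"]))


def compute_cti(species: Iterable[str], sti: Mapping[str, float],
                min_coverage: float = 0.75) -> CTIPoint:
    """Occurrence-based CTI: mean STI over the profiled species present.

    ``coverage`` is the profiled fraction of the species present; the
    point is rejected (``ok=False``, ``cti=None``) when coverage falls
    below ``min_coverage`` or no species is profiled.
    """
    species = list(species)
    if not species:
        raise ValueError("species set is empty")
    values = [sti[s] for s in species if s in sti]
    coverage = len(values) / len(species)
    if not values or coverage < min_coverage:
        return CTIPoint(None, len(values), coverage, False)
    return CTIPoint(float(np.mean(values)), len(values), coverage, True)


def compute_cti_weighted(abundances: Mapping[str, float],
                         sti: Mapping[str, float],
                         min_coverage: float = 0.75) -> CTIPoint:
    """Abundance-weighted CTI: sum(a_i STI_i) / sum(a_i) over profiled species."""
    if not abundances:
        raise ValueError("abundance mapping is empty")
    if any(a < 0 for a in abundances.values()):
        raise ValueError("abundances must be non-negative")
    pairs = [(a, sti[s]) for s, a in abundances.items() if s in sti]
    coverage = len(pairs) / len(abundances)
    total = sum(a for a, _ in pairs)
    if not pairs or coverage < min_coverage or total == 0:
        return CTIPoint(None, len(pairs), coverage, False)
    cti = sum(a * v for a, v in pairs) / total
    return CTIPoint(float(cti), len(pairs), coverage, True)


def thermophilisation_rate(cti_series: pd.DataFrame
                           ) -> tuple[float, float, float, int]:
    """OLS slope of CTI on calendar year for one site.

    Parameters
    ----------
    cti_series : DataFrame with columns ``year`` and ``cti``.

    Returns
    -------
    (slope degC/yr, intercept, standard error of the slope, n_years).
    Requires at least two distinct years; with exactly two points the
    slope standard error is reported as 0.
    """
    df = cti_series.dropna(subset=["cti"])
    years = df["year"].to_numpy(dtype=float)
    cti = df["cti"].to_numpy(dtype=float)
    if len(np.unique(years)) < 2:
        raise ValueError("thermophilisation rate needs >= 2 distinct years")
    res = stats.linregress(years, cti)
    se = 0.0 if len(years) == 2 else float(res.stderr)
    if not np.isfinite(se):
        se = 0.0
    return float(res.slope), float(res.intercept), se, len(years)


def cti_series_for_site(observations: pd.DataFrame, sti: Mapping[str, float],
                        min_coverage: float = 0.75) -> pd.DataFrame:
    """Pooled per-year CTI for one site's observation rows.

    Samples within a year are pooled to the year's species set. Points
    rejected for coverage are omitted, not imputed.
    """
    rows = []
    for year, grp in observations.groupby("year"):
        point = compute_cti(set(grp["species"]), sti, min_coverage)
        if point.ok:
            rows.append({"year": int(year), "cti": point.cti,
                         "n_used": point.n_used,
                         "coverage": point.coverage})
    return pd.DataFrame(rows, columns=["year", "cti", "n_used", "coverage"])


def site_rates(prepped: pd.DataFrame) -> pd.DataFrame:
    """Thermophilisation rate per site from a prepped site-year table.

    ``prepped`` carries one row per site-year with a ``cti`` column (the
    output of rarefaction or of :func:`cti_series_for_site` stacked over
    sites). Sites with fewer than two usable years are dropped.
    """
    out = []
    for site, grp in prepped.dropna(subset=["cti"]).groupby("site_id"):
        if grp["year"].nunique() < 2:
            continue
        slope, intercept, se, n = thermophilisation_rate(grp)
        out.append({"site_id": site, "rate": slope, "intercept": intercept,
                    "rate_se": se, "n_years": n,
                    "first_year": int(grp["year"].min()),
                    "last_year": int(grp["year"].max())})
    return pd.DataFrame(out, columns=["site_id", "rate", "intercept",
                                      "rate_se", "n_years", "first_year",
                                      "last_year"])


def compare_cti_variants(paired: pd.DataFrame) -> tuple[float, int]:
    """Pearson correlation between occurrence and abundance-weighted CTI.

    ``paired`` has columns ``cti`` and ``cti_weighted`` (site-years where
    both are defined). Returns (r, n); r is NaN when either variant has
    zero variance or fewer than 3 pairs remain.
    """
    df = paired.dropna(subset=["cti", "cti_weighted"])
    n = len(df)
    if n < 3 or df["cti"].std() == 0 or df["cti_weighted"].std() == 0:
        return float("nan"), n
    r = float(np.corrcoef(df["cti"], df["cti_weighted"])[0, 1])
    return r, n
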