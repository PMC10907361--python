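"""Inclusion filters and rarefaction-based effort standardisation.

Sites enter the analysis only if (after dropping years before the
configured cut) their series spans at least ``min_span_years``, holds at
least ``min_species`` distinct species, and at least ``min_sti_coverage``
of those species have a thermal profile. Heterogeneous within-year
sampling effort is standardised by repeatedly down-sampling each year to
the series-minimum number of samples and taking the median of every
derived variable across replicates.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .cti import compute_cti
from .types import AnalysisConfig

logger = logging.getLogger("thermoshift")

FILTER_ORDER = ("min_year", "min_span", "min_species", "sti_coverage")


def filter_communities(observations: pd.DataFrame,
                       sti: Optional[Mapping[str, float]] = None,
                       config: Optional[AnalysisConfig] = None,
                       order: tuple = FILTER_ORDER
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the inclusion filters per site.

    Filters run in ``order`` and the exclusion report records only the
    first rule each site triggers. ``min_year`` drops the too-early
    observation years first (a site failing only because nothing remains
    is reported under ``min_year``); span is last year minus first year;
    richness counts distinct species over the whole series; coverage is
    the profiled fraction of those species (checked only when ``sti`` is
    given).

    Returns (kept observations, exclusion report with site_id and rule).
    """
    config = config or AnalysisConfig()
    sti = sti or {}
    df = observations.copy()
    early = df["year"] < config.min_year
    df = df[~early]
    gone = set(observations["site_id"].unique()) - set(df["site_id"].unique())
    excluded = [{"site_id": s, "rule": "min_year"} for s in sorted(gone)]

    checks = {
        "min_year": lambda g: True,  # already applied row-wise above
        "min_span": lambda g: g["year"].max() - g["year"].min()
        >= config.min_span_years,
        "min_species": lambda g: g["species"].nunique() >= config.min_species,
        "sti_coverage": lambda g: (
            True if not sti else
            np.mean([s in sti for s in g["species"].unique()])
            >= config.min_sti_coverage),
    }
    keep_sites = []
    for site, grp in df.groupby("site_id"):
        rule = next((r for r in order if not checks[r](grp)), None)
        if rule is None:
            keep_sites.append(site)
        else:
            excluded.append({"site_id": site, "rule": rule})
    report = pd.DataFrame(excluded, columns=["site_id", "rule"])
    return df[df["site_id"].isin(keep_sites)].reset_index(drop=True), report


def _set_variables(species, sti: Optional[Mapping[str, float]],
                   min_coverage: float) -> dict:
    out = {"richness": float(len(species))}
    if sti is not None:
        point = compute_cti(species, sti, min_coverage)
        out["cti"] = point.cti if point.ok else np.nan
        out["coverage"] = point.coverage
        out["n_used"] = float(point.n_used)
    return out


def _year_variables(grp: pd.DataFrame, sti: Optional[Mapping[str, float]],
                    min_coverage: float) -> dict:
    return _set_variables(set(grp["species"]), sti, min_coverage)


def rarefy_timeseries(observations: pd.DataFrame,
                      config: Optional[AnalysisConfig] = None,
                      seed: Optional[int] = None,
                      sti: Optional[Mapping[str, float]] = None,
                      studies_to_rarefy: Optional[set] = None
                      ) -> pd.DataFrame:
    """Standardise sampling effort per site by sample rarefaction.

    For each site to be rarefied, ``m`` is the minimum number of distinct
    samples in any of its years. Each replicate ``r`` (seeded
    ``seed + r``) draws ``m`` samples without replacement per year, pools
    their species, and computes the derived variables (richness, and CTI
    with coverage when ``sti`` is given); the output value per site-year
    is the median across the ``n_rarefaction_reps`` replicates (odd, so
    medians are attained values). Years with zero samples are dropped
    with a warning.

    Sites belonging to studies outside ``studies_to_rarefy`` (when given)
    pass through: variables are computed once on the pooled samples.

    Returns one row per site-year with columns site_id, year, richness
    (+ cti, coverage, n_used when ``sti`` is given), m_samples, rarefied.
    """
    config = config or AnalysisConfig()
    if seed is None:
        seed = config.rng_seed
    min_cov = config.min_sti_coverage
    rows = []
    for site, site_grp in observations.groupby("site_id"):
        study = site_grp["study_id"].iloc[0]
        do_rarefy = (studies_to_rarefy is None
                     or study in studies_to_rarefy)
        samples_per_year = site_grp.groupby("year")["sample_id"].nunique()
        if (samples_per_year == 0).any():
            logger.warning("site %s has a year with no samples; dropped", site)
        if not do_rarefy:
            for year, grp in site_grp.groupby("year"):
                rows.append({"site_id": site, "year": int(year),
                             "rarefied": False,
                             "m_samples": int(samples_per_year[year]),
                             **_year_variables(grp, sti, min_cov)})
            continue
        m = int(samples_per_year.min())
        if m == 0:
            continue
        # species set per (year, sample) once; replicates only union sets
        sample_sets: dict[int, list[frozenset]] = {}
        for (year, _sid), grp in site_grp.groupby(["year", "sample_id"]):
            sample_sets.setdefault(int(year), []).append(
                frozenset(grp["species"]))
        per_year_reps: dict[int, list[dict]] = {y: [] for y in sample_sets}
        for r in range(config.n_rarefaction_reps):
            rng = np.random.default_rng(seed + r)
            for year, sets in sample_sets.items():
                idx = rng.choice(len(sets), size=m, replace=False)
                pooled = frozenset().union(*(sets[i] for i in idx))
                per_year_reps[year].append(
                    _set_variables(pooled, sti, min_cov))
        for year, reps in per_year_reps.items():
            med = {}
            for k in reps[0]:
                vals = np.asarray([rep[k] for rep in reps], dtype=float)
                finite = vals[np.isfinite(vals)]
                med[k] = float(np.median(finite)) if finite.size else np.nan
            rows.append({"site_id": site, "year": year, "rarefied": True,
                         "m_samples": m, **med})
    cols = ["site_id", "year", "rarefied", "m_samples", "richness"]
    if sti is not None:
        cols += ["cti", "coverage", "n_used"]
    out = pd.DataFrame(rows)
    return out[cols].sort_values(["site_id", "year"]).reset_index(drop=True) \
        if len(out) else pd.DataFrame(columns=cols)
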