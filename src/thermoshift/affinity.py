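"""Species temperature indices and thermal niche breadths from occurrences.

A species' temperature index (STI) is the mean annual-mean temperature
(bio01) over the grid cells its cleaned occurrence records fall in — a
realised-thermal-niche proxy for thermal affinity. Niche breadth is the
difference between the warmest-quarter (bio10) and coldest-quarter
(bio11) means over the same cells. By default both average over *unique
occupied cells* rather than raw records, which blunts sampling-density
bias; the per-record mean is available behind ``per_record=True``.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import locate_cells
from .types import TemperatureGrid

logger = logging.getLogger("thermoshift")

DEFAULT_PRESERVED_LABELS = frozenset({
    "PRESERVED_SPECIMEN", "FOSSIL_SPECIMEN", "LIVING_SPECIMEN",
})

PROFILE_COLUMNS = ["species", "sti", "niche_breadth", "n_records", "provenance"]

#: Default year-bin edges for the temporal-stability check:
#: <=1990, 1991-2000, 2001-2010, >2010.
DEFAULT_BIN_EDGES = (1990, 2000, 2010)


def clean_occurrences(records: pd.DataFrame, drop_preserved: bool = False,
                      preserved_labels=DEFAULT_PRESERVED_LABELS
                      ) -> tuple[pd.DataFrame, dict]:
    """Remove duplicate and erroneous occurrence records.

    Drops, in order: records with invalid coordinates (non-finite, out of
    bounds, or the exact (0, 0) point), preserved-specimen records when
    ``drop_preserved``, and exact duplicates on (species, latitude,
    longitude). Returns the cleaned frame and a report of removal counts
    by reason.
    """
    report = {"n_in": len(records), "invalid_coords": 0, "preserved": 0,
              "duplicates": 0}
    df = records.copy()
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    bad = (~np.isfinite(lat) | ~np.isfinite(lon)
           | ~lat.between(-90, 90) | ~lon.between(-180, 180)
           | ((lat == 0.0) & (lon == 0.0)))
    report["invalid_coords"] = int(bad.sum())
    df = df[~bad]
    if drop_preserved and "basis" in df.columns:
        pres = df["basis"].isin(preserved_labels)
        report["preserved"] = int(pres.sum())
        df = df[~pres]
    n = len(df)
    df = df.drop_duplicates(subset=["species", "latitude", "longitude"])
    report["duplicates"] = n - len(df)
    report["n_out"] = len(df)
    return df.reset_index(drop=True), report


def _cells_by_species(records: pd.DataFrame, grid: TemperatureGrid
                      ) -> tuple[pd.DataFrame, dict]:
    """Attach (row, col) cell indices, dropping out-of-extent records."""
    row, col, ok = locate_cells(grid, records["latitude"].to_numpy(),
                                records["longitude"].to_numpy())
    df = records.loc[ok, ["species"]].copy()
    df["row"] = row[ok]
    df["col"] = col[ok]
    if "year" in records.columns:
        df["year"] = records.loc[ok, "year"].to_numpy()
    return df, {"out_of_extent": int((~ok).sum())}


def _mean_over_cells(located: pd.DataFrame, grid: TemperatureGrid,
                     layer: str, per_record: bool) -> pd.Series:
    """Per-species mean of one layer over occupied cells (or raw records)."""
    values = grid.layers[layer][located["row"], located["col"]]
    df = located.assign(_v=values)
    df = df[np.isfinite(df["_v"])]
    if not per_record:
        df = df.drop_duplicates(subset=["species", "row", "col"])
    return df.groupby("species")["_v"].mean()


def estimate_sti(records: pd.DataFrame, grid: TemperatureGrid,
                 min_records: int = 5, per_record: bool = False
                 ) -> tuple[pd.DataFrame, dict]:
    """Estimate the species temperature index from cleaned occurrences.

    STI is the unweighted mean of bio01 over a species' unique occupied
    cells (or over raw in-extent records with ``per_record``). Species
    with fewer than ``min_records`` retained records get no profile and
    are listed in the report.

    Returns a DataFrame (species, sti, n_records, provenance="species")
    and a report with exclusion lists.
    """
    located, report = _cells_by_species(records, grid)
    counts = located.groupby("species").size()
    enough = counts[counts >= min_records].index
    report["too_few_records"] = sorted(set(counts.index) - set(enough))
    report["no_records_in_extent"] = sorted(
        set(records["species"].unique()) - set(counts.index))
    sti = _mean_over_cells(located[located["species"].isin(enough)],
                           grid, "bio01", per_record)
    out = pd.DataFrame({
        "species": sti.index, "sti": sti.to_numpy(),
        "n_records": counts.reindex(sti.index).to_numpy(),
        "provenance": "species",
    }).reset_index(drop=True)
    return out, report


def estimate_niche_breadth(records: pd.DataFrame, grid: TemperatureGrid,
                           min_records: int = 5, per_record: bool = False,
                           cellwise: bool = False) -> pd.Series:
    """Thermal niche breadth per species: mean(bio10) - mean(bio11).

    Computed over unique occupied cells; ``cellwise=True`` averages the
    per-cell bio10 - bio11 difference instead (the two agree whenever the
    bio10 and bio11 coverage is identical, which it is for grids whose
    layers share missingness).
    """
    located, _ = _cells_by_species(records, grid)
    counts = located.groupby("species").size()
    located = located[located["species"].isin(counts[counts >= min_records].index)]
    if cellwise:
        diff_layer = grid.layers["bio10"] - grid.layers["bio11"]
        values = diff_layer[located["row"], located["col"]]
        df = located.assign(_v=values)
        df = df[np.isfinite(df["_v"])]
        if not per_record:
            df = df.drop_duplicates(subset=["species", "row", "col"])
        return df.groupby("species")["_v"].mean().rename("niche_breadth")
    warm = _mean_over_cells(located, grid, "bio10", per_record)
    cold = _mean_over_cells(located, grid, "bio11", per_record)
    return (warm - cold).rename("niche_breadth")


def build_thermal_profiles(records: pd.DataFrame, grid: TemperatureGrid,
                           min_records: int = 5, per_record: bool = False
                           ) -> tuple[pd.DataFrame, dict]:
    """STI and niche breadth together, in the profile-table contract."""
    profiles, report = estimate_sti(records, grid, min_records, per_record)
    breadth = estimate_niche_breadth(records, grid, min_records, per_record)
    profiles = profiles.merge(breadth, left_on="species", right_index=True,
                              how="left")
    return profiles[PROFILE_COLUMNS], report


def aggregate_sti(profiles: pd.DataFrame,
                  taxonomy: Optional[Mapping[str, str]] = None,
                  complexes: Optional[Mapping[str, Sequence[str]]] = None
                  ) -> pd.DataFrame:
    """Add genus-level and species-complex profiles.

    The genus entry is the unweighted mean STI (and breadth) over
    congeners that have species-level profiles; a complex entry is the
    mean over its profiled members. Complexes with zero profiled members
    get no entry and are logged.
    """
    base = profiles[profiles["provenance"] == "species"]
    extra = []
    if "niche_breadth" not in profiles.columns:
        profiles = profiles.assign(niche_breadth=np.nan)
        base = profiles[profiles["provenance"] == "species"]
    if taxonomy:
        tax = pd.Series(dict(taxonomy), name="genus")
        joined = base.join(tax, on="species", how="inner")
        for genus, grp in joined.groupby("genus"):
            extra.append({"species": genus, "sti": grp["sti"].mean(),
                          "niche_breadth": grp["niche_breadth"].mean(),
                          "n_records": int(grp["n_records"].sum()),
                          "provenance": "genus_mean"})
    if complexes:
        by_species = base.set_index("species")
        for label, members in complexes.items():
            hit = [m for m in members if m in by_species.index]
            if not hit:
                logger.warning("complex %s has no profiled members; skipped",
                               label)
                continue
            grp = by_species.loc[hit]
            extra.append({"species": label, "sti": grp["sti"].mean(),
                          "niche_breadth": grp["niche_breadth"].mean(),
                          "n_records": int(grp["n_records"].sum()),
                          "provenance": "complex_mean"})
    if not extra:
        return profiles.copy()
    return pd.concat([profiles, pd.DataFrame(extra)], ignore_index=True)


def sti_temporal_stability(records: pd.DataFrame, grid: TemperatureGrid,
                           bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
                           min_records: int = 5, min_shared: int = 3
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Range-shift robustness check: STI per year-bin, correlated pairwise.

    Records are split into bins by year at ``bin_edges`` (default:
    <=1990, 1991-2000, 2001-2010, >2010), STI is estimated independently
    per bin, and Pearson correlations are taken over species profiled in
    both bins of a pair. Pairs sharing fewer than ``min_shared`` species
    are reported as NaN.

    Returns (correlation matrix, shared-species count matrix), both
    indexed by bin label.
    """
    edges = [-np.inf, *bin_edges, np.inf]
    labels = [f"<= {bin_edges[0]}"] + [
        f"{bin_edges[i] + 1}-{bin_edges[i + 1]}"
        for i in range(len(bin_edges) - 1)] + [f"> {bin_edges[-1]}"]
    years = pd.to_numeric(records["year"], errors="coerce")
    binned = pd.cut(years, bins=edges, labels=labels)
    per_bin: dict[str, pd.Series] = {}
    for label in labels:
        sub = records[binned == label]
        if len(sub) == 0:
            per_bin[label] = pd.Series(dtype=float)
            continue
        prof, _ = estimate_sti(sub, grid, min_records=min_records)
        per_bin[label] = prof.set_index("species")["sti"]
    corr = pd.DataFrame(np.nan, index=labels, columns=labels)
    counts = pd.DataFrame(0, index=labels, columns=labels)
    for a, b in itertools.combinations_with_replacement(labels, 2):
        shared = per_bin[a].index.intersection(per_bin[b].index)
        counts.loc[a, b] = counts.loc[b, a] = len(shared)
        if len(shared) >= min_shared:
            x, y = per_bin[a][shared], per_bin[b][shared]
            if x.std() > 0 and y.std() > 0:
                r = float(np.corrcoef(x, y)[0, 1])
                corr.loc[a, b] = corr.loc[b, a] = r
    return corr, counts
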