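"""Domain types shared across the pipeline.

Tabular data (occurrence records, community observations, thermal
profiles, per-site results) travels as pandas DataFrames with the column
contracts documented in :mod:`thermoshift.io`; the classes here cover the
structured objects that do not fit a flat table: the temperature raster
stack, the analysis configuration, the simulation scenario and model-fit
results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Union

import numpy as np

#: Layer key: a climatology name ("bio01", "bio10", "bio11") or
#: ("annual_mean", year) for a single year's mean annual temperature.
LayerKey = Union[str, tuple]

CLIMATOLOGY_LAYERS = ("bio01", "bio10", "bio11")


@dataclass
class TemperatureGrid:
    """Regular lat-lon raster stack of temperature layers in deg C.

    The grid is anchored at its north-west corner and indexed row-major,
    north to south. Cells are half-open in both axes: a point on a shared
    edge belongs to the cell to the south (latitude) or east (longitude)
    of the edge, except that the northern and western extent edges are
    included so every point of the closed extent maps to a cell.
    Missing cells are ``NaN``, never a silent zero.
    """

    origin_lat: float
    origin_lon: float
    cell_size: float
    n_rows: int
    n_cols: int
    layers: dict[LayerKey, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        for key, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.n_rows, self.n_cols):
                raise ValueError(
                    f"layer {key!r} has shape {arr.shape}, expected "
                    f"({self.n_rows}, {self.n_cols})"
                )
            self.layers[key] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def years(self) -> list[int]:
        """Years for which an annual-mean layer is present, sorted."""
        return sorted(k[1] for k in self.layers if isinstance(k, tuple)
                      and k[0] == "annual_mean")

    def annual_series(self, row: int, col: int) -> tuple[np.ndarray, np.ndarray]:
        """(years, temperatures) for one cell across annual-mean layers."""
        yrs = self.years()
        temps = np.array([self.layers[("annual_mean", y)][row, col] for y in yrs])
        return np.asarray(yrs), temps

    def cell_centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """Latitude and longitude arrays of every cell centre (2-D)."""
        lat = self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size
        lon = self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size
        return np.meshgrid(lat, lon, indexing="ij")


@dataclass
class AnalysisConfig:
    """Thresholds and knobs shared by the filtering and modelling stages.

    Defaults follow the study design this package reproduces: communities
    need at least four species, a span of five or more years, thermal
    affinity information for 75% of species, sampling from 1980 onward,
    99 rarefaction resamples (odd, so medians are attained values), and a
    five-record minimum for species-level thermal indices.
    """

    min_species: int = 4
    min_span_years: int = 5
    min_sti_coverage: float = 0.75
    min_year: int = 1980
    n_rarefaction_reps: int = 99
    min_sti_records: int = 5
    outlier_sd: float = 2.0
    correlation_warn: float = 0.7
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for f in ("min_species", "min_span_years", "min_sti_coverage",
                  "min_year", "n_rarefaction_reps", "min_sti_records",
                  "outlier_sd", "correlation_warn"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.n_rarefaction_reps % 2 == 0:
            raise ValueError("n_rarefaction_reps must be odd so the median "
                             "is an attained value")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Read a flat key-value config file (``key value`` or ``key=value``)."""
        kwargs = {}
        valid = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.replace("=", " ").partition(" ")
                if key not in valid:
                    raise ValueError(f"unknown config key: {key}")
                current = getattr(cls, key, None)
                typ = type(current) if current is not None else float
                kwargs[key] = typ(value.strip())
        return cls(**kwargs)


@dataclass
class SimulationScenario:
    """Parameters of the virtual warming experiment.

    The defaults describe a temperate monitoring campaign: 200 sites
    followed 2000-2019, a 2-18 deg C baseline gradient, a warming trend of
    0.03 deg C/yr (either one global rate or a per-site range), Gaussian
    occupancy around each species' thermal optimum with width equal to
    niche breadth divided by ``occupancy_width_factor``, imperfect
    detection, and between two and four samples per site-year so that
    effort standardisation has something to do.
    """

    n_sites: int = 200
    n_species: int = 150
    year_start: int = 2000
    year_end: int = 2019
    warming_rate: Union[float, tuple[float, float]] = 0.03
    baseline_temp_range: tuple[float, float] = (2.0, 18.0)
    #: half-amplitude of the seasonal cycle (bio10 = bio01 + a,
    #: bio11 = bio01 - a); a (west, east) pair varies it linearly along
    #: longitude — a continentality gradient orthogonal to the
    #: latitudinal baseline gradient
    seasonal_amplitude: Union[float, tuple[float, float]] = (10.0, 6.0)
    #: inclusive range of per-site series lengths in years; each site is
    #: observed over a random contiguous window of the scenario years,
    #: emulating the heterogeneous durations of real monitoring series
    series_length_range: tuple[int, int] = (10, 20)
    interannual_noise_sd: float = 0.0
    occupancy_width_factor: float = 4.0
    detection_prob: float = 0.8
    samples_per_year: tuple[int, int] = (2, 4)
    n_studies: int = 20
    taxon_group: str = "plants"
    realm: str = "terrestrial"
    with_abundance: bool = False
    abundance_scale: float = 20.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.year_end - self.year_start < 1:
            raise ValueError("scenario must span at least two years")
        if not (0 < self.detection_prob <= 1):
            raise ValueError("detection_prob must be in (0, 1]")
        if self.occupancy_width_factor <= 0:
            raise ValueError("occupancy_width_factor must be positive")
        lo, hi = self.samples_per_year
        if lo < 1 or hi < lo:
            raise ValueError("samples_per_year must be (lo, hi) with 1 <= lo <= hi")
        lo, hi = self.series_length_range
        if lo < 2 or hi < lo:
            raise ValueError("series_length_range must be (lo, hi) with 2 <= lo <= hi")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)


@dataclass
class FateTransition:
    """Species fates between two consecutive sampled years at one site.

    ``persisted | added`` is the later year's species set and
    ``persisted | lost`` the earlier year's; the three sets are pairwise
    disjoint. Contrasts are mean-STI differences in deg C, ``None`` when
    either group is empty or unprofiled.
    """

    site_id: str
    year_from: int
    year_to: int
    persisted: frozenset
    added: frozenset
    lost: frozenset
    added_vs_persisted: Optional[float] = None
    added_vs_lost: Optional[float] = None
    lost_vs_persisted: Optional[float] = None


@dataclass
class ModelFit:
    """Result of a (restricted-maximum-likelihood) mixed-model fit.

    ``params`` etc. are aligned with ``terms``. ``vc`` maps each random
    intercept level to its variance; ``sigma2`` is the residual variance.
    ``rho`` is the Gaussian spatial correlation range in km (``None`` when
    the spatial component is off) and ``nugget`` the proportion of
    residual variance not spatially structured.
    """

    terms: list[str]
    params: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    vc: dict[str, float]
    sigma2: float
    rho: Optional[float]
    nugget: float
    loglik: float
    n_used: int
    df_resid: int
    excluded: list = field(default_factory=list)
    residuals: Optional[np.ndarray] = None
    fitted: Optional[np.ndarray] = None
    converged: bool = True

    def __post_init__(self) -> None:
        k = len(self.terms)
        for name in ("params", "se", "tvalues", "pvalues"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} length does not match terms")

    def summary(self) -> str:
        lines = [f"{'term':<40}{'estimate':>12}{'se':>12}{'t':>9}{'p':>10}"]
        for i, t in enumerate(self.terms):
            lines.append(f"{t:<40}{self.params[i]:>12.5f}{self.se[i]:>12.5f}"
                         f"{self.tvalues[i]:>9.2f}{self.pvalues[i]:>10.4f}")
        for name, v in self.vc.items():
            lines.append(f"random intercept var({name}) = {v:.5g}")
        lines.append(f"residual var = {self.sigma2:.5g}")
        if self.rho is not None:
            lines.append(f"spatial range rho = {self.rho:.4g} km, "
                         f"nugget = {self.nugget:.3g}")
        lines.append(f"REML loglik = {self.loglik:.4f}, n = {self.n_used}, "
                     f"excluded = {len(self.excluded)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "params": [float(x) for x in self.params],
            "se": [float(x) for x in self.se],
            "tvalues": [float(x) for x in self.tvalues],
            "pvalues": [float(x) for x in self.pvalues],
            "vc": {k: float(v) for k, v in self.vc.items()},
            "sigma2": float(self.sigma2),
            "rho": None if self.rho is None else float(self.rho),
            "nugget": float(self.nugget),
            "loglik": float(self.loglik),
            "n_used": int(self.n_used),
            "excluded": list(self.excluded),
        }
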