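# Methods

This note documents the models and procedures `thermoshift` implements,
the conventions and defaults it fixes where several reasonable choices
exist, and what the synthetic-data experiments do and do not demonstrate
about real monitoring data.

## Thermal affinity estimation

A species' temperature index (STI) is the unweighted mean of the
annual-mean temperature layer (bio01) over the species' **unique
occupied grid cells**, not over raw records. Averaging over cells blunts
sampling-density bias: a thousand records in one well-visited cell count
the same as one. The per-record mean is available via
`estimate_sti(..., per_record=True)` for sensitivity analysis. STI is
always bounded by the occupied cells' temperatures and is invariant to
record order and within-cell duplication.

Thermal niche breadth is the difference of range-wide means,
mean(bio10) − mean(bio11) over occupied cells, rather than the mean of
cell-wise differences. The two coincide whenever bio10 and bio11 share
missingness; the cell-wise variant is available via `cellwise=True`.

Occurrence cleaning removes records with non-finite or out-of-bounds
coordinates and the exact (0, 0) point (a classic geocoding artefact),
optionally records whose basis marks a preserved specimen, and exact
duplicates on (species, latitude, longitude). Species with fewer than
`min_sti_records` (default 5) retained in-extent records receive no
profile. Genus-level and species-complex profiles are unweighted means
of the member species' STIs; the temporal-stability check re-estimates
STI independently in year bins (default ≤1990, 1991–2000, 2001–2010,
>2010) and reports pairwise Pearson correlations over shared species.

## Community preparation

Inclusion filters run per site in a fixed order — year cut (drop
observations before `min_year` = 1980), span (last − first year ≥ 5),
richness (≥ 4 distinct species), STI coverage (≥ 75% of distinct species
profiled) — and the exclusion report records the first rule triggered.
The order is configurable; only the report attribution, not the kept
set, depends on it.

Effort standardisation: for each site flagged for rarefaction, `m` is
the minimum number of distinct samples in any year of its series
(interpreting the series minimum, not a per-year target, as the
standard); each of the 99 replicates draws `m` samples per year without
replacement, pools the species, and computes the derived variables
(richness; CTI with its coverage). The reported value per site-year is
the median across replicates of each **derived variable** — medians of
variables, not of species lists — and the replicate count is kept odd so
medians are attained values. The thermophilisation rate is fitted to the
median CTI series. Replicate *r* uses seed `seed + r`, so replicates are
individually reproducible. When every year already has exactly `m`
samples the procedure reduces to the plain pooled computation.

## CTI and thermophilisation

CTI is the unweighted mean STI of the species present (genus/complex
profiles count); a site-year is rejected, not imputed, when profile
coverage falls below the threshold. The thermophilisation rate is the
ordinary least-squares slope of CTI on raw calendar year — only the
slope is interpreted, so no centring is applied (a centring option
exists for extreme year values). Positive slope = thermophilisation,
negative = cryophilisation. The abundance-weighted CTI
(Σ aᵢSTIᵢ / Σ aᵢ) supports the occurrence-vs-abundance comparison;
occurrence remains the primary currency because abundance is absent from
several source datasets and is more weather-sensitive.

## Turnover decomposition

Transitions connect consecutive **sampled** years (gaps allowed,
unweighted). Between two years, persisted = intersection, added = new,
lost = gone; the three mean-STI contrasts (added−persisted, added−lost,
lost−persisted) are defined only when both groups contain at least one
profiled species, and the site value is the mean of the defined
per-transition contrasts. Sign frequencies are tested with the exact
binomial upper tail P(X ≥ k | n, ½); zero differences are dropped from
`n` since a zero is evidence for neither direction. The exact tail (not
a normal approximation) matters because group counts can be small; note
the exact test is conservative, so its realised size sits at or below
the nominal level.

## Driver models

Each filtered site contributes one row: rate, temperature trend over its
own observation window (OLS slope of the site cell's mean annual
temperature), baseline temperature (mean annual temperature over a
configurable climatology window, default 1980–2010, falling back to the
bio01 climatology when no annual layers overlap), community mean body
size over species with trait data (coverage below 70% is flagged),
community mean niche breadth over profiled species, total distinct
species over the series (richness; a mean-annual-richness variant exists
behind a flag) and series length in years. Predictors are z-scored with
the sample (n−1) standard deviation; constant predictors raise an error
naming the offender, and pairwise correlations above 0.7 are flagged.

The mixed model is estimated by REML with marginal covariance
σ²(Σₖ γₖ ZₖZₖ′ + C), where Zₖ are random-intercept indicators (study
nested in taxonomic group for realm-level fits, study only for
taxon-level fits) with variance ratios γₖ, and C is the residual
correlation: identity, or Gaussian spatial
Cᵢⱼ = (1 − ν)exp(−(dᵢⱼ/ρ)²) + ν·1[i = j] with great-circle distances in
km (planar-degree distances behind a flag). γₖ (and the optional nugget
ν) are maximised by Nelder–Mead on log/logit scales; the range ρ is
profiled over a log-spaced grid between the 1st and 99th percentiles of
pairwise distances (default 10 points) and the reported ρ maximises the
profile — robust and directly testable, at the price of grid resolution
in ρ. A tiny diagonal jitter (1e−8) keeps C factorable when sites share
coordinates. Fixed-effect inference is Wald t with n − p residual
degrees of freedom (no Satterthwaite/Kenward–Roger correction), and the
taxon-factor comparison uses a joint Wald F. With no random terms and no
spatial component the fit reproduces OLS exactly; with random intercepts
only it matches statsmodels' MixedLM, which the tests use as an
independent oracle.

The driver formula contains the six main effects, temperature-change
interactions with everything except series length, body size × breadth,
and the temperature × size × breadth three-way term with all its
lower-order terms in a single hierarchical model. After the fit, points
whose marginal residual lies more than `outlier_sd` (default 2) sample
standard deviations from the residual mean are removed and the model
refit **once** (no iteration). Residuals for this rule are marginal
(y − Xβ̂). Trimming protects the normality assumption, but under a
pure-noise null it truncates the residual distribution and makes
per-term tests mildly anti-conservative (≈10% empirical size at nominal
5% in our null experiments, versus ≈5.8% before trimming); calibration
properties are therefore stated for the untrimmed fit
(`driver_model(..., trim_outliers=False)`).

## The synthetic warming experiment

The simulator emulates a temperate multi-site monitoring campaign with
known ground truth. Species receive true thermal optima (normal, mean
12 °C, sd 4 °C), true niche breadths (log-normal, median 16 °C, σ_log
0.2) and body sizes (log-normal, median 0.2 m); genera are blocks of
five species. The landscape is a regular grid whose baseline (bio01)
runs linearly 2–18 °C with latitude, with a seasonal half-amplitude
running 10→6 °C along longitude (a continentality gradient deliberately
orthogonal to the baseline gradient, so the breadth and baseline
predictors are not confounded by construction); yearly layers add
warming·(t − t₀) plus optional i.i.d. interannual noise. Warming can be
one global rate or a per-site uniform range (the default analysis
scenario uses 0–0.06 °C/yr so the temperature-change predictor varies).

Occupancy is a Gaussian function of the site-temperature/optimum
mismatch with width breadth/k (k = 4): thermal generalists tolerate
temperature excursions better, by construction, and expected CTI rises
with site temperature, so the expected thermophilisation rate carries
the sign of the warming rate. Detection is imperfect (0.8) and presences
are split across 2–4 within-year samples (each present species lands in
a random non-empty subset), which is what rarefaction must standardise.
Each site is observed over a random contiguous 10–20-year window of
2000–2019, giving the series-length predictor its variance. Occurrence
records sample cells proportionally to the same thermal suitability
times a seasonality-match factor (cell seasonal range vs true breadth,
width 2·breadth/k) so that the range-based breadth estimator has
recoverable truth; duplicates and invalid coordinates can be injected to
exercise cleaning. An optional abundance model (1 + Poisson with mean
proportional to occupancy) supports the occurrence-vs-abundance
comparison. All generators are pure functions of (parameters, seed).

What passing tests show — and do not. The simulation demonstrates
estimator correctness and signal recovery under a known mechanism:
range-mean STIs recover programmed optima (r > 0.9 at 200
records/species), realised rates are symmetric about zero without
warming and increase monotonically with programmed warming, added
species out-warm lost species under warming, and the driver model
recovers programmed coefficients with calibrated error rates. It does
not model dispersal limitation, biotic interactions, evolutionary
adaptation, land-use change or observation biases beyond random
non-detection; community means of species traits can still correlate
through species sorting (flagged by the correlation check), as they may
in real data. Real-data idiosyncrasies — taxonomic error, uneven GBIF
coverage, water-temperature dynamics — are out of scope.

## Numerical and scale choices

Grid cells are half-open (points on shared edges belong to the
south/east neighbour; the north/west extent edges are included), indexed
from the north-west origin in WGS84 decimal degrees; no-data cells are
NaN, never zero. The plain-text grid dialect round-trips at full decimal
precision. Problem sizes in the test and acceptance runs (25×25
landscapes, 200–500 sites, 150 species, 99 rarefaction replicates, 30–100
model-fit replicates) were chosen to estimate each property's
Monte-Carlo error well below its tolerance while keeping a full run in
the minutes range on a single CPU.
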