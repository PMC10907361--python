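# thermoshift

Thermophilisation analysis for community time-series: as climates warm,
local communities shift toward species with warmer thermal affinities.
`thermoshift` implements the full analytical chain used to quantify that
shift and probe its drivers, together with a virtual-species warming
simulator that provides ground truth for every stage — a stand-in for the
restricted biodiversity-monitoring compilations such analyses are usually
run on.

## What it computes

- **Species temperature index (STI)** — a species' thermal affinity,
  estimated as the mean annual-mean temperature (a Bio01-style layer)
  over the grid cells of its cleaned occurrence records; thermal niche
  breadth is the warmest-quarter minus coldest-quarter mean (Bio10 −
  Bio11) over the same cells. Genus-level and species-complex
  aggregation, and a temporal-stability robustness check, are included.
- **Community temperature index (CTI)** — for a community with *N*
  species, CTI = Σᵢ STIᵢ / N (occurrence-based; an abundance-weighted
  variant Σ aᵢSTIᵢ / Σ aᵢ is provided for comparison).
- **Thermophilisation rate** — the OLS slope of CTI on calendar year at
  each site, after inclusion filters (≥ 4 species, span ≥ 5 years,
  STI coverage ≥ 75%, observations from 1980 on) and effort
  standardisation (99× rarefaction to the series-minimum sample count,
  median across replicates).
- **Immigration/extirpation decomposition** — species fates (persisted /
  added / lost) at each transition, mean-STI contrasts between fate
  groups, and exact one-sided binomial sign tests.
- **Driver models** — REML linear mixed models of rate on z-scored
  predictors (temperature change, community mean body size and niche
  breadth, baseline temperature, richness, series length, and their
  interactions, including a temperature × size × breadth three-way
  term), with study-within-taxon random intercepts, Gaussian spatial
  residual correlation exp(−(d/ρ)²) profiled over a distance grid, and a
  single refit after removing 2-SD residual outliers.

## Worked example

```python
import thermoshift as ts

scenario = ts.SimulationScenario(n_sites=80, n_species=100,
                                 warming_rate=0.04, rng_seed=7)
data = ts.simulate_dataset(scenario, n_records_per_species=100,
                           landscape_shape=(15, 15))
occ, _ = ts.clean_occurrences(data["occurrences"])
profiles, _ = ts.build_thermal_profiles(occ, data["landscape"].grid)
lut = ts.profile_lookup(profiles)
config = ts.AnalysisConfig()
kept, _ = ts.filter_communities(data["observations"], lut, config)
prepped = ts.rarefy_timeseries(kept, config, seed=1, sti=lut)
rates = ts.site_rates(prepped)
print(f"mean rate {rates['rate'].mean():+.4f} degC/yr, "
      f"{(rates['rate'] > 0).mean():.0%} of sites positive")
```

prints

```
mean rate +0.0130 degC/yr, 85% of sites positive
```

i.e. with a programmed warming of 0.04 °C/yr the realised community
composition trends warm at most sites: the CTI slope is positive at 85%
of the 80 simulated communities, against 50% expected with no warming.
The rate is smaller than the temperature trend because occupancy
responds probabilistically and detection is imperfect — community
composition tracks climate with attenuation. The `examples/` scripts
walk each capability: simulation, thermal-affinity estimation, CTI
trends, turnover decomposition, and the driver model.

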