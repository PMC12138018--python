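# heatvuln

Commune-level heatwave-vulnerability scoring for public-health mapping.

Heatwaves kill tens of thousands of people in Europe, yet the tools that
identify vulnerable communities are mostly aimed at urban planners, not at
the primary-care practitioners who see the patients. `heatvuln` implements
the scoring pipeline behind a national heatwave-vulnerability choropleth
for French communes (the smallest administrative unit, mean area
14.9 km²), together with a syndromic heat-morbidity indicator, and a
synthetic geodata generator so the whole pipeline can be exercised and
validated without downloading any national product.

## The index

Four commune-level indicators are combined:

| indicator | construction | orientation |
|---|---|---|
| mean summer surface temperature | per-pixel temporal mean of daily rasters, then zonal mean over pixels whose centre falls in the commune | risk |
| social deprivation (FDep-style) | first principal component of the correlation matrix of unemployment rate, % blue-collar workers (active 15–64), % high-school graduates (≥15), median household income; sign anchored so higher = more deprived | risk |
| artificial / non-vegetated surface | fraction of CORINE land-cover pixels in artificial classes (111–142) or open spaces with little vegetation (331–335); water counts in the denominator only | risk |
| air-conditioning equipment | % of primary residences with an AC unit | protective |

Each indicator x is standardised over all scored communes as a Z-score
z = (x − μ)/σ (population σ), and combined with equal weights, the
protective indicator entering negatively:

    V_i = (z_temp,i + z_fdep,i + z_artif,i − z_ac,i) / 4

Communes are then classed into quintiles of V for mapping. A companion
indicator, **iCanicule**, counts emergency-department and emergency-GP
visits for hyperthermia/heatstroke (ICD-10 T67), dehydration (E86) and
hyponatremia (E87.1) per commune and summer window, as counts and as
rates per 10 000 residents.

## Worked example

Generate a synthetic 10×10-commune study area (urban-heat-island
gradient, one-factor deprivation, Poisson visit counts) and run the whole
pipeline:

```sh
heatvuln run --synth --seed 1 --n-side 10 --out demo
```

```
INFO stage read_units: {'n_units': 100}
INFO stage temporal_mean: {'n_days': 3}
INFO stage zonal_temperature: {'n_scored': 100, 'n_missing': 0, ...}
INFO stage composite_index: {'n_scored': 100, 'n_missing': 0}
INFO stage icanicule: {'n_input': 746, 'n_kept': 746, 'n_dropped': 0, 'n_orphans': 0}
scored 100 units; outputs in demo/outputs
```

`demo/outputs/scores.csv` holds one row per commune:

```
unit_id  z_temperature    z_fdep  z_artificial      z_ac     index  quantile_class
  01001      -1.831684  1.287716     -1.873173 -2.003879 -0.103316               3
  01002      -1.240127 -0.819423     -1.257440 -2.042531 -0.318615               1
  01003      -0.891645  1.064075     -0.859218  0.012483 -0.174818               2
```

Commune 01001 is a cool (z_temp = −1.8), little-urbanised corner commune,
but deprived (z_fdep = +1.3) and almost without air conditioning
(z_ac = −2.0); the protective term therefore pushes its composite index
up to −0.10, the middle quintile (class 3). `demo/outputs/icanicule.csv`
carries the per-commune visit counts by source and cause, with
`rate_per_10k` the seasonal visit rate per 10 000 residents.
`scores.geojson` carries both attribute sets on the commune polygons;
`heatvuln export` renders a quintile choropleth (PNG + GeoJSON) from them.

Individual stages are also available as subcommands (`synth`,
`zonal-temp`, `landcover`, `fdep`, `index`, `icanicule`, `export`) and as
library functions (`heatvuln.zonal`, `heatvuln.deprivation`, …).

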