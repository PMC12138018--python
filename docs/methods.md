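# Methods

## Scope and spatial model

The package scores administrative units (French communes in the intended
use) for heatwave vulnerability and heat morbidity. All geometry lives in
one projected, metre-unit reference system; the default working
projection is RGF93 / Lambert-93 (EPSG:2154), implemented in closed form
(Lambert conformal conic, two standard parallels 44°/49°, GRS80). Vector
input arriving in geographic coordinates is reprojected through this
formula; rasters are never reprojected or resampled — a CRS mismatch is
an error, because silent resampling of temperature or land-cover values
would change results invisibly. The implementation was validated against
the false-origin identity, forward/inverse round-trips, and ellipsoidal
distances along the standard parallel (true scale), which agree with an
independent geodesic computation to sub-millimetre.

Raster convention: origin at the upper-left pixel corner, square pixels,
row index increasing southward. GeoTIFF georeferencing is carried by the
standard tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory,
GDAL_NODATA). GeoJSON is the vector format; `unit_id` is opaque text so
commune codes with leading zeros survive.

## Zonal temperature

Daily rasters are averaged per pixel first (nodata days ignored; a pixel
with no valid day becomes nodata), then reduced per unit. Temporal-then-
zonal order is fixed and documented: the two reductions commute only in
the absence of nodata.

Pixels are assigned to the unit containing their **centre point**; a
centre exactly on a shared boundary goes to the lexicographically first
`unit_id`, so the assignment is independent of feature order. Pixel-
centre assignment (rather than area-weighted overlap) keeps the
operation exact and auditable against a brute-force point-in-polygon
loop; at 100 m pixels against ~15 km² communes the discretisation error
is negligible. Units with zero valid pixels are flagged missing, never
zero-filled — 0 °C is a valid temperature and silent fill would corrupt
the Z-scores.

## Land cover

CORINE codes are grouped by the level-1/level-2 hierarchy: 111–142
artificial, 331–335 open spaces with little or no vegetation, 211–324
vegetated, 411–523 wetlands and water. The exposure numerator is
artificial + open; water stays in the denominator. The source names the
concept ("artificial and non-vegetated surfaces") without listing codes,
so the grouping ships as a plain-text config (`data/corine_groups.txt`)
and alternative readings — e.g. excluding water from the denominator —
are one edit away.

## Deprivation score

The FDep-style score is the first principal component of the
**correlation** matrix (not covariance: the four components have
incommensurable units) of the standardised components, computed on
complete cases with population standardisation (divisor n). Eigenvectors
are sign-ambiguous, so the sign is anchored to a positive correlation
with the unemployment rate: higher score = more deprived. Two equal
leading eigenvalues (within 1e-9) raise an instability error rather than
returning an arbitrary axis. Incomplete units are scored missing and
passed to the index module's imputation policy. The module implements
the construction; it does not reproduce any official national release.

## Composite index

V_i = (z_temp + z_fdep + z_artif − z_ac)/4 over the full non-missing
unit set (the national map compares communes across departments, so
standardisation is national, not per-department). Division by 4 rather
than a raw sum keeps equal weights while leaving V on a z-like scale.
Orientation is data, not code: each indicator column carries
`risk`/`protective`, and the combination refuses columns whose
orientation is absent or inconsistent. Air conditioning is the single
protective indicator.

Missing values: the default imputation is the department median, applied
to the deprivation score only — temperature and land-cover missingness
is structural (no valid pixels) and stays missing. `drop` and
`neighbour_mean` (polygon-adjacent units) are available alternatives.
Units unimputable under their policy stay missing and receive no class.

Mapping classes are k-quantiles (k = 5 by default, the quintile
convention of heat-vulnerability choropleths), inclusive upper edges,
linear-interpolation quantiles; with fewer distinct values than k the
classes collapse to the distinct values with a warning. Both the raw
index and the class are emitted.

## iCanicule

Visits are filtered to a closed summer window and to prefix-matched
diagnosis codes: T67 (heat effects, incl. heatstroke/hyperthermia), E86
(volume depletion/dehydration), E87.1 (hypo-osmolality/hyponatremia) —
the natural ICD-10 reading of the named conditions, shipped as an
editable config with a non-overlap invariant. Units without visits count
0 (absence of events is information in surveillance, not missingness);
records with unknown unit ids are returned as orphans so counts always
reconcile. Both the count and the rate per 10 000 residents are emitted
without endorsing either as canonical. No small-count suppression or
spatial smoothing is applied; small-area rates are statistically noisy
and any disease-mapping model is out of scope.

## Synthetic study area

The generator emulates the statistical structure the index assumes, with
a known ground truth returned alongside the data (`latent_*` / `true_*`
columns are test-only):

- **Communes**: an n×n grid of squares; the default side √14.9 km makes
  the mean area match the 14.9 km² national mean commune area exactly by
  construction. Departments in quadrant blocks; log-normal populations
  (median 2 000, σ = 1), mimicking the long right tail of commune sizes.
- **Urban fraction**: radial urban-heat-island gradient, ≈0.9 at the
  grid centre falling to ≈0.05 at the corners, ±0.02 jitter.
- **Temperature**: pixel = 24 °C baseline + 5 °C × urban fraction +
  N(0, 0.5 °C), three daily rasters with N(0, 1.5 °C) day offsets. The
  5 °C amplitude is a typical surface urban-heat-island contrast; 24 °C a
  plausible June–August daily-mean surface baseline for southern France.
- **Land cover**: within each commune, round(fraction × n_pixels) pixels
  carry an artificial code (112), the rest a vegetated code (311) — the
  realised fraction matches the target within one pixel's worth.
- **Socioeconomics**: one latent factor d ~ N(0,1) with loadings
  (+1, +1, −1, −1) on unemployment / blue-collar / graduates / income
  plus N(0, 0.5) component noise, mapped affinely onto realistic scales
  (e.g. unemployment 10% ± 1.5 per unit of the latent scale, income
  €21 000 ± €2 500). Affine maps preserve all correlations, and the
  slopes are chosen so the schema bounds (percentages in [0, 100],
  positive income) are never hit in practice.
- **AC rates**: clip(15% + 4%/°C × (T − 24 °C), 0, 100) + N(0, 2%),
  re-clipped — uptake rises with local climate.
- **Visits**: per commune, count ~ Poisson(pop/10 000 × 20 ×
  exp(0.5 × true vulnerability)), causes uniform over
  {T67.0, T67.9, E86.0, E87.1}, source ED/GP with probability 0.7/0.3,
  dates uniform over 1 June–31 August 2022.

Every generator draws from a stream seeded by (seed, generator name), so
adding a generator never perturbs existing fixtures and a fixed seed
reproduces every output byte-for-byte.

What the generator does **not** emulate: real commune shapes (squares,
not irregular polygons), real CORINE mosaics (two classes, not 44),
cloud gaps or retrieval artefacts in the temperature product, spatial
autocorrelation of deprivation beyond the single factor, or seasonal
structure in visit dates. Passing tests therefore demonstrate the
correctness of the *computations* — zonal reduction, PCA, Z-scores,
compositing, classing, counting — under a known truth, not the
epidemiological validity of the index on real data.

## Numerical choices

- Standardisation everywhere uses the population convention (divisor n).
- Z-scoring requires ≥ 2 values and non-zero dispersion; a constant
  column is a degenerate-variance error, not a silent zero.
- Quantile edges use linear interpolation; class = smallest c with
  V ≤ c-th k-quantile.
- Composite equality checks hold to 1e-12; geometric and statistical
  invariants (affine invariance, translation invariance, partition of
  land-cover fractions) to 1e-9.
- Eigen-decomposition via symmetric `eigh`; leading-eigenvalue gap below
  1e-9 is an error.
- Test and validation problem sizes — 10×10 communes at 100 m pixels for
  oracle equivalence, 529 communes for factor recovery, 50 replicates
  for the morbidity association — are desk-scale choices that keep the
  whole suite under a minute while leaving no operation untested at a
  non-trivial size.

## Known limitations

- Indicator weights are fixed and equal; weighting by estimated impact
  would require an outcome model and is deliberately out of scope.
- GeoPackage input is not supported; convert to GeoJSON.
- Only EPSG:2154 is registered as a working projection for geographic
  input; any projected metre-unit CRS passes through untouched.
- Commune-level resolution only; no sub-communal (street-level) scoring.
- The deprivation module recomputes an FDep-like score from components;
  it will not numerically match any official release computed on a
  different national basis.
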