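# Methods

This note documents the models implemented in `shrubmap`, the choices
made where the underlying procedures were open, and what the synthetic
study area does and does not emulate.

## Study design

Two invasive understory shrubs are mapped at 1 m resolution: Himalayan
blackberry, which favours open, sunlit, deciduous-associated sites, and
English ivy, a shade-tolerant species associated with coniferous
forest. Because the two strata offer different information — open areas
are visible to the imaging spectrometer while closed canopy hides the
understory — detection is stratified at 20 % canopy cover above 2.5 m:
per species, an *open* random-forest model uses SAM rule images plus
LiDAR-derived predictors, and a *closed* model uses LiDAR-derived
predictors only. The per-stratum maps are merged on the same 20 % break
and validated with a 3 m minimum mapping unit around validation plots.

## LiDAR structure (1 m)

Returns are assigned to pixels by half-open intervals so each return
counts exactly once. Height above ground is the return elevation minus
a bilinear interpolation of the DEM, clamped at zero. Per pixel:

* percentiles use linear interpolation between order statistics (the
  convention is tested against a brute-force order-statistic oracle);
* skewness and excess kurtosis use population moments (normal ⇒ 0) and
  require ≥ 4 returns with non-zero spread, else nodata;
* the coefficient of variation is defined as 0 when all heights are
  equal;
* returns within 0.1 m of the ground model count as ground; *cover
  below 2.5 m* is the fraction of returns above that tolerance and
  below the break, and *canopy cover above 2.5 m* its complement above
  the break.

**Penetration** is defined as the fraction of returns at or below
2.5 m, i.e. the complement of canopy cover. This makes both operational
uses of the term consistent: open areas are pixels with penetration
above 90 % (equivalently, less than 10 % canopy cover), and the
open/closed model stratification uses the 20 % canopy-cover break.
Distance to open areas is the Euclidean distance transform between
pixel centers.

## Orographic predictors

Slope and aspect come from Horn's weighted 3×3 differences; northness
is `cos(aspect)` with aspect the downslope azimuth clockwise from north
(flat pixels: slope 0, northness 0). Curvatures come from the
Zevenbergen–Thorne quadratic surface with the sign convention
*positive = concave* and units of 1/(100 m); a bowl therefore has
positive general and profile curvature. The wetness index is
`ln(a / tan β)` with the specific contributing area `a` from
single-direction (D8) flow accumulation over a priority-flood
pit-filled DEM and `tan β` floored at 10⁻⁶. D8 was chosen over
multiple-direction schemes because its accumulation is exactly
hand-traceable, which makes the oracle tests meaningful; the flow
router sits behind one function and can be swapped.

## Irradiance model (3 m)

Structural inputs are aggregated 1 m → 3 m by block mean (DEM) and
block max (DSM). For each of the eight growing-season days (15th of
March–October) and each whole hour 05:00–22:00 local time:

1. **Solar position** uses the Meeus/NOAA low-accuracy ephemeris
   (geometric, no refraction), accurate to ~0.01°, validated in the
   tests against an independent Astronomical Almanac implementation to
   0.1°.
2. **Atmosphere**: direct-normal irradiance is
   `I₀·E₀·exp(−0.8662·T_L·m·δ_R(m))·c`, with Kasten–Young air mass `m`,
   the standard Rayleigh optical-depth polynomial `δ_R`, Linke
   turbidity `T_L` (scalar, default 3.0, configurable per run) and a
   cloud clearness index `c` (default 0.5). The diffuse component uses
   a Liu–Jordan-type diffuse transmissivity, linear in the beam
   transmissivity and hence a function of turbidity and solar
   elevation; the published source of the original diffuse constants
   does not reproduce them, so the coefficients (0.271, −0.294) are
   explicit configuration.
3. **Viewshed**: per pixel, 36 azimuth sectors; the horizon angle in a
   sector is the largest obstruction angle of the DSM within 100 m,
   seen from 2.5 m above the DEM, floored at 0. The sun contributes
   beam irradiance only when its elevation clears the horizon angle of
   its sector; the sky-view factor is `mean(cos² θ)` over sectors and
   scales diffuse irradiance.
4. **Vegetation**: per 3 m pixel with ≥ 10 canopy returns, a
   two-parameter Weibull CDF is fitted to the empirical CDF of canopy
   return heights by Levenberg–Marquardt least squares (started from
   the log–log linearization; parameter recovery is unbiased within
   5 % at 10⁴ draws). The extinction coefficient is the fraction of all
   returns above 2.5 m. Beam transmission uses the receptor pixel's own
   column only: effective cover is `extinction × (1 − F(z_eye))`, and
   transmission is `(1 − cover)^(1/sin h)`. The single-column
   approximation ignores shading by neighbouring columns' foliage along
   low sun paths; at 3 m pixels and with the horizon viewshed handling
   large obstructions, the residual error is accepted and documented as
   a limitation.

Hourly values are integrated by the trapezoidal rule into daily MJ m⁻²
totals, and the eight monthly totals are averaged into the seasonal
mean, so the seasonal layer conserves the monthly layers by
construction.

## SAM rule images

Reference spectra are extracted from the imagery at the open-stratum
training presence plots (mirroring a field campaign in which plot
spectra are pulled from the georegistered cube). A rule image records,
per open pixel, the *minimum* spectral angle across the species'
reference spectra — the multi-endmember behaviour of standard SAM
tooling; an angle-to-mean-spectrum mode is available. Band subsets are
fixed configuration: the key discriminating channels per species under
the 72 × 9.6 nm band model starting at 363 nm, with half-open intervals
so each wavelength maps to exactly one channel.

## Detection models

Candidate predictors are every structural, orographic, distance and
irradiance layer plus (open stratum) the four rule images and the
land-cover class code. Selection iterates: fit the 2000-tree forest,
drop predictors with negative permutation importance (the
mean-decrease-accuracy analog; scikit-learn does not expose the
original out-of-bag MDA), then for every pair with |Pearson r| ≥ 0.7
drop the less important member, until a fixed point (≤ one iteration
per predictor). Presence uses the 0.5 majority vote; uncertainty is
`U = 1 − max(p, 1 − p) ≤ 0.5`. Features are read at the plot's recorded
(GPS-jittered) pixel; a 3 m-window mean is available but the default
stays single-pixel. Training rows whose pixel has an undefined
predictor (e.g. a rule-image nodata at a stratum edge) are dropped.

## Validation

A plot scores as predicted-present when any presence pixel center lies
within 3 m of its recorded coordinate (pixel-center disc membership).
Metrics follow the standard definitions; kappa is Cohen's kappa with
marginal-product expected agreement; reporting rounds percentages to
one decimal and kappa/TSS to two, and the implementation reproduces all
published reference metric rows at that precision. Per-plot uncertainty
takes `1 − max p(true class)` over the disc.

## Spatial analysis

Abundance is the exact count of presence pixels per 100 m cell (total
conserved). Local Moran's I uses row-standardized queen weights on
deviations from the grid mean with `m₂ = Σz²/n`; significance is by
conditional permutation (999 draws of each cell's neighbours from the
remaining cells, seeded); HH/LL cells are clusters and HL/LH outliers,
and the summary percentages cover significant invaded cells only.
Distance profiles bin the Euclidean distance transform from roads (or
impervious surfaces) and report absolute and proportional invaded area
per bin; bins partition the map so the areas sum to the total.

## Synthetic study area

The generator is the package's study-conditions module, not a test
fixture. It emulates: band-limited random-field terrain; a land-cover
mosaic with stable class fractions (quantile thresholds on a smooth
field: ~27 % deciduous, ~27 % coniferous, grass, bare, water, straight
road corridors with flanking buildings); forest canopy height/cover
fields; species placement by thresholded preference scores that encode
the two shrubs' ecology (blackberry: open, deciduous, sunlit; ivy:
closed, coniferous, shaded; under closed canopy each species keeps to
its preferred forest type — the strong-signal regime); a Poisson
(25 returns/m²) point cloud with ground, species-specific understory,
and Weibull-distributed canopy strata; a linear-mixture reflectance
cube from five-parameter leaf templates with 0.6 % Gaussian noise
(inter-species angles 0.07–0.13 rad, well above the noise angle of
~0.02 rad); and field plots in patches ≥ 40 m², pairwise ≥ 10 m apart,
with uniform-disc GPS jitter ≤ 3 m and a stratified train/validate
split at the survey's 646:496 ratio.

Deliberate idealizations, and hence what passing tests do *not* show
about real data: linear two-endmember mixing with i.i.d. Gaussian noise
(no atmosphere residuals, shadows, or within-canopy spectral
variability); understory signatures cleanly tied to species identity;
plot sites kept clear of the 20 % stratum boundary and absence sites
kept ≥ 8 m (jitter + disc + margin) from species patches so no
validation disc covers true presence by construction; and closed-canopy
niches made forest-type exclusive. Real surveys violate all of these,
which is why the original study's closed-canopy skill (TSS ≈ 0.5) is
lower than what the pipeline achieves on the synthetic scene; the
synthetic conditions are designed to verify that the pipeline recovers
a strong signal when one exists, not to predict field accuracy.

Default problem sizes: 300 m × 300 m scene at 1 m (≈ 2.3 M returns),
30 presence plots per species per stratum plus 64 absences per stratum
(≥ 60 presences and absences per stratum), 2000-tree forests; a full
run takes a few minutes on one CPU. Unit tests use a 200–240 m scene
with proportionally fewer plots.

## Degenerate inputs and tie-breaks

Empty point cloud → all-nodata stack with a warning; no open pixels →
nodata distance raster with a warning; flat DEM → nodata TWI with a
warning; constant abundance grid → Local Moran's I raises; zero
spectral vector → nodata angle; all-equal heights → CV 0 and nodata
moments; correlation ties during variable selection drop the
lexically-later member (deterministic under the run seed).
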