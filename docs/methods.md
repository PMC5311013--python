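# Methods

This note documents the models, algorithms and numerical choices behind
`lidar_agb`, and what the synthetic experiments do and do not demonstrate.

## Problem setting

Airborne discrete-return LiDAR supports two common representations of
forest structure for aboveground biomass (AGB) estimation: the *echo-based*
data model, in which structure metrics are computed directly from the 3D
cloud of height-normalized returns, and the *canopy height model* (CHM), a
1 m raster holding the highest return per cell, from which the same metrics
are computed over pixels. Because survey point density is the dominant cost
driver of LiDAR campaigns, the package quantifies how thinning a cloud from
a high reference density (20 returns/m²) down to 10, 5 and 1 returns/m²,
and varying field-plot size from 0.09 to 1.0 ha, affects (i) ten standard
structure metrics under each data model and (ii) AGB predictions from
power-law models calibrated at the reference density.

## The ten metrics

Height statistics — MaxH, MeanH, P25H, P50H, P75H, P90H, StdH and
CV = StdH/MeanH — are computed over *canopy* returns, i.e. returns with
height ≥ 2 m (the threshold is inclusive and configurable). For the CHM
they are computed over **all** valid pixels with no canopy cut, since each
pixel already represents the top surface; this asymmetry is deliberate and
is itself one source of the data models' different density sensitivity.
Percentiles use linear interpolation between order statistics ("type 7",
numpy's default); the test suite pins this convention against an
independent sort-and-index oracle. A consequence of type 7 is that
percentiles of a duplicated sample can shift by up to one
inter-order-statistic gap; the duplication-consistency test therefore
asserts invariance at that gap scale rather than exactly.

Fractional cover (FC) is the fraction of all returns (any class, any
return number) at or above a cover threshold. The threshold defaults to
the 2 m canopy threshold but is a separate parameter, because in tall
closed-canopy tropical forest a much higher cut (e.g. 27 m) tracks biomass
better. Whether real surveys should use first returns only in the
numerator or denominator is a genuinely open convention; both filters are
exposed as configuration and the default uses all returns.

AUCW (area under the canopy waveform) summarizes the vertical distribution
of canopy material. The exact construction varies in the literature; here
it is fully specified as: histogram canopy-return heights in 0.5 m bins
from the canopy threshold to MaxH rounded up to the next bin edge,
normalize the bin fractions to sum to 1, integrate the fractions against
bin centres by the trapezoid rule, and divide by the height range so
plots of different canopy depth are comparable. A plot with no canopy
returns reports FC = 0, AUCW = 0 and NaN height statistics — NaN rather
than zero so that downstream regressions exclude such plots instead of
absorbing them.

## CHM construction

Rasterization snaps a grid (default 1 m) to the plot bounding box and
keeps, per cell, the maximum height and the *position* of the argmax
return. Cells of circular plots whose centre falls outside the footprint
are excluded permanently. Empty in-plot cells are filled by interpolating
over the Delaunay triangulation of the registered per-cell maxima at their
true return positions. The interpolation contract is: constant fields are
reproduced to machine precision and planar fields to 1e-6 inside the
convex hull; cells outside the hull stay nodata and are excluded from
metrics, because extrapolation has no support in the triangulation. The
implementation uses barycentric linear interpolation on the Delaunay
triangulation (scipy's `LinearNDInterpolator`), which satisfies the
contract exactly; any interpolant with the same two properties (e.g.
Sibson natural-neighbour) is an acceptable drop-in, and the tests assert
the contract rather than the algorithm. Interpolating an already-complete
raster is a no-op; fewer than three non-collinear generators leaves the
raster unchanged with a warning.

## Thinning and density accounting

Thinning keeps a uniform random subset, without replacement, of exactly
`round(target_density × plot_area)` returns — individual returns, not
pulses, which mirrors how density reduction is typically emulated in
retrospective studies but does *not* reproduce the covariation of footprint
size and return statistics that a real lower-PRF or higher-altitude survey
would show. Density is counted over all returns of any class. Thinning is
always per plot after clipping, is a strict subset operation, and records
its seed and target in the cloud's provenance. Sub-ground heights after
DEM normalization are clamped to 0 above −0.5 m and dropped below it.

## Statistics

Per metric and condition pair, per-plot differences (paired by plot id,
NaN pairs dropped with a count) are tested with a two-sided Wilcoxon
signed-rank test: zeros dropped, mid-ranks for ties, exact null by
convolution for n ≤ 25 after zero removal (mid-ranks are handled by
doubling the ranks to an integer lattice), and a normal approximation with
tie and continuity corrections above. The exact path is verified against
full 2ⁿ sign enumeration and against scipy on tie-free inputs; its
measured type-I error at n = 60, α = 0.05 is ≈ 0.048 — slightly below
nominal purely through the discreteness of the exact distribution. A
two-sided one-sample t-test accompanies each comparison for reference, and
a Lilliefors-style Kolmogorov–Smirnov screen (normal reference with
estimated parameters, via statsmodels) reports normality but never gates
which test is used. α defaults to 0.05 with no multiple-testing
correction across the metric × condition grid (a Holm option exists,
default off). Every experiment condition draws its thinning seed from the
master seed by the counter scheme (seed, plot index, size index, density
index), so any cell of the grid is re-runnable in isolation and the whole
grid is bit-reproducible.

## AGB models

Both model forms, ŷ = αXᵝ (X = mean canopy height) and ŷ = αx₁ᵝx₂ᵞ
(x₂ = FC), are fitted by nonlinear least squares on the original scale,
initialized from OLS on log y vs log X (and log x₂). The log-linear start
is kept as a floor: if the optimizer cannot improve its SSE the start is
returned flagged unconverged, so the fit never underperforms the log-OLS
solution. Parameter SDs come from the asymptotic covariance. A log-scale
OLS mode exists for sensitivity analysis. Evaluation reports R² about the
observed mean, RMSE in Mg/ha, and relRMSE = 100·RMSE/mean(observed AGB of
the evaluation set); protocols are a seeded 70/30 plot-level holdout
(calibration size = round(0.7 n), n ≥ 5) or leave-one-out jackknife for
small samples (n ≥ 4), which also yields per-fold parameter means and SDs.

Cross-density transfer applies the reference-density fit to thinned-density
metrics of the same plots and reports the RMS difference between
thinned-input and reference-input predictions as a percent of the mean
reference prediction — the AGB error attributable to the density change
alone — alongside a standard evaluation against field AGB.

## The synthetic study

No suitable public LiDAR + field-plot dataset accompanies this problem at
desk scale, so the generator produces studies with the statistical
structure the analysis assumes, with known truth:

* **Stands.** 100 independent 1 ha stands (100 × 100 m). Stems follow a
  homogeneous Poisson process at 500 trees/ha — a closed-canopy moist
  forest above a ~10 cm census threshold. Trees are also placed in a 10 m
  buffer around the extent so crowns overhang the edges and boundary cells
  are not artificially sparse. Heights are 3 m + Weibull(shape 2.2) with
  the scale varied 8–25 m *between* stands: the between-plot height
  gradient that AGB models exploit. Crown ratio is 0.6 (crown base at 40%
  of height) and crown radius 1.2 + 0.18·height (m), giving ≈ 0.9
  projected cover.
* **Returns.** Exactly `round(20 × area)` pulses per stand at uniform
  planimetric positions, one return each. Under a crown the return sits at
  the local paraboloid crown envelope minus an exponential penetration
  offset with mean 10% of crown depth, truncated at the crown base — this
  is the mechanism that makes observed maxima (and CHM cell maxima) grow
  with density and hence shrink under thinning. 15% of pulses penetrate
  to the ground anywhere; gaps always yield ground returns at height 0.
  Vertical noise (sd 0.05 m) is truncated at ±3 sd so the height-bounds
  invariant is hard rather than probabilistic. The ground is flat at
  elevation 0 with a zero DEM emitted alongside: normalization is
  exercised but trivially invertible.
* **Field AGB.** Per tree, a synthetic stem diameter dbh = 0.8·h^1.4·
  lognormal(sd 0.15) cm feeds the power-law allometry
  agb_kg = 0.06·dbh^2.4·exp(ε), ε ~ N(0, 0.3²); plot AGB is the tree sum
  over the field geometry in Mg/ha.

What this emulates: the power-law AGB–height relation with multiplicative
noise, density-dependent sampling of the canopy envelope, realistic height
percentile behaviour, and CHM gap formation at low density. What it does
not: terrain and DEM error, multi-return pulse structure, scan-angle and
footprint physics, sensor noise correlated with range, spatial
autocorrelation between plots, and allometric model error structure beyond
lognormal scatter. Consequently, passing the qualitative-replication suite
shows the *pipeline* reproduces the expected directional phenomena on data
with known structure; it does not validate magnitudes for any real forest.

## Experiment problem sizes

The replication study uses 100 plots, densities {orig = 20, 10, 5, 1}
returns/m² and plot sizes {0.09 (circle), 0.25, 0.5, 1.0 (squares)} ha,
with the 1 ha square as the reference size; these sizes keep the full
factorial run at roughly two minutes on one CPU. Bit-reproducibility is
asserted on an 8-plot sub-study re-run end to end; the thinning and
metric-ordering contracts are asserted across every condition of the full
grid.

## Known limitations

* CHM metrics on circular plots use centre-in-footprint cell selection;
  partial edge cells are all-or-nothing.
* The exact Wilcoxon path is O(n·Σranks) per call; it switches to the
  corrected normal approximation above n = 25.
* `read_point_cloud` supports the plain CSV dialect out of the box; LAS
  requires the optional `laspy` extra, and rasters are exchanged as ESRI
  ASCII grids rather than GeoTIFF.
* Negative interpolated CHM values cannot arise for clouds whose heights
  are non-negative (linear interpolation stays within the generator
  range); real-data use with sub-ground noise should clamp first.
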