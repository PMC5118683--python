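# Methods

## Change model

The unit of analysis is the big grid cell: a block of B × B pixels
(default B = 10; 2.5 × 2.5 km for the nominal 250 m pixel, cell area
6.25 km²). For cell *i*, class *k*, year index *t* = 0…n−1, the observed
cover fraction is

    f_ikt = (valid pixels of class k in cell i, year t) / (valid pixels in cell i, year t)

and the trend model is simple linear regression
f_ikt = a_ik + b_ik·t + ε_ikt with iid errors. The slope b (fraction yr⁻¹)
carries a two-sided t test with n−2 degrees of freedom; cells with p < α
(default α = 0.1) are change hotspots. Net change over the series is
Δf = b × L and ΔA = Δf × cell_area, with one-standard-deviation uncertainty
SD = se(b) × L × cell_area, where L is the span multiplier in years.

**Span convention.** For a 13-year annual series the multiplier is L = 13,
although 13 annual observations span only 12 inter-year intervals. This is
the convention of the analysis style the package implements, and it is kept
as-is rather than silently corrected; `endpoint_change` makes the
discrepancy visible (a noiseless slope of 0.02 yr⁻¹ gives an endpoint
difference of 0.24 but a regression net fraction of 0.26). Users who prefer
the interval count can pass `interval=12`.

**Regressor choice.** Regression runs on the year index, not calendar
years; the slope, its SE and p-value are invariant to this shift, only the
intercept changes.

**Assumptions.** Errors are treated as iid across years within a cell;
under classification noise they are approximately binomial/multinomial
proportions over ~100 pixels, close enough to Gaussian for the t test (the
type-I error stays within [0.08, 0.12] empirically). No multiple-testing
correction is applied across cells or classes — each (cell, class) series
is tested at α independently, so with ~8 classes × many cells a null
landscape still flags ≈10% of series; the zonal tables should be read with
that in mind. Significance is a per-cell mask, not a family-wise claim.

**Degenerate series.** A constant series gets slope 0 and an undefined
(NaN) p-value, reported non-significant (total variation ≤ 1e-24 counts as
constant, absorbing float round-off). A perfect linear fit with nonzero
slope (residual sum ≤ 1e-12 of the total variation) gets p = 0. Cells with
any year lacking valid pixels, or fewer than 3 years, are nodata in all
layers.

**Masking and conservation.** Because fractions over the *full* legend sum
to 1 in fully valid cells and OLS is linear, per-cell slopes over all
legend classes cancel exactly (≤1e-9). The fraction denominator therefore
counts all valid pixels, including classes outside the eight-class analysis
set, so the analysis-set fractions may sum to less than 1. Significance
masking breaks cross-class conservation of zonal totals: gains of one class
can be significant where the compensating losses are spread below the
significance floor. The unmasked net areas, which do cancel (≤1e-6 km² per
cell), are retained alongside the masked layers.

**Partial-validity cells** keep the reduced denominator rather than being
dropped, to avoid biasing edge (coast/water) cells; `--min-valid` on the
CLI can void cell-years below a pixel count. Trailing partial edge blocks
are dropped and counted.

**Zonal accounting** assigns each cell to the zone covering its center
pixel (offset B//2 in each axis) when the zone map is at pixel resolution;
zone SDs assume independent cells: sd_zone = sqrt(Σ sd_cell²). Gains and
losses are accumulated separately before netting.

**Detection floor.** One map pixel on the 231.656 m sinusoidal grid is
5.3 ha (truncated to one decimal); sub-pixel conversions cannot enter any
fraction series.

## Classifier fusion

Where all models agree, the pixel keeps the agreed class (flagged
consensus). Otherwise the fused posterior is the weighted arithmetic mean
of the models' per-class membership vectors — equal weights by default, or
proportional to supplied overall accuracies — and the label is its argmax,
with exact ties resolved to the lowest class code and counted. Arithmetic
(rather than geometric) pooling is a design choice: it is the standard
model-averaging combination, keeps the fused vector on the simplex, and is
well defined when a model assigns an exact zero.

## Synthetic scenarios

The generator emulates the data regime the method targets: an initial
mosaic with exact per-region class counts (largest-remainder apportionment,
seeded placement), then constant-rate conversions within named regions.
Yearly demand converts the cumulative target `round(t·rate·N_region)` so the
expected fraction trajectory is exactly affine in t; `clustered` mode
converts the eligible pixels nearest (Euclidean distance, ties row-major)
to existing target-class cover — contiguous rings and fronts — while
`random` mode samples eligible pixels uniformly. Infeasible demand fails
loudly with region/class/year.

Observation noise relabels each pixel-year independently with probability
`noise_rate`, drawing the replacement from a row-stochastic confusion table
(default: uniform over the other classes). No statistical model of real
classification error is claimed; the confusion-flip model is a stand-in
that produces iid fraction noise at cell level. Anomaly years substitute a
one-year elevated noise rate — a transient perturbation, not a level shift —
which is the failure mode endpoint differencing is sensitive to and the
regression resists.

Ground truth is computed from the configuration, never from a realization:
per-region designed net areas are exact (rate × region pixels × L ×
pixel area); per-cell designed slopes (±rate × cell∩region overlap / B²)
are exact in expectation for `random` mode with spatially uniform initial
cover of the source class, and only approximate for `clustered` mode, where
the conversion front sweeps cells in sequence. Recovery tests therefore
score per-cell estimates against random-mode or direct Gaussian-noise
scenarios and clustered scenarios against region totals.

The `linear_fraction_cube` generator bypasses the categorical layer and
adds iid Gaussian noise (default sd 0.03) directly to designed fraction
series. Values are deliberately not clipped to [0, 1], so
(b̂ − b)/se(b̂) is exactly t(n−2)-distributed: the ±1 SD coverage of the
designed net change is 2·P(t₁₁ ≤ 1) − 1 ≈ 66.1%, which the coverage checks
target with a ±3-point band.

**Classifier-output fixtures.** Each simulated model labels a pixel
correctly with probability equal to its reliability and uniformly wrongly
otherwise; the probability vector is a Dirichlet draw (concentration 100)
whose mean puts the reliability's mass on the *assigned* class. Label
accuracy therefore equals the reliability in expectation; the mean mass on
the *true* class is necessarily lower (for reliability r > 0.5 no symmetric
scheme can give the true class mean mass r while keeping argmax accuracy
at r). Labels always equal the realized argmax.

**What passing tests do not show.** Synthetic scenarios have linear trends,
stationary iid noise, and hard labels; real map series carry spatially and
temporally correlated classification error, nonlinear and abrupt change
(fire, flood), and registration drift. The linear model cannot represent
nonlinear change, and correlated errors would widen the true uncertainty
beyond the reported SD.

## Problem sizes and numerics

Test and acceptance runs use grids of 50–320 pixels square, 13 years, and
1,000–20,000 cells per statistical check — sizes chosen so Monte-Carlo
standard errors are several times smaller than the acceptance bands (e.g.
20,000 cells put the coverage SE near 0.3 points against a 3-point band)
while any run completes in seconds. All randomness flows through
`numpy.random.default_rng` with explicit seeds; identical configuration and
seed reproduce every artifact bit-exactly.

Raster artifacts are multi-band TIFFs with a JSON sidecar carrying the
affine transform (GDAL order), CRS string, band semantics and analysis
provenance (block size, interval, alpha, years, cell area); tables are
CSV with fixed headers. No reprojection or resampling is performed —
inputs must be co-registered.
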