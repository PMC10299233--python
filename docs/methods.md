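# Methods

This note documents the models, conventions and numerical choices behind
scaffoldquant, and what its synthetic-data validation does and does not
demonstrate about acquired data.

## Pore analysis (transversal cuts)

Segmentation is plain binary thresholding followed by connected-component
labeling. The threshold method is Otsu by default with a fixed-threshold
override; whichever is used is recorded in the output for audit, since
SEM contrast varies between sessions. Polarity (dark pores on bright
walls, or the inverse) is an explicit parameter for the same reason.
Labeling uses scikit-image's implementation; any correct labeling
algorithm — including the optimized block-based two-scan variants — is
output-equivalent, and the test suite enforces equivalence with a
brute-force flood fill on random masks for both 4- and 8-connectivity.
Default connectivity is 8, which avoids splitting thin diagonal lamellae;
it is configurable.

Per-pore geometry: area is the component pixel count times the squared
pixel scale; the bounding box is axis-aligned; the aspect ratio is
bounding-box width divided by height with no min/max reordering, so
values below 1 mean taller-than-wide (lamellar) pores and values above 1
are possible. Border-touching components are retained but flagged —
peripheral pores in real scaffolds partially collapse and excluding them
silently would bias counts. Components below `min_area_px` (default 5)
are dropped and counted as noise; holes inside pore walls are not
filled. The pixel scale is always a required user input: micrograph
metadata is not parsed and no default magnification is assumed.

Distributions are normalized densities (they integrate to 1 over the bin
range) with linear or logarithmic binning, plus the five-number box-plot
summary. Pore areas in freeze-cast scaffolds are approximately
log-normal, which is why the generator draws them that way and the stats
module offers a log-normal fit with a D'Agostino K² test on log-values.

## Orientation analysis (longitudinal cuts)

Gradients are 3×3 Sobel filters with reflective borders. The structure
tensor is the Gaussian-smoothed outer product of the gradient; the
integration scale `window_sigma` defaults to 2 px. Sigma 0 degenerates
to the pointwise rank-1 tensor whose coherency is identically 1 wherever
the gradient is nonzero; it is supported but discouraged for anything
but noise-free synthetic imagery.

The reported feature orientation is the direction of the eigenvector of
the *smaller* tensor eigenvalue — perpendicular to the dominant gradient
— mapped to [0, 180) with the y-axis pointing up. This makes vertical
channels report 90° and horizontal ones 0°/180°, and makes a
counter-clockwise image rotation by δ shift the reported angle by +δ
(mod 180), which the rotation-equivariance tests assert at δ = 15°, 30°,
45°. Coherency is (λ₁ − λ₂)/(λ₁ + λ₂), defined as 0 where the tensor
trace vanishes (within a relative floor of 1e-12 of the field's maximum
trace, so constant images give exactly 0 and intensity rescaling cannot
change the result).

Histograms weight each pixel's angular vote by its coherency, so
isotropic or flat regions contribute nothing. Density is reported per
degree (integrates to 1 over [0, 180)); this convention is stored in the
histogram metadata because a per-bin convention would rescale values by
the bin width. Default bin width is 1°, and the bin width must divide
180 evenly. The ROI is explicit user input; the default is the full
image minus a 3 px border where Sobel responses are one-sided.

## Mechanics

Conversion uses engineering stress and strain with the nominal initial
cross-section π·d²/4 — hydrated scaffolds in a PBS bath preclude optical
area tracking, and no transverse measurement exists in the log. The
zero reference is the first sample at which the load-cell force reaches
the pre-tension weight-equivalent (default 3 g at g = 9.80665 m/s²);
earlier samples are discarded, strain is measured from that sample's
displacement, and the pre-tension force is subtracted from the stress so
the curve starts at the origin of the pre-tensioned state. The gauge
length is a required user input (the distance between anchors after
mounting, not the nominal specimen length) and the nominal dry-mold
diameter is the default section, flagged in output metadata.

Region segmentation works on a Savitzky–Golay-smoothed stress trace
(cubic, window equal to the sliding-fit window, polynomial edge fitting
so a clean piecewise-polynomial curve is reproduced exactly, including
its terminal value). Failure is the first sample where the smoothed
stress drops more than `failure_fraction` (default 30%) below its
running peak; the drop rule is armed only once the running peak exceeds
a quarter of the global maximum, so noise around zero stress at the
start of a test cannot trigger it. A curve that never drops ends in a
censored "end of course" failure at the last sample.

The linear region is found in two passes. Detection: sliding windows
(default width one eighth of the strain span) are fitted by least
squares; windows whose slope is within 2% of a reference plateau slope
and whose R² is at least 0.99 qualify, and the longest contiguous run
wins. The reference slope is the 75th percentile of all window slopes:
on a clean curve this equals the plateau slope, while the maximum —
which noise inflates by several standard errors — would push the
threshold above every true plateau window. Refinement: half a window is
trimmed from each end of the run (curvature bleeds that far in), a line
is fitted to the core, and the boundaries are walked outward while the
smoothed stress stays within a deviation tolerance of
max(1.5·10⁻³ of the fitted span, 4 robust SDs of the core residuals).
This locates toe and yield onsets to well under a window width on clean
curves and degrades gracefully under noise. If no window qualifies, the
module falls back to the fixed 3–6% strain window typical of soft-tissue
curves and flags the result.

The viscoelastic modulus is the least-squares slope of raw stress versus
strain (as a fraction) over the detected linear region — this package's
operationalization for a single monotonic ramp, not a cyclic or
relaxation measurement. Maximum tensile strength is the maximum of the
smoothed stress up to failure (raw maxima ride on noise peaks);
elongation at break is the strain at the failure sample.

## Statistics

Factorial ANOVA is an OLS fit via statsmodels with interactions up to a
chosen order; unbalanced designs use Type II sums of squares by default
(I and III selectable) and the convention is recorded in every result.
Tukey–Kramer all-pairs comparisons are computed in-package from the
studentized-range distribution with the 1/nᵢ + 1/nⱼ unequal-n
correction and the one-way pooled MSE; the statsmodels implementation
serves as an independent cross-check in the tests, not as the
implementation. Stars map adjusted p-values as ns (≥0.05), * (<0.05),
** (<0.01), *** (<0.001). The experimental unit is whatever the rows of
the input table are; the package does not attempt to infer whether
pores, images or scaffolds are the unit of replication — that caveat
travels with the results. Normality and homoscedasticity are not
enforced; diagnostics are advisory.

## Synthetic data: what it emulates, and what it does not

Pore fields are ellipses (real lamellar pores are ovoid) with log-normal
areas (defaults: log-mean 7.5 in log-µm², log-SD 0.6, i.e. a median
around 1800 µm²), truncated-normal bounding-box aspect ratios (mean
0.67, SD 0.2, matching the magnitudes reported for freeze-cast
collagen/chitosan scaffolds), and a configurable major-axis angle
(default vertical). Non-overlap is enforced by rejection sampling with a
2 px dilation margin so 8-connected labeling cannot merge neighbors,
bounded at 10,000 attempts per pore before an infeasible-packing error.
The ground-truth table stores both the analytic draw and the rasterized
geometry; re-rasterizing the table with the same pixel-center rule
reproduces the image mask exactly, which is what makes the recovery
tests exact. The generator does *not* emulate SEM texture, charging
artifacts, wall-thickness variation, or partially collapsed peripheral
pores — pipeline recovery on these fields demonstrates algorithmic
correctness, not robustness to acquisition artifacts.

Channel fields are periodic stripe textures with anti-aliased edges
(~1.5 px ramp) at a controlled angle and duty cycle. Clean stripes have
a single global orientation, so they validate conventions and
equivariance, not performance on curved or branching channels.

Stress–strain curves use a slope profile that ramps quadratically from 0
to the modulus across the toe (any smooth convex form would do), stays
constant through the linear region, then decays linearly through yield
to a terminal slope solved so the stress reaches the target strength
exactly at the break strain, where the test ends (end-of-course). Specs
whose strength is unreachable (or overshot) under this profile are
rejected as inconsistent. Sampling is 1%/s strain rate at 100
samples/s. The recovery ensemble draws modulus and strength
independently (500–4000 kPa × 50–150 kPa) and scales the canonical
region layout (toe 0–3%, linear 3–6%, yield 6–7%, break 8%)
geometrically so every draw is feasible with the strength at the middle
of its reachable band; stress noise is Gaussian with SD uniform in
[0, 5%] of the strength. Real curves fail abruptly or raggedly;
the ensemble's end-of-course convention means elongation recovery there
is easier than on brittle specimens.

Temperature logs are a linear ramp (default −1 °C/min from 20 °C)
followed by an isothermal hold (default −40 °C for 90 min) sampled at
10 Hz with optional Gaussian jitter. Ramp verification fits the cooling
rate on the *nominal* ramp window and summarizes the hold plateau;
the segment split deliberately comes from the nominal profile rather
than change-point detection so jitter cannot move the boundary.

All generators are pure functions of their spec including the seed; no
global random state is used anywhere.

## Numerical conventions

CSV output is comma-separated UTF-8 with a header row and '.' decimals;
images are 8-bit grayscale TIFF/PNG; orientation fields dump as 32-bit
float TIFF. Histogram and distribution densities integrate to 1 within
1e-9. Degenerate inputs fail loudly: constant images for Otsu, empty
record lists, untextured ROIs, logs that never reach pre-tension, and
saturated ANOVA designs each raise a specific error rather than
returning NaNs.

## Validation sizes

The test suite and `scripts/acceptance.py` use: 500 random ≤32×32 masks
for labeling equivalence; 20 noise-free pore fields of 10–200 pores on
1024² images at 2 µm/px (log-mean 7.2, log-SD 0.5, chosen to keep
200-pore fields at a realistic ~7% area fraction and packable without
overlap); 200 tensile curves from the recovery ensemble; 1000 null
replicates of a 2×2 design with n=5 per cell for ANOVA calibration; and
100 random 3–5-group datasets for post-hoc monotonicity. The full suite
runs in well under two minutes on one CPU; the acceptance script in
about half a minute.
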