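# Methods

## Scope and design

The package reconstructs a chain of quantitative-microscopy measurements
used to study heat-regulated PI4P polarity in budding yeast: line-scan
polarity ratios, prominence-based puncta detection with binary
ER-association classification, thresholded-overlap colocalization, FRAP
mobile-fraction estimation, aggregation-state scoring, and sedimentation
densitometry.  Raw imaging data for such studies is generally not deposited,
so each measurement is validated by parameter recovery: a synthetic
generator renders the input with a known ground truth, the measurement runs
blind to that truth, and the test checks the recovered value.  Ground truth
is carried in separate objects (`CellPairGeometry`, `FieldTruth`,
`FrapTruth`) that the measurement code never reads.

## Synthetic data: what it emulates and what it does not

**Noise model.**  All image generators apply Poisson shot noise on the
signal plus additive Gaussian read noise over a constant camera bias,
emulating EMCCD acquisition without modeling EM gain.  The single `snr`
parameter fixes the total relative noise at the reference intensity: the
Poisson gain is chosen so shot noise contributes half the variance and read
noise the other half, giving total SD = `base_intensity/snr` at the base
intensity.  `snr = inf` disables noise and yields the deterministic mean
image, which the exactness tests rely on.  Published acquisition SNR and
camera bias are not stated anywhere we could anchor to; the defaults
(snr 10, bias 100 counts) are plausible spinning-disk values and are
exposed as parameters.

**Cell pairs.**  Mother and daughter are axis-aligned ellipses (defaults
90×72 px and 48×40 px at 0.1 µm/px, i.e. ~9 µm and ~5 µm cells) whose
membranes are Gaussian-profiled rings of FWHM `pm_thickness` (2 px).  The
two cells are separated by a small neck gap (`neck_offset`, 4 px between
membranes) so that a horizontal line through both centers crosses exactly
four distinct membranes — two per cell — matching the two-peaks-per-cell
averaging rule of the estimator.  Touching or overlapping ellipses are
rejected as degenerate geometry.  The marker channel carries equal membrane
intensity on both cells; the reporter carries `ratio_true`-fold higher
intensity on the daughter ring.  A uniform cytoplasmic/extracellular
background (20 counts against a 1000-count membrane) is included; it is
*not* subtracted by the estimator, which biases measured ratios slightly
toward 1 (−2% at ratio 7.5) — well inside the 10% recovery band and
representative of how line scans are read in practice.

**Cortical fields.**  The ER network is a random walk of tubule segments
plus occasional elliptical patches, dilated to ~3 px tubules and grown
until pixel coverage reaches `er_coverage` (default 0.30).  ER-on pixels
draw intensities uniformly from `er_intensity_range` (200–400 counts);
ER-free pixels stay at or below `background_max` (100 counts), so the two
intensity populations are separable by construction, as they are for a
well-expressed luminal ER marker.  Exactly `round(assoc_fraction_true ·
n_maxima)` spot centers are placed on ER pixels, the rest on ER-free
pixels, all with a minimum separation (6 px) enforced by rejection
sampling; Gaussian spots (σ 1.5 px, amplitude 500) form the puncta channel.

**FRAP stacks.**  Each simulated series holds one bleached 5×5 punctum and
two never-bleached reference puncta on a dim diffuse background.  The
bleached ROI follows the single-exponential recovery with ground-truth
mobile fraction and rate; the whole field decays by
e^(−incidental_rate·frame); a constant (optionally x-graded) bias is added
per pixel; and a 100-frame dark stack is provided for bias correction.
The published bleaching protocol used several short laser cycles; these are
collapsed into a single effective `bleach_depth` (default 0.8), since only
the post-bleach trace, not the bleach kinetics, enters the analysis.

**Not modeled:** 3-D/z-stacks, PSF convolution beyond Gaussian spots,
photophysics (blinking, triplets), cell-to-cell expression variability,
drift, and autofluorescence.  Passing recovery tests therefore demonstrate
estimator correctness under the stated noise and geometry, not robustness
to every artifact of real acquisitions.

## Measurement details and numerical choices

**Line profiles** are sampled by bilinear interpolation (matching the Fiji
line-profile default) on the half-open segment [p0, p1) at 0.5 px spacing;
coordinates are 0-based (x, y) with pixel centers at integers.  Line width
is 1 px (no transverse averaging); this is exposed nowhere because profile
peaks, not areas, are consumed downstream.

**1-D peaks** are local maxima with topographic prominence at least a
threshold; plateaus report their integer-rounded centroid.  The default
threshold is 3× a robust noise SD — 1.4826·MAD of the profile's first
differences divided by √2 — so it adapts to each profile without a global
tuning constant.

**Polarity estimation** finds marker peaks within each cell's stretch of
the line, takes reporter peaks within ±2 px of a marker peak as membrane
candidates (the coincidence window; the protocol's "coincided" carries no
stated tolerance), and averages the two highest candidates per cell.
Cells with fewer than two coincident peaks in a segment are flagged and
excluded from cohort statistics rather than raising, preserving per-cell
counts.  The ratio is exactly Fd/Fm, so it is invariant to common scaling
of both channels and inverts exactly under daughter/mother relabeling.

**2-D maxima** follow the noise-tolerance path criterion (ImageJ Find
Maxima semantics): a pixel is accepted iff no path to a strictly higher
pixel exists along which intensity stays above value − tolerance.  The
implementation activates pixels in descending order into a union-find
structure tracking component maxima and evaluates each pixel exactly when
its threshold is crossed (O(n α(n)) after the sort); a brute-force
per-pixel breadth-first search of the criterion serves as the test oracle.
Two consequences of taking the criterion literally: equal-valued maxima
separated by a shallow saddle are *both* reported (ImageJ would merge
them; ties are measure-zero on noisy data), and a constant image reports
no maxima by convention.  Borders act as −∞ neighbors, so edge pixels are
eligible.  8-connectivity throughout.

**ER-association threshold.**  `min_specific` is the 1st percentile of
ER-mask intensities and `background_max` the 99th percentile of ER-free
intensities — percentiles rather than extrema to resist single-pixel
outliers — and the binary threshold sits midway between them
(interpolation factor 0.5, exposed).  Non-separable ranges raise.  A
maximum whose ER intensity equals the threshold counts as associated
(≥, not >).

**Marker masks** default to an Otsu-seeded half-maximum contour: Otsu
separates foreground coarsely, then the mask is cut at background median +
half of the robust (95th-percentile) peak over background.  Plain Otsu is
available but includes the dim fringe of smooth membrane profiles,
overestimating contour area by ~20%.

**FRAP.**  Bias correction subtracts the mean of up to 100 dark frames and
clips at zero.  The automatic reference region is the brightest quartile of
above-Otsu, never-bleached pixels of the mean pre-bleach frame; dim
background pixels are excluded because their zero-clipped noise decays
differently from fluorescent signal and would distort the normalization.
Normalization is N(t) = [roi(t)/ref(t)]·[mean(ref_pre)/mean(roi_pre)], so
the pre-bleach mean of every normalized trace is exactly 1.  The recovery
fit initializes F_post at the first post-bleach value, F∞ at the mean of
the last three points, and k at ln2 over half the post-bleach window, with
bounds k > 0 and F∞ ≤ 1.5.  When the fitted k·T_post < 1 the plateau is an
unconstrained extrapolation (k → 0 trades off against F∞ at its bound, a
degeneracy that otherwise turns flat immobile traces into clipped
mobile-fraction-1 fits); the plateau then falls back to the endpoint
estimate (mean of the final 20% of frames), which is also available
throughout as a model-free cross-check mode.  Mobile fractions outside
[0, 1] are clipped with a warning; non-convergent fits are flagged and
excluded from cohort means.

**Aggregation scoring** erodes the cell mask by a 3 px cortical band
(~0.3 µm) and calls a cell aggregated iff any detected maximum lies in the
eroded interior; a single interior punctum suffices (strict rule).  This
is a stated re-operationalization of what the original assay scored
visually.

**Statistics.**  Pairwise comparisons default to Welch's t (the original
legends do not state Welch vs Student; Welch is the robust choice and
Student is a flag away); multi-group comparisons use one-way ANOVA.  Two
zero-variance groups with equal means return p = 1 by convention.  No
multiple-testing correction is applied, matching single-pairwise-test
usage.  Calibration tests confirm both tests hold their nominal 5% type-I
error within ±0.01 over 10⁴ null simulations.

## Problem sizes

The recovery suites use the cohort sizes of the analyses they emulate:
40/45 cells for the 26 °C/42 °C polarity cohorts and 105/117 for the
wild-type/osh3∆ comparison; 1000 puncta per cortical field (three fields
averaged in the reproduction script); 22 FRAP ROIs in vivo and 8 in vitro
at 5% noise; triplicate sedimentation rows per temperature.  Oracle
equivalence for the maxima finder runs on 500 random 6×6–10×10 integer
images, where exhaustive search is exact and fast.

## Known limitations

- Cell segmentation, bud detection, and tracking are out of scope; line
  placement and cell-segment intervals come from the generator's geometry
  (or would come from manual annotation on real data).
- The background of the reporter channel is not subtracted before peak
  reading, so extreme ratios carry a small toward-1 bias (see above).
- The FRAP model is a single-exponential recovery; diffusion-model FRAP
  (Soumpasis/Axelrod) and reaction-diffusion inference are not provided.
- The maxima finder's plateau handling follows the stated path criterion
  exactly, which can differ from ImageJ on images with exact ties.
- TIFF I/O covers 8/16-bit grayscale single- and multi-page files only.
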