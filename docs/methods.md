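# Methods

`cardiocohere` quantifies *brain-heart coherence*: how tightly beat-to-beat
heart-rate dynamics track regional BOLD activity and inter-regional dynamic
connectivity, and whether that coupling changes between experimental
conditions (a suspenseful movie, a neutral movie, rest). This note records
the models, the parameters that matter, the numerical choices, and what the
synthetic benchmark does and does not establish.

## Cardiac preprocessing

The cardiac input is a beats-per-minute (BPM) series at a nominal 1 Hz,
assumed to come from an upstream beat detector; beat detection itself and
heart-rate-variability metrics are out of scope (the coherence measures
operate on second-to-second BPM dynamics, where ultra-short-window HRV is
unstable). The fixed chain is:

1. **Gap filling.** Interior missing samples are filled with a cubic spline
   through the valid samples; missing samples before the first (after the
   last) valid one take the first (last) valid value. With fewer than four
   valid samples the spline is underdetermined and linear interpolation is
   used, flagged in provenance.
2. **Savitzky-Golay smoothing.** Window 15 samples (15 s at 1 Hz),
   polynomial order 3 by default. The source analysis does not state its
   smoothing parameters; these defaults sit at typical heart-rate smoothing
   scales and are configurable. Edges are handled by polynomial fits on
   truncated windows, so polynomials up to the fit order pass unchanged.
3. **Resampling with hemodynamic lag.** The continuous interpolant is
   evaluated at `t_k = k*TR - lag` with TR = 0.7 s and lag = 6 s, matching
   the canonical delay between a physiological event and the peak BOLD
   response. The shift is exact in seconds, not rounded to whole TRs
   (6 s = 8.571 TRs); grid times before the first sample take the first
   value, so the lag pads the head. The upsample-then-shift order in the
   original description is ambiguous at non-integer TR multiples; the
   continuous evaluation makes the two orders identical.
4. **Legendre detrending.** Residual of a least-squares projection onto
   Legendre polynomials of degree 0..p on time mapped to [-1, 1], with
   p = 1 + floor(duration / 150 s) — the standard automatic drift-order
   rule (an 8 min run gets p = 4, a 5.5 min run p = 3). The heart-rate
   trace uses the same order as its paired fMRI run.
5. **Z-normalization** with the n-1 denominator. The coherence measures are
   correlation-based and scale-invariant, so the denominator convention
   only affects reported traces.

## fMRI denoising

Each voxel or ROI series is residualized against a nuisance design:
Legendre drift columns (same automatic order), CSF and WM mean signals, and
the 24-parameter motion expansion (6 raw parameters, their first
differences with a leading zero, and the squares of all 12). Designs with
condition number above 1e10 are rejected with the offending columns named.
ROI series are unweighted means over mask voxels; masks are
nearest-neighbour resampled in world space onto the functional grid. The
voxel-wise branch additionally smooths to 6 mm FWHM with a plain Gaussian
kernel (sigma = FWHM / sqrt(8 ln 2) per axis, reflecting boundaries — a
documented simplification of iterative smoothing-*to* a target FWHM; the
reflecting boundary conserves per-volume mass but does not reproduce any
specific tool's edge behaviour). Smoothing is never applied on the ROI
branch.

## Dynamic connectivity

For every unordered ROI pair, a per-TR correlation series: Gaussian weights
centred at each timepoint (sd = window/3 ~ 9.7 TRs), truncated at the
29-TR (20.3 s) window half-width and renormalized — the sd is the one free
parameter the source description leaves open; window/3 keeps >= 99% of the
untruncated mass inside the stated width. The weighted Pearson correlation
is Fisher-transformed (r clipped at 1 - 1e-7 to keep z finite) and the
series is z-normalized. Output is full length: near the edges the kernel is
truncated rather than samples dropped, keeping the connectivity series
aligned with the heart-rate trace. A degenerate pair (identical series;
constant z) cannot be z-normalized and is returned flagged instead.

## Coherence estimators

Per subject x condition x target (10 ROI activity series + 45 edges):

* **Bivariate coherence** — Fisher z of the Pearson correlation between the
  6 s-lagged, z-scored heart-rate trace and the neural series.
* **DTW distance** — dynamic time warping with squared-difference local
  cost, symmetric (diagonal/left/up) recursion, anchored endpoints, and a
  Sakoe-Chiba band of 14 TRs (~10 s), confining the alignment to
  quick-acting co-fluctuations. The distance is the square root of the
  accumulated cost, *not* path-normalized: distances are only compared
  across conditions after the longer condition's head is trimmed
  (`match_condition_lengths`) so both contribute the same number of TRs.
  Trimming removes the opening of the longer (suspense) condition.
* **Cross-correlation maxima** — the largest positive Pearson correlation
  over a grid of whole-TR offsets spanning +-10 s around the
  hemodynamically lagged alignment, i.e. raw-HR-to-BOLD delays from
  6-10 = -4 s (BOLD precedes the heart rate) to 6+10 = 16 s. The original
  tool searched one-sidedly with an extra 10 s shift worked into the
  heart-rate series and an under-documented polarity; the symmetric grid is
  this package's documented superset of that search. The reported value is
  the Fisher z of the maximum positive r with its delay in seconds; with no
  positive correlation anywhere the value is 0, flagged. A minimum overlap
  of 30 samples guards spurious maxima at extreme offsets. Applied per
  voxel (brain = nonzero-variance voxels) this yields the lag map. Note the
  maximum over a grid is selection-biased upward under the null; group
  inference contrasts conditions, which share the bias.

## Group inference

Within-subject condition differences go to two-tailed paired t-tests
(t = mean/ (sd/sqrt(n)), df = n-1) with paired Cohen's d = mean/sd.
Bonferroni families mirror the study design: the five a-priori activation
ROIs (bilateral amygdala, bilateral anterior insula, dmPFC) test at
alpha/5 = .01; every other ROI or edge target tests at alpha divided by the
*total* roi+edge target count (55 for the 10-region network, .0009 at four
decimals). A target sits in exactly one family here; the original
exploratory family nominally re-included the hypothesis ROIs, a bookkeeping
difference with no effect on the edge tests. Subjects missing a condition
are excluded listwise per target (logged); zero-variance differences are
flagged and dropped.

Voxel-wise lag-map contrasts use sign-flip permutation cluster-extent
correction: per-voxel paired t thresholded two-tailed at voxel-wise
p < .001, clusters by face connectivity (NN1; NN2/NN3 configurable — the
original tool's connectivity level is not stated), and a null built by
randomly negating subject difference maps (exhaustive when 2^n does not
exceed the permutation budget, otherwise seeded Monte-Carlo), recording
each permutation's maximum cluster extent over both signs. Sign flips leave
per-voxel sums of squares unchanged, so all permutation t-maps come from a
single matrix product. The extent threshold is the ceiling of the
(1-alpha) 'higher' quantile of the null maxima; a cluster survives when its
corrected p = (1 + #{null max >= extent}) / (n_perms + 1) is at most alpha.
The original analysis reported a k > 16 threshold from its data; this
package always recomputes the threshold from its own null. Integer extents
tie heavily on small grids, making the procedure mildly conservative —
measured family-wise error on smoothed null maps sits just below the
nominal level but inside its binomial sampling band.

## Synthetic benchmark

The generator is the package's ground truth and encodes the minimal
structure the coherence measures assume; the source study is observational
and states no generative model.

* **Heart rate**: 1 Hz BPM = subject baseline (mean 66, between-subject sd
  9 bpm) + condition offset (suspense +1.41, control -1.41, rest +0.53,
  reproducing the observed ~2.8 bpm suspense-control separation and
  ordering) + slow sinusoidal drift (2 bpm, 120 s period) + stationary
  AR(1) fluctuation (coefficient 0.9, marginal sd 1.5 bpm). A 5% fraction
  of samples is missing completely at random (never the endpoints);
  oximeter artifact structure is not modelled. Condition durations default
  to the study's 480/330/420 s.
* **ROI activity**: y = beta * zHR(t - 6 s) + Legendre drift + white noise,
  with the lagged regressor standardized so the population correlation with
  it is exactly beta / sqrt(beta^2 + sigma^2) (verified by Monte-Carlo).
  Default beta: +0.3 control, -0.3 suspense, 0 rest.
* **Edges**: two series sharing a latent s(t) ~ N(0,1) with gain
  g(t) = clip(0.6 + b * zHR(t - 6 s), 0, 2) plus independent unit noise —
  the simplest mechanism making windowed correlation track lagged heart
  rate; b = +0.4 control / -0.4 suspense reproduces the qualitative
  sign-reversal finding (positive coherence under control, reduced/negative
  under suspense).
* **Volumes**: a 12x12x12 grid (2.5 mm voxels) whose central 3^3 blob
  carries the lagged signal (coupling 1.0) over drift + thermal noise.

Everything is reproducible from the config seed via per-subject x condition
spawned streams.

What passing the benchmark does *not* show: the generator has Gaussian
noise, linear coupling, no respiration or vasomotion, no motion artifact,
no inter-edge dependence, and condition effects injected as clean offsets —
real-data effect sizes, confound structure, and the behaviour of the
estimators under physiological noise are outside what these tests certify.

## Problem sizes and numerical choices

The Monte-Carlo suites use scaled-down study conditions chosen once:
150/120 s condition durations for the calibration and directional-effect
replications (n = 29 subjects throughout), 200 s single-condition runs and
12^3 or 10^3 grids for lag-map recovery, 500-1000 sign-flip permutations
with 12 subjects for cluster inference. Tolerances: z-scored traces are
validated to 1e-9; design-residual orthogonality to 1e-6 relative;
Fisher clipping at |r| = 1 - 1e-7; weighted-variance floors at 1e-15 of the
squared data scale. Degenerate inputs (constant series, zero-variance
differences, masks that resample to nothing) raise named errors rather
than propagating NaNs.

## Known limitations

Upstream stages (fMRIPrep-style realignment, beat detection, mask
derivation) are inputs, not code. The DTW distance is unnormalized, so it
is only meaningful between equal-length series. The Gaussian-kernel sd of
the dynamic-connectivity stage is the chief free parameter for sensitivity
analysis. The lag-search polarity convention follows this package's
symmetric-superset definition and may differ from other tools' sign
conventions when comparing lag values directly.
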