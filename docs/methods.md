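# Methods

This note documents the models implemented by `optonotch`, what the
synthetic-data generators do and do not emulate, and the numerical choices
made where the underlying published procedures leave freedom.

## Spot detection (`spotcall`)

Each movie frame runs through a fixed cascade: (1) per-z-slice 3×3 median
filter; (2) subtraction of a per-slice 100×100 mean-filter background;
(3) maximum z-projection; (4) subtraction of the projection's 30×30
median-filtered version; (5) Gaussian filter with σ = 3 px, the size of a
diffraction-limited spot at the emulated sampling (0.13 µm/px); (6) the
candidate blobs are the connected regions where the Laplacian of the
filtered image is negative, i.e. regions bounded by the Laplacian's zero
crossings; (7) blobs outside configurable area and intensity bounds are
rejected.

Numerical conventions that the cascade's description does not pin down:

* **Interior sign.** "Bounded by zero crossings" does not say which side
  of the crossing a blob lies on.  We take the negative-Laplacian side
  (the interior of a bright blob); connectivity defaults to 8.
* **Even windows.** The 100×100 and 30×30 windows have no centre pixel;
  we anchor them with the extra row/column toward larger indices.  All
  filters use reflect padding.
* **Negative values.** Background subtraction may produce negatives;
  they are kept through segmentation (clipping would bias weak spots) and
  clipped to zero only where integrated intensities are measured, so
  reported intensities are non-negative.
* **Rejection thresholds.** The original analysis curated final masks by
  hand.  Here curation is replaced by the area bounds (default 8–400 px:
  the negative-Laplacian core of a σ = 3 spot after the σ = 3 smoothing
  covers ≈ 115 px, while the large background plateau forms one huge blob)
  and a data-dependent intensity threshold (default 0 = off).  A useful
  rule of thumb on this pipeline's synthetic movies is ≈ 0.4 × 2πσ²A for
  mean spot amplitude A.
* **Centroids** are intensity-weighted centres of mass on the clipped
  background-subtracted projection (sub-pixel).

Frames smaller than a filter window raise an error naming the offending
stage rather than silently shrinking the window.

FISH-style single-time-point calling (`call_fish_spots`) reuses the same
cascade and then assigns each spot the nucleus label under its centroid;
nuclei may carry 0, 1 or 2 (or more) foci, and spots outside any nucleus
are flagged rather than dropped.

## Activation kinetics (`kinetics`)

The tissue-level readout is the spot-density curve n(t): distinct spots
per frame divided by the measured mesectoderm length (µm), with times
aligned so ventral-furrow onset is t = 0.  It is fitted by least squares
with

    N(t) = N_max (1 − exp(−k (t − t₀))),   N(t) ≡ 0 for t < t₀,

* **Clamping.** The formula is negative for t < t₀; clamping to zero is
  the only sensible reading and makes leading all-zero time points
  informative rather than harmful (the fit is invariant to adding them).
* **N_max** is the number of nuclei that can activate.  It is a required
  input (ground-truth census for synthetic data, user census for real
  data); the method holds it constant and adjusts only k and t₀.
* **Optimization.** A fixed grid of starting values (8 log-spaced k ×
  ~7 t₀ candidates up to the first nonzero point) refined with
  `scipy.optimize.least_squares` (tolerances 1e-15); best residual wins.
  The fit is deterministic given the data, and recovers noiseless
  model-generated curves to 1e-6 relative error.  An all-zero curve is
  reported as non-converged with k and t₀ missing, never as k = 0.
* **Estimator behaviour.** On stochastic 60-nucleus simulations at the
  default regime the median relative error of k̂ is 8–10 %; most of this
  is intrinsic sampling noise (the maximum-likelihood rate from the raw
  onset times has ≈ 9 % median error at n = 60).  Detection misses bias
  k̂ slightly downward when N_max is taken at the full census.
* **Onset-delay statistic.** Condition comparisons use the fitted t₀,
  which is noise-robust, rather than the first nonzero frame; the raw
  first-detection time remains available from the curve itself.
* **Tests.** Condition tables report mean ± s.e.m. of k and t₀ per
  condition and Welch (unequal-variance) two-sample t-tests against the
  control — the unequal-variance flavour is our choice where only a
  "two-sample t-test" is specified.  Single-embryo conditions are
  reported without p-values.
* **Rates in tissue units.** The initial slope of the density curve is
  k·N_max/L (spots·min⁻¹·µm⁻¹).  `synthgen.per_nucleus_rate` converts a
  tissue rate to a per-nucleus k given the linear nucleus density, which
  must be user-supplied: the density of the mesectoderm rows is a
  property of the tissue, not of the method.

**Intensity stability.** The stability report separates temporal from
population variability: `cv_over_time` is the mean over tracked spots of
each spot's CV across frames; `cv_within_timepoint` is the mean over
frames of the CV across spots within the frame.  The per-spot (rather
than population-mean) temporal CV is used deliberately: averaging ~60
spots per frame would shrink any temporal fluctuation by ~1/√n and the
statistic would no longer measure the stability of individual
transcription sites, which is the biological question (ON/OFF behaviour).

## Cluster kinetics (`clusterquant`)

Clusters are the connected components above median + m·MAD (default
m = 3) of the frame's strictly positive pixels, minimum size 2 px.  Both
statistics scale with the image, so segmentation and index are invariant
under intensity rescaling; computing them over the positive support keeps
a large zero background from dragging the threshold to zero.  The
clustering index is (Σ intensity inside clusters)/(total intensity): the
"number of clusters × mean cluster intensity" numerator equals the summed
in-cluster intensity because the mean is over per-cluster *integrated*
intensities.  The rise is fitted with index(t) = P(1 − 2^(−t/t½)) by
multi-start least squares; flat or collapsed series are flagged
non-converged.  On noise-free synthetic movies the measured index tracks
the generating clustered fraction to < 0.02 (the residual is the membrane
base intensity inside the small cluster footprint), and t½ = 40 s is
recovered within 10 % at 5 % plateau noise and 2-s sampling.

## Membrane and interface measurements (`memquant`)

* **Interface profiles** are sampled with `skimage.measure.profile_line`
  at ~1 px steps, averaging 7 px perpendicular to the line.  The dominant
  peak of the σ = 1 px smoothed profile is found with a prominence-based
  peak finder (prominence configurable; the original used an unspecified
  peak routine).  The raw profile is integrated over 0.78 µm centred at
  the peak by the trapezoidal rule with linear interpolation at the
  window edges; windows truncated by the profile ends set a `clipped`
  flag.  Against the closed-form Gaussian-ridge integral
  A·σᵣ·√(2π)·erf(0.39/(√2 σᵣ)) the error is < 0.1 % at 0.05 µm pixels
  and decreases monotonically under refinement.
* **Normalization** divides each interface integral by the per-embryo
  median of the reference region (default ectoderm).
* **Membrane bands**: each cell label is eroded by a disk of radius
  round(0.3 µm / pixel size); the band is the removed rim (physical
  thickness within one pixel of 0.3 µm), the cytoplasm is the remaining
  interior, and the ratio is cytoplasm mean / band mean.  Cells that
  vanish under erosion are flagged.  The band mean includes whatever
  diffuse cytoplasmic floor overlaps the band — there is no background
  subtraction — so depletion estimates assume the membrane signal
  dominates the band, as in the synthetic lattice (floor 1 % of ridge
  amplitude).
* **Colocalization** runs the spot detector per channel in single-frame
  mode and classifies each channel-A particle by ≥ 1-pixel overlap of its
  segmented mask with any channel-B mask.  Coordinates are 0-based pixel
  centres throughout; distances convert to µm via the pixel size.

## Clone-border statistics (`clonescore`)

An SOP is "at the border" when its Euclidean distance to the clone
boundary (via distance transforms, offset half a pixel so
boundary-adjacent pixels count) is at most `border_band_px` — the
operational version of scoring borders by eye; the default band is one
proneural-cluster radius.  Per-pupa tallies summarize as mean ± s.d. of
the inside percentage; the pooled counts get an exact two-sided binomial
test against 0.5 (our choice of null test; only percentages ± s.d. were
originally reported), and two conditions are compared by a Welch t-test
on per-pupa percentages.  `genotype_ratio_test` is the same exact
binomial machinery applied to a printed cross count.

## The synthetic generators (`synthgen`)

The generators define the study conditions; all are deterministic given
their seed, and all record complete ground truth.

* **Spot movies.**  Two parallel rows of static nuclei (3 µm spacing,
  4 µm between rows, 0.13 µm pixels).  Nucleus i switches ON at
  t₀ + Exp(k) minutes — irreversibly, since once ON the reporter's dot
  intensity is stable — and shows a 2-D Gaussian spot of σ = 3 px.  The
  per-spot mean amplitude is lognormal with CV 0.75 between spots; the
  per-frame amplitude fluctuates lognormally around that mean with CV
  0.20 (lognormal is our choice; only the CV magnitudes are given).
  Defaults: t₀ = 30 min after the start of the interphase, k = 0.3 min⁻¹
  (so ≈ 95 % of nuclei are ON within 10 min of the first onsets, and the
  implied tissue rate k·N_max/L is 0.2 spots·min⁻¹·µm⁻¹ at the default
  geometry), amplitude 500 on background 100, movie 25–55 min at 0.5-min
  frames.  Not emulated: photobleaching and blinking, 3-D PSFs, nuclear
  movement or division (the analysed interphase has none), embryo
  curvature.  Passing detection tests on these movies therefore
  demonstrates correctness of the segmentation and bookkeeping, not
  robustness to drift or bleaching.
* **Cluster movies.**  A square membrane lattice carries fixed total
  mass M; at time t a fraction f(t) = f_max(1 − 2^(−t/t½)) of M sits in
  small disks at fixed membrane sites, the rest uniformly on the
  lattice.  Mass is conserved exactly per noise-free frame.  Defaults:
  t½ = 40 s, 2-s frames over 6 min.  The cluster footprint is ≈ 1 % of
  the membrane so the measured index can track f(t) closely.
* **Interface images.**  A rectangular cell lattice; each edge is a
  ridge with Gaussian cross-section (σ = 0.15 µm).  Left-half cells are
  "ectoderm", right-half "mesoderm" with ridge amplitude multiplied by
  the depletion factor (default 0.3, i.e. 70 % depletion).  Cytoplasm is
  a faint uniform floor (1 % of the ridge amplitude) per region.
* **Vesicle fields.**  Channel-A disks (r = 2 px) are placed on a
  jittered grid whose guaranteed centre separation (≥ 13 px) exceeds the
  detector's blob-merging distance; a Bernoulli(overlap) subset receives
  a channel-B partner within half a radius (certain ≥ 1-px mask
  overlap), the rest get B spots at least 16 px from every A centre so
  that even the broadened detected masks cannot touch.  The ground truth
  records the per-vesicle indicator, so the estimator can be compared to
  the realized (not just nominal) overlap.
* **Clone tissues.**  The clone is the left half-plane; each
  boundary-straddling proneural cluster yields one SOP that falls inside
  with probability exp(β)/(1+exp(β)).  β = 0 reproduces the 50 % null;
  β = ln(94.6/5.4) ≈ 2.86 gives the strongly biased condition.

## Orchestration (`pipeline`, `cli`)

`RunConfig` (YAML-loadable) validates all module configs before any
computation; a SHA-256 hash of the analysis parameters (excluding the
output path) is stamped into every output.  One master seed drives every
stochastic stage through per-stage derived seeds, so reruns are
byte-identical.  TIFF output is ImageJ-compatible (resolution tags,
`spacing`, `finterval` in seconds); 2-D/3-D/4-D TIFFs are normalized to
T×Z×Y×X on read (trailing axes are Y, X; a declared Z axis without T maps
to Z, any other third axis to T), and a file without a recoverable pixel
size raises unless an override is given.

## Problem sizes in tests

The test-suite simulations use the default study conditions at sizes
chosen to keep each check sharp but quick: detection performance on one
60-nucleus, 40-frame movie at SNR 5; kinetics recovery over 20 replicate
embryos; colocalization coverage over 200 seeded 50-vesicle fields;
clone-test calibration over 1,000 simulated 100-SOP tissues; statistical
power and type-I checks of the condition comparison on simulated
rate estimates (the estimate distribution, not full movies, since the
fit itself is validated separately).

## Known limitations

* The detector is tuned for diffraction-limited spots at σ ≈ 3 px; very
  dense fields (centre separation below ~2√2·σ_eff) merge blobs.
* The saturating-exponential fit assumes a known, constant N_max; an
  over-stated census biases k̂ downward.
* The clustering index conflates cluster and membrane-base intensity
  within the cluster footprint; with large cluster footprints it
  overestimates the clustered fraction.
* Interface measurements assume a single dominant peak per profile;
  double-membrane profiles (two abutting cells resolved separately) need
  narrower integration windows than the default.
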