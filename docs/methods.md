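# Methods

`smlmkit` implements the quantitative analyses used to characterize membrane
protein complexes — canonically the γ-secretase protease (PSEN1, NCT, APH1,
PEN2) — at the plasma membrane with single-molecule microscopy: two-channel
spot colocalization, subunit counting, single-particle-tracking motility, and
nanodomain (hotspot) analysis. Each stage is paired with a simulator that
plants ground truth, so every estimator in the package is validated by
recovery rather than by eye.

## Nearest-neighbor colocalization

Spot centroids are detected per channel (local maxima above an intensity
threshold seed a watershed; each basin contributes one intensity-weighted
centroid). For each query-channel centroid we record the Euclidean distance
to the nearest reference-channel centroid. Distances are **asymmetric**
(query → reference), which matches how association is reported per channel;
run the channels in the opposite order for the reverse direction.

The null model is empirical: each query ROI (cell) is paired with every
*non-corresponding* reference ROI, after affine-rescaling the reference ROI
into the query frame, and all distances are pooled. For independent
homogeneous Poisson channels this control reproduces the analytic 2-D
nearest-neighbor law `P(D > r) = exp(−πρr²)`, which is used in the tests as
an independent check but never as the control itself. Matched and control
distributions are compared with a two-sided Mann-Whitney test.

Associations are distances below 100 nm — the lateral resolution of
structured illumination microscopy, so co-resolution cannot be claimed below
it — with a tighter 50 nm fraction reported alongside. Both thresholds are
configuration constants.

Because a GFP tag is non-fluorescent with probability ~0.2, even perfectly
paired channels show only ~80% association; the simulator reproduces this by
independently deleting each molecule with the configured dark probability
before emission.

## Subunit stoichiometry

Two independent routes:

**Photobleaching steps.** Spot-intensity traces are segmented by penalized
least-squares change-point fitting (optimal partitioning, O(n²) dynamic
program with cumulative-sum segment costs). The penalty is
`sensitivity · σ̂² · log n` with σ̂ estimated robustly from first differences
(median absolute deviation of `diff/√2`), i.e. a BIC-scaled penalty whose
`sensitivity` knob (default 2.0) maps inversely to detection eagerness. Steps
are downward transitions between fitted levels; net-increasing traces are
flagged rather than rejected. On noise-free staircases the segmentation is
exact for 1–5 steps; at a 5:1 step-to-noise ratio ≥95% of simulated traces
are scored with the planted count.

**Intensity-histogram decomposition.** The late-movie intensity distribution
(after most tags have bleached) estimates the one-fluorophore ("unit")
density; the two-fluorophore density is its discrete self-convolution; the
early-movie histogram is fitted as `w·pdf₁ + (1−w)·pdf₂`. With two
components the least-squares weight has a closed form (projection clipped to
[0, 1]); higher orders (iterated convolutions) use non-negative least
squares and are off by default. Binning is Freedman–Diaconis on the unit
sample, shared across epochs, for fit stability. Different conventions exist
for the early window (frames 1–30 vs the first 100 frames); the default is
frames 1–30 and the window is configurable, with only spots present in the
early window entering the fit.

**Dark-fraction correction.** With per-tag fluorescence probability
`p = 1 − q` and a fraction `f_d` of complexes carrying two tags, the visible
two-unit fraction is

    f₂ = f_d·p² / (f_d·(1 − (1−p)²) + (1 − f_d)·p) = f_d·p / (1 + f_d·(1−p))

(at `p = 0.8`, `f_d = 1` this gives 2/3 ≈ 67%), inverted in closed form as
`f_d = f₂ / (p − f₂(1−p))`. Observed fractions above the attainable bound
`p/(2−p)` are out of the model: the standalone function raises with the
bound, the mixture estimator flags the fit instead of failing.

## Motility analysis

Per track, the time-averaged MSD is computed over all overlapping point
pairs at each frame lag (displacements spanning gaps simply do not
contribute). Two fits per track:

* **Diffusion coefficient** — OLS line through the first four nonzero MSD
  lags (no (0, 0) anchor), `D = slope/4` for 2-D diffusion; the free
  intercept absorbs the static localization-error floor (≈ `4σ_loc²`,
  verified at σ_loc = 16 nm). Negative slopes are floored at `D = 0` and
  flagged.
* **Anomaly exponent** — bounded nonlinear least squares of
  `MSD(t) = Γ·t^α + k` with `Γ > 0`, `k ≥ 0`, `α ∈ (0, 2]`. The textbook
  relation `MSD = t^α + k` is dimensionally incomplete, so the amplitude Γ
  (µm²/s^α) is a deliberate addition. The fit uses the first half of
  available lags (long-lag TA-MSD is noisy on ≤ 50-frame tracks) and
  inverse-variance weighting reflecting the TA-MSD error structure
  (sd growing as `MSD·√lag`); unweighted linear residuals bias the ensemble
  mean of per-track α upward by ~0.05–0.08 on 50-frame tracks, the weighted
  fit keeps it within ~0.03 of the generating exponent. Initialization is a
  log-log slope after offset subtraction, with two fallback restarts.

Classification: tracks with `D ≤ 0.01 µm²/s` are immobile (inclusive
boundary; this is the instrument's ~50 nm resolution footprint,
log₁₀D = −2) and are excluded before α is consulted. Mobile tracks are
confined (α < 0.1), anomalous (0.1 ≤ α < 0.9), Brownian (0.9 ≤ α ≤ 1.1), or
directed (α > 1.1). The published interval endpoints overlap at 0.9; the
package resolves them as half-open intervals so the partition is exhaustive
and mutually exclusive. Whether a reported mean exponent is a per-track mean
or an ensemble-MSD fit is convention-dependent, so `MotilityClassifier`
reports both (`mean_alpha_` and `ensemble_alpha_`).

## Hotspot analysis

Hotspots are DBSCAN clusters of localizations: eps = 80 nm, minPts = 20
(reading "minimum localization density of 20" as the DBSCAN core-point
threshold — an interpretation, recorded as such), and a minimum of 18
localizations per cluster so a hotspot holds more than one short track;
whole-cell PALM mode uses eps = 100 nm and ≥ 10 localizations. Input points
are sorted lexicographically before clustering so border points reachable
from several clusters resolve deterministically regardless of input order.
Footprints are convex hulls (area in µm²); collinear or 2-point clusters
have no area and are reported missing.

A diffraction-limited projection (localizations binned at 100 nm pixels,
blurred with a 200 nm-FWHM Gaussian, thresholded at the 0.99 intensity
quantile) yields binary masks for Pearson and Mander's M1/M2 overlap between
channels. A track is associated with a hotspot when at least one of its
localizations lies inside the footprint polygon (≥ 1 interior point; the
association rule is artifact-defined since the original counting was
manual); association reports per-hotspot visit counts, the fraction of
hotspots visited, and diffusion coefficients of visiting vs non-visiting
tracks.

## Synthetic data

All generators draw from a single seed through `numpy.random.SeedSequence`
spawning, so one seed reproduces an experiment bit-for-bit and distinct
seeds give statistically indistinguishable ensembles.

* **Spot maps** — channel A homogeneous Poisson at the configured density
  (default 10 spots/µm²); a configurable fraction of channel-B molecules
  placed at an A-partner plus an isotropic Gaussian offset (default scale
  20 nm, standing in for the tag-to-tag linker separation of up to ~60 nm);
  every molecule independently dark with probability 0.2 by default.
* **Bleach traces** — `k` fluorophores drawn from configurable weights
  (default 0.35/0.30/0.20/0.15, monomers most abundant followed by dimers),
  per-fluorophore bleach times i.i.d. *truncated* exponential (mean 30 s)
  so every trace ends at background and all planted steps are observable;
  unit step plus Gaussian read noise; default 2 min at 0.1 s/frame.
* **Intensity populations** — 1- or 2-tag complexes; each tag's intensity
  is an independent lognormal draw (default mean 100 a.u., CV 0.35 — the
  single-fluorophore distribution is not pinned down by the source data, so
  a lognormal typical of EMCCD single-fluorophore statistics is the
  configurable default); dark-fraction thinning drops dark tags and
  all-dark complexes.
* **Tracks** — 50 frames at 0.05 s/frame (one acquisition cycle) with
  16 nm i.i.d. Gaussian localization error by default. Brownian: increments
  of variance `2DΔt` per axis (default D = 0.15 µm²/s). Anomalous:
  fractional Brownian motion with Hurst `H = α/2` (default α = 0.844),
  generated *exactly* by Cholesky factorization of the analytic increment
  covariance — exact generation is cheap for ≤ 50-frame tracks and removes
  simulation bias as a confounder in exponent-recovery tests. Directed:
  Brownian plus constant drift in a random direction. Confined:
  Ornstein–Uhlenbeck per axis (stationary RMS radius = corral radius; a
  standard corralled-diffusion surrogate, since the motion classes are
  defined only through α ranges). Immobile: pure localization noise, or
  residual diffusion at a configurable sub-threshold D.
* **Hotspot tables** — homogeneous Poisson background plus Gaussian
  clusters of planted counts; overlapping configurations allowed but
  flagged.

What the generators do **not** emulate: camera/PSF image formation, mEOS3.2
blinking (multiple localizations per molecule), track-linking errors,
drift, or the optics of density-reduction pre-bleaching (emulated only as
low spot density). Recovery of planted parameters therefore demonstrates
estimator correctness under the stated stochastic models, not robustness to
those instrument artifacts.

## Validation scales

Recovery suites use 600–2000 tracks of 50 frames, 5000-spot intensity
populations, and 50 random instances per oracle-equivalence check
(nearest-neighbor vs exhaustive all-pairs scan; DBSCAN vs brute-force
density connectivity). At these sizes the ensemble α estimate lands within
±0.03 of the planted 0.844, the D estimator within ~1% of 0.15 µm²/s, the
mixture fit within ~1 percentage point of a planted 42%, and
mobile-fraction classification inside the 95% binomial interval of a
planted 87%.

## Known limitations

* Per-track α estimates on 50-frame tracks have sd ≈ 0.45: individual
  track classification by α is intrinsically noisy; only ensemble
  statistics are reliable at this track length.
* The two-component mixture fit assumes the late epoch is a pure
  one-fluorophore sample; residual dimers there bias the recovered
  fraction downward.
* Convex-hull footprints overestimate the area of non-convex hotspots; an
  alpha-shape option would tighten them but is not implemented.
* The step counter merges bleach events closer than ~2 frames.
* `detect_spots` is a plain watershed detector adequate for well-separated
  diffraction-limited spots; it is not a multi-emitter fitter.
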