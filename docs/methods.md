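# Methods

## The scientific problem

The nonmonotonic plasticity hypothesis (NMPH) predicts that the change
in overlap between two memory representations is a U-shaped function of
their coactivation during learning: none at low coactivation,
differentiation at moderate, integration at high. Testing the full U
requires stimuli whose representational similarity spans the whole axis
in a controlled way. This package implements (a) an image-synthesis
procedure that manufactures such stimuli by driving inter-image feature
correlations in a layered vision model to prescribed values, and (b) the
analysis chain that measures the resulting representational change and
fits the U-shaped model to it.

## Feature extractor and synthesis

**Toy extractor.** The synthesis engine is written against a minimal
contract — a deterministic forward pass producing a flattened activation
vector per tapped layer, and the pixel gradient of any scalar of those
activations. The bundled fixture is a fixed-random-weight stack of 3x3
convolutions with softplus nonlinearities and 2x2 average pooling
between layers (default 3 layers with 8/8/16 channels; shallow taps are
"constrained", the deepest is the correlation "target"). Forward and
backward passes are hand-written numpy (im2col via
`sliding_window_view`); gradient correctness is verified against central
finite differences (relative error < 1e-4 on small images, in practice
~1e-8).

**Response-normalized tap read-out.** Raw softplus activations carry
strong image-independent channel-gain structure: for *any* two images
the Pearson correlation of raw flattened features sits near 1, making
low-correlation targets unreachable. Tap read-outs therefore standardize
each channel's activation map (zero mean, unit variance over spatial
positions) before flattening — the same role response-normalization
layers play in classic vision architectures. With normalized features,
independent images correlate near 0 and identical images at 1, so the
full 0-to-1 target range is reachable. Channel-maximization objectives
(which the normalized read-out would erase) address the raw
pre-normalization channel means through a separate gradient path.

**Three phases.**
1. *Endpoint selection:* one activation-maximized image per channel of
   the deepest layer; the k = 16 least inter-correlated channel images
   (total absolute pairwise correlation of their target-layer features)
   are selected and paired. Subset search is exhaustive when C(n, k) is
   at most 50,000 and otherwise greedy backward elimination (repeatedly
   dropping the image with the largest mean |r| to the rest); survivors
   are paired greedily by ascending |r|. The hybrid exists because the
   greedy rule is the only feasible one at realistic scale while the
   exhaustive rule is exactly optimal at test scale.
2. *Initialization:* each image of a pair ascends
   `own_channel + w * other_channel` mean activation, where w is the
   level's intended correlation (level schedule: linear from 0 to 1, so
   level 2 of 8 is 1/7 ~ 0.14).
3. *Correlation tuning:* alternating gradient descent (A on even, B on
   odd iterations) on `sum_l (r_l - t_l)^2`, with `t_l = 0.25` at
   constrained taps and the level's scheduled value at target taps. The
   returned pair is the best-so-far by total cost, so the reported cost
   trace is non-increasing; achieved correlations are re-measured by
   fresh forward passes on the returned images.

**Optimizer.** Plain gradient steps with a fixed step size (default
0.05) after two normalizations: Laplacian-pyramid band equalization
(each band of the gradient rescaled to unit RMS; suppresses the
high-frequency bias of activation maximization) and global scaling to
unit mean absolute value. Pixels live in [0, 1] and are clipped after
each step. Ten consecutive vanishing gradients trigger a flat-objective
warning and early exit with the best-so-far image. Noise starts are
uniform in [0.4, 0.6] (gray-centered, avoiding immediate clipping at the
box bounds).

**Multi-scale loop.** The init+tune procedure can be repeated over
several volleys, bilinearly magnifying the image by 40% between volleys
(sizes rounded half-up). Gradients are applied inside a square moving
window (default side 0.9 of the image, uniformly positioned per
iteration); a per-pair update-count map accumulates window hits. Both
pair images share one count map so the final crop — stripping boundary
rows/columns whose mean count falls below the 0.1 quantile of the
per-row/column distribution — keeps the two images the same size and
their feature vectors comparable. A crop that would remove more than
half the pixels raises an error. With one volley, a full window and no
crop, the loop reduces bitwise to initialization followed by tuning.

**Desk-scale validation grid.** The standard validation configuration is
8 endpoint pairs x 8 levels at 64 x 64 with 100 init + 100 tune
iterations, one volley, full window, no crop (about 3 minutes on one
CPU). Under it the achieved target-layer correlations track the intended
schedule with a second-order Pearson r above 0.99 and the constrained
taps stay within a few hundredths of 0.25. These sizes are the package's
validation defaults; production use would raise iterations, volleys and
resolution.

## Experiment designs

Runs are 203 volumes at TR 1.5 s (304.5 s), 1 s stimuli, first onset at
6 s, ISIs drawn from {1, 3, 5} s at a 40:40:20 ratio. ISI counts are
allocated by largest remainder and shuffled, not sampled i.i.d.: exact
allocation guarantees every generated run fits the fixed scan length,
which i.i.d. sampling cannot. Templating runs are five blocks of all 16
images, each block a uniform random permutation rejected until no image
repeats across any boundary; statistical-learning runs permute the eight
pairs per block under the same no-repeat rule, with each pair always
presented intact, A then B. Exactly round(10%) of trials are flagged as
catch trials (uniform without replacement) — a fixed count, not
per-trial Bernoulli, because a fixed rate is what the cover task
prescribes and a fixed count is exactly testable.

## Synthetic data

**Patterns.** Voxel patterns are unit-variance Gaussians. Pairmate B is
`alpha * A + sqrt(1 - alpha^2) * e`, with A and e shared between the pre
and post runs (a stable item code) and only alpha changing; independent
N(0, s^2) measurement noise is added per run. Since the observed
correlation under this model is `alpha / (1 + s^2)`, alpha is set to
`r_target * (1 + s^2)`: planted correlations refer to what the estimator
sees, which is what makes recovery tests exact. Defaults: 36
participants, 2000 voxels, measurement noise s = 0.4, pre-learning
baseline correlation rising linearly 0 to 0.3 across levels (a
reduced-magnitude analogue of the model-to-brain correspondence in
high-level visual cortex; per-level baselines in hippocampus are not
established quantities, so these are explicit placeholders), and a
planted cubic change curve with coefficients (0.04, 0.035, -0.075,
-0.047) on the standardized level axis — a gentle U with its
differentiation trough at levels 5-6 (~ -0.07) and a rebound to ~ +0.06
at level 8.

**BOLD.** The forward model convolves per-image onset delta trains with
a double-gamma impulse response — gamma densities with modes exactly at
the 6 s peak and 16 s undershoot, undershoot weighted 1/6 — on a 0.1 s
grid, samples at volume times, multiplies by the patterns and adds white
Gaussian noise. The GLM inverts this exactly at zero noise (same design
matrix on both sides, by construction). Realistic fMRI noise
(autocorrelation, drift) is out of scope, and the GLM correspondingly
uses an intercept as its only nuisance regressor.

**Arrangements.** Behavioral placement tables put each shown pair at a
random position and orientation in a circular arena (radius 450 px) with
separation `intercept + slope * level + participant offset + trial
noise` (defaults 500, -45, sd 40, sd 60): distances fall linearly with
similarity level, every simulated participant's level-distance
correlation is negative under the defaults, and trial subsets cycle
through the 64-pair pool so every pair is measured for every
participant. Non-pairmate distances are arbitrary — only pairmate
distances carry signal, matching what the analysis consumes.

What passing these simulation-based tests shows is that the estimators
are unbiased and correctly calibrated *under the generative model*; real
data add spatial and temporal noise structure, pattern drift, and
segmentation error that the generator deliberately omits.

## Analysis and inference

Pairmate similarity is the Pearson correlation of the two pairmate
pattern vectors, one value per level; representational change is post
minus pre (positive = integration, negative = differentiation);
model-brain correspondence is the Fisher-transformed correlation between
level and similarity (|r| clamped at 1 - 1e-7 before atanh; zero
variance profiles reported as NaN with a warning).

The theory-constrained cubic is least squares on the standardized level
axis (centering/scaling for conditioning; coefficients reported on both
scales) subject to `a >= a_min` (default 1e-6; the bound's exact value
only matters when the unconstrained leading coefficient is negative,
where any small positive bound yields the same boundary solution —
sensitivity to a_min is therefore negligible below ~1e-3). Positivity of
the leading coefficient is the *only* shape constraint: it is what
guarantees a dip followed by a positive inflection, and no additional
constraint forces the critical points into the observed range. Because
only one coefficient is bounded, the solution is closed-form (KKT):
unconstrained fit if feasible, otherwise the bound binds and the
remaining coefficients are re-fit on the residual. An independent
bounded-least-squares solver (scipy's `lsq_linear`) serves as the
cross-check in tests, never as the implementation.

Cross-validation leaves out one participant, fits the constrained cubic
to the level-wise *mean* of the training participants' curves (fitting
the averaged curve and fitting pooled points are equivalent here since
the level axis repeats), predicts the held-out curve, and averages
per-fold Pearson correlations raw (not Fisher-transformed). Inference:
percentile 95% CIs from with-replacement participant bootstrap;
one-tailed p-values from re-pairing nulls in which A and B images are
re-paired uniformly at random, the true pairing *not* excluded (a
conservative null). P-values use the add-one rule (k+1)/(n+1); ties
between null and observed count half, so a pairing-invariant statistic
yields p ~ 0.5 rather than 1. Searchlight maps apply any pattern
statistic over (2r+1)^3 cube neighborhoods intersected with the mask
(125 voxels at radius 2) and Fisher-transform the result; neighborhoods
below a minimum voxel count are skipped. Cluster-level family-wise
correction is out of scope.

## Numerical and design notes

- One master seed per run; per-pair synthesis streams derive from
  (seed, endpoint index, level) via `SeedSequence`, and CLI subcommands
  derive module seeds from the master seed plus fixed offsets —
  reproducibility with module independence.
- Activation flattening is channel-major, row-major within channel; any
  fixed order works for correlations, one is fixed for reproducibility.
- The constrained-layer target (0.25) enters only in tuning;
  initialization uses the weighted channel objective alone.
- Level-8 pairs (t = 1) remain distinct images — different noise starts
  and symmetric objectives make them "almost identical", never
  byte-equal.
- Bootstrap and permutation defaults are 50,000 in the `paper` CLI
  profile and 2,000 in the `test` profile; the statistic definitions are
  identical. Tests use yet smaller counts where the check is about
  calibration, not precision.
- The `nmphfit` subcommand consumes a change-curve CSV (no image
  patterns), so its permutation null shuffles level labels; the
  image-re-pairing null is available in the library
  (`analysis.shuffle_null` with `fitting.cv_fit_stat`) and is the
  appropriate one when pattern matrices are at hand.
- Percentile bootstrap CIs undercover for very small cohorts (a known
  O(1/n) property); the calibration test therefore measures coverage at
  n = 50, where the percentile interval is within its nominal band.
- Expected-value tests of sequence statistics (ISI ratios, catch
  uniformity, transition probabilities) use 3-3.5 SE bands around exact
  enumerations or binomial expectations.

## Known limitations

- The toy extractor is a fixed random-weight hierarchy: it validates the
  optimization machinery, not the semantics of any pretrained feature
  space. Pretrained networks can be plugged in by implementing the
  two-method contract, but no adapter ships here.
- At the top similarity level the deep-correlation target (1.0) and the
  shallow 0.25 target genuinely compete; the tuning compromise leaves
  deep correlations slightly below 1 (~0.99) and shallow ones near 0.25.
- The BOLD model omits hemodynamic nonlinearity and structured noise;
  GLM results on real data would need the usual preprocessing upstream.
- Whether initialization re-runs in every magnification volley (as
  implemented) or only tuning repeats is an open reading of the
  procedure; re-running both phases is the literal one and is what the
  multi-scale loop does.
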