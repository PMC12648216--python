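# Methods

This note records the models, numerical choices and limitations behind the
pipeline, in the order the analysis runs.

## Coordinate and geometry conventions

All geometry lives in display space: origin top-left, x rightward, y
downward, pixel units, canvas 1,920 x 1,080. Ellipse orientation is the
major-axis angle from +x toward +y, reported modulo pi (the 180-degree
ambiguity of an ellipse is not resolved, and no finer angle adjustment is
attempted). ROI geometry comes from image moments: the reported axis
lengths are those of the ellipse whose second central moments match the
pixel region (full length = 4 sqrt(eigenvalue)); near-circular regions
report orientation 0 by convention.

## Expert-mask consensus

Per-label preprocessing uses small-blob removal (components < 25 px),
interior hole filling, then a morphological opening with a 1-px disc —
deliberately conservative defaults, both configurable. Masks covering more
than 50% of the canvas or more than 1.5x the within-image median coverage
are dropped as overgeneralised. The leave-one-out consensus is a *strict*
majority of the remaining experts (2 of 3 when one of four is held out);
ties at even counts are thereby excluded by construction. The
representative is the argmax-F1 expert with the tie cascade (i) ROI count,
(ii) IoU with consensus, (iii) coverage nearest the median. Note that on
binary masks Dice = F1 and IoU = Dice/(2 - Dice) are monotone transforms,
so rule (ii) can only matter when the comparisons involve different
consensus masks that happen to give equal F1; it is kept for fidelity to
the documented procedure.

Grid agreement: cells partition the real-valued canvas extents equally
(32x64 cells over 1080x1920 are 33.75 x 30 px); pixels are assigned by
centre location, and a cell counts as marked when its occupied fraction
exceeds the threshold (0 = any pixel). Fleiss' kappa is computed over cells
x experts x {marked, unmarked}; when every cell is unanimous in a single
category, kappa is reported as 1 with a `perfect_degenerate` flag (the
formula itself is 0/0 there). Sensitivity mode repeats at 24x48, 16x32 and
a 20% occupancy threshold.

## Windowing and exclusion

A trial is excluded when any uncovered span — before the first fixation,
between the end of one fixation and the onset of the next, or after the
last fixation — exceeds 2 s; grayscale-condition trials are removed from
the analysis set. Cumulative windows are half-open [0, t): a fixation
starting exactly at t belongs to the next window. Each window is fitted
independently (no incremental updating across windows).

## The fixed-emission variational HMM

States are the EGP ROIs in path order. Emissions are fixed bivariate
Gaussians: mean at the centroid, covariance R(theta) diag((major/4)^2,
(minor/4)^2) R(theta)^T, so the drawn ellipse sits near the 2-sigma
contour. The divisor 4 is a modelling choice — nothing in the annotation
defines how ellipse extent maps to fixation spread — and is exposed as a
parameter. Fixations are weighted equally regardless of duration; dwell
time is deliberately not modelled.

Priors are symmetric Dirichlet with pseudo-count 1 on pi and on each row of
A. The variational E-step runs scaled forward–backward under
exp(digamma(posterior) - digamma(sum)); the M-step adds expected
initial-state and transition counts to the prior. The bound
log Z~ - KL(q(pi)||prior) - sum_j KL(q(A_j)||prior) is evaluated at each
E-step and is non-decreasing; iteration stops when it improves by less than
1e-5 (max 100 iterations). Point estimates are posterior means, which are
strictly positive — VH-LL is therefore always finite. A window with zero
fixations is an error surfaced to the caller (the pipeline simply skips
that participant-window).

## Strategy clustering

Because all models for an image share fixed emissions, the divergence
between two participant models reduces to their Markov parameters, and the
full hierarchical EM over HMMs specialises to a hard-assignment EM on
transition matrices: model i scores a candidate representative c as
sum_j nu_i(j) sum_k A_i(j,k) log A_c(j,k) + (1/T_i) sum_j pi_i(j) log
pi_c(j), where nu_i is i's expected state occupancy from its own fit and
T_i its fixation count (so the single initial-state observation is weighted
like one transition). M-steps average member rows weighted by occupancy; a
state no member occupies gets a uniform row (it cannot affect any score).
Emptied clusters are re-seeded from the worst-fitting model; the best of 10
random restarts by total score wins. K is fixed at 2; no model-order
selection. The cluster with higher mean self-transition is labelled
*focused*, ties broken by lower mean row entropy.

## Ratings, groups and the gaze-rating link

Normalisation is a z-score within participant x attribute across images
with the population-SD denominator (ddof = 0; the sample-SD alternative is
a parameter). Zero-variance raters are flagged and set to 0. Groups come
from 1-D k-means (k = 3, 25 initialisations, seeded) on the normalised
values of the analysed participants, clusters ordered by centroid into
high/middle/low; a constant input degenerates to everyone-middle with a
flag.

VH-LL scores the expert's ordered path under the participant's model
(prior times chained transitions). The reverse direction — a participant's
fixation data scored under a representative model via the forward
algorithm — is provided as an alternative mode. CVB is the Pearson
correlation of VH-LL with the normalised rating over a group subset;
subsets smaller than 3 or with zero variance yield a flagged NaN rather
than an error. The default CVB mode intersects rating-group membership with
strategy-cluster membership ("membership" mode); scoring all group members
under each representative is the documented alternative.

Consistency labels compare CVB(high) with CVB(low) under the image's
configured message direction (positive: high group expected to track the
expert path more closely). Significance comes from a two-sided variance
F-test at alpha = 0.05 gating an equal-variance two-sample t-test versus a
Mann-Whitney test on the VH-LL values, one-tailed in the hypothesised
direction. No multiple-comparison correction is applied across the image x
window x cluster grid; p-values are reported raw, by design.

The design-stage power computation uses d = 2r/sqrt(1 - r^2) and the
one-tailed normal approximation n = ceil(((z_{1-alpha} + z_{power})/d)^2)
per group, times three rating groups.

## Pupil preprocessing and window tests

The baseline is the uncorrected mean of the 5-s rest-screen trace and is
subtracted sample-wise. Outlier detection (|x - mean| > 3 sigma) runs on
the baseline-corrected series — sigma is unchanged by the subtraction but
the mean is not, and this choice is fixed and documented. Missing runs are
bridged linearly between anchors that are means of up to 50 valid samples
on each side (a single-nearest-sample anchor mode exists); edge runs extend
the available anchor. Traces left more than 50% missing are flagged
unusable. Left and right eyes are analysed separately throughout; no
latency shift is applied.

The window test fits a linear mixed model on samples in [0, t): fixed
high/low effect, random intercept per participant, REML. Two numerical
choices matter. First, responses are decimated to 10 Hz (every 30th sample
at 300 Hz): the series is heavily oversampled for a between-group contrast,
and the decimation leaves the test's information content — which is
between-participant — intact. Second, the one-tailed p uses a t reference
with df = n_high + n_low - 2 rather than the Wald normal: a between-subject
effect has at most the between-participant degrees of freedom, and with
~16 participants the normal reference is anticonservative. Simulation at
the generator's null puts the rejection rate at ~0.05 (the acceptance suite
checks [0.03, 0.07] over 1,000 replicates). A singular mixed fit (detected
by a nonsense standard error) falls back to a one-tailed t-test on
participant window means, recorded in the output. Cohen's d always comes
from participant window means with the pooled SD; d > 0.30 is banded
medium, d > 0.20 small.

## The synthetic study

The generator produces the inputs the analysis assumes, with one seed
driving named substreams (bit-identical reruns, independent of Python's
hash salt):

- **ROI layouts**: 12–14 non-overlapping ellipses (semi-major 70–120 px)
  placed by rejection sampling on the 1,920 x 1,080 canvas.
- **Expert annotations**: per-expert centroid jitter (SD 55 px), log-normal
  axis scaling (SD 0.2), orientation jitter (SD 0.3 rad), 6% dropped and 4%
  oversized ROIs. These rates were chosen so the synthetic annotators
  disagree about as much as real experts plausibly do (grid kappa ~ 0.25–
  0.36, mean IoU ~ 0.13–0.24, consensus ratios of the same order as a real
  multi-annotator study); an optional overgeneralised expert exceeds the
  50% coverage filter.
- **Scanpaths**: focused (mean self-transition 0.62–0.72, off-diagonal mass
  concentrated on ~3 ROIs) versus explorative (Dirichlet-near-uniform rows,
  row entropy >= 80% of log n) strategy chains; individual participants get
  Dirichlet-perturbed copies. Fixation durations are log-normal with median
  250 ms (the field's typical free-viewing value; no study-specific
  statistic exists to calibrate against), separated by exponential saccade
  intervals whose mean makes fixations arrive at 3/s — the trial is tiled,
  so no spurious 2-s gaps arise, and exclusion-rule tests inject gaps
  explicitly.
- **Ratings**: per image, latent beauty = rho z(similarity) +
  sqrt(1 - rho^2) noise with rho = 0.30 by default (the medium effect the
  power computation assumes), discretised by an affine map to 1–10 and
  rounding; favourability shares part of the beauty latent, other
  attributes are independent.
- **Pupil**: baseline ~ N(4.0, 0.3) a.u. shared with the rest trace, plus a
  per-trial arousal offset (SD 0.06 a.u., shared across eyes, absent from
  the rest screen — the component baseline correction cannot remove), an
  AR(1) process (coefficient 0.9, stationary SD 0.05) and a -0.1 a.u.
  offset for the high-rated group. The planted offset is deliberately
  strong relative to the noise (recovered at d > 1), so detection tests are
  decisive; real pupil effects are far smaller.
- **Coder labels**: 3 coders x 9 categories with per-category base rates
  spanning 0.06–0.45; each coder copies the true label with probability
  `coder_agreement` (default 0.8) and otherwise flips a fair coin, so
  agreement 1 gives identical sets and agreement 0 gives kappa ~ 0.

What the generator does not emulate: image content and saliency (scanpaths
depend only on the ROI chain), dwell-time/rating feedback loops, blink
dynamics or luminance-driven pupil responses, and coder label correlations
across categories. Passing tests therefore demonstrate that the *pipeline*
recovers planted structure under its own assumptions, not that those
assumptions hold for any particular real dataset.

## Problem sizes used in tests

The recovery suites use the sizes at which the statistical guarantees are
stated: ~2,000 fixations for transition recovery (max-abs error < 0.05),
40 models for cluster recovery, 200 participants for the planted-
correlation check, 1,000 replicates for the type-I calibration of the
pupil test, and the full 48-participant x 12-image study for the
end-to-end determinism check.

## Known limitations

- Dwell time is not modelled; every fixation counts equally.
- The EGP fixes the state count; no hidden-state-count selection.
- VH-LL direction (expert path under participant model) is one of two
  defensible readings; the reverse is available but not the default.
- The consistency/significance grid is reported without multiplicity
  correction.
- The coder-reliability module treats the 9-category codebook as given;
  no text processing is attempted.
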