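# Methods

This note documents the models, procedures and numerical choices behind
`movenc`, and what the synthetic-data studies do and do not establish.

## Task and data model

The package analyzes sessions from a delayed-response licking task: on each
trial an auditory cue during the **sample** epoch instructs a lick direction,
the animal withholds licking through a **delay** epoch (1.2 s in the
reference task), and reports its choice by directional licking in the
**response** epoch after a go cue. The raw inputs per session are high-speed
grayscale video (treated as a 3.4 ms frame period), tracked 2-D body-part
markers (jaw, nose, tongue, paws; DeepLabCut-style CSV layout), spike times
per sorted unit with CCF atlas coordinates, and a trial table with epoch
boundaries and exclusion flags.

## Preprocessing

* **Binning.** Spikes become firing rates with a 40 ms window sliding at the
  3.4 ms stride, anchored per trial at the go cue (t = 0). Bins are centered
  on grid timepoints and half-open, `[t - w/2, t + w/2)`; centering keeps
  the temporal-offset analysis symmetric around zero.
* **Marker cleaning.** Frame-to-frame velocity outliers beyond 5 sigma are
  replaced by linear interpolation from the nearest clean frames. The sigma
  is robust: the per-axis velocity SD is estimated by MAD x 1.4826 (which is
  calibrated for the roughly normal per-axis components, not for the
  Rayleigh-like speed magnitude) and combined in quadrature. Tongue frames
  with low likelihood (occluded in the mouth) are set to the tongue's mean
  visible position; occlusion-imputed frames are never treated as outliers,
  and steps across an occlusion boundary are exempt, which makes cleaning
  idempotent.
* **Selection.** Trials flagged photoinhibition / free-water / early-lick /
  ignored are excluded everywhere; choice analyses additionally keep correct
  trials only. Neurons with session-mean rate below 2 Hz are dropped.
* **Folds.** Cross-validation folds are stratified on lick direction x
  correctness via a seeded within-stratum permutation; strata smaller than
  k are merged with a warning. The three-method comparison instead uses a
  single held-out test split (64 trials by default) balanced the same way.

## Predicting activity from video

Three predictors of increasing expressiveness, scored identically:

* **Marker ridge.** For target time t, the features of the five frames at
  t - 6.8 ... t + 6.8 ms are concatenated; with one scalar per marker
  (height) for jaw, nose and tongue this is a 15-d vector. A 2-D variant
  (30-d) is available behind a switch; the scalar form is the default to
  match the printed dimension. A separate ridge regression is fit per
  timepoint (targets at a timepoint are predicted across trials).
* **Embedding ridge.** The same windows over the 16-d convolutional-
  autoencoder code (80-d features).
* **End-to-end CNN.** Each of the five window frames passes through a trunk
  of three residual blocks (four convolutions each, the first 1x1 and the
  rest 3x3; 16/32/32 output channels; batch normalization with epsilon 1e-5
  and momentum 0.1; kernel-4 stride-4 max pool and ReLU after each block),
  giving 32 features per frame; the five outputs concatenate to the 160-d
  pre-output vector read out by one linear layer sized to the session's
  neuron count. One network serves all neurons and timepoints of a session.

Ridge solutions come from an SVD path (exact closed form, shared across the
regularization grid and all neuron targets), with the penalty chosen per
neuron by nested 5-fold cross-validation on training trials only, on a
log-spaced grid 1e-3 ... 1e4 (8 points). The per-timepoint R^2 on held-out
trials uses the training-fold mean in the denominator, so no test statistic
leaks into the score. Zero-variance targets are recorded as 0 and flagged.

**Epoch-averaged EV.** Per-timepoint, per-fold R^2 is rectified at zero,
averaged over folds, then averaged over the timepoints of an epoch
excluding 150 ms at each edge. Neurons with EV below 0.01 are dropped from
downstream population summaries. Rectification makes the noise floor
slightly positive; this is accounted for wherever near-zero EVs matter
(see the peak filter below).

**Reliable-but-unpredicted neurons** are those with response-epoch
embedding EV < 0.1 whose single-trial traces correlate with the
trial-averaged pattern above 0.4 and whose mean across-trial rate variance
stays below 100 s^-2 — the signature of reliable, movement-independent
(e.g. cue-locked) firing.

## Temporal offsets (lead/lag)

The embedding feature window is shifted by tau in {-102 ... +102} ms (6.8 ms
steps, 31 values) and the per-timepoint ridge analysis repeated; EV(tau) is
the response-epoch average. tau > 0 means future video predicts current
activity — activity leads movement (motor-like); tau < 0 is sensory-like.
The best offset tau* is the argmax of fold-mean EV, with exact ties resolved
toward the smallest |tau| (negative before positive), so null-lag neurons
prefer zero. A profile has a valid peak when max EV >= 1.2 x mean EV over
the 31 shifts **and** the peak EV reaches the 0.01 floor; without the floor
the ratio rule passes vacuously for near-zero noise profiles. Significance
of tau* uses a two-sided one-sample t-test of the per-fold best offsets
against zero, with Benjamini-Hochberg control at Q = 0.05 across the
analysis batch. To keep the 31-shift scan tractable the ridge penalty is
selected per (neuron, fold) at tau = 0 (summed over three probe timepoints)
and reused across shifts and timepoints; the plain predictor keeps the full
nested search per timepoint.

## Choice and uninstructed movement

Lick direction is decoded from video with L2 logistic regression (IRLS) on
correct trials under stratified 20-fold CV; each trial's held-out
delay-epoch prediction (vL/vR) uses the delay-epoch mean of the feature
series, chosen for stability and determinism. Correct trials are split into
the four contingencies L-vL / L-vR / R-vR / R-vL; sessions with fewer than
20 trials in any group are invalid. Per neuron, choice AUC is the average of
decoding L vs R within vL and within vR trials from the delay-epoch mean
rate (movement AUC symmetrically decodes vL vs vR within each choice), with
held-out AUC averaged over stratified folds and conditions with fewer than
10 trials per class skipped. Labels use the 0.65 AUC threshold; a neuron may
carry both. For the one-dimensional neuron decoders the held-out AUC is
invariant to the L2 penalty (the score is monotone in the rate), so the
default penalty grid is a single value; supplying a grid enables the nested
(leave-one-out) search. The residual variant subtracts the held-out
embedding-ridge prediction per timepoint before re-decoding choice from the
delay-mean residual (5-fold CV, same threshold).

Session-level analyses: Pearson correlation between per-session video
choice-predictability and fraction correct; and the Calinski-Harabasz index
of animal clustering in decoding-feature space against a 1,000-fold
label-shuffle null (degenerate zero-within-spread configurations are capped
at 1e6; under a Gaussian null the index follows an F(k-1, n-k) law with
mean (n-k)/(n-k-2), near 1). The marker variant keeps sessions with jaw or
nose AUC >= 0.65 and animals with at least two such sessions.

## Spatial statistics

Neurons pool across sessions only at the level of per-neuron scalars, in
CCF space. The uniformity test bins neurons into cubic voxels (0.2 mm for
subregion-scale EV analyses, 0.5 mm for modulation maps; grid anchored at
the CCF origin — the phase is immaterial, as the translation-invariance
test verifies), computes a one-way F statistic over the voxel grouping and
compares it with 10,000 value shuffles (coordinates fixed). The smoothness
test compares the mean |EV difference| between nearest-neighbor pairs
(Euclidean, within anatomical group, ties to the lowest index) against
1,000 within-group shuffles. Bootstrap p-values use the (r+1)/(n+1)
correction. Display maps aggregate a per-voxel statistic on a projected
2-D grid (150-300 um voxels) with an optional 3x3 median filter that
ignores empty voxels.

## Synthetic sessions

The generator emulates the statistical structure the analyses assume, with
full ground truth:

* **Latents.** Per body part, a stationary Ornstein-Uhlenbeck wander
  (timescale 0.15 s, SD 1 px) around a resting pose; during the response
  epoch the jaw oscillates at the 7 Hz licking rhythm (amplitude jittered
  ~15% per trial, phase random per trial) with a lateral component signed
  by lick direction, and the tongue protrudes on the positive half-cycle.
  Optionally, a choice-biased lateral jaw offset (the "uninstructed
  movement") is present through sample and delay; its direction matches the
  upcoming choice on a configurable fraction of trials (0.7 by default), so
  choice/movement mismatch trials exist.
* **Frames.** Isotropic Gaussian blobs at the latent positions on a fixed
  smooth background plus pixel noise; deterministic per frame given the
  latents.
* **Markers.** Latents plus Gaussian noise; occasional large jumps (>= 8
  sigma of the marker velocity) at a configurable per-frame rate; occluded
  tongue at rest position with low likelihood.
* **Spikes.** Inhomogeneous Poisson with rate(t) = max(0, baseline +
  gain * g(latent(t + lag)) + choice offset), where positive lag means the
  activity leads the movement. g is the identity for linear neurons, a tanh
  squashing or a centered square (selectable) for nonlinear ones; cue-driven
  neurons follow the sample-epoch envelope only; untuned neurons are
  homogeneous. The half-wave rectification keeps the intensity valid even
  though the *predictors* may output negative rates.
* One RNG per session seed, split into named substreams (latents /
  background / frames / markers / spikes), so each stream is reproducible
  independently; identical configs give bit-identical sessions.

**What the generator does not emulate:** photorealistic video, multi-view
geometry, non-Poisson spiking statistics, history dependence, or any
realistic model of why animals make uninstructed movements (the choice-bias
model is a stand-in). Passing tests therefore demonstrate that the
*analyses* recover what they claim from data with the assumed structure,
not that real sessions satisfy those assumptions.

## Problem sizes and study conditions

All validation studies run on a desk-scale profile chosen once: 16 x 16
pixel frames (Gaussian blobs of sigma 2.4 px), epochs 0.3 / 0.45 / 0.6 /
0.75 s on the 3.4 ms frame grid, 200-260 trials, and evaluation timepoints
subsampled every 4-6 strides within an epoch. The generator's *defaults*
keep the reference geometry (120 x 112 frames, 1.2 s delay), and the
architecture invariants (288-d flatten, 16-d code, 160-d pre-output) are
asserted at that geometry. On small frames the two encoder block pools and
the trunk pools adapt their kernels (4 on large maps, 2 on small ones) so
the code retains spatial information; at 120 x 112 the kernels are exactly
the reference 2/4/4 (encoder) and 4/4/4 (trunk), and the end-to-end trunk
ends at 1 x 1 x 32 for any input size, preserving the 160-d pre-output.

Model-fit budgets at this scale: autoencoder trained with Adam (lr 5e-3
with late step decay, batch 64, 18-30 epochs on 2,000-3,000 subsampled
frames, early stopping on a 10% frame split); end-to-end network trained
for 200-300 Adam steps (batch 24, lr 2e-3) with checkpoint selection on an
inner validation split of training trials. Planted effect sizes are set so
that the quantities under test are clearly identifiable at these sizes:
linear coupling 6 Hz/px on a 10 Hz baseline, nonlinear (squared) coupling
8 Hz/px on 5 Hz, choice offsets of 5 Hz, movement coupling 3 Hz/px with a
0.9 px delay bias (3x the marker noise SD).

## Numerical choices and degenerate inputs

* Ridge and logistic solvers are exact/Newton with float64 accumulation;
  sklearn equivalents serve as independent test oracles.
* AUC uses the midrank tie convention (constant scores give 0.5).
* Epoch averages raise on epochs shorter than 300 ms (twice the edge
  exclusion); all-flagged marker traces and single-class decoding raise.
* The t-test on per-fold offsets degenerates when all offsets are equal:
  p = 1 at zero mean (no evidence against zero), p = 0 otherwise.
* Voxel tests require at least two occupied voxels (two with >= 2 neurons
  for the F test); nearest-neighbor ties break toward the lowest index.

## Known limitations

* The embedding and end-to-end models are trained at small scale; their
  absolute EVs on synthetic data are not comparable to real-data values,
  and only orderings/recoveries are asserted.
* Per-timepoint regressions with 80-d features on ~10^2 trials are
  variance-limited; the expressiveness comparison therefore plants strong
  nonlinear couplings to keep the ordering identifiable.
* The offset scan's shared per-(neuron, fold) penalty is an approximation
  to full nested selection at every shift; with the planted effect sizes it
  does not change recovered offsets, but very heterogeneous real sessions
  might warrant the full search.
* The uninstructed-movement generative model is deliberately minimal; no
  claim is made about its behavioral realism.
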