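# Methods

This note documents the generative model behind `seqmvpa.simulate`, the
analysis conventions, the parameter choices that matter, and what the
passing test suite does and does not establish about real data.

## Task designs

Three designs are generated, all expressed in seconds from run start and
binned to volumes at TR = 1.5 s (an event occupies volume *v*, 1-based
from trial onset, in proportion to its overlap with [(v−1)·TR, v·TR)).

**Event-related scan trials (28.5 s).** The printed component durations
are reconciled into 28.5 s by absorbing the fixation after the eighth
grating into the blank: 8×0.25 + 7×0.2 (gratings) + 11.6 (blank) + 0.5
(cue) + 0.5 (test) + 2.0 (response) + 10.5 (inter-trial fixation). The
control trial replaces the first 11.6 s of blank with a 0.25 s letter cue
plus 11.35 s of fixation. Each run is 12 trials between two 15 s fixation
blocks (248 volumes). With this decomposition the blank fully occupies
trial volumes 4–10, which is exactly the no-stimulation window the
analysis assumes; a 3-volume shift maps it to 7–13 and the decoded window
is 8–13 (volume 7 dropped to avoid spill-over from the sequence), with a
conservative variant 10–12.

**Run composition.** The four sequences are allocated equally across the
12 trials of a prediction run (3 each; the allocation rule is a design
choice — only the 12-trial run length is fixed by the task description),
with an exact 50% match rate and the randomized first item balanced 6/6.
Control runs draw random orientation-balanced sequences and are paired
trial-by-trial to a prediction schedule so the cue reproduces the paired
trial's expected orientation. Training runs hold 40 trials (10 per
sequence, match rate exactly 50% within each sequence's trials), each
showing two sequence repeats at 0.3 s on / 0.3 s off with the test
stimulus at a uniformly random position 1–5 of the second repeat; every
training trial lasts exactly 13 s. The localizer run is 20 blocks of 15 s
(30 gratings at 0.25 s on/off; 10 blocks per orientation) between two
fixation blocks.

## Generative model of the BOLD signal

Each voxel *v* has an orientation preference (code 1, 2, or untuned), a
selectivity amplitude *a_v*, a stimulus activation gain *g_v*, a noise SD
(default 1, which makes all gains interpretable in noise-SD units), and an
edge flag marking voxels at the stimulus border (activated but untuned;
selection must reject them explicitly). Neural drive per volume is

* during grating/test events: `stim_gain · (g_v + a_v·[preference = shown])`,
* during the prediction-task blank: `reactivation_gain · a_v·[reactivation
  preference = internally predicted orientation]` (structured sequences
  only),
* during the control-task blank: the same with `cued_gain` (default 0)
  toward the held cue.

Drive maps to BOLD through a pure 3-volume lag shift by default, mirroring
the shift the analysis applies, so noiseless closed forms are checkable;
a canonical double-gamma convolution is available for stress-testing.
Noise is i.i.d. Gaussian per voxel·volume. The reactivation target is the
*participant's* per-trial internal prediction (correct with probability
p), which makes the response-implied label the exact label of the signal
and the sequence-expected label a noisy version of it — matching the
analysis' two label sources.

The reactivation code defaults to the stimulus code (`reactivation
preference = preference`), the regime in which cross-decoding from
stimulus-driven patterns succeeds. Two counterfactual populations exist
for testing: an independently re-drawn code (chance-level overlap that
fluctuates like 1/√n per draw) and an exactly balanced orthogonal code
(zero net overlap), which is the clean construction for asserting that
cross-decoding fails without a shared code.

**Effect sizes.** No effect size for the blank-interval signal is
published; the gains are free parameters with a purely qualitative
contract — post-training > pre-training for the prediction task,
unchanged for the control task. Defaults are `reactivation_gain_pre =
0.02` and `post = 0.15` (noise-SD units), chosen once so that, at the
study's dimensions (7 runs × 12 trials, 300 of 400 voxels), pre-training
decoding sits modestly above chance (~0.6) and post-training well above
(~0.9). These values are a simulation regime, not an estimate of the real
effect.

**Behaviour.** p(correct) = clamp(k·log(run) + c, 0.5, 1) across
cumulative training runs; defaults k = 0.1, c = 0.55 reach ≈0.83 by run
16 (four sessions of four runs), consistent with a training criterion of
80%. Control-task accuracy is constant at 0.9 in both sessions.

**Motion.** Per-volume translations/rotations are small i.i.d.
Gaussians plus per-trial spikes (probability 0.01, ~1.3 mm). "Sharp"
motion is operationalized as volume-to-volume translation change above
0.5 mm (the thresholds 1 mm / 1° / 0.5 mm live in preprocessing, which
also drops runs losing more than half their trials).

## Analysis conventions

* Z-scoring is per voxel within run; zero-variance voxels are zeroed with
  a warning rather than raising (they arise in synthetic edge cases).
* The cost-weighted linear SVM multiplies each class's error penalty by
  `n_samples / (2·n_class)`, compensating the class-count ratio exactly;
  the regularization strength C is unspecified in the underlying
  procedure, defaults to 1.0, and a sensitivity test confirms linear
  decoding conclusions are robust to it across two orders of magnitude.
* Fold accuracies are averaged with equal fold weight. With 7 runs the
  averaged-window analysis trains on 72 patterns and tests on 12 per fold;
  the implementation always reports actual counts.
* The activation contrast is computed from the localizer (block) runs —
  stimulus-rich and independent of the decoded interval; which scan
  defined "activated by gratings" is ambiguous in the source procedure,
  so the contrast accepts any runs. p-threshold 0.05 one-sided,
  uncorrected, configurable.
* RFE eliminates 10% of surviving voxels per step by default (the
  original step size is unstated); `step_fraction = 1/n` gives exact
  one-at-a-time elimination. Ties in |weight| break by voxel index.
* "Informative in both analyses" is implemented as the top-n by combined
  rank = max(rank₁, rank₂) (enforcing joint informativeness rather than
  averaging), with rank-sum then index as tie-breaks.
* The permutation control shuffles the pattern–label correspondence
  across the whole session and re-runs the full leave-one-run-out
  decoding per iteration; the voxel set is reused because selection is
  label-free. Default 10,000 iterations; 1,000 are used in tests and in
  the acceptance script.
* Cross-decoding with per-fold joint selection excludes the held-out run
  from both the RFE and the decoding. The classic circular variant
  (selection sees the held-out run) is implemented only as a diagnostic:
  on within-session null data it inflates accuracy by ~0.25 while the
  fold-respecting procedure stays at chance. Note that in *cross*-decoding
  proper — where the classifier is trained on an independent localizer —
  selection on test data does not systematically inflate accuracy, because
  |weight|-based selection is sign-blind with respect to the externally
  trained decision direction; the inflation requires selection and
  decoding to share a session.

## Numerical and statistical notes

* All randomness flows through `numpy.random.Generator`; identical seeds
  give bit-identical datasets and results tables.
* The learning-curve fit is linear in (log x, 1), so least squares is
  exact; k̂ recovers the generator's k to machine precision on noiseless
  curves and is unbiased under binomial trial noise.
* Paired comparisons handle zero-variance differences explicitly
  (identical lists → t = 0, p = 1; constant nonzero shift → p = 0).
* Null decoding accuracies of a single 48–84-trial session have
  dispersion noticeably wider than the naive binomial SD because all test
  trials share a small set of fitted decision rules; chance-level
  assertions in the tests therefore average over replicate sessions (or
  use the permutation distribution, whose mean is the calibrated
  quantity).

## What the tests do and do not show

The suite establishes, against generator ground truth: exact design
arithmetic; correct volume/shift bookkeeping; chance-level decoding and a
chance-centered permutation null in the absence of signal; monotonicity
of accuracy in signal-to-noise; class-balance of the cost-weighted
decoder under imbalance; leakage-free cross-validated selection; and
cross-decoding that succeeds if and only if prediction and stimulus share
a population code. The generator omits spatial and temporal noise
correlations, scanner drift, retinotopic spatial layout, eye movements
and biophysical BOLD nonlinearity; passing tests therefore validate the
*pipeline's* logic and calibration, not the magnitude of any real-data
effect.
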