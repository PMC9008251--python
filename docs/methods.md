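# Methods

`synadapt` implements an adaptive, user-independent gesture-recognition
pipeline for surface electromyography (sEMG). The classifier never sees
calibration data from a new user; instead it adapts online, replacing
train-set rows and re-weighting neighbors with test samples that pass a
risk gate. This note documents the model, the parameter choices, the
synthetic cohort generator the tests rely on, and the numerical decisions
where the design was genuinely open.

## Signal model and preprocessing

A recording is an `n x m` matrix of m-channel sEMG samples with
per-sample gesture labels (0 = rest) and repetition indices. The
preprocessing chain is:

1. **Full-wave rectification** — elementwise absolute value.
2. **Envelope** — per-channel third-order Butterworth low-pass at 1 Hz,
   applied *causally* (`sosfilt`, not `filtfilt`): online recognition
   cannot look ahead, so we accept the filter's group delay (~0.3 s at
   these settings) rather than use zero-phase filtering. Ringing below
   zero is clamped; an envelope is a nonnegative amplitude.
3. **Active-segment extraction** — the m channels are summarized by their
   per-sample mean; the signal is tiled by windows of
   `round(window_ms * fs / 1000)` samples (200 ms → 40 samples at
   200 Hz, 20 at 100 Hz) and a window is *active* when at least
   `ceil(active_fraction * win_len)` of its samples exceed
   `threshold_coef` times the **peak of the summary envelope over the
   recording** (defaults: `active_fraction = 35/40`,
   `threshold_coef = 0.015`). Runs of active windows merge into one
   segment, labelled by the majority nonzero sample label (ties to the
   smaller gesture id). A window-local peak cannot work here: a
   rest-only window would always exceed 1.5 % of its own tiny peak, so
   the threshold reference is global per recording.
4. **Analysis windows** — 200 ms windows overlapped by 50 ms
   (step = 150 ms) inside each segment; the last partial window is
   dropped.

`discard_outlier_repetitions` screens repetitions whose mean-envelope
vector lies more than 3 robust z-scores (median / 1.4826·MAD of the
distances to the per-gesture median) from typical. It is an offline
data-preparation step for existing users and is not applied during
online sessions.

## Synergy features

Each window (transposed to channels × time, `m x n`) is factored at rank
1 by nonnegative matrix factorization, V ≈ w h, using the multiplicative
updates

    w ← w · (V h) / (w (h·h) + ε),   h ← h · (w·V) / ((w·w) h + ε)

with ε = 1e-12, strictly positive uniform initialization in (0.1, 1.1]
(seeded), at most 500 sweeps, and termination when the relative change of
the Frobenius reconstruction error drops below 1e-6. One synergy is used
throughout (r = 1). The scale ambiguity is fixed by normalizing h to unit
sum; the feature is the min-max-normalized w (constant vectors map to
zeros). The multiplicative updates never increase the objective; the
feature is invariant to positive rescaling of the window, which is why
uniform amplitude changes (electrode pressure, global effort) do not
move it.

Min-max normalization is applied per feature vector, not per channel
across the dataset: the feature is the *shape* of the channel-weight
profile, and per-vector scaling makes windows comparable regardless of
contraction strength.

## Representative train set

One cluster per gesture is refined by Lloyd iterations seeded at the
class mean (supervised prototype refinement; there is no random-restart
unsupervised clustering). Iterations stop when the largest centroid
displacement falls below 0.02 or after 100 iterations; centroids of every
generation are retained so the clustering error can be audited. The final
centroids are the gesture *templates* µ_g.

For every (user, gesture) pair, the 30 features nearest (squared
Euclidean) to that gesture's template are kept, ties resolved by original
order. With 9 existing users and 4 gestures this yields the 1,080 × 16
train set. Every row starts with weight q = 1.

## Adaptive-K weighted KNN

For a query x the squared Euclidean distances to all train rows are
stably sorted. Candidate neighborhood sizes are the multiples of
`k_step = 5` up to `k_max`; at each k the `ceil(N/2)` most frequent
classes are recorded. Three decision paths:

* **Intersection** — if the identity of the leading class changes along
  the grid, the class distributions overlap; `p_f` is the smallest k at
  which another recorded class's count reaches the initial leader's, and
  K = max(1, floor(p_f / 2)).
* **Small ratio** — leader stable and (leader count)/(runner-up count) at
  the largest k is below 2: K = 5. A ratio of exactly 2 falls through to
  the score path.
* **Score** — otherwise each k is scored by purity v = s/k plus density
  den = k/(π d²) (s = leader count within the k nearest, d = the largest
  distance among those leaders, guarded below by 1e-12), each normalized
  by its maximum over the grid; the smallest maximizing k wins.

The vote is weighted: each of the K nearest contributes its weight q to
its class; ties break by smaller summed distance, then smaller class id.
With all weights 1 and a single-point grid this is exactly textbook KNN
(asserted against an independent oracle in the tests).

**Neighborhood cap.** The classifier module's default grid extends to
min(100, n_train), but the session pipeline caps `k_max` at 10. The
reason is the weight dynamics: each qualified sample reinforces the
chosen-K neighbors of its class (q ← 3/(1+e^(−q)), bounded above by 3)
and divides the others' weights by 4. With K ~ 100 a handful of
qualified samples can crush the weights of whole boundary regions,
and the adaptive scheme then performs *worse* than the frozen baseline;
with K ≤ 10 updates stay local to the query (the regime the
weight-update schematic depicts) and adaptation is beneficial. Both
limits are configurable.

## Risk evaluator and train-set replacement

A candidate A assigned to class g is scored as

    risk(A) = 1 / ( cos(A, µ_g) + (1/m) Σ_{j≠g} ‖A − µ_j‖² )

the reciprocal of intra-class similarity (cosine to the own-class
template) plus inter-class separation. The inter-class distances are
measured per coordinate — the channel count m is the characteristic
length — so the two denominator terms are commensurate. This matters:
with raw summed distances the separation term (≈ 5–10 for these
features) swamps the cosine (≤ 1), the farthest-from-template sample
becomes the *lowest*-risk sample of its class, and the gate never fires.
With the per-coordinate form, samples close to their own template and far
from the others score well, remote samples score badly, and the
replacement logic behaves as intended. A denominator ≤ 1e-12 maps to an
infinite-risk sentinel.

After each classification, the farthest same-class row from the template
(p_s) is found; if the test sample's risk is strictly lower than p_s's,
p_s is replaced by the test sample (weight reset to 1, source recorded as
the new user) and the chosen-K neighbor weights are updated with the
predicted label as the qualified label. Replacement conserves the
train-set size and per-class counts. Templates stay frozen during a
session by default (`recompute_templates` flag available): frozen
templates keep successive risk comparisons stationary.

The gate is deliberately conservative and double-edged: predictions are
unsupervised, so a misclassified sample that qualifies inserts a wrongly
labelled row. The scheme's net benefit relies on correct predictions
outnumbering wrong ones; the evaluation below quantifies when that holds.

## Evaluation protocol

Leave-one-user-out over M users. Per fold and cycle, the held-out user's
*repetition groups* (one repetition index of every gesture) are presented
in a seeded random order until all are tested; 10 cycles are averaged by
default, and state resets to the initial representative train set at the
start of every cycle so that cycle averages are comparable. Accuracy is
windows-correct / windows-total (a per-movement majority-vote accuracy is
also reported). Benchmark schemes:

* **A** — pooled baseline: all existing-user synergies, unweighted KNN.
* **B** — frozen representative train set, unweighted KNN.
* **C** — user-dependent ceiling: per-user random 70/30 split.
* **D** — the adaptive method. Forcing the risk gate to reject
  everything makes D prediction-identical to B (asserted in the tests).

All randomness flows from one master seed; equal seeds reproduce reports
bit-for-bit.

## Synthetic cohort generator

The generator produces rectified-envelope-level recordings — the
classifier only ever sees 1 Hz envelopes, so post-envelope morphology is
what matters and generation stays fast. Structure, and what it emulates:

* **Base patterns** — one nonnegative channel-activation profile per
  gesture: Gaussian bumps at distinct ring positions over a small common
  baseline, widened until neighboring gestures overlap strongly
  (pairwise cosine up to ~0.94) while staying distinguishable, the way
  adjacent wrist/hand gestures recruit overlapping electrode sites.
* **User gains** — each user multiplies channels by 1 + ε with ε Gaussian
  (spread `user_gain_sd = 0.3`), *spatially correlated* over ~3
  neighboring channels (Gaussian filter on the ring). Correlated gains
  emulate arm geometry, skin impedance and slight armband rotation; they
  translate and reshape activation bumps, which is what actually breaks
  cross-user recognition. Independent per-channel gains are statistically
  indistinguishable from window noise and cannot reproduce the regime
  where the user-dependent ceiling is high while cross-user transfer is
  poor.
* **Within-session drift** — gains drift per repetition as
  g · (1 + drift_rate · r · δ) along a fixed per-user random per-channel
  direction δ (unit RMS, spatially correlated). A uniform scale-up would
  be invisible to the scale-invariant synergy feature, so drift must act
  on pattern shape.
* **Bursts** — each movement is a 2.5 s Hann-shaped burst (trapezoid
  optional) followed by 2 s rest, with per-burst channel jitter
  (`rep_gain_sd = 0.1`), slow within-burst per-channel fluctuation
  (amplitude 0.4 at ~0.75 Hz, below the envelope cut-off) so successive
  analysis windows differ as they do in real recordings, and a small
  nonnegative noise floor (`noise_sd = 0.002`, ~1 % of burst amplitude).
* **Mis-executed repetitions** — with probability 0.06 per movement the
  subject blends the intended gesture 0.8 of the way toward another one
  (hesitation, wrong grip). These are the "apparently different"
  repetitions offline screening exists for; they give representative
  selection its denoising role — without them a pooled train set with
  3× more rows always edges out the pruned representative set.
* Optional extras (off by default): transition co-contraction phases at
  burst edges, short heavy-tailed channel distortions.

What the generator does **not** emulate: raw interference EMG and its
spectral content, motor-unit physiology, electrode-shift geometry beyond
smooth gain fields, inter-session re-donning effects, and class-dependent
temporal envelope shapes. Passing tests on this generator show the
pipeline's mechanics and the direction of its comparative claims, not
absolute accuracies on any real database.

## Study conditions used by the tests and acceptance script

Desk-scale conditions, fixed once: 10 cohorts (master seeds 0–9) of
6 users × 4 gestures × 16 channels × 6 repetitions, drift 0.05 per
repetition, user gain spread 0.3; scheme D runs 10 presentation cycles
per fold, the frozen schemes 2 (their predictions are
order-independent). The whole study runs in about a minute on one CPU.
Under these conditions the user-dependent ceiling C sits near 90 %,
cross-user baselines near 60 %, the adaptive scheme gains ~1–2 points
over the frozen baseline on average, and its per-step accuracy curve
rises (Spearman ρ ≈ 0.7–0.8 on the mean curve). The per-cohort
final-vs-first-step comparison is noisier: the ~1-point effect sits close
to the per-cohort sampling error at this scale, so individual cohorts can
show flat or slightly negative differences.

## Numerical choices and degenerate inputs

* NMF: ε = 1e-12 denominator guards; all-zero windows are rejected
  (they cannot occur downstream of active-segment extraction).
* Min-max normalization maps constant vectors to zeros.
* k-means: empty clusters keep their previous centroid; displacement
  metric is the max over classes (mean available).
* select_k: d = 0 (all leaders coincide with the query) is guarded by
  d ← max(d, 1e-12); every sort is stable; all tie-breaks are explicit
  (smaller k, smaller class id, smaller summed distance, lower index).
* Risk: zero-norm features or templates are rejected; the tie
  risk(x) = risk(p_s) rejects (strict inequality), so re-presenting a
  train row never churns the set.
* Weights: 3/(1+e^(−q)) has its fixed point just below 2.84, so weights
  stay in (0, 3) under any update sequence; penalties preserve
  positivity.

## Known limitations

* The adaptive gain over the frozen baseline is a ~2-point effect under
  these synthetic conditions, not the double-digit gap reported on real
  multi-user recordings; the generator's users are more mutually
  consistent than real subjects.
* Adaptation can lock in errors: when a whole gesture of a new user maps
  onto another class's territory, qualified samples carry the wrong
  label and reinforce the confusion. This is inherent to unsupervised
  self-training and is visible in individual folds.
* The risk evaluator favors samples far from *other* templates; a sample
  far from everything can score deceptively well. The per-coordinate
  scaling bounds but does not eliminate this.
* NinaPro-convention MATLAB files are supported directly
  (`read_ninapro_mat`; sampling rate supplied per database profile since
  the files do not store it), but no accuracies on DB1/DB5 are asserted
  anywhere in the test suite — reproducing them requires the external
  download and hours of computation.
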