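# Methods

## The classification problem

A collar-mounted triaxial accelerometer samples a dairy cow's neck motion at
25 Hz and broadcasts it in five-sample BLE packets.  In a barn with many
tags, roughly half of those packets are never received, so the recorded
stream has missing runs in multiples of five samples (measured loss in this
setting is around 52–53%).  The task is to classify fixed-length windows of
this stream into three mutually exclusive behaviors — feeding, ruminating,
other — and to understand two practical questions: how much labeled data a
CNN classifier needs, and how much a model pretrained on a different (10 Hz,
lossless) public dataset helps via transfer learning.

## Synthetic study conditions

Real recordings are not required anywhere in the package: the
`cowfeed.synthetic` generator produces labeled cow-day recordings with the
statistical structure the pipeline depends on.

**Bout structure.**  Each recording is tiled exactly by alternating behavior
bouts.  Every class receives its configured share of the recording time
(defaults 19.7 / 36.9 / 43.3% for feeding / ruminating / other, renormalized
to sum to one), split into log-normal bout durations (shape σ = 0.6,
minimum 10 s) and interleaved avoiding same-class adjacency.  Exact
per-class budgeting was chosen over sequential bout drawing because with
only a handful of bouts per class per day, duration variance makes
sequential schemes miss the target fractions by far more than the few
percent the analysis assumes.  With the default class mean durations
(1100, 1140, 800 s) the fraction of bouts shorter than 300 s lands in the
3–9% range per class, matching barn ethogram statistics.

**Signal surrogate.**  Within a bout the tag signal is: a 1 g gravity vector
whose orientation about the neck (X) axis drifts as a bounded random walk
(default scale 0.5 rad/hour) — this is what makes rotational augmentation
matter — plus a class-specific motion component along a fixed body-frame
direction, plus Gaussian sensor noise:

| class      | carrier        | amplitude | envelope                        | noise σ |
|------------|----------------|-----------|---------------------------------|---------|
| feeding    | 1.5–3 Hz       | 0.50 g    | 0.4 Hz on/off bursts (60% duty) plus sparse jerk impulses (rate 0.08/sample, σ 0.5 g) | 0.08 g |
| ruminating | ~1.2 Hz        | 0.18 g    | steady                          | 0.04 g |
| other      | —              | 0         | —                               | 0.03 g |

The burst envelope and jerk impulses encode the physical signature of
feeding (bite/tear activity with pauses) versus the steady chewing rhythm of
rumination.  They matter beyond realism: impulses and envelopes are *local*
features that survive both sensor profiles' very different zero patterns
(the regular comb left by 10→25 Hz zero insertion versus bursty five-sample
loss runs), which is what allows convolutional features learned on one
profile to be useful on the other.  These surrogates are stipulated, not
fitted to real cows; real collar data has richer within-class variability
(posture changes, scratching, social behavior), so passing tests here shows
the pipeline's machinery works under the assumed structure, not that the
absolute F1 values carry over to any barn.

**Sensor profiles.**  The target profile is 25 Hz with packets of 5 samples
dropped independently at probability 0.526; the source profile (emulating a
public halter-labeled dataset used for pre-training) is 10 Hz with no loss.
Missing runs are therefore always multiples of five samples on the target
profile.  All randomness flows through one seed; per-file substreams derive
deterministically from (seed, cow, day).

## Preprocessing

Fixed order for 25 Hz recordings: **impute zeros → high-pass → normalize →
segment**.  Source-profile recordings are first placed onto the 25 Hz grid
by zero insertion (each source sample at its nearest target tick; all other
ticks zero and flagged missing — the 2.5× ratio is non-integer, so
nearest-tick placement is this package's defined semantics).

* Zeros are imputed *before* filtering: the classifiers consume zero-gapped
  inputs end to end, at training and deployment alike.
* The high-pass is a 512-tap (order 511) linear-phase FIR, Hamming window,
  cutoff 0.1 Hz, applied with group-delay compensation (255.5 → 256 slots)
  and zero-padded edges.  An even-length symmetric FIR cannot be produced by
  standard lowpass spectral inversion, so the ideal response is sampled
  directly at fractional delay and a constant correction nulls the DC gain
  exactly; the unavoidable type-II zero at Nyquist is irrelevant at this
  cutoff.  Gain at 1 Hz is within 1% of unity.
* Amplitude normalization scales by the global maximum absolute value over
  all three axes of a cow-day recording (not per window, not per axis);
  all-zero input passes through unchanged.
* Segmentation emits only *pure* windows — every slot labeled and all slots
  the same class; windows straddling bout boundaries or unlabeled spans are
  dropped.  Window starts advance by `window_s × (1 − overlap)` with
  overlap ∈ {0, 0.5}; 50% overlap is a training-set augmentation and is
  never applied to validation windows.

## Augmentation and balancing

Every training window is rotated about the neck axis by a fresh
α ~ Uniform[0, 2π) (collars can rest at any angle).  Whether *all* windows
or only balancing copies are rotated is a switch
(`rotate_every_window`, default on).  Balancing then equalizes class counts
within each cow-day file by adding rotated copies of that file's
minority-class windows, drawn with replacement; a file with no windows of
some class borrows from the class pool across files (or errors if that
fallback is disabled).  Balancing never removes windows.  On a 56-file
fixture with the default proportions this grows the training set by roughly
25–40%.

## Models and training

Both classifiers are scikit-learn estimators over (n, L, 3) window arrays
(or the flattened (n, 3L) layout), with the convolution engine implemented
in numpy inside the package:

* **CNN2**: conv(k=3) → conv(k=3) → dropout 0.5 → max-pool 2 → flatten →
  softmax(3).  Default 64 filters per layer.
* **CNN4**: conv(k=52) → conv(k=52) → conv(k=1) → conv(k=1) → dropout 0.5 →
  global max pool → softmax(3).  Default 16/16/32/32 filters.

Filter counts, pooling and dropout are configurable; "same" padding keeps
every window length in the 5–300 s grid valid (kernel 52 exceeds half of a
5 s window otherwise).  Training is categorical cross-entropy with Adam,
learning rate 0.001, 30 epochs, batch 32 by default — no early stopping and
no schedule.  Dropout, initialization and shuffling all derive from
`random_state`, so single-threaded runs reproduce bit-identically.

**Transfer learning** copies all weights from a source-profile model and
freezes every convolution before the last one (CNN2: layer 1; CNN4: layers
1–3); the last convolution and all subsequent layers are retrained.  Frozen
parameters are bit-identical afterwards (checksummed in tests).

**Prediction** is argmax of the softmax; exact ties resolve to the lowest
class index (feeding < ruminating < other).

## Evaluation

Per-class precision, recall and F1 come from the 3×3 confusion matrix, with
macro F1 the unweighted mean and micro precision the trace over the total.
A class with a zero denominator scores 0 rather than NaN, keeping fold
aggregation total.  Cross-validation is stratified at the window level
(k = 10 in the full protocol) — the ≈ 9/10 training fraction per fold
indicates sample-level splitting; cow-level grouping is available for
leakage-aware evaluation.  Augmentation and balancing apply to the training
partition of each fold only.

The deployment-time label stream can be smoothed by a length-5 categorical
median filter over the integer class codes (the coding order is therefore
part of the contract).  Edges truncate symmetrically (length 3 at the
second and second-to-last positions; endpoints pass through).  Metrics are
reported on unfiltered window predictions; the post-filter is a separate
deployment stage.  Note a single median pass is not idempotent (e.g.
`…1,1,0,0,1,1…` smooths only on a second pass); iterated application
converges to a root signal.

## Experiments

* **Learning curves**: training-set sizes follow the per-file regime
  (n windows per class per cow-day file: 56 files give 168, 336, …, 1680)
  then the fraction regime (10%…100% of the full store).  Folds are split
  on the full store and only the training partition is subsampled, so every
  size is scored against identical held-out windows.  The transfer regime
  can average over independently pretrained source models (one per seed):
  pretraining quality varies draw to draw, and the protocol-level mean is
  the statistic of interest.
* **Window-size search**: full cross-validation per window size in
  [5, 10, 30, 60, 90, 120, 180, 300] s; best size is the argmax of mean
  macro F1, ties broken toward the smaller window (long windows mix
  behaviors at deployment time).
* **Cross-profile evaluation**: a model trained on one profile is scored on
  the other's window store without retraining.

Each (size, regime, fold) combination receives a sub-seed derived from the
top-level seed, so results are independent of execution order.

## Scaled-down problem sizes

The test suite and the acceptance script run the full protocol at desk
scale, as the package's own default study size for automated verification:
20-minute cow-day files with mean bout durations scaled to (90, 95, 70) s —
keeping ~15 bouts per file, the property that matters for per-file
balancing and subsampling — 10 s windows, 2-fold cross-validation, 5–20
epochs, 16-filter CNNs, and a batch size of 4–16 for the minimal-size
learning-curve points (three windows per file is less than one default
batch, which would starve the fixed 5-epoch budget of optimizer steps).
The full-scale day-length defaults remain the package defaults.

## Known limitations

* The surrogate signal model is stipulated; absolute synthetic F1 values do
  not predict real-barn accuracy.  Qualitative orderings (more data helps;
  transfer helps most at small sizes; cross-profile evaluation degrades) are
  the meaningful outputs.
* Cross-profile degradation on synthetic data is stronger than on real
  data: with a single carrier per class, the zero-pattern mismatch between
  profiles dominates, and a source-profile model can fall below chance on
  target windows rather than merely losing accuracy.
* The ±1 s label/clock synchronization uncertainty of real systems is not
  modeled; bout edges are taken at face value.
* The sampling-loss augmentation and gap-imputation schemes that were found
  unhelpful for this system are deliberately not implemented.
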