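# Methods

This note records the modelling and design choices behind `preictal`,
the reasoning where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## Labeling model

All times are seconds, floating point, 0-based and recording-local;
sample index is `floor(t * fs)` and every interval is half-open, so no
boundary sample is counted twice. A trial `(SPH, SOP)` defines the
preictal interval `[onset - (SPH+SOP)*60, onset - SPH*60)`. Seizures
with less than `(SPH+SOP)` minutes of pre-onset signal are skipped with
a logged warning rather than partially labeled. The two shipped trials
are (5, 25) and (10, 20) minutes; their sum may not exceed the 30-minute
pre-onset span a usable seizure must have.

Interictal spans keep a safety margin (default 60 minutes,
configurable) from the widest preictal definition (30 minutes before
onset) and from the ictal interval itself, because peri-ictal dynamics
are neither clean baseline nor labeled preictal. Whether interictal
windows should come from the same files as preictal ones is not
prescribed; the pipelines here draw them from seizure-free recordings,
which is the cleaner protocol for short fixtures.

## Preprocessing

A 4th-order Butterworth bandpass (0.5–100 Hz) and a Q=30 IIR notch
(60 Hz; set 50 Hz outside the Americas) are applied forward-backward:
zero phase matters because a phase shift would move the preictal
boundary relative to the annotations. Normalization is a per-channel
z-score over the whole recording — it preserves relative within-recording
dynamics, and its contract (mean 0, sd 1 per channel, idempotent,
constant channels rejected by name) is what the tests pin down.

Separately from recording-level normalization, the encoder standardizes
each channel of each input window (zero mean, unit variance per channel
per 5-s segment) before the first convolution. This makes the classifier
invariant to slow gain drift and to how a window's parent recording was
scaled — without it, a model can learn overall amplitude scale as a
shortcut, which is not a transferable preictal feature and behaves
erratically across recordings of different lengths and compositions.

## Windowing and balancing

Windows are 5 s (1280 samples at 256 Hz), giving 16 x 1280 segment
matrices. Test sets are strictly non-overlapping and unbalanced.
Training sets are balanced exactly: the interictal target is the
non-overlapping interictal count (optionally capped by
`max_per_class`); the preictal overlap escalates deterministically
through {0, 0.25, 0.5, 0.75, 0.9} until the preictal count reaches the
target, and both classes are then subsampled to the common count with a
seeded uniform draw that preserves chronological order. The escalation
grid is a reproducibility device — any fixed schedule would do, but it
must be deterministic.

## Classifier

The encoder is fixed at two 3x3/stride-1 convolutions with batch
normalization in every layer, ReLU, dropout, and a single 2x2/stride-2
max pool after both convolutions; block order is conv → batch norm →
ReLU → dropout. Filter counts default to (16, 32), giving a flattened
feature length of 32·8·640 = 163 840; the FC head has two hidden layers
(256, 64) with batch norm and dropout 0.5 and a 2-unit softmax output.
The SVM head (linear, C = 1) is fitted on the frozen flattened features
after the encoder has been trained end-to-end with a temporary FC head.
Both heads expose the same monotone score: softmax preictal probability
(threshold 0.5) or decision-function value (threshold 0).

Training is Adam (lr 1e-3, batch 32), cross-entropy, with a stratified
validation split (10 %), early stopping on validation loss, and
restoration of the best-epoch parameters. Everything — initialization,
shuffling, dropout masks, the validation split — derives from one seed,
and the whole stack is numpy, single-threaded; two runs with the same
seed produce bit-identical models. The hand-written backward passes are
verified against central-difference gradients in the test suite.

## Few-shot adaptation

Adaptation to a new patient freezes the full convolutional encoder:
weights, biases, batch-norm affine parameters *and* running statistics.
Freezing the statistics makes the encoder a pure function, so tuning can
run on cached features and the bit-identity of the encoder before/after
fine-tuning is checkable exactly. The FC head continues training at
lr/10 for at most 20 epochs (few samples; a large step would erase the
source knowledge), while an SVM head is simply refitted. Seizure splits
are chronological by default — tune on the earliest seizures, test on
the next ones — which is the clinically honest ordering; a seeded random
split exists behind a flag. Tuning data is audited: any segment from a
non-target patient raises a contamination error.

## Alarms and metrics

The segment-to-alarm rule is not part of the prediction model and is
fully configurable: an alarm fires at the end of a window when at least
k of the last n binarized scores are positive (default 8-of-10), then a
refractory period (default (SPH+SOP)·60 s) suppresses firing; k=n=1
reproduces naive per-segment alarming. An alarm at time t is true iff an
onset lies in the closed window [t+SPH, t+SPH+SOP]; a seizure is
predicted iff at least one true alarm maps to it. FPR/h divides false
alarms by the monitored hours of the interictal test recordings (false
alarms and hours are both accrued only there, keeping numerator and
denominator consistent). AUC is the rank-based (Mann–Whitney) area under
the ROC of raw segment scores, ties counted ½. Cross-validation is
leave-one-patient-out. Table averages are unweighted means, reported to
2 decimals (sensitivity) or 3 (FPR, AUC).

## The synthetic cohort

The simulator emulates the structure of CHB-MIT-style data — 16
channels, 256 Hz, one recording per seizure (default 40 min pre-onset +
5 min ictal + padding) plus seizure-free interictal recordings — not its
physiology. Per patient, a seeded set of traits fixes: a 16x16 mixing
matrix for 1/f pink-noise sources, a 10 Hz rhythm with per-channel
amplitude/phase, a persistent narrowband background rhythm
(beta-burst-like), and per-channel weights for the preictal signature.
The signature is 6 Hz-wide band-limited noise whose amplitude ramps
linearly from 0 to `effect_size` x background RMS over the 30 minutes
before onset; `shift` displaces its center (30 Hz for source patients).
Ictal spans are a 3 Hz high-amplitude oscillation. A slow multiplicative
gain drift (±15 %, ~10-minute period) models electrode-impedance
variation.

Three design points deserve explanation:

- **The background rhythm.** Without narrowband structure in the
  interictal background, "any excess high-frequency power" is a
  sufficient discriminator and transfers to *any* shifted signature
  band, so domain shift would be free. The background rhythm occupies
  whichever of the two spectral niches (≈30 Hz / ≈45 Hz) the patient's
  signature does not, which forces frequency-specific discrimination and
  makes the +15 Hz target shift a genuine distribution shift: the
  target's background now lives exactly where the source cohort's
  signatures were.
- **The gain drift** (together with the encoder's per-window
  standardization) removes overall amplitude scale as a learnable
  shortcut. In early versions the per-recording z-score made seizure
  recordings globally down-scaled relative to seizure-free ones — a cue
  that classifiers found instantly and that inverted within a recording.
- **Effect size and weights.** `effect_size` defaults to 3.0 with
  per-channel signature weights U(0.5, 1): scalp potentials are spatially
  smeared by volume conduction, so a cortical source contributes to most
  bipolar derivations. These values put a plain Welch band-power detector
  well above 0.9 segment AUC on source-distribution patients (the test
  suite computes this) while staying below 1: because the ramp starts at
  zero, the earliest preictal windows are *undetectable in principle*, so
  imperfect segment AUC is a property of the labeling, not a model
  deficiency.

What passing the synthetic benchmark shows: the pipeline's mechanics
(labeling, balancing, training, freezing, adaptation, adjudication) work
end to end, and the few-shot procedure recovers performance lost to a
controlled spectral domain shift. What it does not show: performance on
real scalp EEG, whose preictal signatures are far subtler and less
stationary, and which contains artifacts (EMG, eye blinks, electrode
pops) the simulator deliberately omits.

## Benchmark problem sizes

The transfer benchmark (`preictal.experiment.run_fewshot_benchmark`, also
run by `scripts/acceptance.py`) uses desk-scale sizes chosen so the whole
five-seed experiment fits comfortably on one CPU: 31-minute pre-onset
blocks with 1-minute ictal spans; 4 source patients (1 seizure + 25 min
interictal each); one held-out source-distribution patient (2 seizures);
one target with shift +15 Hz, 6 seizures (first 3 tune, next 3 test) and
two 30-minute interictal recordings (one for tuning, one for testing);
at most 300 training segments per class; encoder widths (4, 8) with FC
hidden (32, 16); at most 8 epochs with early stopping (patience 3).
Each seed simulates its own cohort; reported AUCs are seed averages.

## Numerical choices and degenerate inputs

float32 throughout the network; convolutions evaluated as nine shifted
BLAS matmuls (fastest layout for 16 x 1280 inputs); batch-norm epsilon
1e-5; batches of fewer than 2 samples are skipped (batch statistics
undefined); He initialization; non-finite losses raise immediately
rather than silently continuing. The EDF writer quantizes to 16 bits
against a per-channel symmetric physical range, so round-trip error is
bounded by max|x|/32767; it requires integer sampling rates and
whole-second recordings (all fixtures satisfy both). Constant channels,
single-class AUC inputs, zero monitored hours, and empty tune sets all
raise informative errors instead of returning degenerate numbers.

## Known limitations

- The per-patient CHB-MIT numbers in the published tables are not
  reproducible here by construction: they depend on the real corpus and
  on unstated training hyperparameters. The package reproduces the
  *aggregation* of those printed values and demonstrates the method's
  claims on the synthetic cohort instead.
- Leave-one-*seizure*-out evaluation, GAN-style augmentation, artifact
  rejection, montage re-referencing and resampling are out of scope.
- The alarm rule is a pragmatic default; the study it follows does not
  state one, so absolute FPR/sensitivity values depend on it (k, n,
  threshold and refractory are all configurable).
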