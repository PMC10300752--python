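# Methods

## Problem and data model

The task is 3-way classification of breathing condition — baseline, loaded
(breathing against resistance), rapid/shallow (paced tachypnea at
25 breaths/min) — from short windows of chest-wall NIRS hemodynamics.
Recordings are per-participant, per-condition time series sampled at 10 Hz
(baseline 3 min, the other conditions 5 min), with channels O₂Hb, HHb and
optionally THb/TSI. Only O₂Hb and HHb may feed the classifier: THb is their
sum and TSI their ratio, so both are excluded by design and the reader
refuses them explicitly. The classifier's input unit is a 64-sample
(6.4 s) window, cut left-to-right; windows are non-overlapping by default
(stride = window length), with overlap available as an option. A trailing
remainder shorter than one window is discarded.

Preprocessing is deliberately minimal: per-window, per-channel zero-mean
scaling (removing the offset and most slow drift while preserving
oscillation amplitude, which is class-informative). It can be disabled
(`--no-normalize`), and the choice is recorded in each run manifest. No
automatic artifact detection is performed; the reader accepts an optional
JSON exclusion-mask sidecar listing sample ranges to drop.

## Splitting

`stratified_random` splits within each class with train count
`ceil(train_fraction × class_size)`. Ceiling is the only rounding
convention consistent with all three published per-class train/test rows
(425/531, 624/780, 700/874 at 0.8); with the defaults those counts are
reproduced exactly for any seed. `subject_level` assigns whole participants
(`ceil(0.8 × 21) = 17` train, 4 test), guaranteeing no subject appears on
both sides. Splits are deterministic functions of the seed.

## Architecture

Pre-activation bottleneck residual units: BN → ReLU → 1×1 conv → BN → ReLU
→ 1×k conv → BN → ReLU → 1×1 conv, added to a shortcut. The shortcut is the
identity when shapes match; when channels or stride change it is a 1×1
projection convolution (with matching stride) applied to the pre-activated
input — the Pre-ResNet convention, since no projection type is dictated by
the design itself. Stride-2 downsampling lives in the *first* (1×1) conv of
the first unit of Stage 1 and Stages 3–4. The stem (Stage 0) is a plain
1×5 convolution on the raw input, stride 1; a final BN → ReLU precedes
global average pooling. Convolutions carry no bias (redundant with the BN
shift); the classifier keeps its bias. Note one published description says
feature dimensions double in Stages 1, 3 and 4; the architecture table has
Stage 1 entirely at 16 channels, with widening occurring at Stage 2's
bottleneck expansion and at Stages 3–4. We follow the table.

Weight initialization is He fan-in for convolutions, BN scale 1 / shift 0 —
unstated in the original description; chosen to match the ResNet lineage.
Builds are deterministic in the seed.

The `ds` control variant has no Stage 1; "halving the signal" is
implemented as taking every second sample, with non-overlapping pair
averaging as an option.

### Accounting conventions

* **Weighted layers** count convolutional and fully connected layers only
  (no BN/ReLU, no projection shortcuts): 1 + 3 + 3×12×3 + 1 = 113 for the
  Stage-1 variants at 12 blocks/stage, 110 for `ds`.
* **FLOPs**: 2 per multiply–accumulate, summed over main-path convolutions
  and the classifier at the stated input length; projections, BN, ReLU and
  pooling excluded. This yields 15,019,520 (15.0 M) for `stage1_k5` at
  length 64; including projections would give ≈16 M.
* **Parameters**: the headline figure uses the same main-path convention
  (717,523 → 0.7 M for `stage1_k5`), which is the only reading under which
  the published 0.7 M figure and the FLOP convention agree; the full
  trainable total including projections is 759,763 (0.76 M) and is always
  reported alongside (`LayerAccount.total_parameter_count`,
  `count_parameters(model)`).

All counts are verified in the test suite against an independent
closed-form per-layer ledger.

## Training

SGD with momentum 0.9, batch size 64 (last partial batch kept), 120 epochs
by default, cross-entropy loss, learning rate 0.1 divided by 10 every 30
epochs. The schedule is 0-based: drops land at epochs 30, 60, 90. Weight
decay is 1e-4 (a lineage convention; it is not part of the published
recipe) and applies to convolution/classifier weights only, not to BN
parameters or biases. No early stopping, augmentation or class weighting.
Evaluation uses the final-epoch model. Training is deterministic given the
seed and data: the only stochastic elements are initialization and the
per-epoch shuffle, both driven by seeded generators.

The repeated-run protocol (`run_experiment`, default 5 repeats) re-derives
both the split and the initialization from the master seed and run index
(whether the original five tests re-drew the split is not stated; a flag
fixes the split instead). It reports per-run held-out accuracy with mean,
standard deviation and best, and attaches the best run's confusion matrix
and recalls.

### The NumPy engine

The network and backpropagation are implemented directly in NumPy
(`breathnet.nn`): im2col-based 1D convolution, batch normalization with
running statistics, ReLU, global average pooling, a fully connected head,
softmax cross-entropy and momentum SGD. Float32 throughout. Backward passes
are validated against central-difference numerical gradients, and the
convolution forward against an independent scipy correlation reference. At
this model size (≈0.76 M parameters, ≈15 M FLOPs/window) a forward+backward
epoch over 720 windows takes a few seconds on one CPU core.

## Metrics

Accuracy = 100 × correct / total. Confusion matrices use rows = true
labels, columns = predicted; per-class recall is the diagonal over row
sums; row normalization divides by row sums, with empty rows surfaced as
undefined (NaN/None), never silently zero. Balanced accuracy is the
unweighted mean of the three recalls × 100. The class order is fixed
everywhere as (baseline, loaded, rapid/shallow). Values are carried at full
precision and printed at two decimals. One printing quirk worth noting:
the published balanced accuracy of the `ds` variant, 89.66%, is the
two-decimal *truncation* of (0.92+0.81+0.96)/3 = 89.666…%; the acceptance
script reproduces the printed figures with the same truncating convention.
Prediction ties break toward the lowest class index (`argmax` convention).

## Synthetic generator

`breathsim` emulates only the structure the classifier relies on: breath i
has rate rᵢ ~ N(rate_mean, rate_jitter) and amplitude
aᵢ ~ N(amplitude_mean, amplitude_jitter); phase accumulates 2π per breath;
the waveform is sin φ + 0.2 sin 2φ (the fixed second harmonic prevents the
classes from being trivially linearly separable); a slow sinusoidal drift
and white noise are added. HHb is anti-phase at 0.4× the O₂Hb amplitude
with independent noise of the same s.d. (hence lower SNR, as for real
HHb); THb is their sum. Defaults:

| condition      | rate (breaths/min) | rate jitter | amplitude (a.u.) | amp. jitter | drift | noise s.d. |
|---------------|--------------------|-------------|------------------|-------------|-------|------------|
| baseline      | 14                 | 1.0         | 1.0              | 0.15        | 0.5 / 60 s | 0.1  |
| loaded        | 12                 | 1.0         | 2.5              | 0.375       | 0.5 / 60 s | 0.1  |
| rapid/shallow | 25                 | 2.0         | 0.5              | 0.075       | 0.5 / 60 s | 0.1  |

Only the 25 breaths/min pacing and the qualitative ordering (loaded
largest amplitude; rapid shortest period, smallest amplitude; baseline
intermediate) are grounded in the real protocol; every other number is a
generator choice — amplitude jitter at 15% of each mean, rate jitter ~1
breath/min (2 for the paced condition, which is harder to hold steady) —
fixed once here. Absolute scales are arbitrary; no attempt is made to
match real amplitude units. `make_synthetic_dataset` builds per-"subject"
recordings (one per condition per subject, mild between-subject variation:
rate ±0.5 breaths/min s.d., amplitude ×N(1, 0.1)), so subject-level
splitting is exercisable, and returns an exactly balanced window set.

**What passing on synthetic data shows — and what it does not.** The
synthetic classes are separable by two window-level features (dominant
frequency, peak-to-peak amplitude): a training-free periodogram-threshold
oracle (`PeriodogramOracle`) reaches ≈97–98%. A network that trains
correctly should approach 100% here, so the synthetic benchmark verifies
the pipeline's mechanics (windowing, training dynamics, evaluation), not
real-world difficulty: real NIRS recordings carry artifacts, physiological
confounds and between-subject variability the generator deliberately
omits (no cardiac pulsation, Mayer waves, or motion artifacts).

## Problem sizes in the shipped checks

The test suite and acceptance script run the full 113-layer model on 300
windows/class (720 train / 180 test) for 40 epochs — enough for the
learning-rate schedule's first drop to bite and for held-out accuracy to
saturate on this generator — and exercise everything else on toy
configurations (1 block/stage) and small window sets. The full 120-epoch
recipe is the library default.

## Numerical notes and edge cases

* Batch norm uses eps 1e-5, running-stat momentum 0.1; evaluation uses
  running statistics, so inference is deterministic and batch-size
  independent.
* A recording shorter than one window yields zero windows (not an error);
  a class or subject pool too small to populate both split sides raises.
* Non-numeric cells in a CSV raise naming the row and column; nothing is
  imputed.
* Degenerate generator settings (zero jitter/drift/noise) reduce to an
  exact closed-form sinusoid, which the tests assert to numerical
  precision.

## Known limitations

* The NumPy engine targets this architecture family; it implements only
  the layers used here and runs on CPU.
* Synthetic results do not transfer to claims about real recordings (see
  above); the published real-data accuracies (≈88–92%) require the
  original dataset.
* Checkpoints store raw arrays keyed by parameter order and are not
  portable across architectural changes.
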