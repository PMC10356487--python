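# Methods

## Problem and pipeline

kicksense estimates *what* football motion a player performed and *how
intensely* they performed it, from a single ankle-worn 6-axis IMU
(tri-axial accelerometer + tri-axial gyroscope). The pipeline is

1. **Denoising** — a three-point moving average on each channel.
2. **Segmentation** — peak detection on the Euclidean norm of the filtered
   acceleration; one fixed-length window per detected motion burst.
3. **Spectral min/max features** — an STFT per sensor per window; the S
   smallest and L largest power densities, pooled over all time–frequency
   cells, form an ordered (SA, LA, SG, LG) matrix.
4. **Augmentation** — local-mean downsampling (two levels) plus seeded
   per-class row randomization.
5. **Multitask LSTM** — one shared recurrent encoder feeding a softmax
   classification head and a regression head, trained jointly under a
   weighted composite loss.
6. **Evaluation** — accuracy, macro F1, mAP for classification; MAE and
   MAPE for intensity.

## Preprocessing

The three-point filter is `out[i] = mean(x[i-1..i+1])`. At the boundaries
the window shrinks to the two available samples, which preserves length
without padding bias. Note the filter's frequency response at sampling rate
fs crosses zero near 0.33·fs (≈16.7 Hz at 50 Hz): motion content near that
frequency is attenuated essentially to nothing, which constrains what the
synthetic generator may emit (below).

Segmentation finds candidate peaks above a configurable height on the
filtered acceleration norm, then keeps them greedily by descending height
(earlier index wins ties) subject to a minimum separation (default: half
the window length). Each kept peak centers a window of `window_len` samples
(default 128, i.e. 2.56 s at 50 Hz, matching the public-dataset
convention); windows that would cross a recording boundary are discarded.
The channel driving detection and the threshold are deliberately exposed as
configuration: no fidelity to any particular hardware is claimed.

## Spectral features

The STFT cuts a signal into frames of `frame_len` samples (default 16)
advancing by `hop` (default 8, i.e. 50% frame overlap), applies a taper
(Hamming by default; Hann and rectangular available), and takes the DFT of
each frame. Power densities are |coefficient|² over every time–frequency
cell of the window, pooled across frames. Per sensor, the S smallest
densities (ascending) and L largest (descending) are kept; S must equal L.
A window therefore contributes S + L feature vectors per sensor pair:
100 at S = L = 50 and 200 at S = L = 100.

By default densities are computed on the Euclidean norm of the three axes
of each sensor (one pool for the accelerometer, one for the gyroscope,
4 columns), which is invariant to sensor-orientation displacement. A
per-axis mode (2 columns per axis) exists for datasets that supply only
accelerometer channels.

Numerical notes: sorting is a full `np.sort` (exact, duplicates kept —
multiset semantics); scaling a window's signal by a scales every matrix
entry by a² (power homogeneity, tested); a zero window yields a valid
all-zero matrix.

## Augmentation

Level 1 averages non-overlapping row pairs of a feature matrix
(floor(n/2) rows); level 2 repeats the operation on the level-1 rows
(floor(floor(n/2)/2) rows). Variants are *new samples* carrying the
parent's labels, not rows interleaved into the parent: separate samples
keep the sequence length consistent within each provenance level, which a
sequence model requires. Pairwise means of sorted columns stay sorted and
never escape the parent's column hull, so the structural invariants
survive augmentation. With both levels and n ≥ 4, the dataset size exactly
triples. A sliding-pair variant (n−1 rows) is available behind a flag.

Whether the second level means "average across columns" or "a second pass
of row averaging" is genuinely ambiguous in the source material; the
second-pass reading is implemented because it preserves the 4-column
layout of the randomized dataset.

The per-class interline randomization permutes which sample of a class
occupies each of that class's positions, reproducibly from a seed, leaving
the per-class multiset unchanged.

## Multitask LSTM

The network is implemented directly in NumPy: one or two stacked LSTM
layers (gate order input/forget/cell/output, forget bias initialized to 1,
uniform ±1/√fan-in weights from a seeded generator) encode the feature-row
sequence; the final hidden state feeds (a) a fully connected softmax layer
over C classes and (b) a regression branch — optionally a ReLU fully
connected layer (default 32 units) with dropout (default rate 0.5),
then a scalar intensity output. Both heads read the same encoder state
from one forward pass.

The training objective is

    L = α_c·Lc + α_i·Li + r·Σ_w (|w| + w²)

with Lc the mean cross-entropy (probabilities clamped at 1e−12 inside the
log so a confident wrong prediction stays finite), Li the mean squared
error of the intensity estimate (nonnegative by construction), and an
elastic L1+L2 penalty with constant r = 2e−4 on all weight matrices.
Defaults: α_c = 1 and α_i = 0.001 in count mode — intensity losses start
roughly three orders of magnitude above the classification loss — or
α_i = 0.1 in completion-rate mode. Gradients are hand-derived
backpropagation through time and are verified against central differences
in the test suite (observed agreement ~1e−9). Optimization is Adam
(β = 0.9/0.999, ε = 1e−8) at learning rate 2e−4 with *decoupled* weight
decay 1e−5 on weight matrices — "weight decay" and the explicit elastic
penalty are distinct mechanisms and both are implemented. Default batch
size 300; default iteration budget 14,000 (a 50,000-iteration setting is
also quoted in the source hyperparameter list; both are selectable, the
smaller is the default).

Setting α_i = 0 freezes the regression head entirely (no updates, no
penalty), making the model an exact single-task classifier; symmetrically
for α_c = 0. In count mode the intensity output is rounded to a
nonnegative integer at inference only; training regresses the real value.

Inputs are z-scored per channel with statistics fitted on the training
data only. Augmented variants are shorter sequences; when stacked they are
front-padded, and padding normalizes to exactly zero (a silent prefix).
Per-position z-scoring and log-compression of the power densities were
evaluated and classified worse, so plain per-channel z-scoring stands.

## Synthetic data generator

The generator emulates the study conditions — two motion classes
(inside-foot pass, arch shot), 20 motions per class per subject, default
10 subjects (400 labeled windows), 50 Hz sampling. Each motion is a
two-sided exponentially damped cosine burst (peak exactly at the window
center) injected on all six channels (gyro scaled 20 deg/s per m/s²
of accel burst), over Gaussian noise (σ = 0.3 m/s²), slow sinusoidal
baseline drift (0.5 amplitude, 0.2 Hz) and gravity on the accelerometer
z axis. Class spectra are disjoint by construction: pass bursts at
3–6 Hz (amplitude ~N(8, 2²) m/s², 0.5 s), shot bursts at 10–13 Hz
(~N(14, 3²), 0.4 s). The shot band is kept inside the passband of the
three-point denoiser (zero near 16.7 Hz at 50 Hz) — bursts the
preprocessing itself would annihilate cannot be segmented by any method.

Integer intensity labels derive monotonically from the burst peak
amplitude: level = round(K·amp/amp_ref) clipped to [0, K], K = 10 levels,
amp_ref = the largest class mean + 3 sd. A completion-rate mode divides by
K to emit values in [0, 1], exercising the α_i = 0.1 configuration. The
generator is an emulation, not a biomechanical model: it has no
subject-specific gait signature, no inter-motion variability in burst
shape, and no sensor saturation. Tests passing on it show the pipeline's
machinery is correct under controlled, separable conditions; they say
nothing about accuracy on real football recordings.

## Evaluation choices

Macro-averaged F1 (standard for two balanced classes); AP per class is the
area under the one-vs-rest precision–recall curve from ranked probability
scores (step interpolation, as in scikit-learn), mAP their mean over
classes present in the truth; MAPE excludes zero-valued truths from the
denominator and reports the exclusion count, or is absent if every truth
is zero. Splits are seeded and stratified by class (unstratified fallback
with a warning when a class has fewer than 2 samples). Cross-validation
offers both seeded stratified k-fold and leave-one-subject-out; the two
protocols are reported separately, never blended.

## Desk-scale experiment sizes

The parameter-recovery experiment in the acceptance tests uses the default
generator (400 windows), S = L = 8 feature rows, the single-layer 32-unit
multitask model, batch 100 and the default 14,000 iterations, three seeds;
metrics are averaged over seeds. At this scale a probe linear classifier
separates the classes perfectly, so remaining held-out error reflects LSTM
optimization rather than generator ambiguity. The augmentation is applied
to the training split only and evaluation uses held-out original windows —
augmenting before splitting (as the source protocol does) is also
supported in the pipeline command, but leaks augmented variants of test
parents into training, so the experiment uses the leak-free order.

## Known limitations

- The count-mode α_i = 0.001 was calibrated for intensity losses starting
  near 6000; on targets with other scales the regression head still trains
  (Adam is scale-invariant per parameter) but the encoder remains
  classification-dominated.
- The on-disk feature container is a versioned CSV; fine for desk-scale
  datasets, not for millions of windows.
- Peak segmentation assumes isolated bursts; overlapping motions closer
  than the separation threshold collapse to the higher peak.
- No GPU path; the NumPy implementation is adequate for the data sizes
  here (about 4 ms per training step at batch 100, T = 8, H = 32 on one
  CPU).
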