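# Methods

## Problem and approach

`gaitfuse` classifies the instantaneous gait sub-phase of a walking person —
swing, pre-stance, mid-stance, ter-stance — from wearable-sensor streams, the
control signal a lower-limb rehabilitation exoskeleton needs to time its
assistance. Three information sources are fused:

* six channels of surface EMG (vastus medialis, vastus lateralis, biceps
  femoris, semitendinosus, gastrocnemius lateralis, tibialis anterior) at a
  nominal 1500 Hz;
* one knee-joint flexion angle channel at 50 Hz;
* six plantar-pressure channels (heel/sole/toe of each foot) at 50 Hz,
  sharing the angle channel's A/D clock.

Plantar pressure is never an input to the classifier: it supplies the
*labels*. Each study-foot pressure channel is binarized into a foot switch,
and the 3-bit (heel, sole, toe) state maps to a sub-phase: `000` swing,
`100` pre-stance, `001` ter-stance, and any sole-loaded or multi-sensor
state (`110`, `111`, `010`, `011`) mid-stance. The state `101` does not
appear in the standard mapping; because two sensors are loaded and the state
can only arise transiently during heel-to-toe rollover, we assign it to
mid-stance so that the mapping is total (it is flagged in debug logs).

## Multi-rate alignment

The sEMG rate must be an integer multiple R of the low rate (R = 30 for
1500/50 Hz). Low-rate tick *k* owns the half-open sEMG block
[R·k, R·(k+1)); these blocks tile the stream with no gaps or overlaps, and
trailing sEMG samples that do not fill a block are discarded. This
sample-index contract — rather than timestamp search — is what makes the
non-overlapping 30-sample/30-step feature windowing land exactly on the
50 Hz clock, one feature frame per tick. How two free-running hardware
clocks should be reconciled under drift is out of scope; the integer-ratio
block contract is the package's stand-in.

## Denoising

sEMG is band-passed 20–450 Hz with a 4th-order digital Butterworth (two
poles per edge, bilinear transform) and then notched at 50 Hz with a
2nd-order IIR notch. The notch bandwidth is not prescribed anywhere, so we
chose quality factor Q = 30 (≈ 1.7 Hz of −3 dB width) — narrow enough to
leave the 40–60 Hz sEMG content essentially untouched. A narrow notch rings
for roughly a second, so amplitude-response tests measure √2·RMS over the
central 80 % of an 8 s tone, past the transient.

Filters are applied per channel. The default is zero-phase
(forward–backward) application, appropriate for offline training data; a
causal single-pass mode exists for streaming use. Whether a real-time
deployment would accept the causal filters' group delay is a systems
question the package does not answer.

## Features and fusion

Per channel and per 30-sample window (step 30, i.e. non-overlapping):

* MAV = (1/N)·Σ|xᵢ|
* RMS = √((1/N)·Σ(xᵢ − x̄)²)

The RMS here is deliberately the **mean-centered** form — a window standard
deviation — which is translation-invariant (RMS(x + c) = RMS(x)); the
classic uncentered RMS is available via `rms_eq2(..., centered=False)` for
users who want the conventional amplitude feature. Both features scale
linearly: f(a·x) = |a|·f(x).

Six channels × two features give 12 feature columns; the knee angle is the
13th. A sliding window of length 20 (step 1 — the step is a free choice;
step 1 maximizes the number of training samples) slices the T×13 matrix
into 20×13 feature images. Each image is labeled with the phase at its
*last* row, so the classifier learns to name the phase at the current
instant from the preceding 0.4 s of context. Channel order (MAV×6, RMS×6,
angle) is fixed and recorded in dataset metadata.

Per-channel z-score normalization is fit on the training portion only and
applied to both portions; it can be disabled for a strictly raw-feature run.

## Splits

Two evaluation modes, treated as alternatives:

* **temporal** — first 80 % of images train, last 20 % test;
* **5-fold cross-validation** — five *contiguous* blocks, each tested once.
  Blocks are contiguous in time rather than shuffled because step-1 images
  overlap in 19 of 20 rows; random folds would place near-duplicates on
  both sides of the split and inflate accuracy.

## Classifiers

The primary model is a pooling-free CNN: the 20×13 input is already
low-dimensional, and pooling would discard signal rather than nuisance
resolution. Stack: Conv 3×3×32 (same padding, stride 1, ReLU) → Conv
3×3×64 → flatten → dense 128 (ReLU) → softmax over 4 classes. Exact layer
counts for this architecture are not prescribed anywhere; these are the smallest
conventional pooling-free choices and every count is configurable.

Training: Adam (lr 0.001), batch size 100, cross-entropy loss, softmax
output. The reference regime is 300 epochs; the package default is 50,
which on the default synthetic data is well past convergence — the
`strict_regime` flag restores 300/100/0.001. One integer seed drives
initialization and per-epoch shuffling; same-platform reruns reproduce
loss histories exactly (bit-exactness across platforms is not promised).

No deep-learning framework is a dependency: the CNN, BPNN and LSTM (and
their backprop and Adam) are implemented directly in NumPy (`_nn.py`), with
every layer's gradients verified against finite differences in the test
suite. Baselines: RBF-kernel SVM (scikit-learn, C = 1, gamma = "scale") on
the flattened 260-vector, with one-vs-rest decision scores softmaxed into
pseudo-probabilities; BPNN = one 128-unit hidden layer; LSTM = one 64-unit
layer over the 20-step sequence. The baselines' hyper-parameters are
conventional defaults — they are named comparators, not tuned rivals.

The single-information condition (sEMG only) drops the knee-angle column,
12 channels instead of 13, leaving everything else identical.

## Evaluation

Accuracy is the exact-match fraction — the multi-class reading of
(TP+TN)/(TP+TN+FP+FN). F1 per class is one-vs-rest 2TP/(2TP+FP+FN); since
the aggregation of the single printed F1 numbers is not stated anywhere, we
report per-class values plus an unweighted **macro** average, labeled as
such. When a class is absent from both truth and prediction the F1 is 0
with a warning rather than undefined. Confusion matrices are true-class ×
predicted-class; row normalization puts per-class recall on the diagonal.
Cross-validated reports average metrics over folds without weighting and
report the across-fold standard deviation.

## Synthetic data

No public recordings accompany this problem, so the simulator is
first-class, tested code; its defaults define the study conditions used by
the test suite and the acceptance script.

* **Schedule** — cycles of fixed duration split into pre-stance /
  mid-stance / ter-stance / swing with fractions (0.15, 0.40, 0.15, 0.30),
  a stance-dominated cycle. Default 20 cycles of 1.6 s at 50 Hz → 1600
  low-rate samples, 48 000 sEMG samples, ~1581 feature images — a
  desk-scale problem size chosen so the full CNN train/evaluate cycle runs
  in minutes on one CPU. Walking-speed presets map 1/2/3 km/h to
  2.2/1.6/1.3 s cycles; these are simulator conventions.
* **Pressure** — on/off levels 1/0 with bounded uniform noise (default
  ±0.02); mid-stance rolls heel+sole → full-foot → sole+toe in equal
  thirds, following the heel-to-toe rollover. Left foot replays the
  schedule half a cycle out of phase.
* **Knee angle** — 5° baseline, a single sin² flexion peak of 60° over each
  swing run, a 15 %-amplitude loading-response bump over stance, 0.5°
  Gaussian noise. sin² bumps have zero value and slope at run edges, so the
  waveform is smooth across phase boundaries.
* **sEMG** — per muscle, unit-variance 20–450 Hz band-limited noise (shaped
  by the package's own band-pass) scaled by a per-phase activation
  amplitude, plus a 0.05 white-noise floor and a 0.2-amplitude 50 Hz line
  sinusoid that the notch must remove. The default activation profile
  follows qualitative gait physiology (quadriceps at loading,
  plantar-flexor building to push-off, dorsiflexor and hamstrings in
  swing); swing and pre-stance deliberately share elevated flexor activity
  so that the knee angle carries genuinely complementary information —
  which is what makes the multi- vs single-information comparison
  meaningful rather than vacuous.

What the simulator does **not** emulate: motion artifact, electrode lift,
amplitude drift with fatigue, inter-subject variability, stochastic phase
durations, co-contraction dynamics, or any musculoskeletal mechanics. The
synthetic envelopes are piecewise constant at phase boundaries, which makes
the classes more separable than real sEMG. Consequently, passing tests
demonstrate that the pipeline is implemented correctly and that fusion
helps when the fused channel is informative — they do not certify the
accuracy levels achievable on human recordings.

## Numerical choices and degenerate inputs

* Softmax subtracts the row maximum before exponentiation (stable at
  |logit| = 1e4); cross-entropy clamps true-class probabilities at 1e-12.
* Argmax ties in prediction resolve to the lowest class code.
* Schmitt-trigger binarization uses the 5th percentile as baseline and the
  95th−5th percentile as range (offset-robust); defaults threshold 0.3,
  hysteresis 0.05 of range. A zero-range channel is held off with a
  warning. Default label smoothing is off (length 1) so the standard
  mapping is exercised unmodified; a majority-vote smoother is available.
* Empty feature windows, too-short streams and sub-k datasets raise typed
  errors or return explicitly empty results with warnings; a feature/angle
  length mismatch of one sample (trailing partial block) is truncated,
  anything larger is an alignment error.
* Timestamps are validated uniform within 1 %, and declared versus inferred
  rates must agree within 1 %.

## Known limitations

* Single-subject, single-session scope: no cross-subject transfer, no
  subject pooling beyond averaging.
* The SVM baseline emits softmaxed margins, not calibrated probabilities.
* The NumPy networks run on one CPU; the default problem size is chosen
  accordingly, and much larger datasets would want a GPU framework.
* Causal-mode filtering changes feature values near phase boundaries
  relative to the zero-phase default; models trained in one mode should be
  deployed in the same mode.
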