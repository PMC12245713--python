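# Methods

## Problem and model

`sleepstager` assigns one of three vigilance states — REM/paradoxical
sleep (P), NREM/slow-wave sleep (S), wake (W) — to every 10 s epoch of a
single-channel rodent EEG recording. The classifier is an end-to-end
CNN-LSTM:

* **Epoch encoder.** Each 10 s epoch (5,000 samples at the native
  500 Hz) is encoded independently by a stack of three residual blocks.
  A block is three (convolution → layer normalization → ReLU) stages
  with an elementwise residual connection added before the block's final
  ReLU; the three blocks use kernel sizes 8, 5 and 3. Convolutions are
  stride 1 with "same" padding so the residual addition is always
  shape-compatible; when a block changes channel width the shortcut is a
  1×1 convolution, otherwise the identity. Global average pooling over
  the temporal axis reduces the last block's activation to one value per
  channel.
* **Temporal encoder.** A single-layer unidirectional LSTM (hidden size
  64) consumes the 9 encoder vectors of a stride-1 context window; its
  hidden state after the final step is the context vector
  (`ModelConfig.lstm_output="center"` switches to the hidden state at
  the center step, which is equivalent to truncating the window there).
* **Head.** A linear map 64 → 3 and a softmax produce the probability
  triple for the **center** epoch of the window. The argmax is the
  predicted stage (exact ties, a measure-zero event, break toward the
  lowest class index, P < S < W); the max probability is the confidence,
  necessarily > 1/3.

Layer normalization is computed over the channel axis at every time
position (ε = 1e-5). Weights are initialized from the run seed: He
(fan-in) normal for convolutions, Glorot uniform for the head, uniform
±1/√H for LSTM matrices with forget-gate bias +1.

The network, its gradients and the Adam optimizer are implemented
directly in NumPy (float32, im2col + BLAS GEMM convolutions,
hand-derived backward passes, verified against float64 central
differences to ~1e-5 relative error). Everything is single-threaded
deterministic given the seed.

## Data preparation

Recordings at foreign rates are resampled in the frequency domain
(`scipy.signal.resample`), preserving duration to within half a sample
period. The signal is partitioned into 10 s epochs (trailing partial
epoch dropped with a warning — partial epochs are never scored), and the
epoch sequence is zero-padded with (k−1)/2 = 4 all-zero epochs at each
end so that every real epoch is the center of exactly one 9-epoch,
stride-1 window. The padding value is literally 0 µV. Windows never
cross recording boundaries. Raw physical units (µV) are fed to the model
by default; `make_windows(..., standardize=True)` optionally z-scores
the whole recording with one mean/std (used by the reduced recipe below).

## Training and validation

* **Folds.** Leave-one-subject-out: each subject's data forms exactly
  one test fold; all recordings of a subject travel together, so no
  subject contributes to both sides of any split.
* **Validation slice.** 5% of the training windows, taken as one
  contiguous block per recording at a seeded random position. Contiguous
  rather than random because stride-1 windows overlap neighbors by 8
  epochs: a random split would place near-duplicates of validation
  windows in the training set.
* **Optimization.** Adam, learning rate 3e-4, batch size 32, plain
  (unweighted) cross-entropy; optional per-class weights exist but are
  off by default. Mini-batches are reshuffled each epoch from the run
  seed; the last short batch is kept.
* **Early stopping.** Validation loss is evaluated once per training
  epoch; an improvement is a strictly lower loss by ≥ 1e-6. Training
  halts after 30 epochs without improvement (or at `max_epochs`,
  default 500) and the best-validation checkpoint — not the last — is
  returned.
* **Grid search.** Plain exhaustive search over learning rate × batch
  size × window length, scored by best validation loss.

## Synthetic cohorts

The generator emulates the two statistical properties a sleep stager
exploits, with everything else deliberately simple:

* **Stage dynamics.** A semi-Markov chain: each stage dwells for a
  geometric number of 10 s epochs (means W 12, S 18, P 6 — i.e. 2, 3 and
  1 minutes) and then moves to a *different* stage drawn from a
  row-stochastic transition matrix with zero diagonal (defaults: W→S
  0.95/W→P 0.05, S→W 0.65/S→P 0.35, P→W 0.8/P→S 0.2 — sleep onset is
  almost always NREM, REM mostly ends in an awakening). Under these
  defaults P occupies roughly 7% of recording time, comparable to the
  REM fraction of a rat's day, so the rare-class problem of real scoring
  is represented.
* **Spectra.** The trace is 1/f background noise plus stage-conditioned
  band-limited noise: S = high-amplitude delta (0.5–4 Hz, relative
  amplitude 3), P = theta (5–8 Hz, 1.5), W = low-amplitude fast activity
  (8–30 Hz, 1). Streams are unit-variance band-passed white noise
  (4th-order Butterworth, zero-phase), scaled by 20 µV. Stage changes
  are blended with a 0.5 s crossfade (two 0.25 s box filters on the
  stage indicator), so the trace is continuous and masks still sum to 1.
  A `hardness` knob in [0, 1] shrinks the amplitude contrast toward
  zero for stress tests; the default 1.0 is the "easy", well-separated
  setting, where a linear classifier on per-epoch band powers exceeds
  95% accuracy — this guarantees the deep model's parameter-recovery
  test is well-posed.

What the generator does **not** emulate: spindles, K-complexes, phasic
theta, movement artifacts, electrode drift, inter-animal spectral
variability beyond the seed. Passing the recovery test therefore shows
the pipeline can learn stage-conditioned spectral structure end-to-end;
it does not certify performance on real polysomnography.

Per-subject sub-seeds derive from the master seed via
`numpy.random.SeedSequence.spawn`, so cohorts are reproducible
file-for-file.

## The reduced (desk-scale) recipe

`reduced_recipe(seed)` is the configuration used for synthetic-cohort
experiments on a single CPU core: input decimated to 25 Hz (250 samples
per epoch — all synthetic stage bands lie below the 12.5 Hz Nyquist),
block channels (8, 16, 16), LSTM width 32, per-recording
standardization on, learning rate 3e-3, at most 30 epochs with patience
8. The architecture's structure (three residual blocks, kernels 8/5/3,
9-epoch stride-1 windows, last-step LSTM output) is unchanged from the
native configuration. The raised learning rate and standardization
matter for the rare P class, which otherwise needs many more epochs to
be picked up; at these settings a 4-subject leave-one-out run on 30–45
minute recordings takes ~9–13 minutes on one core and reaches mean macro
F1 ≈ 0.9.

Cohort sizing note: with the default bout dynamics the expected number
of P bouts in a 30 min trace is only ~2, so a noticeable fraction of
30 min synthetic subjects contain *no* REM at all — exactly as can
happen in a real half-hour of rat sleep. Such a subject's fold has zero
P support, and under the zero-support-F1=0 convention its macro F1 is
capped near 0.67 no matter how good the stager is. Recovery experiments
in this repository therefore prefer ≥ 45 min per subject, which makes a
REM-free subject rare (~2%) while keeping runtimes practical.

## Evaluation conventions

* Reference epochs labeled `X` (artifact/unscored) are masked out of all
  metric tallies; predictions are always over {P, S, W}.
* A zero-denominator precision/recall is reported as 0 and recorded in
  `MetricsReport.undefined_metrics`; macro F1 always averages over all
  three classes, keeping it defined on degenerate folds.
* Cross-resolution (10 s predictions vs 4 s reference): within each 20 s
  block, the reference epochs [0,4) and [4,8) score against the first
  prediction and [12,16), [16,20) against the second with weight 1; the
  straddling epoch [8,12) adds weight 0.5 against *each* prediction.
  This expresses the mean-of-the-metric rule as a fractional confusion
  matrix, conserves total mass exactly (= number of scored 4 s epochs),
  and reduces to plain accuracy whenever both predictions of a block
  agree.
* Per-fold metrics are computed on the held-out subject and averaged
  with equal fold weight.

## Sleep architecture

Bouts are maximal same-stage runs; they tile the hypnogram exactly.
Summaries report per stage: total duration, bout count, mean bout
duration (total/count) and proportion of recording time, optionally per
fixed time bin (1 h Zeitgeber-time bins by default; ZT 0 is the
recording start unless an offset is supplied). A bout straddling a bin
boundary has its duration apportioned to bins by overlap — so per-bin
durations sum exactly to the bin length — but is counted once, in the
bin containing its onset; a bin's mean bout duration is its apportioned
duration over its onset count (0 if no bout starts there). No minimum
bout length or smoothing is applied by default. `compare_scorers` emits
the tidy paired table (subject × bin × stage × parameter) consumed by
external statistics software; inferential statistics are out of scope.

## I/O and numerics

* EDF reading uses MNE; values are returned in µV. EDF writing is a
  minimal 16-bit encoder (one data record per second, symmetric integer
  physical range): quantization error is below 1/32,767 of full scale,
  and write→read round-trips preserve the sample count exactly (signals
  are truncated to whole seconds, consistent with the epoching rule).
* Label files are plain CSV; the canonical dialect is headerless
  `epoch_index,stage`, and the writer's richer
  `epoch_index,onset_s,stage[,p_P,p_S,p_W]` form round-trips through the
  reader. Onset-based files are accepted by dividing onsets by the epoch
  length. Gaps, duplicates and unknown symbols are hard errors with row
  numbers.
* Checkpoints are NumPy `.npz` archives holding every parameter, the
  full model configuration (verified on load) and a fingerprint of the
  training subjects.

## Known limitations

* Inference and especially training are NumPy on CPU; the native
  500 Hz / (32, 64, 64) configuration trains impractically slowly at
  real-cohort scale. The architecture is faithful at any size; the
  reduced recipe is the practical operating point in this repository.
* The synthetic cohort is far easier than real EEG (see above); reported
  recovery scores are upper bounds on real-data performance.
* Unidirectional last-step LSTM output means the rare-class gradient
  signal must traverse four steps from the center epoch; the center-step
  option trades away future context instead. Neither variant showed an
  advantage on synthetic cohorts.
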