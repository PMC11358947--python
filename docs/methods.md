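# Methods

## Problem and data model

The decoding target is the driver's attention state over 1-s windows of
scalp EEG: one of four classes — focused driving, visual distraction,
auditory distraction, cognitive distraction. The experimental protocol
the package models uses state-specific trial lengths (visual 5 s,
auditory 15 s, cognitive 10 s, focused 5 s), so a trial contributes
exactly 5/15/10/5 labelled windows. Amplitudes are microvolts
throughout, time is seconds, sample indexing is 0-based with half-open
intervals.

Acquisition is a 64-electrode 10-20 montage with Fz as online reference.
Preprocessing re-references to the TP9/TP10 (mastoid) average, drops
{Fz, Fp1, Fp2, TP9, TP10} — the reference plus the sites most
contaminated by ocular and mastoid activity — leaving 59 scalp channels,
and downsamples to 100 Hz, so each window is a 59 × 100 matrix.

## Preprocessing choices

* **Filter realisation.** 4th-order Butterworth, applied
  forward–backward (`sosfiltfilt`): zero phase, so event latencies are
  preserved. Two presets exist and are deliberately not unified:
  offline 0.5–50 Hz, online (streaming) 0.1–45 Hz. Both target 100 Hz.
* **Artifact rule.** Any window containing a sample with |amplitude| >
  100 µV (absolute, not peak-to-peak) is dropped whole. Windows are the
  classification atom, so interpolation inside a window is not
  attempted. Rejection happens after windowing; invalid trials (missing
  response feedback) are excluded earlier, at epoching, before any
  feature computation.
* **Windows are non-overlapping**, consecutive within each trial.
* **Downsampling** uses polyphase resampling (`resample_poly`), which
  includes the anti-alias filter; event indices are rescaled.

## Spectral estimation

The Welch estimator is implemented from its definition rather than
delegated, because the estimator itself is under test: segments of M
samples at step M(1−overlap), data window ω(n), per-segment modified
periodogram normalised by M·U with U = (1/M)Σω²(n), averaged over
segments. Scaling is one-sided density (power/Hz); interior bins are
doubled, DC and Nyquist are not. The implementation is validated in the
test suite against (a) a deliberately naive per-segment DFT-sum oracle
and (b) `scipy.signal.welch`, both to ~1e-12.

For 1-s, 100-sample windows the only configuration that produces 1 Hz
bins over 0–50 Hz from a single segment is M = nfft = 100, L = 1; the
default window is Hann. Multi-segment configurations remain available
for longer inputs.

* **dB + normalisation.** Powers are floored at 1e-12 before
  10·log₁₀, then each channel is z-scored across its 51 bins *within
  the sample*. Per-sample normalisation (rather than corpus-level) keeps
  the transform stateless, which the online loop requires; a channel
  with zero spread is flagged and zero-filled.
* **Band blocks.** θ = 4–8 Hz, α = 8–13 Hz, β = 13–35 Hz, edges
  inclusive, so adjacent bands share an edge bin and the blocks are
  exactly 5/6/23 bins × 59 channels. (Only the 8–13 α reading is
  consistent with 6 bins at 1 Hz resolution.)
* **SVM features.** Mean power per band per channel, concatenated
  θ‖α‖β → 177 values. The reducer is pluggable; the mean is the
  default. The "full-band" comparison arm flattens all 51 × 59
  dB-normalised values.

## EEGNet

The architecture follows the compact-EEGNet pattern: temporal
convolution (F1 = 16 filters, kernel 50, 'same' padding), full-channel
depthwise spatial convolution (depth D = 2, kernel (59, 1)), batch
normalisation, ELU, average pooling (1, 4), dropout; separable
convolution (depthwise (1, 16) + pointwise to F2 = D·F1 = 32), batch
normalisation, ELU, pooling (1, 8), dropout; flatten; dense softmax.
Flatten length is F2·((T÷p1)÷p2) with floor division at each pool —
96 for T = 100.

Because no deep-learning framework is a dependency, the layers are
implemented directly in numpy with hand-written backward passes; every
backward pass is verified against central finite differences in the
test suite, and the symbolic `shape_trace` is checked against runtime
tensor shapes layer by layer.

Choices where the parameterisation was open:

* Dropout default p = 0.25 (within-subject 0.5 available as a setting).
* Batch-norm momentum 0.99, ε = 1e-3.
* No max-norm constraint on the depthwise weights (not part of this
  model's description; available nowhere — deliberately omitted).
* Glorot-uniform initialisation, seeded; training is Adam (lr 1e-3),
  cross-entropy, batch 64, deterministic given `random_state`.
* **PSD mode.** The same network runs on band PSD blocks with the
  frequency-bin axis in the role of T — the only axis of length > 1
  besides channels. The raw-mode pooling (4, 8) would collapse 5/6/23
  bins to length 0, so per-band configs use pooling (2,1)/(2,1)/(2,2),
  leaving post-pooling sequences of 2/3/5 steps, and clamp kernels to
  the input length.

## GRU

The cell follows the standard two-gate recurrence with weight matrices
over the concatenation [h_{t−1}, x_t] and **no bias terms** by default
(a flag adds them). Initialisation is uniform(−k, k), k = 1/√hidden.
Initial state h₀ = 0. Hidden size defaults to 32 (matching F2, keeping
the stage-2 parameter count small); the size is not dictated by the
method and is configurable.

Two implementations coexist on purpose: a scalar-loop reference
(`gru_step_naive`) that serves as the correctness oracle, and the
vectorised/batched layer with backpropagation through time used for
training. Their agreement (≤1e-8 over random instances) and the BPTT
gradients (finite differences) are tested.

## GRU-EEGNet composite

Each of the three band branches re-reads the pre-flatten EEGNet feature
map (F2 × T′) as a T′-step sequence of F2-vectors — the only
within-sample sequence available between Flatten and Dense — and feeds
it to a GRU whose final state enters a dense softmax head.

Training is two-stage: stage 1 trains each band EEGNet end-to-end with
a temporary head (batch 64, Adam lr 1e-3, dropout 0.25); stage 2 freezes
all EEGNet weights and trains GRUs + heads (batch 16, lr 1e-3, dropout
0.5 on the GRU output). Freezing is verified by hashing every trunk
parameter and batch-norm running statistic before and after stage 2
(`frozen_ok_`). Because the trunks are frozen, stage 2 runs on cached
trunk outputs, which makes the freezing invariant structural as well as
verified.

Fusion is the unweighted average of the three branch softmax outputs
(default); a concat-of-final-GRU-states joint dense head is available
(`fusion="concat_dense"`). Stage-1 heads are discarded; only trunks are
reused. Task restriction (2-/3-/4-class, codes fv…fvac) is a label
subset, not an architecture change. Ties in argmax break toward the
lower class index in the fixed class order.

## Baselines

The six compared classifiers are decision tree, linear discriminant
analysis (the generic "discriminant analysis" is taken as LDA), Gaussian
naive Bayes, RBF-kernel SVM (C = 1, γ = 'scale' — library-conventional
defaults, recorded in results metadata), kNN, and a one-hidden-layer
(64-unit) network, all behind a standardising pipeline, scored by
stratified k-fold CV accuracy. The full-vs-band comparison uses the
same folds and seed for both arms, with the full-band arm on
dB-normalised values for symmetry with the model inputs.

## Metrics and the online loop

Cohen's κ is computed from the multi-class confusion matrix with
chance agreement from the marginal products; F1 is macro (unweighted).
The online loop replays a recording in 1-s chunks through the online
preset, predicts each chunk, and tallies per state the total (T) and
correct (C) windows; overall accuracy is ΣC/ΣT. Chunk ground truth is
the majority state of the chunk's samples (focused where no event
covers it); a trailing partial chunk is dropped. Offline and online
chains produce identical features on identical input when configured
with the same band (tested), so the presets differ only by their stated
filter parameters.

## Synthetic generator

The generator is the package's sole data source and encodes the study
conditions:

* **Design**: 7 laps × 300 s, up to 12 distractor subtasks per lap
  (exactly 12 at maximum density → 84 events), types uniform over
  {visual, auditory, cognitive}, durations 5/15/10 s, non-overlapping
  with ≥5 s gaps (slack distributed Dirichlet-uniformly), remaining time
  focused; focused 5-s trials are carved from gaps ≥5 s, mirroring the
  5-s focused trials of the protocol.
* **Signal**: per channel, 1/f-shaped Gaussian background (exponent 1.0,
  8 µV RMS), narrowband θ/α/β oscillations synthesised as band-filtered
  Gaussian noise — not sinusoids, so Welch estimates have realistic
  variance — at 3/5/2.5 µV RMS, plus 1.5 µV white sensor noise.
* **Effects**: multiplicative band-amplitude gains per state, applied at
  full strength over a state's scalp region (by electrode-name prefix)
  and at 0.4 of the log-gain elsewhere. Base gains (strength 1):
  visual (1.0, 0.70, 0.75) parieto-occipital; auditory (1.0, 1.60,
  1.10); cognitive (1.50, 1.40, 1.0) fronto-central; focused is the
  (1,1,1) baseline. A strength exponent scales all log-gains: 0 = null,
  2 = the "strong" fixture. These values are the package's own
  calibration of the qualitative topographic findings the generator
  emulates; no quantitative effect sizes exist to match.
* **Fixtures**: `separable_2class` (240 windows, strength 2.5),
  `strong_4class` (4 × 200, strength 2.0), `null_4class` (4 × 100,
  strength 0), `artifact_spiked` (100 windows, 7 planted 150 µV spikes),
  all byte-reproducible per seed with manifests of expected counts.

What the generator does **not** model: volume conduction and realistic
topographies (region gains are a caricature), ocular/EMG artifacts
beyond amplitude spikes, non-stationarity within a state, inter-subject
variability. Passing recovery tests therefore shows that the pipeline
detects band-power contrasts of plausible magnitude under realistic
estimator variance — not that real-EEG accuracies are reproduced.
Published real-data accuracies enter the package only as printed tally
tables whose summary statistics the evaluation module recomputes.

## Problem sizes

The recovery suite trains on ~800 windows with reduced epochs (stage 1:
30, stage 2: 20) and an 80/20 split; the null check uses 400 windows;
the band-vs-full comparison runs ten generator seeds at 80
windows/class with 5-fold CV. These sizes give stable results for the
planted effect magnitudes while keeping the whole suite comfortably
runnable on one CPU. File-format and online-loop tests use short
recordings (≤60 s) at 200–1000 Hz.

## Known limitations

* The numpy training loop is single-threaded BLAS-bound; it is sized
  for the fixture scale, not for large corpora.
* EDF output is 16-bit (quantisation ~range/2¹⁵); the HDF5 container is
  the lossless interchange format.
* The reduced 10-channel online montage variant is not implemented (no
  channel subset is defined for it).
* Per-sample dB normalisation discards absolute power; corpus-level
  normalisation is a documented alternative not currently wired in.
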