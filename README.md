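# neurodrive

EEG decoding of **driving attention states** — focused driving versus
visual, auditory and cognitive distraction — from 1-second windows of
59-channel EEG.

Driver distraction produces reliable spectral signatures: θ (4–8 Hz) and
α (8–13 Hz) power rise under cognitive load, parieto-occipital α/β
(13–35 Hz) power falls under visual distraction, and α activity is
elevated under auditory secondary tasks. This package implements a
decoding pipeline built on those signatures:

1. **Preprocessing** — band-pass filtering (0.5–50 Hz offline,
   0.1–45 Hz online), mastoid (TP9/TP10) re-referencing, selection of 59
   scalp channels from a 64-electrode montage, downsampling to 100 Hz,
   epoching by state-specific trial length (5/15/10/5 s), slicing into
   non-overlapping 1-s windows, and rejection of windows exceeding
   100 µV.
2. **Spectral features** — Welch power spectral density per channel per
   window. For x(n) of length N split into L segments of M samples with
   window ω(n) and normalisation U = (1/M)·Σω²(n), the estimate is the
   average of the modified periodograms
   I_i(ω) = |Σ x_i(n)ω(n)e^{-jωn}|²/(MU). On 1-s, 100-sample windows
   (M = 100, L = 1, Hann) this yields 51 bins at 1 Hz over 0–50 Hz; after
   dB conversion and per-channel z-scoring, the θ (5×59), α (6×59) and
   β (23×59) blocks are the model inputs, and their per-channel band
   means form the 177-dimensional SVM feature vector.
3. **Classifiers** —
   * `EEGNetClassifier`: the compact convolutional EEGNet (temporal
     convolution F1=16, full-channel depthwise spatial convolution D=2,
     separable convolution F2=32, ELU, average pooling, softmax head),
     implemented in pure numpy with hand-written backpropagation and
     Adam.
   * `GRUEEGNetClassifier`: three band-specific EEGNet branches whose
     pre-flatten feature maps (F2 × T′) are read as T′-step sequences by
     a gated recurrent unit
     (z_t = σ(W_z·[h_{t−1},x_t]), r_t = σ(W_r·[h_{t−1},x_t]),
     h̃_t = tanh(W·[r_t⊙h_{t−1},x_t]),
     h_t = (1−z_t)⊙h_{t−1} + z_t⊙h̃_t), trained in two stages: EEGNet
     trunks first (batch 64), then GRUs and heads with the trunks frozen
     (batch 16). Branch softmax outputs are averaged.
   * `train_psd_svm` / `compare_classifiers`: the RBF-SVM reference
     method and a six-classifier comparison over seven task codes
     (fv … fvac).
4. **Evaluation** — accuracy, Cohen's κ, macro F1, per-class
   precision/recall, stratified 5-fold CV, and a simulated **online
   loop** that replays a recording in 1-s chunks and tallies total (T)
   vs correct (C) windows per state.
5. **Synthetic data** — a seeded generator producing labelled EEG with
   1/f background, narrowband θ/α/β oscillations with state- and
   region-dependent gains, a lap/subtask experiment-design simulator
   (up to 12 distractors per lap over 7 laps → 84 events), and writers
   for BrainVision/EDF/HDF5 so the readers are exercised end to end.

## Worked example

```python
import numpy as np
from neurodrive import GRUEEGNetClassifier, make_fixture
from neurodrive.spectral import WelchPSD, PSDNormalizer

fx = make_fixture("strong_4class", seed=0)            # 800 windows, 4 states
psd = PSDNormalizer().transform(WelchPSD(fs=100.0).transform(fx.X))
print(psd.shape)

idx = np.random.default_rng(0).permutation(800)
tr, te = idx[:640], idx[640:]
model = GRUEEGNetClassifier(stage1_epochs=30, stage2_epochs=20, random_state=1)
model.fit(psd[tr], fx.y[tr])
print("held-out accuracy:", np.mean(model.predict(psd[te]) == fx.y[te]))
print("trunks frozen through stage 2:", model.frozen_ok_)
```

Output:

```
(800, 51, 59)
held-out accuracy: 0.9875
trunks frozen through stage 2: True
```

`psd` holds one 51-bin × 59-channel normalised spectrum per window; the
model slices the θ/α/β blocks internally. The held-out accuracy shows
the three-branch model recovering the planted band-power contrasts;
`frozen_ok_` verifies bit-identical EEGNet weights across stage 2.

A command-line interface covers the same pipeline
(`neurodrive simulate | preprocess | features | train | evaluate |
replay | compare-classifiers`); every artifact gets a JSON sidecar with
seed, config hash and versions.

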