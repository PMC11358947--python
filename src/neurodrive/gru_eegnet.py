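"""GRU-EEGNet: three band-specific EEGNet+GRU branches with late fusion.

Each branch takes one band's PSD block (θ: 5x59, α: 6x59, β: 23x59,
frequency bins x channels, dB-normalised), runs it through a band-adapted
EEGNet trunk, re-reads the pre-flatten feature map (F2 maps x T' steps)
as a T'-step sequence of F2-vectors, and feeds it to a GRU whose final
hidden state enters a dense softmax head.

Training is two-stage: stage 1 trains each band's EEGNet end-to-end with
a temporary softmax head (batch 64, 300 epochs, Adam lr 1e-3, dropout
0.25); stage 2 freezes every EEGNet weight — verified bit-identical via a
hash — and trains the GRUs and heads (batch 16, 100 epochs, Adam lr 1e-3,
dropout 0.5).  Fusion is the average of the three branch softmax outputs
by default; a concat-of-final-GRU-states joint dense head is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .eegnet import EEGNetClassifier, adapt_config_for_band
from .gru import GRULayer
from .spectral import BANDS, BandFeatures, band_bin_indices

_BAND_POOLS = {"theta": (2, 1), "alpha": (2, 1), "beta": (2, 2)}


@dataclass(frozen=True)
class StageConfig:
    batch_size: int
    epochs: int
    lr: float = 1e-3
    dropout: float = 0.25


@dataclass(frozen=True)
class TrainStageConfig:
    """The two-stage training recipe."""

    stage1: StageConfig = field(default_factory=lambda: StageConfig(64, 300, 1e-3, 0.25))
    stage2: StageConfig = field(default_factory=lambda: StageConfig(16, 100, 1e-3, 0.5))
    seed: int | None = None
    folds: int = 5


class GRUEEGNetClassifier(ClassifierMixin, BaseEstimator):
    """Three-branch GRU-EEGNet with the sklearn estimator interface.

    ``X`` is the dB-normalised PSD stack, shape (n, 51, 59) (frequency
    bins 0–50 Hz x channels) or flattened (n, 51*59); the θ/α/β blocks
    are sliced internally (inclusive band edges at 1 Hz resolution).
    """

    def __init__(self, gru_hidden: int = 32, fusion: str = "softmax_average",
                 stage1_epochs: int = 300, stage1_batch: int = 64,
                 stage2_epochs: int = 100, stage2_batch: int = 16,
                 lr: float = 1e-3, stage1_dropout: float = 0.25,
                 stage2_dropout: float = 0.5, fs: float = 100.0,
                 nfft: int = 100, random_state: int | None = None,
                 verbose: int = 0):
        self.gru_hidden = gru_hidden
        self.fusion = fusion
        self.stage1_epochs = stage1_epochs
        self.stage1_batch = stage1_batch
        self.stage2_epochs = stage2_epochs
        self.stage2_batch = stage2_batch
        self.lr = lr
        self.stage1_dropout = stage1_dropout
        self.stage2_dropout = stage2_dropout
        self.fs = fs
        self.nfft = nfft
        self.random_state = random_state
        self.verbose = verbose

    # -- band slicing ------------------------------------------------------

    def _band_blocks(self, X) -> dict[str, np.ndarray]:
        """(n, bins, channels) PSD stack -> per-band (n, C, T_band) inputs."""
        X = np.asarray(X, dtype=np.float64)
        freqs = np.fft.rfftfreq(self.nfft, d=1.0 / self.fs)
        n_bins = freqs.size
        if X.ndim == 2:
            if X.shape[1] % n_bins != 0:
                raise ValueError(f"cannot reshape flat input of width {X.shape[1]}")
            X = X.reshape(X.shape[0], n_bins, -1)
        if X.ndim != 3 or X.shape[1] != n_bins:
            raise ValueError(f"expected (n, {n_bins}, channels); got {X.shape}")
        out = {}
        for band in BANDS:
            idx = band_bin_indices(freqs, band)
            # channels become EEGNet's C axis, bins its T axis
            out[band] = X[:, idx, :].transpose(0, 2, 1)
        return out

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        blocks = self._band_blocks(X)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        seed_rng = np.random.default_rng(self.random_state)
        seeds = seed_rng.integers(0, 2**31 - 1, size=8)

        # stage 1: band EEGNets with temporary heads
        self.branches_: dict[str, EEGNetClassifier] = {}
        for i, band in enumerate(BANDS):
            p1, p2 = _BAND_POOLS[band]
            est = EEGNetClassifier(
                pool1=p1, pool2=p2, dropout=self.stage1_dropout,
                epochs=self.stage1_epochs, batch_size=self.stage1_batch,
                lr=self.lr, random_state=int(seeds[i]),
            )
            est.fit(blocks[band], y)
            self.branches_[band] = est
        self.trunk_hashes_ = {b: est.trunk_weight_hash()
                              for b, est in self.branches_.items()}

        # stage 2: frozen trunks -> cached sequences -> GRU heads
        seqs = {b: est.transform_sequences(blocks[b])
                for b, est in self.branches_.items()}
        self._fit_stage2(seqs, y_enc, seeds[3:])

        # freezing invariant: trunk weights unchanged by stage 2
        self.frozen_ok_ = all(
            est.trunk_weight_hash() == self.trunk_hashes_[b]
            for b, est in self.branches_.items()
        )
        return self

    def _fit_stage2(self, seqs: dict[str, np.ndarray], y_enc: np.ndarray,
                    seeds) -> None:
        n_classes = len(self.classes_)
        H = self.gru_hidden
        n = len(y_enc)
        self.grus_: dict[str, GRULayer] = {}
        self.heads_: dict[str, nn.Dense] = {}
        rngs = {b: np.random.default_rng(int(s)) for b, s in zip(BANDS, seeds)}

        if self.fusion == "softmax_average":
            for band in BANDS:
                rng = rngs[band]
                gru = GRULayer(seqs[band].shape[2], H, rng)
                head = nn.Dense(H, n_classes, rng)
                drop = nn.Dropout(self.stage2_dropout, rng)
                opt = nn.Adam(lr=self.lr)
                for _ in range(self.stage2_epochs):
                    order = rng.permutation(n)
                    for s in range(0, n, self.stage2_batch):
                        b = order[s:s + self.stage2_batch]
                        h = gru.forward(seqs[band][b], training=True)
                        hd = drop.forward(h, training=True)
                        probs = nn.softmax(head.forward(hd, training=True))
                        g = nn.softmax_xent_grad(probs, y_enc[b])
                        gru.backward(drop.backward(head.backward(g)))
                        opt.step([gru, head])
                self.grus_[band] = gru
                self.heads_[band] = head
        elif self.fusion == "concat_dense":
            rng = rngs["theta"]
            for band in BANDS:
                self.grus_[band] = GRULayer(seqs[band].shape[2], H, rngs[band])
            joint = nn.Dense(3 * H, n_classes, rng)
            drop = nn.Dropout(self.stage2_dropout, rng)
            opt = nn.Adam(lr=self.lr)
            for _ in range(self.stage2_epochs):
                order = rng.permutation(n)
                for s in range(0, n, self.stage2_batch):
                    b = order[s:s + self.stage2_batch]
                    hs = [self.grus_[band].forward(seqs[band][b], training=True)
                          for band in BANDS]
                    hcat = drop.forward(np.concatenate(hs, axis=1), training=True)
                    probs = nn.softmax(joint.forward(hcat, training=True))
                    g = joint.backward(nn.softmax_xent_grad(probs, y_enc[b]))
                    g = drop.backward(g)
                    for i, band in enumerate(BANDS):
                        self.grus_[band].backward(g[:, i * H:(i + 1) * H])
                    opt.step([*self.grus_.values(), joint])
            self.joint_head_ = joint
        else:
            raise ValueError(f"unknown fusion {self.fusion!r}")

    # -- inference ---------------------------------------------------------

    def _branch_probs(self, blocks: dict[str, np.ndarray]) -> np.ndarray:
        check_is_fitted(self, "branches_")
        seqs = {b: self.branches_[b].transform_sequences(blocks[b]) for b in BANDS}
        if self.fusion == "softmax_average":
            probs = [
                nn.softmax(self.heads_[b].forward(self.grus_[b].forward(seqs[b])))
                for b in BANDS
            ]
            return np.mean(probs, axis=0)
        hs = [self.grus_[b].forward(seqs[b]) for b in BANDS]
        return nn.softmax(self.joint_head_.forward(np.concatenate(hs, axis=1)))

    def predict_proba(self, X) -> np.ndarray:
        return self._branch_probs(self._band_blocks(X))

    def predict(self, X) -> np.ndarray:
        # argmax breaks ties toward the lower class index (fixed order)
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def predict_bands(self, theta: np.ndarray, alpha: np.ndarray,
                      beta: np.ndarray) -> np.ndarray:
        """Probabilities from per-band blocks of shape (n, bins, channels)."""
        blocks = {
            "theta": np.asarray(theta).transpose(0, 2, 1),
            "alpha": np.asarray(alpha).transpose(0, 2, 1),
            "beta": np.asarray(beta).transpose(0, 2, 1),
        }
        return self._branch_probs(blocks)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def train_two_stage(X, y, cfg: TrainStageConfig | None = None,
                    gru_hidden: int = 32, fusion: str = "softmax_average",
                    random_state: int | None = None) -> GRUEEGNetClassifier:
    """Fit a GRU-EEGNet under an explicit two-stage recipe."""
    cfg = cfg or TrainStageConfig()
    model = GRUEEGNetClassifier(
        gru_hidden=gru_hidden, fusion=fusion,
        stage1_epochs=cfg.stage1.epochs, stage1_batch=cfg.stage1.batch_size,
        stage2_epochs=cfg.stage2.epochs, stage2_batch=cfg.stage2.batch_size,
        lr=cfg.stage1.lr, stage1_dropout=cfg.stage1.dropout,
        stage2_dropout=cfg.stage2.dropout,
        random_state=cfg.seed if cfg.seed is not None else random_state,
    )
    return model.fit(X, y)


def predict_state(model: GRUEEGNetClassifier, bands: BandFeatures):
    """Class probabilities and argmax label for one band-feature sample."""
    probs = model.predict_bands(bands.theta[None], bands.alpha[None],
                                bands.beta[None])[0]
    label = model.classes_[int(np.argmax(probs))]
    return probs, label
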