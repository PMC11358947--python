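"""EEGNet: compact convolutional network for EEG classification.

Architecture (input (C, T) -> reshape (1, C, T)):

    Block 1: Conv2D F1 x (1, k_t) 'same'  ->  BatchNorm
             DepthwiseConv2D (C, 1), depth D  ->  BatchNorm -> ELU
             AveragePool (1, p1) -> Dropout
    Block 2: SeparableConv2D F2 x (1, k_s) 'same' -> BatchNorm -> ELU
             AveragePool (1, p2) -> Dropout
    Head:    Flatten -> Dense(n_classes) -> Softmax

Default parameterisation: F1 = 16 temporal filters, depth multiplier
D = 2, F2 = D*F1 = 32 pointwise filters, temporal kernel 50, separable
kernel 16, pooling (4, 8) — sized for raw 1-s windows (C=59, T=100
samples at 100 Hz).  The same architecture also runs on band power
spectra, where the frequency-bin axis plays the role of T; per-band
configs shrink the kernels and pooling so the post-pooling sequence
length stays >= 2 (see :func:`adapt_config_for_band`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn


@dataclass(frozen=True)
class EEGNetConfig:
    """Architecture hyperparameters (Table-style parameterisation)."""

    C: int
    T: int
    F1: int = 16
    D: int = 2
    F2: int = 32
    n_classes: int = 4
    dropout_p: float = 0.25
    temporal_kernel: int = 50
    separable_kernel: int = 16
    pool1: int = 4
    pool2: int = 8

    def __post_init__(self) -> None:
        if self.pool1 < 1 or self.pool2 < 1:
            raise ValueError("pool factors must be >= 1")
        if self.F2 != self.D * self.F1:
            raise ValueError(f"F2 must equal D*F1 ({self.D}*{self.F1})")

    @property
    def t_pooled(self) -> int:
        return (self.T // self.pool1) // self.pool2

    @property
    def flatten_len(self) -> int:
        return self.F2 * self.t_pooled


def shape_trace(cfg: EEGNetConfig) -> list[tuple[str, tuple]]:
    """Symbolic per-layer output shapes (maps, channels, time)."""
    t1 = cfg.T // cfg.pool1
    t2 = t1 // cfg.pool2
    if t1 < 1 or t2 < 1:
        raise ValueError(
            f"pooling ({cfg.pool1},{cfg.pool2}) collapses T={cfg.T} below 1")
    trace = [
        ("input", (cfg.C, cfg.T)),
        ("reshape", (1, cfg.C, cfg.T)),
        ("conv_temporal", (cfg.F1, cfg.C, cfg.T)),
        ("batchnorm_1", (cfg.F1, cfg.C, cfg.T)),
        ("depthwise_spatial", (cfg.D * cfg.F1, 1, cfg.T)),
        ("batchnorm_2", (cfg.D * cfg.F1, 1, cfg.T)),
        ("elu_1", (cfg.D * cfg.F1, 1, cfg.T)),
        ("avgpool_1", (cfg.D * cfg.F1, 1, t1)),
        ("dropout_1", (cfg.D * cfg.F1, 1, t1)),
        ("separable_depthwise", (cfg.D * cfg.F1, 1, t1)),
        ("separable_pointwise", (cfg.F2, 1, t1)),
        ("batchnorm_3", (cfg.F2, 1, t1)),
        ("elu_2", (cfg.F2, 1, t1)),
        ("avgpool_2", (cfg.F2, 1, t2)),
        ("dropout_2", (cfg.F2, 1, t2)),
        ("flatten", (cfg.F2 * t2,)),
        ("dense", (cfg.n_classes,)),
    ]
    return trace


def build_eegnet(cfg: EEGNetConfig, rng: np.random.Generator) -> nn.Sequential:
    """Instantiate the network; layer output shapes equal shape_trace."""
    shape_trace(cfg)  # validates
    t1 = cfg.T // cfg.pool1
    t2 = t1 // cfg.pool2
    layers: list[nn.Layer] = [
        nn.TemporalConv(1, cfg.F1, cfg.temporal_kernel, rng),
        nn.BatchNorm(cfg.F1),
        nn.DepthwiseSpatialConv(cfg.F1, cfg.D, cfg.C, rng),
        nn.BatchNorm(cfg.D * cfg.F1),
        nn.ELU(),
        nn.AvgPoolTime(cfg.pool1),
        nn.Dropout(cfg.dropout_p, rng),
        nn.DepthwiseTemporalConv(cfg.D * cfg.F1, cfg.separable_kernel, rng),
        nn.PointwiseConv(cfg.D * cfg.F1, cfg.F2, rng),
        nn.BatchNorm(cfg.F2),
        nn.ELU(),
        nn.AvgPoolTime(cfg.pool2),
        nn.Dropout(cfg.dropout_p, rng),
        nn.Flatten(),
        nn.Dense(cfg.F2 * t2, cfg.n_classes, rng),
    ]
    return nn.Sequential(layers)


#: index of the Flatten layer within the built Sequential (trunk ends before it)
FLATTEN_INDEX = 13


def adapt_config_for_band(band: str, n_channels: int = 59,
                          n_classes: int = 4,
                          dropout_p: float = 0.25) -> EEGNetConfig:
    """Per-band config for PSD inputs (frequency bins as the T axis).

    The default raw-mode pooling (4, 8) would collapse 5/6/23-bin inputs
    to zero length, so each band gets pooling chosen to leave a
    post-pooling sequence of >= 2 steps for the downstream GRU:
    θ: (2,1) -> 2 steps, α: (2,1) -> 3 steps, β: (2,2) -> 5 steps.
    Kernels are clamped to the input length.
    """
    n_bins = {"theta": 5, "alpha": 6, "beta": 23}
    pools = {"theta": (2, 1), "alpha": (2, 1), "beta": (2, 2)}
    if band not in n_bins:
        raise ValueError(f"unknown band {band!r}")
    T = n_bins[band]
    p1, p2 = pools[band]
    return EEGNetConfig(
        C=n_channels, T=T, n_classes=n_classes, dropout_p=dropout_p,
        temporal_kernel=min(50, T), separable_kernel=min(16, T),
        pool1=p1, pool2=p2,
    )


class EEGNetClassifier(ClassifierMixin, BaseEstimator):
    """Trainable EEGNet with the sklearn estimator interface.

    Expects ``X`` of shape (n_samples, C, T): raw 1-s windows (channels x
    time samples) or per-band PSD blocks (channels x frequency bins).

    Parameters mirror the published training recipe: Adam, learning rate
    1e-3, cross-entropy loss, batch size 64, dropout 0.25.  ``epochs``
    defaults to 300; reduce for quick runs.
    """

    def __init__(self, F1: int = 16, D: int = 2, F2: int = 32,
                 temporal_kernel: int = 50, separable_kernel: int = 16,
                 pool1: int = 4, pool2: int = 8, dropout: float = 0.25,
                 epochs: int = 300, batch_size: int = 64, lr: float = 1e-3,
                 validation_fraction: float = 0.0,
                 random_state: int | None = None, verbose: int = 0):
        self.F1 = F1
        self.D = D
        self.F2 = F2
        self.temporal_kernel = temporal_kernel
        self.separable_kernel = separable_kernel
        self.pool1 = pool1
        self.pool2 = pool2
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.verbose = verbose

    # -- internals ---------------------------------------------------------

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(f"X must be (n_samples, C, T); got shape {X.shape}")
        return X

    def _make_config(self, C: int, T: int, n_classes: int) -> EEGNetConfig:
        return EEGNetConfig(
            C=C, T=T, F1=self.F1, D=self.D, F2=self.F2, n_classes=n_classes,
            dropout_p=self.dropout,
            temporal_kernel=min(self.temporal_kernel, T),
            separable_kernel=min(self.separable_kernel, T),
            pool1=self.pool1, pool2=self.pool2,
        )

    def _forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        return self.model_.forward(X[:, None, :, :], training=training)

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y, validation_data: tuple | None = None):
        X = self._validate_X(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        n, C, T = X.shape
        self.config_ = self._make_config(C, T, len(self.classes_))
        rng = np.random.default_rng(self.random_state)
        self.model_ = build_eegnet(self.config_, rng)

        if validation_data is not None:
            Xval = self._validate_X(validation_data[0])
            yval = np.searchsorted(self.classes_, np.asarray(validation_data[1]))
            Xtr, ytr = X, y_enc
        elif self.validation_fraction > 0:
            idx = rng.permutation(n)
            n_val = max(1, int(round(self.validation_fraction * n)))
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            Xtr, ytr = X[tr_idx], y_enc[tr_idx]
            Xval, yval = X[val_idx], y_enc[val_idx]
        else:
            Xtr, ytr = X, y_enc
            Xval = yval = None

        opt = nn.Adam(lr=self.lr)
        self.history_ = {"loss": [], "acc": [], "val_loss": [], "val_acc": []}
        for epoch in range(self.epochs):
            order = rng.permutation(len(Xtr))
            losses, accs = [], []
            for start in range(0, len(order), self.batch_size):
                b = order[start:start + self.batch_size]
                logits = self._forward(Xtr[b], training=True)
                probs = nn.softmax(logits)
                loss = nn.cross_entropy(probs, ytr[b])
                if not np.isfinite(loss):
                    raise RuntimeError(f"NaN loss at epoch {epoch}")
                self.model_.backward(nn.softmax_xent_grad(probs, ytr[b]))
                opt.step(self.model_.layers)
                losses.append(loss)
                accs.append(float(np.mean(probs.argmax(axis=1) == ytr[b])))
            self.history_["loss"].append(float(np.mean(losses)))
            self.history_["acc"].append(float(np.mean(accs)))
            if Xval is not None:
                vp = nn.softmax(self._forward(Xval, training=False))
                self.history_["val_loss"].append(nn.cross_entropy(vp, yval))
                self.history_["val_acc"].append(float(np.mean(vp.argmax(axis=1) == yval)))
            if self.verbose:
                print(f"epoch {epoch}: " + ", ".join(
                    f"{k}={v[-1]:.4f}" for k, v in self.history_.items() if v))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = self._validate_X(X)
        if X.shape[1] != self.config_.C or X.shape[2] != self.config_.T:
            raise ValueError(
                f"input shape {X.shape[1:]} does not match fitted "
                f"({self.config_.C}, {self.config_.T})")
        out = []
        for start in range(0, X.shape[0], 256):
            out.append(nn.softmax(self._forward(X[start:start + 256])))
        return np.concatenate(out) if out else np.empty((0, len(self.classes_)))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    # -- feature access for the recurrent head -----------------------------

    def transform_sequences(self, X) -> np.ndarray:
        """Pre-flatten feature maps as sequences: (n, T', F2).

        The (F2, 1, T') map entering Flatten is re-read as a T'-step
        sequence of F2-dimensional vectors for the GRU head.
        """
        check_is_fitted(self, "model_")
        X = self._validate_X(X)
        out = []
        for start in range(0, X.shape[0], 256):
            h = X[start:start + 256][:, None, :, :]
            for layer in self.model_.layers[:FLATTEN_INDEX]:
                h = layer.forward(h, training=False)
            out.append(h[:, :, 0, :].transpose(0, 2, 1))      # (B, T', F2)
        return np.concatenate(out)

    def trunk_weight_hash(self) -> str:
        """SHA-256 over all trunk (pre-Flatten) parameters and BN running
        statistics; used to verify stage-2 freezing bit-exactly."""
        import hashlib

        check_is_fitted(self, "model_")
        hsh = hashlib.sha256()
        for layer in self.model_.layers[:FLATTEN_INDEX]:
            for name in sorted(layer.params):
                hsh.update(np.ascontiguousarray(layer.params[name]).tobytes())
            if isinstance(layer, nn.BatchNorm):
                hsh.update(np.ascontiguousarray(layer.running_mean).tobytes())
                hsh.update(np.ascontiguousarray(layer.running_var).tobytes())
        return hsh.hexdigest()

    def runtime_shapes(self, X) -> list[tuple[str, tuple]]:
        """Observed per-layer output shapes for one forward pass (sans batch)."""
        check_is_fitted(self, "model_")
        X = self._validate_X(X[:1])
        names = [name for name, _ in shape_trace(self.config_)[2:]]
        h = X[:, None, :, :]
        shapes = []
        for name, layer in zip(names, self.model_.layers):
            h = layer.forward(h, training=False)
            shapes.append((name, tuple(h.shape[1:])))
        return shapes
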