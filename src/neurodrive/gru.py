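"""Gated recurrent unit, from first principles.

One step of the cell, for input x_t and previous hidden state h_{t-1}:

    z_t  = sigmoid(W_z . [h_{t-1}, x_t])        (update gate)
    r_t  = sigmoid(W_r . [h_{t-1}, x_t])        (reset gate)
    h~_t = tanh(W . [r_t * h_{t-1}, x_t])       (candidate state)
    h_t  = (1 - z_t) * h_{t-1} + z_t * h~_t

All three weight matrices are (hidden, hidden + input); there are no bias
terms by default (an optional flag adds them for parity with common GRU
variants).  The update gate interpolates between keeping the previous
state (z -> 0) and adopting the candidate (z -> 1); the reset gate scales
how much of the previous state enters the candidate.

Two implementations coexist deliberately: a vectorised one used for
training/inference, and a scalar-loop reference (:func:`gru_step_naive`)
that serves as the correctness oracle in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class GRUParams:
    """Weight container for one GRU cell."""

    W_z: np.ndarray
    W_r: np.ndarray
    W: np.ndarray
    hidden_size: int
    input_size: int
    b_z: np.ndarray | None = None
    b_r: np.ndarray | None = None
    b: np.ndarray | None = None

    def __post_init__(self) -> None:
        expected = (self.hidden_size, self.hidden_size + self.input_size)
        for name, m in (("W_z", self.W_z), ("W_r", self.W_r), ("W", self.W)):
            if m.shape != expected:
                raise ValueError(f"{name} has shape {m.shape}, expected {expected}")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"{name} contains non-finite entries")

    @classmethod
    def init(cls, hidden_size: int, input_size: int,
             rng: np.random.Generator | int | None = None,
             bias: bool = False) -> "GRUParams":
        """Uniform(-k, k) initialisation with k = 1/sqrt(hidden_size)."""
        rng = np.random.default_rng(rng)
        k = 1.0 / math.sqrt(hidden_size)
        shape = (hidden_size, hidden_size + input_size)
        mats = [rng.uniform(-k, k, size=shape) for _ in range(3)]
        biases = [np.zeros(hidden_size) for _ in range(3)] if bias else [None] * 3
        return cls(mats[0], mats[1], mats[2], hidden_size, input_size,
                   b_z=biases[0], b_r=biases[1], b=biases[2])


@dataclass
class GRUState:
    """Hidden state plus the gate intermediates of one step."""

    h: np.ndarray
    z: np.ndarray
    r: np.ndarray
    h_tilde: np.ndarray


def gru_step(params: GRUParams, h_prev: np.ndarray, x_t: np.ndarray) -> GRUState:
    """One vectorised GRU step (single sample: vectors in, vectors out)."""
    h_prev = np.asarray(h_prev, dtype=np.float64)
    x_t = np.asarray(x_t, dtype=np.float64)
    if h_prev.shape[-1] != params.hidden_size or x_t.shape[-1] != params.input_size:
        raise ValueError(
            f"dimension mismatch: h {h_prev.shape}, x {x_t.shape} for "
            f"hidden={params.hidden_size}, input={params.input_size}")
    hx = np.concatenate([h_prev, x_t], axis=-1)
    az = params.W_z @ hx + (params.b_z if params.b_z is not None else 0.0)
    ar = params.W_r @ hx + (params.b_r if params.b_r is not None else 0.0)
    z = sigmoid(az)
    r = sigmoid(ar)
    rhx = np.concatenate([r * h_prev, x_t], axis=-1)
    ac = params.W @ rhx + (params.b if params.b is not None else 0.0)
    h_tilde = np.tanh(ac)
    h = (1.0 - z) * h_prev + z * h_tilde
    return GRUState(h=h, z=z, r=r, h_tilde=h_tilde)


def gru_step_naive(params: GRUParams, h_prev, x_t) -> GRUState:
    """Element-by-element scalar-loop evaluation of the four cell
    equations.  Independent oracle for :func:`gru_step`; intentionally
    avoids any vectorised matrix product."""
    H, I = params.hidden_size, params.input_size
    hx = [float(v) for v in h_prev] + [float(v) for v in x_t]
    z = [0.0] * H
    r = [0.0] * H
    for i in range(H):
        sz = sr = 0.0
        for j in range(H + I):
            sz += float(params.W_z[i, j]) * hx[j]
            sr += float(params.W_r[i, j]) * hx[j]
        if params.b_z is not None:
            sz += float(params.b_z[i])
            sr += float(params.b_r[i])
        z[i] = 1.0 / (1.0 + math.exp(-sz))
        r[i] = 1.0 / (1.0 + math.exp(-sr))
    rhx = [r[i] * float(h_prev[i]) for i in range(H)] + [float(v) for v in x_t]
    h_tilde = [0.0] * H
    for i in range(H):
        s = 0.0
        for j in range(H + I):
            s += float(params.W[i, j]) * rhx[j]
        if params.b is not None:
            s += float(params.b[i])
        h_tilde[i] = math.tanh(s)
    h = [(1.0 - z[i]) * float(h_prev[i]) + z[i] * h_tilde[i] for i in range(H)]
    return GRUState(h=np.array(h), z=np.array(z), r=np.array(r),
                    h_tilde=np.array(h_tilde))


def gru_sequence(params: GRUParams, h0: np.ndarray | None,
                 xs: np.ndarray) -> tuple[np.ndarray, list[GRUState]]:
    """Left-to-right recurrence over a (T, input_size) sequence.

    Returns (final hidden state, list of per-step states).  An empty
    sequence returns h0 unchanged with an empty state list.
    """
    h = np.zeros(params.hidden_size) if h0 is None else np.asarray(h0, dtype=np.float64)
    states: list[GRUState] = []
    for x_t in xs:
        st = gru_step(params, h, x_t)
        states.append(st)
        h = st.h
    return h, states


# ---------------------------------------------------------------------------
# trainable batched layer (BPTT)
# ---------------------------------------------------------------------------

class GRULayer:
    """Batched GRU over (B, T, input) sequences, returning the final
    hidden state, with backpropagation through time.

    Exposes ``params``/``grads`` dicts compatible with
    :class:`neurodrive.nn.Adam`.
    """

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator | int | None = None):
        self.input_size, self.hidden_size = input_size, hidden_size
        p = GRUParams.init(hidden_size, input_size, rng)
        self.params = {"W_z": p.W_z, "W_r": p.W_r, "W": p.W}
        self.grads: dict[str, np.ndarray] = {}

    def to_cell_params(self) -> GRUParams:
        return GRUParams(self.params["W_z"], self.params["W_r"], self.params["W"],
                         self.hidden_size, self.input_size)

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        B, T, I = X.shape
        H = self.hidden_size
        Wz, Wr, W = self.params["W_z"], self.params["W_r"], self.params["W"]
        h = np.zeros((B, H))
        cache = []
        for t in range(T):
            x = X[:, t, :]
            hx = np.concatenate([h, x], axis=1)              # (B, H+I)
            z = sigmoid(hx @ Wz.T)
            r = sigmoid(hx @ Wr.T)
            rhx = np.concatenate([r * h, x], axis=1)
            h_tilde = np.tanh(rhx @ W.T)
            h_new = (1 - z) * h + z * h_tilde
            cache.append((h, hx, z, r, rhx, h_tilde))
            h = h_new
        self._cache, self._X = cache, X
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        X = self._X
        B, T, I = X.shape
        H = self.hidden_size
        Wz, Wr, W = self.params["W_z"], self.params["W_r"], self.params["W"]
        gWz = np.zeros_like(Wz)
        gWr = np.zeros_like(Wr)
        gW = np.zeros_like(W)
        dX = np.zeros_like(X)
        dh = dh.copy()
        for t in range(T - 1, -1, -1):
            h_prev, hx, z, r, rhx, h_tilde = self._cache[t]
            dz = dh * (h_tilde - h_prev)
            dht = dh * z
            dh_prev = dh * (1 - z)
            dac = dht * (1 - h_tilde ** 2)                   # (B,H)
            gW += dac.T @ rhx
            drhx = dac @ W
            dr = drhx[:, :H] * h_prev
            dh_prev += drhx[:, :H] * r
            dX[:, t, :] += drhx[:, H:]
            daz = dz * z * (1 - z)
            dar = dr * r * (1 - r)
            gWz += daz.T @ hx
            gWr += dar.T @ hx
            dhx = daz @ Wz + dar @ Wr
            dh_prev += dhx[:, :H]
            dX[:, t, :] += dhx[:, H:]
            dh = dh_prev
        self.grads = {"W_z": gWz, "W_r": gWr, "W": gW}
        return dX
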