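"""Evaluation: cross-validated metrics and the simulated online loop.

Offline metrics follow the standard multi-class schema: accuracy (%),
Cohen's κ (chance agreement from the confusion-matrix marginals), macro
F1, and per-class precision/recall for the four states.

The online loop replays a recording in 1-s chunks through the online
preprocessing preset (0.1–45 Hz, 100 Hz), predicts each chunk, and
tallies per state the total windows presented (T) and correctly
predicted (C); overall accuracy is ΣC/ΣT.  A 5/15/10-s distractor event
therefore contributes exactly 5/15/10 tallied windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (cohen_kappa_score, confusion_matrix, f1_score,
                             precision_score, recall_score)
from sklearn.model_selection import StratifiedKFold

from .io import RawRecording, STATES
from .preprocess import preprocess_chunk

STATE_ABBREV = {"visual": "V", "auditory": "A", "cognitive": "C", "focused": "F"}


@dataclass
class MetricsReport:
    """Offline classification metrics (percentage accuracy, κ, macro F1,
    per-class precision/recall, confusion matrix)."""

    accuracy_pct: float
    kappa: float
    macro_f1: float
    precision: dict[str, float]
    recall: dict[str, float]
    confusion: np.ndarray
    classes: list[str]
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        rows = {"Acc(%)": self.accuracy_pct, "K value": self.kappa,
                "F1 score": self.macro_f1}
        for c in self.classes:
            a = STATE_ABBREV.get(c, c)
            rows[f"Precision {a}"] = self.precision[c]
            rows[f"Recall {a}"] = self.recall[c]
        return pd.DataFrame({"value": rows})


def compute_metrics(y_true, y_pred, classes: list[str] | None = None) -> MetricsReport:
    """Metric schema over predicted vs true state labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if classes is None:
        classes = [c for c in STATES if c in set(y_true) | set(y_pred)]
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    prec = precision_score(y_true, y_pred, labels=classes, average=None,
                           zero_division=0)
    rec = recall_score(y_true, y_pred, labels=classes, average=None,
                       zero_division=0)
    return MetricsReport(
        accuracy_pct=100.0 * float(np.mean(y_true == y_pred)),
        kappa=float(cohen_kappa_score(y_true, y_pred, labels=classes)),
        macro_f1=float(f1_score(y_true, y_pred, labels=classes, average="macro",
                                zero_division=0)),
        precision=dict(zip(classes, prec.astype(float))),
        recall=dict(zip(classes, rec.astype(float))),
        confusion=cm,
        classes=list(classes),
        n_samples=int(y_true.size),
    )


def mean_report(reports: list[MetricsReport]) -> MetricsReport:
    """Aggregate fold/subject reports: metric means, confusions summed."""
    classes = reports[0].classes
    return MetricsReport(
        accuracy_pct=float(np.mean([r.accuracy_pct for r in reports])),
        kappa=float(np.mean([r.kappa for r in reports])),
        macro_f1=float(np.mean([r.macro_f1 for r in reports])),
        precision={c: float(np.mean([r.precision[c] for r in reports])) for c in classes},
        recall={c: float(np.mean([r.recall[c] for r in reports])) for c in classes},
        confusion=np.sum([r.confusion for r in reports], axis=0),
        classes=classes,
        n_samples=int(np.sum([r.n_samples for r in reports])),
    )


def kfold_cv(model_builder, X, y, k: int = 5, seed: int | None = 0
             ) -> tuple[list[MetricsReport], MetricsReport]:
    """Stratified k-fold cross-validation; every sample is tested exactly
    once.  ``model_builder()`` must return a fresh fit/predict estimator."""
    X = np.asarray(X)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs >= {k} samples for {k}-fold CV")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    classes = [c for c in STATES if c in set(y)] or sorted(set(y))
    reports = []
    for tr, te in cv.split(X, y):
        model = model_builder()
        model.fit(X[tr], y[tr])
        reports.append(compute_metrics(y[te], model.predict(X[te]), classes))
    return reports, mean_report(reports)


# ---------------------------------------------------------------------------
# online tally
# ---------------------------------------------------------------------------

@dataclass
class TallyTable:
    """Per-state totals (T) and correct counts (C) of 1-s windows."""

    table: pd.DataFrame  # index: states, columns: ["T", "C"]

    @classmethod
    def from_predictions(cls, y_true, y_pred,
                         states: tuple[str, ...] = STATES) -> "TallyTable":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        rows = {}
        for s in states:
            mask = y_true == s
            rows[s] = {"T": int(mask.sum()),
                       "C": int(np.sum(y_pred[mask] == s))}
        return cls(pd.DataFrame(rows).T[["T", "C"]])

    @classmethod
    def from_counts(cls, counts: dict[str, tuple[int, int]]) -> "TallyTable":
        """Build from printed per-state (T, C) pairs."""
        df = pd.DataFrame({s: {"T": t, "C": c} for s, (t, c) in counts.items()}).T
        return cls(df[["T", "C"]])

    @property
    def overall_accuracy(self) -> float:
        t = int(self.table["T"].sum())
        if t == 0:
            return float("nan")
        return float(self.table["C"].sum()) / t


def overall_accuracy_pct(counts: dict[str, tuple[int, int]]) -> float:
    """ΣC/ΣT as a percentage, from per-state (T, C) counts."""
    return 100.0 * TallyTable.from_counts(counts).overall_accuracy


def truth_per_chunk(rec: RawRecording, chunk_s: float = 1.0) -> list[str]:
    """Ground-truth state of each chunk: majority label of its samples
    (focused where no event covers the chunk)."""
    n_chunks = int(rec.n_samples / (chunk_s * rec.fs))
    state_at = np.full(rec.n_samples, STATES.index("focused"), dtype=np.int8)
    for ev in rec.events:
        if not ev.valid:
            continue
        a = ev.sample_index
        b = min(a + int(round(ev.duration_s * rec.fs)), rec.n_samples)
        state_at[a:b] = STATES.index(ev.state)
    size = int(round(chunk_s * rec.fs))
    labels = []
    for i in range(n_chunks):
        seg = state_at[i * size:(i + 1) * size]
        labels.append(STATES[int(np.bincount(seg).argmax())])
    return labels


def replay_online(rec: RawRecording, predict_fn, chunk_s: float = 1.0,
                  preset: str = "online", channel_policy: str = "default"
                  ) -> tuple[pd.DataFrame, TallyTable]:
    """Replay a recording through the streaming chain in 1-s chunks.

    ``predict_fn`` receives one preprocessed chunk (channels x T' at the
    preset's target rate) and returns a state label.  A trailing partial
    chunk is dropped.  Returns the per-chunk log and the tally table.
    """
    size = int(round(chunk_s * rec.fs))
    n_chunks = rec.n_samples // size
    truths = truth_per_chunk(rec, chunk_s)
    records = []
    for i in range(n_chunks):
        raw = rec.data[:, i * size:(i + 1) * size]
        chunk = preprocess_chunk(raw, rec.fs, rec.channel_names,
                                 preset=preset, channel_policy=channel_policy)
        pred = predict_fn(chunk)
        records.append({"chunk": i, "t_start_s": i * chunk_s,
                        "truth": truths[i], "prediction": pred})
    log = pd.DataFrame(records)
    tally = TallyTable.from_predictions(log["truth"].to_numpy(),
                                        log["prediction"].to_numpy())
    return log, tally


def make_psd_decoder(model, fs: float = 100.0):
    """Wrap a fitted PSD-input classifier (e.g. GRUEEGNetClassifier) as a
    chunk decoder: chunk (channels x T) -> Welch PSD -> dB-normalise ->
    predicted state."""
    from .spectral import PSDNormalizer, WelchPSD

    welch = WelchPSD(fs=fs)
    norm = PSDNormalizer()

    def predict(chunk: np.ndarray) -> str:
        psd = norm.transform(welch.transform(chunk[None]))
        return str(model.predict(psd)[0])

    return predict
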