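"""EEG data model and file I/O.

The in-memory container is :class:`RawRecording`: a channels x samples
matrix in microvolts with a sampling rate, ordered channel labels and a
list of event markers.  Markers carry one of the four driving attention
states (focused / visual / auditory / cognitive distraction), the
state-specific trial duration, and a validity flag (trials without the
required paddle-feedback response are flagged invalid and excluded from
analysis).

Supported on-disk formats:

* ``internal`` — an HDF5 container (one float array + header attributes +
  an events table).  Lossless round trip.
* ``brainvision`` — the .vhdr/.vmrk/.eeg triplet (IEEE float32,
  multiplexed), read through :mod:`mne`.
* ``edf`` — EDF+ with an annotations channel, read through :mod:`mne`.
  16-bit physical scaling, so the round trip is only near-lossless.

Writers for BrainVision and EDF live in :mod:`neurodrive.synthetic` (they
exist so the readers can be exercised end-to-end on generated data).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

STATES: tuple[str, ...] = ("focused", "visual", "auditory", "cognitive")

#: Trial duration in seconds for each attention state.
TRIAL_DURATIONS_S: dict[str, float] = {
    "focused": 5.0,
    "visual": 5.0,
    "auditory": 15.0,
    "cognitive": 10.0,
}

#: Default mapping from marker description ("S 1".."S 4") to state.
DEFAULT_MARKER_MAP: dict[str, str] = {
    "S 1": "focused",
    "S 2": "visual",
    "S 3": "auditory",
    "S 4": "cognitive",
}

STATE_TO_MARKER: dict[str, str] = {v: k for k, v in DEFAULT_MARKER_MAP.items()}


class FormatError(ValueError):
    """Raised for malformed or internally inconsistent recording files."""


@dataclass(frozen=True)
class EventMarker:
    """One trial-onset marker.

    Parameters
    ----------
    sample_index : int
        0-based sample position of trial onset.
    state : str
        One of :data:`STATES`.
    duration_s : float
        Trial length in seconds (state-specific by design).
    valid : bool
        False when the paddle-feedback task was not completed; such
        trials are discarded at epoching.
    """

    sample_index: int
    state: str
    duration_s: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.sample_index < 0:
            raise ValueError("sample_index must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass
class RawRecording:
    """Multichannel EEG segment: channels x samples, amplitudes in µV."""

    data: np.ndarray
    fs: float
    channel_names: list[str]
    events: list[EventMarker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        self.channel_names = list(self.channel_names)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] != len(self.channel_names):
            raise FormatError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        for ev in self.events:
            if not 0 <= ev.sample_index < self.n_samples:
                raise ValueError(
                    f"event at sample {ev.sample_index} outside recording "
                    f"of {self.n_samples} samples"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "RawRecording":
        return RawRecording(
            self.data.copy(), self.fs, list(self.channel_names), list(self.events)
        )

    def with_data(self, data: np.ndarray, fs: float | None = None,
                  events: list[EventMarker] | None = None,
                  channel_names: list[str] | None = None) -> "RawRecording":
        return RawRecording(
            data,
            self.fs if fs is None else fs,
            list(self.channel_names) if channel_names is None else channel_names,
            list(self.events) if events is None else events,
        )


# ---------------------------------------------------------------------------
# internal HDF5 container
# ---------------------------------------------------------------------------

def write_internal(rec: RawRecording, path: str | Path) -> Path:
    """Write *rec* to the internal HDF5 container (lossless)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["fs"] = float(rec.fs)
        f.attrs["units"] = "uV"
        f.create_dataset(
            "channel_names",
            data=np.array(rec.channel_names, dtype=h5py.string_dtype()),
        )
        ev = rec.events
        g = f.create_group("events")
        g.create_dataset("sample_index", data=np.array([e.sample_index for e in ev], dtype=np.int64))
        g.create_dataset("state", data=np.array([e.state for e in ev], dtype=h5py.string_dtype()))
        g.create_dataset("duration_s", data=np.array([e.duration_s for e in ev], dtype=np.float64))
        g.create_dataset("valid", data=np.array([e.valid for e in ev], dtype=bool))
    return path


def _read_internal(path: Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        data = np.asarray(f["data"])
        fs = float(f.attrs["fs"])
        names = [s.decode() if isinstance(s, bytes) else str(s) for s in f["channel_names"][()]]
        if data.shape[0] != len(names):
            raise FormatError(
                f"{path}: header lists {len(names)} channels but data has "
                f"{data.shape[0]} rows"
            )
        g = f["events"]
        events = [
            EventMarker(int(s), st.decode() if isinstance(st, bytes) else str(st), float(d), bool(v))
            for s, st, d, v in zip(
                g["sample_index"][()], g["state"][()], g["duration_s"][()], g["valid"][()]
            )
        ]
    return RawRecording(data, fs, names, events)


# ---------------------------------------------------------------------------
# BrainVision / EDF readers (via mne)
# ---------------------------------------------------------------------------

_MARKER_RE = re.compile(r"^(?P<kind>[^/]+)/(?P<desc>.+)$")


def _normalize_marker(desc: str) -> str:
    """Collapse whitespace: 'S  2' -> 'S 2'."""
    return " ".join(desc.split())


def _events_from_annotations(annotations, fs: float, n_samples: int,
                             marker_map: dict[str, str]) -> list[EventMarker]:
    norm_map = {_normalize_marker(k): v for k, v in marker_map.items()}
    events: list[EventMarker] = []
    for onset, duration, desc in zip(
        annotations.onset, annotations.duration, annotations.description
    ):
        m = _MARKER_RE.match(desc)
        if m:
            kind, label = m.group("kind"), m.group("desc")
        else:
            kind, label = "Stimulus", desc
        if kind.lower() in ("new segment", "edge"):
            continue
        label = _normalize_marker(label)
        if label not in norm_map:
            continue
        state = norm_map[label]
        sample = int(round(onset * fs))
        if not 0 <= sample < n_samples:
            continue
        dur = float(duration) if duration > 0 else TRIAL_DURATIONS_S[state]
        events.append(
            EventMarker(sample, state, dur, valid=(kind.lower() != "comment"))
        )
    return events


def _read_mne(path: Path, fmt: str, marker_map: dict[str, str]) -> RawRecording:
    import mne

    if fmt == "brainvision":
        for ext in (".vmrk", ".eeg"):
            if not path.with_suffix(ext).exists():
                raise FormatError(f"missing BrainVision sidecar file {path.with_suffix(ext)}")
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif fmt == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:  # pragma: no cover - guarded by caller
        raise FormatError(f"unknown format {fmt!r}")
    data_uv = raw.get_data() * 1e6  # mne returns Volts
    fs = float(raw.info["sfreq"])
    names = list(raw.ch_names)
    events = _events_from_annotations(raw.annotations, fs, data_uv.shape[1], marker_map)
    return RawRecording(data_uv, fs, names, events)


def read_recording(path: str | Path, format: str | None = None,
                   marker_map: dict[str, str] | None = None) -> RawRecording:
    """Read an EEG recording.

    Parameters
    ----------
    path : path-like
        File path (.h5 internal, .vhdr BrainVision header, .edf EDF).
    format : {"internal", "brainvision", "edf"}, optional
        Inferred from the suffix when omitted.
    marker_map : dict, optional
        Marker-description -> state mapping; defaults to ``"S 1".."S 4"``
        -> focused/visual/auditory/cognitive.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".h5": "internal", ".hdf5": "internal",
                  ".vhdr": "brainvision", ".edf": "edf"}.get(suffix)
        if format is None:
            raise FormatError(f"cannot infer format from suffix {suffix!r}")
    if format == "internal":
        return _read_internal(path)
    if format in ("brainvision", "edf"):
        return _read_mne(path, format, marker_map or DEFAULT_MARKER_MAP)
    raise FormatError(f"unknown format tag {format!r}")


def export_features_csv(path: str | Path, rows: list[dict]) -> Path:
    """Write tabular feature rows (channel, band, bin_hz, value, label, window_id)."""
    import pandas as pd

    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def save_json(path: str | Path, obj: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
    return path
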