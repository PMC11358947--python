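"""Offline and online EEG preprocessing chains.

The chain mirrors standard driving-EEG practice: band-pass filtering,
mastoid re-referencing, channel selection down to 59 scalp electrodes,
downsampling to 100 Hz, epoching by state-specific trial length, slicing
into non-overlapping 1-s windows, and amplitude-based artifact rejection
(any window with |amplitude| > 100 µV on any channel is dropped whole —
windows are the classification atom, so partial interpolation is not
attempted).

Two named presets exist and are deliberately not unified: the offline
pipeline filters 0.5–50 Hz, the online (streaming) pipeline 0.1–45 Hz;
both downsample to 100 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import RawRecording, EventMarker, TRIAL_DURATIONS_S
from .montage import DROP_DEFAULT, MASTOIDS

logger = logging.getLogger(__name__)


@dataclass
class TrialEpoch:
    """One trial: channels x (duration_s * fs) samples, µV."""

    data: np.ndarray
    state: str
    trial_id: int
    fs: float

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class WindowSample:
    """One labelled 1-s analysis window (the classification atom)."""

    data: np.ndarray            # channels x T (T = fs * 1 s)
    state: str
    source_trial: int
    window_index: int
    fs: float


@dataclass(frozen=True)
class PreprocessConfig:
    """Filter band + target rate for one preprocessing preset."""

    low_hz: float
    high_hz: float
    target_fs: float = 100.0
    artifact_threshold_uv: float = 100.0
    name: str = "custom"


OFFLINE_PRESET = PreprocessConfig(0.5, 50.0, name="offline")
ONLINE_PRESET = PreprocessConfig(0.1, 45.0, name="online")

PRESETS = {"offline": OFFLINE_PRESET, "online": ONLINE_PRESET}


# ---------------------------------------------------------------------------
# channel operations
# ---------------------------------------------------------------------------

def select_channels(rec: RawRecording, policy: str | list[str] = "default") -> RawRecording:
    """Apply a channel-selection policy.

    ``"default"`` drops {Fz, Fp1, Fp2, TP9, TP10} from the 64-channel
    montage (online reference + ocular/mastoid sites), leaving 59 scalp
    channels in stable order.  ``"identity"`` keeps everything.  A list of
    names keeps exactly those channels, in recording order.
    """
    if policy == "identity":
        return rec.copy()
    if policy == "default":
        missing = DROP_DEFAULT - set(rec.channel_names)
        if missing:
            raise ValueError(f"montage lacks channels required by policy: {sorted(missing)}")
        keep = [n for n in rec.channel_names if n not in DROP_DEFAULT]
    else:
        missing = set(policy) - set(rec.channel_names)
        if missing:
            raise ValueError(f"requested channels absent: {sorted(missing)}")
        keep = [n for n in rec.channel_names if n in set(policy)]
    idx = [rec.channel_names.index(n) for n in keep]
    return rec.with_data(rec.data[idx], channel_names=keep)


def rereference_mastoid(rec: RawRecording) -> RawRecording:
    """Subtract the TP9/TP10 average from every channel, sample-wise."""
    try:
        i9 = rec.channel_names.index(MASTOIDS[0])
        i10 = rec.channel_names.index(MASTOIDS[1])
    except ValueError:
        raise ValueError("mastoid channels TP9/TP10 absent; cannot re-reference") from None
    ref = 0.5 * (rec.data[i9] + rec.data[i10])
    return rec.with_data(rec.data - ref[None, :])


# ---------------------------------------------------------------------------
# temporal operations
# ---------------------------------------------------------------------------

def bandpass_filter(rec: RawRecording, low_hz: float, high_hz: float,
                    order: int = 4) -> RawRecording:
    """Zero-phase Butterworth band-pass (forward-backward, per channel)."""
    nyq = rec.fs / 2.0
    if not 0 <= low_hz < high_hz < nyq:
        raise ValueError(f"invalid band ({low_hz}, {high_hz}) for fs={rec.fs}")
    if low_hz > 0:
        sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos")
    else:
        sos = signal.butter(order, high_hz, btype="lowpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.with_data(filtered)


def downsample(rec: RawRecording, target_fs: float = 100.0) -> RawRecording:
    """Anti-alias filter and decimate to *target_fs*.

    Event sample indices are rescaled to the new rate.  1 s of 1000 Hz
    data becomes exactly 100 samples.
    """
    if target_fs > rec.fs:
        raise ValueError(f"target_fs {target_fs} exceeds fs {rec.fs}")
    if target_fs == rec.fs:
        return rec.copy()
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(rec.data, up, down, axis=1)
    ratio = target_fs / rec.fs
    n_new = data.shape[1]
    events = [
        EventMarker(min(int(round(e.sample_index * ratio)), n_new - 1),
                    e.state, e.duration_s, e.valid)
        for e in rec.events
    ]
    return rec.with_data(data, fs=target_fs, events=events)


# ---------------------------------------------------------------------------
# epoching / windowing / rejection
# ---------------------------------------------------------------------------

def epoch_trials(rec: RawRecording,
                 durations: dict[str, float] | None = None) -> list[TrialEpoch]:
    """Cut one epoch per *valid* event at the state-specific duration.

    Invalid trials (no paddle feedback) are skipped here, before any
    feature computation.  Epochs that would run past the end of the
    recording are skipped with a logged count.
    """
    durations = durations or TRIAL_DURATIONS_S
    epochs: list[TrialEpoch] = []
    n_truncated = 0
    for trial_id, ev in enumerate(rec.events):
        if not ev.valid:
            continue
        dur = ev.duration_s if ev.duration_s > 0 else durations[ev.state]
        n = int(round(dur * rec.fs))
        stop = ev.sample_index + n
        if stop > rec.n_samples:
            n_truncated += 1
            continue
        epochs.append(TrialEpoch(rec.data[:, ev.sample_index:stop].copy(),
                                 ev.state, trial_id, rec.fs))
    if n_truncated:
        logger.warning("skipped %d epochs extending past end of recording", n_truncated)
    return epochs


def window_epochs(epochs: list[TrialEpoch], window_s: float = 1.0) -> list[WindowSample]:
    """Slice epochs into non-overlapping windows of *window_s* seconds.

    A D-second trial yields exactly D windows (for the default 1 s), each
    inheriting the trial's label.
    """
    windows: list[WindowSample] = []
    for ep in epochs:
        n = int(round(window_s * ep.fs))
        n_win = ep.data.shape[1] // n
        for w in range(n_win):
            windows.append(WindowSample(ep.data[:, w * n:(w + 1) * n].copy(),
                                        ep.state, ep.trial_id, w, ep.fs))
    return windows


def reject_artifacts(windows: list[WindowSample],
                     threshold_uv: float = 100.0) -> list[WindowSample]:
    """Drop any window whose absolute amplitude exceeds *threshold_uv* on any channel."""
    kept = [w for w in windows if np.max(np.abs(w.data)) <= threshold_uv]
    n_rej = len(windows) - len(kept)
    if n_rej:
        logger.info("rejected %d/%d windows above %.0f uV", n_rej, len(windows), threshold_uv)
    return kept


# ---------------------------------------------------------------------------
# full chains
# ---------------------------------------------------------------------------

def preprocess_recording(rec: RawRecording, preset: str | PreprocessConfig = "offline",
                         channel_policy: str | list[str] = "default",
                         reject: bool = True) -> list[WindowSample]:
    """Full chain: filter -> re-reference -> select -> downsample -> epoch ->
    window -> (optionally) reject.  Returns labelled 1-s windows."""
    cfg = PRESETS[preset] if isinstance(preset, str) else preset
    out = bandpass_filter(rec, cfg.low_hz, cfg.high_hz)
    if set(MASTOIDS) <= set(out.channel_names):
        out = rereference_mastoid(out)
    out = select_channels(out, channel_policy)
    out = downsample(out, cfg.target_fs)
    windows = window_epochs(epoch_trials(out))
    if reject:
        windows = reject_artifacts(windows, cfg.artifact_threshold_uv)
    return windows


def preprocess_chunk(data_uv: np.ndarray, fs: float, channel_names: list[str],
                     preset: str | PreprocessConfig = "online",
                     channel_policy: str | list[str] = "default") -> np.ndarray:
    """Online chain for one streamed chunk (no epoching): returns the
    preprocessed channels x T' array at the preset's target rate."""
    cfg = PRESETS[preset] if isinstance(preset, str) else preset
    rec = RawRecording(data_uv, fs, channel_names)
    out = bandpass_filter(rec, cfg.low_hz, cfg.high_hz)
    if set(MASTOIDS) <= set(out.channel_names):
        out = rereference_mastoid(out)
    out = select_channels(out, channel_policy)
    out = downsample(out, cfg.target_fs)
    return out.data


def windows_to_array(windows: list[WindowSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into (n, channels, T) plus the label vector."""
    if not windows:
        return np.empty((0, 0, 0)), np.empty((0,), dtype=object)
    X = np.stack([w.data for w in windows])
    y = np.array([w.state for w in windows], dtype=object)
    return X, y
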