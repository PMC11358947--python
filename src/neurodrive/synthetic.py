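"""Synthetic EEG with the statistical structure the decoder assumes.

The generator emulates a distracted-driving protocol: laps of simulated
driving during which visual (5 s), auditory (15 s) and cognitive (10 s)
distractor subtasks appear at uniformly random, non-overlapping times (up
to 12 per lap over 7 laps by default, i.e. 84 distractor trials), with
the remaining time labelled focused driving.

Signals are 1/f-shaped background noise plus narrowband θ/α/β
oscillations (band-filtered Gaussian noise, not pure sinusoids, so Welch
estimates carry realistic variance) and white sensor noise, calibrated in
µV.  Each attention state multiplies the band amplitudes by
state-specific gains, applied fully over a state-specific scalp region
and attenuated elsewhere — a caricature of the reported topographies
(visual distraction suppresses parieto-occipital α/β; auditory
distraction elevates α; cognitive load elevates frontal θ/α), not a
biophysical forward model.

Everything is seeded and reproducible; fixtures ship with a manifest of
expected counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import (DEFAULT_MARKER_MAP, STATE_TO_MARKER, EventMarker,
                 RawRecording, TRIAL_DURATIONS_S)
from .montage import CHANNELS_64, DROP_DEFAULT, region_mask

DISTRACTORS: tuple[str, ...] = ("visual", "auditory", "cognitive")


@dataclass(frozen=True)
class SimDesign:
    """Experiment-design parameters."""

    laps: int = 7
    max_subtasks_per_lap: int = 12
    lap_duration_s: float = 300.0
    durations: dict = field(default_factory=lambda: {
        "visual": 5.0, "auditory": 15.0, "cognitive": 10.0})
    min_gap_s: float = 5.0
    seed: int | None = 0


@dataclass(frozen=True)
class DesignEvent:
    onset_s: float
    state: str
    duration_s: float
    lap: int
    valid: bool = True


def simulate_design(cfg: SimDesign) -> list[DesignEvent]:
    """Place subtask events uniformly at random without overlap.

    Each lap receives exactly ``max_subtasks_per_lap`` distractors with
    uniformly random types; inter-event gaps are at least ``min_gap_s``
    (so focused segments exist) with the slack distributed uniformly
    (Dirichlet over the gaps).  Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    events: list[DesignEvent] = []
    n = cfg.max_subtasks_per_lap
    for lap in range(cfg.laps):
        if n == 0:
            continue
        types = [DISTRACTORS[i] for i in rng.integers(0, len(DISTRACTORS), n)]
        total_busy = sum(cfg.durations[t] for t in types)
        slack = cfg.lap_duration_s - total_busy - (n + 1) * cfg.min_gap_s
        if slack < 0:
            raise ValueError(
                f"lap {lap}: {n} subtasks need {total_busy + (n + 1) * cfg.min_gap_s:.0f}s "
                f"but lap is {cfg.lap_duration_s:.0f}s")
        gaps = cfg.min_gap_s + slack * rng.dirichlet(np.ones(n + 1))
        t = lap * cfg.lap_duration_s
        for g, state in zip(gaps, types):
            t += g
            events.append(DesignEvent(t, state, cfg.durations[state], lap))
            t += cfg.durations[state]
    return events


def focused_trials(events: list[DesignEvent], cfg: SimDesign,
                   trial_s: float = 5.0) -> list[DesignEvent]:
    """Carve one focused trial from each inter-event gap of >= trial_s."""
    out: list[DesignEvent] = []
    total = cfg.laps * cfg.lap_duration_s
    bounds = sorted((e.onset_s, e.onset_s + e.duration_s) for e in events)
    prev = 0.0
    for start, stop in bounds + [(total, total)]:
        gap = start - prev
        if gap >= trial_s:
            onset = prev + (gap - trial_s) / 2.0
            out.append(DesignEvent(onset, "focused", trial_s,
                                   int(onset // cfg.lap_duration_s)))
        prev = max(prev, stop)
    return out


def design_summary(events: list[DesignEvent], cfg: SimDesign) -> dict:
    """Label bookkeeping: event seconds + focused seconds = total exactly."""
    total = cfg.laps * cfg.lap_duration_s
    busy = sum(e.duration_s for e in events if e.state != "focused")
    return {"total_s": total, "distractor_s": busy, "focused_s": total - busy,
            "n_events": sum(e.state != "focused" for e in events)}


# ---------------------------------------------------------------------------
# effect profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectProfile:
    """State-dependent multiplicative band-amplitude gains.

    ``gains[state] = (g_theta, g_alpha, g_beta)`` apply at full strength
    over ``regions[state]`` and with exponent ``off_region_weight`` of
    their log-gain elsewhere.  The focused state is the (1, 1, 1)
    baseline by construction.
    """

    gains: dict = field(default_factory=dict)
    regions: dict = field(default_factory=dict)
    background_exponent: float = 1.0
    background_rms_uv: float = 8.0
    osc_rms_uv: dict = field(default_factory=lambda: {
        "theta": 3.0, "alpha": 5.0, "beta": 2.5})
    sensor_noise_uv: float = 1.5
    off_region_weight: float = 0.4

    def __post_init__(self) -> None:
        for state, g in self.gains.items():
            if any(v <= 0 for v in g):
                raise ValueError(f"gains must be positive ({state}: {g})")
        if tuple(self.gains.get("focused", (1, 1, 1))) != (1, 1, 1):
            raise ValueError("focused gains must be (1, 1, 1)")

    @classmethod
    def default(cls, strength: float = 1.0) -> "EffectProfile":
        """Base qualitative profile raised to the given log-strength.

        strength 0 -> no class contrast (null); 1 -> moderate; 2 ->
        strong, clearly recoverable contrast.
        """
        base = {
            "focused": (1.0, 1.0, 1.0),
            "visual": (1.0, 0.70, 0.75),    # parieto-occipital α/β suppression
            "auditory": (1.0, 1.60, 1.10),  # α (spindle-band) elevation
            "cognitive": (1.50, 1.40, 1.0),  # frontal θ/α load response
        }
        gains = {s: tuple(float(g) ** strength for g in v) for s, v in base.items()}
        regions = {
            "focused": ("frontal", "central", "parietal", "occipital"),
            "visual": ("parietal", "occipital"),
            "auditory": ("central", "parietal"),
            "cognitive": ("frontal", "central"),
        }
        return cls(gains=gains, regions=regions)


# ---------------------------------------------------------------------------
# noise primitives
# ---------------------------------------------------------------------------

def pink_noise(rng: np.random.Generator, shape: tuple, fs: float,
               exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent-shaped Gaussian noise along the last axis, unit RMS."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    rms = np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def band_noise(rng: np.random.Generator, shape: tuple, fs: float,
               lo: float, hi: float) -> np.ndarray:
    """Narrowband Gaussian noise (FFT brick-wall band-pass), unit RMS."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[..., ~((freqs >= lo) & (freqs <= hi))] = 0.0
    x = np.fft.irfft(spec, n=n, axis=-1)
    rms = np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


_BAND_EDGES = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 35.0)}


def _effective_gains(profile: EffectProfile, state: str,
                     channel_names: list[str]) -> dict[str, np.ndarray]:
    """Per-channel amplitude gain for each band under *state*."""
    g = profile.gains.get(state, (1.0, 1.0, 1.0))
    mask = region_mask(channel_names, profile.regions.get(
        state, ("frontal", "central", "parietal", "occipital")))
    w = np.where(mask, 1.0, profile.off_region_weight)
    return {band: np.exp(w * math.log(gv))
            for band, gv in zip(_BAND_EDGES, g)}


# ---------------------------------------------------------------------------
# continuous recordings
# ---------------------------------------------------------------------------

def simulate_eeg(events: list[DesignEvent], profile: EffectProfile,
                 duration_s: float, n_channels: int = 64, fs: float = 1000.0,
                 seed: int | None = 0,
                 artifact_times_s: list[float] | None = None) -> RawRecording:
    """Synthesize a continuous multichannel recording with embedded markers.

    Includes the full 64-channel montage (with Fz/Fp1/Fp2/TP9/TP10) so
    the complete preprocessing chain is exercised.  Optional artifact
    pulses of 150 µV are planted at the given times.
    """
    rng = np.random.default_rng(seed)
    names = list(CHANNELS_64[:n_channels])
    n = int(round(duration_s * fs))
    data = profile.background_rms_uv * pink_noise(
        rng, (len(names), n), fs, profile.background_exponent)

    # state timeline (piecewise constant)
    state_at = np.full(n, -1, dtype=np.int8)  # -1 = focused background
    order = {"visual": 0, "auditory": 1, "cognitive": 2, "focused": 3}
    for ev in events:
        a = int(round(ev.onset_s * fs))
        b = min(int(round((ev.onset_s + ev.duration_s) * fs)), n)
        if ev.state != "focused":
            state_at[a:b] = order[ev.state]

    for band, (lo, hi) in _BAND_EDGES.items():
        osc = band_noise(rng, (len(names), n), fs, lo, hi)
        env = np.ones((len(names), n))
        for state in ("visual", "auditory", "cognitive"):
            seg = state_at == order[state]
            if seg.any():
                gch = _effective_gains(profile, state, names)[band]
                env[:, seg] = gch[:, None]
        data += profile.osc_rms_uv[band] * osc * env

    data += profile.sensor_noise_uv * rng.standard_normal(data.shape)

    if artifact_times_s:
        for t in artifact_times_s:
            i = int(round(t * fs))
            if 0 <= i < n:
                data[rng.integers(len(names)), i] += 150.0

    markers = [
        EventMarker(int(round(ev.onset_s * fs)), ev.state, ev.duration_s, ev.valid)
        for ev in events
        if 0 <= int(round(ev.onset_s * fs)) < n
    ]
    return RawRecording(data, fs, names, sorted(markers, key=lambda e: e.sample_index))


# ---------------------------------------------------------------------------
# window-space fixtures
# ---------------------------------------------------------------------------

POST_CHANNELS: list[str] = [c for c in CHANNELS_64 if c not in DROP_DEFAULT]


def generate_windows(n_per_class: dict[str, int], profile: EffectProfile,
                     fs: float = 100.0, seed: int | None = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Labelled 1-s windows directly in post-preprocessing space
    (59 channels at 100 Hz), bypassing the filtering chain.

    Returns ``(X, y)`` with X of shape (n, 59, fs) in µV, class blocks
    interleaved deterministically.
    """
    rng = np.random.default_rng(seed)
    names = POST_CHANNELS
    T = int(fs)
    blocks, labels = [], []
    for state in ("focused", "visual", "auditory", "cognitive"):
        m = n_per_class.get(state, 0)
        if m == 0:
            continue
        x = profile.background_rms_uv * pink_noise(
            rng, (m, len(names), T), fs, profile.background_exponent)
        gains = _effective_gains(profile, state, names)
        for band, (lo, hi) in _BAND_EDGES.items():
            osc = band_noise(rng, (m, len(names), T), fs, lo, hi)
            x += profile.osc_rms_uv[band] * gains[band][None, :, None] * osc
        x += profile.sensor_noise_uv * rng.standard_normal(x.shape)
        blocks.append(x)
        labels.extend([state] * m)
    X = np.concatenate(blocks) if blocks else np.empty((0, len(names), T))
    y = np.array(labels, dtype=object)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


@dataclass
class Fixture:
    name: str
    X: np.ndarray
    y: np.ndarray
    manifest: dict


FIXTURE_NAMES = ("separable_2class", "strong_4class", "null_4class",
                 "artifact_spiked")


def make_fixture(name: str, seed: int = 0) -> Fixture:
    """Small deterministic datasets powering the test suite.

    * ``separable_2class`` — focused vs auditory at high contrast.
    * ``strong_4class``    — 4 balanced classes x 200 windows, strong
      band effects (the recovery benchmark).
    * ``null_4class``      — zero contrast (all gains 1): chance-level.
    * ``artifact_spiked``  — 100 windows, 7 planted >100 µV spikes.
    """
    if name == "separable_2class":
        prof = EffectProfile.default(strength=2.5)
        X, y = generate_windows({"focused": 120, "auditory": 120}, prof, seed=seed)
        manifest = {"counts": {"focused": 120, "auditory": 120}, "strength": 2.5}
    elif name == "strong_4class":
        prof = EffectProfile.default(strength=2.0)
        counts = {s: 200 for s in ("focused", "visual", "auditory", "cognitive")}
        X, y = generate_windows(counts, prof, seed=seed)
        manifest = {"counts": counts, "strength": 2.0}
    elif name == "null_4class":
        prof = EffectProfile.default(strength=0.0)
        counts = {s: 100 for s in ("focused", "visual", "auditory", "cognitive")}
        X, y = generate_windows(counts, prof, seed=seed)
        manifest = {"counts": counts, "strength": 0.0}
    elif name == "artifact_spiked":
        prof = EffectProfile.default(strength=1.0)
        counts = {s: 25 for s in ("focused", "visual", "auditory", "cognitive")}
        X, y = generate_windows(counts, prof, seed=seed)
        rng = np.random.default_rng(seed + 1)
        spiked = sorted(rng.choice(len(y), size=7, replace=False).tolist())
        for i in spiked:
            ch = int(rng.integers(X.shape[1]))
            t = int(rng.integers(X.shape[2]))
            X[i, ch, t] = 150.0
        manifest = {"counts": counts, "n_windows": len(y), "spiked_indices": spiked,
                    "expected_survivors": len(y) - len(spiked)}
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return Fixture(name, X, y, manifest)


# ---------------------------------------------------------------------------
# file writers (exercise the mne-backed readers end to end)
# ---------------------------------------------------------------------------

def write_brainvision(rec: RawRecording, basepath) -> "Path":
    """Write the .vhdr/.vmrk/.eeg triplet (IEEE float32, multiplexed,
    resolution 1 µV).  Returns the .vhdr path."""
    from pathlib import Path

    base = Path(basepath)
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    interval_us = 1e6 / rec.fs
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "", "[Common Infos]", "Codepage=UTF-8",
        f"DataFile={eeg.name}", f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY", "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={interval_us:g}",
        "", "[Binary Infos]", "BinaryFormat=IEEE_FLOAT_32",
        "", "[Channel Infos]",
    ]
    for i, name in enumerate(rec.channel_names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "", "[Common Infos]", "Codepage=UTF-8", f"DataFile={eeg.name}",
        "", "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, ev in enumerate(rec.events, start=2):
        kind = "Stimulus" if ev.valid else "Comment"
        desc = STATE_TO_MARKER[ev.state]
        size = int(round(ev.duration_s * rec.fs))
        mlines.append(f"Mk{k}={kind},{desc},{ev.sample_index + 1},{size},0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    rec.data.T.astype("<f4").tofile(eeg)
    return vhdr


def write_edf(rec: RawRecording, path) -> "Path":
    """Minimal EDF+C writer (16-bit, 1-s records, one annotations signal).

    Requires an integer number of seconds at an integer sampling rate.
    Events become EDF+ annotations "Stimulus/S k" (or "Comment/S k" for
    invalid trials) with onset and duration.
    """
    from pathlib import Path

    path = Path(path)
    fs = int(rec.fs)
    if fs != rec.fs:
        raise ValueError("EDF writer requires integer sampling rate")
    if rec.n_samples % fs != 0:
        raise ValueError("EDF writer requires an integer number of seconds")
    n_rec = rec.n_samples // fs
    nch = rec.n_channels

    # annotations: all event TALs live in record 0
    tals = []
    for ev in rec.events:
        kind = "Stimulus" if ev.valid else "Comment"
        desc = f"{kind}/{STATE_TO_MARKER[ev.state]}"
        onset = ev.sample_index / rec.fs
        tals.append(f"+{onset:.4f}\x15{ev.duration_s:.4f}\x14{desc}\x14\x00".encode())
    tal0 = b"+0\x14\x14\x00" + b"".join(tals)
    ann_bytes = max(64, 2 * ((len(tal0) + 24) // 2 + 2))
    ann_samples = ann_bytes // 2

    pmax = np.maximum(np.abs(rec.data).max(axis=1), 1e-6) * 1.000001
    digital = np.round(rec.data / pmax[:, None] * 32767).astype("<i2")

    def f(s: str, width: int) -> bytes:
        b = s.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    ns = nch + 1
    header = b"".join([
        f("0", 8), f("X X X X", 80), f("Startdate 01-JAN-2026 X X X", 80),
        f("01.01.26", 8), f("00.00.00", 8), f(str(256 * (ns + 1)), 8),
        f("EDF+C", 44), f(str(n_rec), 8), f("1", 8), f(str(ns), 4),
    ])
    labels = [f(n, 16) for n in rec.channel_names] + [f("EDF Annotations", 16)]
    fields = [
        labels,
        [f("", 80)] * ns,
        [f("uV", 8)] * nch + [f("", 8)],
        [f(f"{-p:.6g}"[:8], 8) for p in pmax] + [f("-1", 8)],
        [f(f"{p:.6g}"[:8], 8) for p in pmax] + [f("1", 8)],
        [f("-32768", 8)] * ns,
        [f("32767", 8)] * ns,
        [f("", 80)] * ns,
        [f(str(fs), 8)] * nch + [f(str(ann_samples), 8)],
        [f("", 32)] * ns,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.writelines(group)
        for r in range(n_rec):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())
            if r == 0:
                ann = tal0
            else:
                ann = f"+{r}\x14\x14\x00".encode()
            fh.write(ann + b"\x00" * (ann_bytes - len(ann)))
    return path
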