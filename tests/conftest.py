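import numpy as np
import pytest

from neurodrive.spectral import PSDNormalizer, WelchPSD
from neurodrive.synthetic import (EffectProfile, SimDesign, focused_trials,
                                  make_fixture, simulate_design, simulate_eeg)


@pytest.fixture(scope="session")
def strong_fixture():
    return make_fixture("strong_4class", seed=0)


@pytest.fixture(scope="session")
def strong_psd(strong_fixture):
    psd = PSDNormalizer().transform(WelchPSD(fs=100.0).transform(strong_fixture.X))
    return psd, strong_fixture.y


@pytest.fixture(scope="session")
def small_recording():
    """1 lap x 60 s continuous recording at 500 Hz with markers."""
    design = SimDesign(laps=1, max_subtasks_per_lap=3, lap_duration_s=60.0, seed=5)
    events = simulate_design(design)
    events = sorted(events + focused_trials(events, design), key=lambda e: e.onset_s)
    return simulate_eeg(events, EffectProfile.default(1.0), duration_s=60.0,
                        fs=500.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
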