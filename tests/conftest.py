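import numpy as np
import pytest
from scipy.signal import lfilter

from bicisim import (
    BinauralScene,
    MapParameters,
    SourceSpec,
    StrategyConfig,
    default_weights,
    process_bilateral,
    render_scene,
)

RATE = 16000.0


@pytest.fixture(scope="session")
def weights():
    return default_weights()


@pytest.fixture(scope="session")
def flat_map():
    return MapParameters.default()


def make_vowel(formants=(500.0, 1500.0, 2500.0), bw=80.0, duration=1.0,
               f0=100.0, rate=RATE):
    """Synthetic vowel: glottal impulse train through a resonator cascade."""
    n = int(duration * rate)
    src = np.zeros(n)
    src[:: int(rate / f0)] = 1.0
    y = src
    for f in formants:
        r = np.exp(-np.pi * bw / rate)
        y = lfilter([1.0], [1.0, -2.0 * r * np.cos(2.0 * np.pi * f / rate), r * r], y)
    return y / np.max(np.abs(y))


@pytest.fixture(scope="session")
def vowel_500_1500_2500():
    return make_vowel()


@pytest.fixture(scope="session")
def neg90_ace_sync():
    """440 Hz tone at -90 degrees, ACE on both ears (shared heavy run)."""
    scene = BinauralScene(source=SourceSpec(kind="tone", freq=440.0), azimuth=-90.0)
    stereo = render_scene(scene, duration=3.0, seed=1)
    cfg = StrategyConfig(strategy="ACE")
    return process_bilateral(stereo.channel(0), stereo.channel(1), cfg, cfg, seed=1)
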