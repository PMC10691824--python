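"""Binaural test-scene synthesis.

Emulates a circular loudspeaker array (24 speakers at 15 degree spacing)
around a dummy head at the level of signal statistics: a source and any
number of interferers are each placed at an azimuth on the 15 degree grid,
and the head is reduced to two interaural cues per component:

    ITD = itd_at_90 * sin(azimuth)        (740 us default lateral lead)
    ILD = ild_at_90 * sin(azimuth)  dB    (10 dB default)

with negative azimuths leading (and favouring) the left ear.  The sine law
stands in for full head-related transfer functions, which the model does
not attempt to reproduce.  Available components: pure tones (with 10 ms
raised-cosine ramps), speech-shaped noise (SSN), a multi-stream babble
surrogate, and a speech-like amplitude-modulated carrier for competing
talkers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.signal import firwin2, lfilter, butter

from .audio_io import AudioSignal, DEFAULT_RATE, fractional_delay

logger = logging.getLogger("bicisim")

#: Interaural delay of a fully lateral (+/-90 degree) source, seconds.
DEFAULT_ITD_AT_90 = 740e-6
#: Interaural level difference of a fully lateral source, dB.
DEFAULT_ILD_AT_90 = 10.0
AZIMUTH_STEP = 15.0

NOISE_TYPES = ("SSN", "babble")
INTERFERER_TYPES = ("SSN", "babble", "competing")

# Long-term speech-spectrum shaping for SSN: flat through the first-formant
# region, then falling roughly 9 dB/octave.  (frequency Hz, gain dB) pairs.
_LTSS_POINTS = (
    (0.0, -30.0),
    (100.0, -12.0),
    (300.0, 0.0),
    (500.0, 0.0),
    (1000.0, -7.0),
    (2000.0, -15.0),
    (4000.0, -23.0),
    (8000.0, -32.0),
)


class SceneError(ValueError):
    """Raised for invalid scene specifications."""


@dataclass(frozen=True)
class SourceSpec:
    """What a scene component plays: a tone, a noise class or a WAV file."""

    kind: str = "tone"  # tone | speech | SSN | babble | file
    freq: float = 440.0  # Hz, for tones
    path: str | None = None  # for kind == "file"


@dataclass(frozen=True)
class Interferer:
    kind: str  # SSN | babble | competing
    azimuth: float  # degrees
    snr_db: float  # source-to-interferer ratio

    def __post_init__(self) -> None:
        if self.kind not in INTERFERER_TYPES:
            raise SceneError(
                f"unknown interferer type {self.kind!r}; expected {INTERFERER_TYPES}"
            )
        _check_azimuth(self.azimuth)
        if not np.isfinite(self.snr_db):
            raise SceneError("SNR must be finite")


@dataclass
class BinauralScene:
    """A source plus interferers on the 15 degree azimuth grid."""

    source: SourceSpec = field(default_factory=SourceSpec)
    azimuth: float = 0.0
    interferers: tuple = ()
    itd_at_90: float = DEFAULT_ITD_AT_90
    ild_at_90: float = DEFAULT_ILD_AT_90

    def __post_init__(self) -> None:
        _check_azimuth(self.azimuth)
        if self.itd_at_90 <= 0:
            raise SceneError("itd_at_90 must be positive")
        self.interferers = tuple(self.interferers)

    @classmethod
    def from_yaml(cls, path) -> "BinauralScene":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        src = doc.get("source", {})
        return cls(
            source=SourceSpec(
                kind=src.get("kind", "tone"),
                freq=float(src.get("freq", 440.0)),
                path=src.get("path"),
            ),
            azimuth=float(doc.get("azimuth", 0.0)),
            interferers=tuple(
                Interferer(
                    kind=row["kind"],
                    azimuth=float(row["azimuth"]),
                    snr_db=float(row["snr_db"]),
                )
                for row in doc.get("interferers", [])
            ),
            itd_at_90=float(doc.get("itd_at_90", DEFAULT_ITD_AT_90)),
            ild_at_90=float(doc.get("ild_at_90", DEFAULT_ILD_AT_90)),
        )


def _check_azimuth(azimuth: float) -> None:
    if not -180.0 <= azimuth < 180.0:
        raise SceneError(f"azimuth {azimuth} outside [-180, 180)")
    if abs(azimuth / AZIMUTH_STEP - round(azimuth / AZIMUTH_STEP)) > 1e-9:
        raise SceneError(f"azimuth {azimuth} not on the {AZIMUTH_STEP} degree grid")


def make_tone(freq: float, duration: float, rate: float = DEFAULT_RATE) -> AudioSignal:
    """Unit-amplitude sinusoid with 10 ms raised-cosine onset/offset ramps."""
    if duration <= 0:
        raise SceneError("duration must be positive")
    if not 0 < freq < rate / 2:
        raise SceneError(f"tone frequency {freq} Hz must be below Nyquist ({rate / 2})")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    x = np.sin(2.0 * np.pi * freq * t)
    ramp_n = min(int(round(0.010 * rate)), n // 2)
    if ramp_n > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        x[:ramp_n] *= ramp
        x[-ramp_n:] *= ramp[::-1]
    return AudioSignal(x, rate)


def make_noise(
    kind: str, duration: float, rate: float = DEFAULT_RATE, seed: int = 0
) -> AudioSignal:
    """Unit-RMS interferer noise, deterministic given the seed.

    ``SSN``: white noise shaped by a fixed long-term-speech-spectrum filter.
    ``babble``: sum of eight independent amplitude-modulated narrowband
    streams, a statistical surrogate for multi-talker babble.
    """
    if duration <= 0:
        raise SceneError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    if kind == "SSN":
        x = _shape_ssn(rng.standard_normal(n), rate)
    elif kind == "babble":
        x = _babble(rng, n, rate)
    else:
        raise SceneError(f"unknown noise type {kind!r}; expected one of {NOISE_TYPES}")
    return AudioSignal(x / _rms(x), rate)


def _shape_ssn(white: np.ndarray, rate: float) -> np.ndarray:
    freqs = np.array([f for f, _ in _LTSS_POINTS])
    gains = 10.0 ** (np.array([g for _, g in _LTSS_POINTS]) / 20.0)
    freqs = np.clip(freqs, 0.0, rate / 2.0) / (rate / 2.0)
    freqs[-1] = 1.0
    taps = firwin2(257, freqs, gains)
    return lfilter(taps, [1.0], white)


def _babble(rng: np.random.Generator, n: int, rate: float, n_streams: int = 8) -> np.ndarray:
    """Sum of amplitude-modulated narrowband voice-surrogate streams."""
    out = np.zeros(n)
    t = np.arange(n) / rate
    for _ in range(n_streams):
        lo = rng.uniform(150.0, 1200.0)
        hi = lo * rng.uniform(1.8, 3.5)
        hi = min(hi, 0.45 * rate)
        b, a = butter(2, [lo / (rate / 2), hi / (rate / 2)], btype="band")
        carrier = lfilter(b, a, rng.standard_normal(n))
        # syllabic-rate envelope around 2-6 Hz
        mod_rate = rng.uniform(2.0, 6.0)
        env = 0.5 * (1.0 + np.sin(2 * np.pi * mod_rate * t + rng.uniform(0, 2 * np.pi)))
        out += carrier * env
    return out


def make_speech_like(
    duration: float, rate: float = DEFAULT_RATE, seed: int = 0
) -> AudioSignal:
    """Speech-like surrogate: SSN carrier with syllabic amplitude modulation."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    carrier = _shape_ssn(rng.standard_normal(n), rate)
    t = np.arange(n) / rate
    env = 0.55 + 0.45 * np.sin(
        2 * np.pi * 4.0 * t + rng.uniform(0, 2 * np.pi)
    )
    x = carrier * env
    return AudioSignal(x / _rms(x), rate)


def _rms(x: np.ndarray) -> float:
    r = float(np.sqrt(np.mean(x**2)))
    if r == 0.0:
        raise SceneError("zero-energy signal")
    return r


def _component_signal(
    spec: SourceSpec, duration: float, rate: float, seed: int
) -> np.ndarray:
    if spec.kind == "tone":
        return make_tone(spec.freq, duration, rate).samples
    if spec.kind in ("speech", "competing"):
        return make_speech_like(duration, rate, seed).samples
    if spec.kind in NOISE_TYPES:
        return make_noise(spec.kind, duration, rate, seed).samples
    if spec.kind == "file":
        from .audio_io import load_audio

        sig = load_audio(spec.path, target_rate=rate)
        x = sig.samples if not sig.is_stereo else sig.samples.mean(axis=1)
        n = int(round(duration * rate))
        if x.shape[0] < n:
            x = np.pad(x, (0, n - x.shape[0]))
        return x[:n]
    raise SceneError(f"unknown source kind {spec.kind!r}")


def _spatialize(
    x: np.ndarray, azimuth: float, rate: float, itd_at_90: float, ild_at_90: float
) -> np.ndarray:
    """Apply azimuth-derived interaural delay and level difference.

    Returns an (n, 2) stereo array.  Positive azimuth (right side) delays
    and attenuates the left ear; negative azimuth mirrors this.
    """
    s = np.sin(np.deg2rad(azimuth))
    tau = itd_at_90 * s  # >0: source right, left ear lags
    if tau >= 0:
        left = fractional_delay(x, tau * rate)
        right = x.copy()
    else:
        left = x.copy()
        right = fractional_delay(x, -tau * rate)
    half_ild = ild_at_90 * s / 2.0
    left *= 10.0 ** (-half_ild / 20.0)
    right *= 10.0 ** (half_ild / 20.0)
    return np.column_stack([left, right])


def render_scene(
    scene: BinauralScene,
    duration: float = 3.0,
    rate: float = DEFAULT_RATE,
    seed: int = 0,
    lead_s: float = 0.05,
) -> AudioSignal:
    """Render a binaural scene to stereo audio, deterministic given seed.

    Each component is generated mono for ``duration`` seconds, scaled so
    that the source-to-interferer power ratio matches the requested SNR
    (measured on the mono signals before spatialization), then
    delayed/attenuated per its azimuth and mixed.  ``lead_s`` of silence is
    placed before and after the stimulus — as in a playback booth — so
    every component's onset and offset transients sit fully inside the
    buffer for both ears even after the interaural delay.  If the mix
    exceeds full scale both ears are scaled by the same factor, which
    leaves the interaural cues untouched.
    """
    if duration <= 0:
        raise SceneError("duration must be positive")
    lead = int(round(lead_s * rate))
    tail = lead + int(np.ceil(scene.itd_at_90 * rate)) + 81

    def padded(x: np.ndarray) -> np.ndarray:
        return np.pad(x, (lead, tail))

    source = _component_signal(scene.source, duration, rate, seed)
    mix = _spatialize(
        padded(source), scene.azimuth, rate, scene.itd_at_90, scene.ild_at_90
    )
    source_rms = _rms(source)
    for i, interferer in enumerate(scene.interferers):
        noise = _component_signal(
            SourceSpec(kind=interferer.kind), duration, rate, seed + 1000 * (i + 1)
        )
        noise = noise * (source_rms * 10.0 ** (-interferer.snr_db / 20.0) / _rms(noise))
        mix += _spatialize(
            padded(noise), interferer.azimuth, rate, scene.itd_at_90, scene.ild_at_90
        )
    peak = float(np.max(np.abs(mix)))
    if peak > 0.99:
        mix *= 0.99 / peak
    return AudioSignal(mix, rate)
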