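"""Audio input/output, frame streaming and electrodogram serialization.

The processing chain consumes audio in fixed 128-sample frames (8 ms at the
16 kHz platform rate).  This module reads and writes RIFF/WAV files, produces
the hop-advanced frame stream that drives one stimulation cycle per frame,
and serializes electrodograms as a columnar text format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger("bicisim")

#: Platform sampling rate in Hz.
DEFAULT_RATE = 16000.0
#: Analysis frame length in samples (8 ms at 16 kHz).
FRAME_LENGTH = 128

ELECTRODOGRAM_HEADER = "time_s,electrode,current_level"


class AudioInputError(ValueError):
    """Raised for unreadable, empty or malformed audio input."""


@dataclass
class AudioSignal:
    """A sampled pressure waveform.

    Parameters
    ----------
    samples
        Dimensionless amplitudes nominally in [-1, 1]; shape ``(n,)`` for
        mono or ``(n, 2)`` for stereo (column 0 = left, column 1 = right).
    rate
        Sampling frequency in Hz.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise AudioInputError(f"sampling rate must be positive, got {self.rate}")
        if self.samples.ndim not in (1, 2):
            raise AudioInputError("samples must be 1-D (mono) or 2-D (stereo)")
        if self.samples.ndim == 2 and self.samples.shape[1] != 2:
            raise AudioInputError("stereo signals must have exactly two channels")
        if not np.all(np.isfinite(self.samples)):
            raise AudioInputError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.n_samples / self.rate

    @property
    def is_stereo(self) -> bool:
        return self.samples.ndim == 2

    def channel(self, index: int) -> "AudioSignal":
        """Extract one ear's mono signal (0 = left, 1 = right)."""
        if not self.is_stereo:
            if index == 0:
                return AudioSignal(self.samples.copy(), self.rate)
            raise AudioInputError("mono signal has a single channel")
        return AudioSignal(self.samples[:, index].copy(), self.rate)


@dataclass(frozen=True)
class FrameSpec:
    """Analysis framing: ``length`` samples per frame advanced by ``hop``."""

    length: int = FRAME_LENGTH
    hop: int = FRAME_LENGTH
    rate: float = DEFAULT_RATE

    def __post_init__(self) -> None:
        if self.length < 1 or not (0 < self.hop <= self.length):
            raise AudioInputError(
                f"require 0 < hop <= length, got hop={self.hop} length={self.length}"
            )

    @property
    def duration(self) -> float:
        """Frame duration in seconds (8 ms at the defaults)."""
        return self.length / self.rate


def hop_for_rate(rate: float, pps: float) -> int:
    """Frame advance in samples for one analysis per stimulation cycle.

    The frame shift follows the chosen per-channel stimulation rate:
    ``hop = rate / pps`` rounded to the nearest integer sample, at least 1.
    """
    return max(1, int(round(rate / pps)))


def load_audio(path, target_rate: float = DEFAULT_RATE) -> AudioSignal:
    """Read a RIFF/WAV file, normalize to [-1, 1] and resample.

    Integer PCM is divided by its full-scale value; floating-point WAV is
    passed through unchanged.  Resampling uses a polyphase filter.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # wavfile raises assorted ValueError/OSError
        raise AudioInputError(f"could not read WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise AudioInputError(f"zero-length audio in {path!r}")
    if data.dtype.kind == "i":
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(np.float64) / scale
    elif data.dtype.kind == "u":  # 8-bit WAV is unsigned, midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2 and samples.shape[1] > 2:
        raise AudioInputError("more than two channels are not supported")
    if rate != target_rate:
        up, down = _resample_ratio(target_rate, rate)
        samples = resample_poly(samples, up, down, axis=0)
    return AudioSignal(samples, float(target_rate))


def _resample_ratio(target: float, source: float) -> tuple[int, int]:
    from math import gcd

    up, down = int(round(target)), int(round(source))
    g = gcd(up, down)
    return up // g, down // g


def save_audio(path, signal: AudioSignal) -> None:
    """Write an :class:`AudioSignal` as a 32-bit float WAV file."""
    wavfile.write(path, int(round(signal.rate)), signal.samples.astype(np.float32))


def frame_stream(signal: AudioSignal, spec: FrameSpec):
    """Yield hop-advanced frames of exactly ``spec.length`` samples.

    The final partial frame, if any, is zero-padded so the full stimulus
    duration is preserved (this matters for onset/offset timing cues).

    Raises
    ------
    AudioInputError
        If the signal is stereo (frame one ear at a time) or shorter than
        one frame.
    """
    if signal.is_stereo:
        raise AudioInputError("frame_stream expects a mono signal; use .channel()")
    x = signal.samples
    L, hop = spec.length, spec.hop
    if x.shape[0] < L:
        raise AudioInputError(
            f"signal of {x.shape[0]} samples is shorter than one frame ({L})"
        )
    n_full = (x.shape[0] - L) // hop + 1
    for i in range(n_full):
        yield x[i * hop : i * hop + L]
    # pad one extra frame only if samples remain uncovered by any frame
    if (n_full - 1) * hop + L < x.shape[0]:
        tail = np.zeros(L, dtype=x.dtype)
        remainder = x[n_full * hop :]
        tail[: remainder.shape[0]] = remainder
        yield tail


def n_frames(n_samples: int, spec: FrameSpec) -> int:
    """Number of frames :func:`frame_stream` yields for ``n_samples``."""
    if n_samples < spec.length:
        raise AudioInputError("signal shorter than one frame")
    n_full = (n_samples - spec.length) // spec.hop + 1
    uncovered = (n_full - 1) * spec.hop + spec.length < n_samples
    return n_full + (1 if uncovered else 0)


def fractional_delay(
    x: np.ndarray, delay_samples: float, taps: int = 81
) -> np.ndarray:
    """Delay a signal by a possibly fractional number of samples.

    The fractional part is realized with a Hann-windowed-sinc FIR
    interpolator (odd ``taps``); the integer part by zero-padded shifting.
    Output length equals input length (the shifted-out tail is dropped).
    """
    if delay_samples < 0:
        raise AudioInputError("negative delays are not supported; delay the other ear")
    x = np.asarray(x, dtype=np.float64)
    n_int = int(np.floor(delay_samples))
    frac = delay_samples - n_int
    if frac > 1e-9:
        half = (taps - 1) // 2
        m = np.arange(taps) - half
        h = np.sinc(m - frac) * np.hanning(taps)
        h /= h.sum()
        y = np.convolve(x, h)[half : half + x.shape[0]]
    else:
        y = x.copy()
    if n_int > 0:
        out = np.zeros_like(y)
        out[n_int:] = y[: y.shape[0] - n_int]
        return out
    return y


# ---------------------------------------------------------------------------
# Electrodogram serialization (columnar text, lossless round-trip)
# ---------------------------------------------------------------------------

def write_electrodogram(e, path) -> None:
    """Write an electrodogram as ``time_s,electrode,current_level`` rows.

    Rows are sorted by time, ties broken by ascending electrode.  Times are
    written in microsecond precision, which is exact because event times are
    multiples of the 1 MHz pulse-clock quantum.
    """
    order = np.lexsort((e.electrodes, e.times))
    with open(path, "w") as fh:
        fh.write(ELECTRODOGRAM_HEADER + "\n")
        fh.write(f"# duration_s={e.duration!r} pps={e.pps!r}\n")
        for i in order:
            fh.write(f"{e.times[i]:.6f},{e.electrodes[i]:d},{e.levels[i]:d}\n")


def read_electrodogram(path):
    """Read an electrodogram written by :func:`write_electrodogram`."""
    from .mapping import Electrodogram

    times, electrodes, levels = [], [], []
    duration = 0.0
    pps = 0.0
    with open(path) as fh:
        header = fh.readline().strip()
        if header != ELECTRODOGRAM_HEADER:
            raise AudioInputError(f"not an electrodogram file: {path!r}")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    key, _, value = token.partition("=")
                    if key == "duration_s":
                        duration = float(value)
                    elif key == "pps":
                        pps = float(value)
                continue
            t, el, lv = line.split(",")
            times.append(float(t))
            electrodes.append(int(el))
            levels.append(int(lv))
    return Electrodogram(
        times=np.asarray(times, dtype=np.float64),
        electrodes=np.asarray(electrodes, dtype=np.int64),
        levels=np.asarray(levels, dtype=np.int64),
        duration=duration,
        pps=pps,
    )
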