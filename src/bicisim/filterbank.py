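"""Spectral front end shared by all coding strategies.

Each 128-sample frame is Hann-windowed, transformed with a 128-point FFT,
and reduced to the magnitude-squared spectrum of the 64 positive-frequency
bins (125 Hz spacing at 16 kHz).  A bin-to-channel weight matrix a(n, k)
groups bins into N contiguous filter channels whose envelopes are

    Y(n) = sum_k a(n, k) X^2(k),      Z(n) = G(n) Y(n)

with per-channel gains G(n).  Envelopes are kept in the power domain; the
acoustic-to-electric normalization happens later in the strategy layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio_io import DEFAULT_RATE, FRAME_LENGTH

#: Default analysis band covered by the 22-channel table, in Hz.
DEFAULT_BAND = (188.0, 7938.0)
DEFAULT_N_CHANNELS = 22


class FilterbankError(ValueError):
    """Raised for dimension mismatches or invalid filterbank parameters."""


def hann_window(length: int) -> np.ndarray:
    """Hann window w(m) = 0.5 [1 - cos(2 pi m / (L - 1))], m = 0..L-1.

    Symmetric with zero endpoints.
    """
    if length < 2:
        raise FilterbankError(f"window length must be >= 2, got {length}")
    m = np.arange(length)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * m / (length - 1)))


@dataclass
class SpectralFrame:
    """Magnitude-squared spectrum of one frame, bins k = 1..L/2."""

    power: np.ndarray  # amplitude^2, length L/2
    bin_spacing: float  # Hz

    @property
    def n_bins(self) -> int:
        return self.power.shape[0]

    def bin_frequency(self, k: int) -> float:
        """Centre frequency of 1-based bin ``k`` in Hz."""
        return k * self.bin_spacing


def power_spectrum(frame: np.ndarray, rate: float = DEFAULT_RATE) -> SpectralFrame:
    """Magnitude-squared spectrum X^2(k) = X_R^2(k) + X_I^2(k), k = 1..L/2.

    The input frame is assumed already windowed.  The real-input FFT output
    is Hermitian symmetric, so only the positive-frequency bins 1..L/2 are
    kept (DC is dropped, the Nyquist bin is included).
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 1:
        raise FilterbankError("frame must be 1-D")
    L = frame.shape[0]
    if L % 2:
        raise FilterbankError(f"frame length must be even, got {L}")
    spectrum = np.fft.rfft(frame)  # bins 0..L/2
    power = (spectrum.real**2 + spectrum.imag**2)[1:]
    return SpectralFrame(power=power, bin_spacing=rate / L)


@dataclass
class ChannelWeights:
    """Bin-to-channel weight matrix a(n, k) with per-channel gains G(n).

    ``weights`` has one row per channel (ascending centre frequency) and one
    column per positive-frequency bin; column j corresponds to FFT bin j+1.
    ``edges`` holds the bin-index boundaries of the contiguous allocation:
    channel n (1-based) owns bins edges[n-1]..edges[n]-1.
    """

    weights: np.ndarray
    gains: np.ndarray
    bin_spacing: float
    edges: np.ndarray = field(default=None)  # len n_channels+1, 1-based bins

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.gains = np.asarray(self.gains, dtype=np.float64)
        if self.weights.ndim != 2:
            raise FilterbankError("weights must be a 2-D matrix")
        if self.gains.shape != (self.weights.shape[0],):
            raise FilterbankError("one gain per channel required")
        if np.any(self.weights < 0) or np.any(self.gains <= 0):
            raise FilterbankError("weights must be >= 0 and gains > 0")
        if np.any(self.weights.sum(axis=1) == 0):
            raise FilterbankError("every channel needs at least one nonzero bin")
        if np.any(self.weights.sum(axis=0) > 1 + 1e-12):
            raise FilterbankError("bin column sums must not exceed 1")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]

    @property
    def n_bins(self) -> int:
        return self.weights.shape[1]

    def band_edges(self) -> np.ndarray:
        """Channel frequency bands as an (N, 2) array of Hz boundaries.

        A bin's band extends half a bin spacing either side of its centre.
        """
        if self.edges is None:
            raise FilterbankError("no contiguous edge table available")
        lo = (self.edges[:-1] - 0.5) * self.bin_spacing
        hi = (self.edges[1:] - 0.5) * self.bin_spacing
        return np.column_stack([lo, hi])

    def channel_for_frequency(self, freq: float) -> int:
        """1-based channel whose band contains ``freq``; boundary ties go low.

        Frequencies outside the analysis band clamp to the edge channels.
        """
        bands = self.band_edges()
        uppers = bands[:, 1]
        idx = int(np.searchsorted(uppers, freq, side="left"))
        return min(idx, self.n_channels - 1) + 1


def channel_envelopes(spec: SpectralFrame, cw: ChannelWeights) -> np.ndarray:
    """Gain-scaled channel envelopes Z(n) = G(n) sum_k a(n, k) X^2(k)."""
    if cw.n_bins != spec.n_bins:
        raise FilterbankError(
            f"weight matrix has {cw.n_bins} bins, spectrum has {spec.n_bins}"
        )
    return cw.gains * (cw.weights @ spec.power)


def default_weights(
    n_channels: int = DEFAULT_N_CHANNELS,
    rate: float = DEFAULT_RATE,
    length: int = FRAME_LENGTH,
    band: tuple[float, float] = DEFAULT_BAND,
    gains: np.ndarray | None = None,
) -> ChannelWeights:
    """Contiguous, non-overlapping bin-to-channel allocation.

    Bins whose band overlaps ``band`` are partitioned into ``n_channels``
    contiguous groups whose widths follow a geometric progression in
    frequency, subject to at least one bin per channel — this yields the
    conventional CI layout of single-bin low-frequency channels widening
    towards the base.  Each allocated bin is weighted 1 in exactly one
    channel; unallocated bins (below the band) have all-zero columns.
    """
    n_bins = length // 2
    bin_spacing = rate / length
    if not (1 <= n_channels <= n_bins):
        raise FilterbankError(
            f"n_channels must be in [1, {n_bins}], got {n_channels}"
        )
    k_lo = max(1, int(round(band[0] / bin_spacing)))
    k_hi = min(n_bins, int(round(band[1] / bin_spacing)))
    if k_hi - k_lo + 1 < n_channels:
        raise FilterbankError("band holds fewer bins than channels")
    edges = _geometric_edges(k_lo, k_hi, n_channels)
    weights = np.zeros((n_channels, n_bins))
    for n in range(n_channels):
        weights[n, edges[n] - 1 : edges[n + 1] - 1] = 1.0
    if gains is None:
        gains = np.ones(n_channels)
    return ChannelWeights(
        weights=weights, gains=gains, bin_spacing=bin_spacing, edges=edges
    )


def _geometric_edges(k_lo: int, k_hi: int, n_channels: int) -> np.ndarray:
    """Integer channel boundaries in bin space, geometric with min width 1.

    Returns ``edges`` of length n_channels+1 with edges[0]=k_lo and
    edges[-1]=k_hi+1, strictly increasing.
    """
    ideal = k_lo * (float(k_hi + 1) / k_lo) ** (
        np.arange(n_channels + 1) / n_channels
    )
    edges = np.empty(n_channels + 1, dtype=np.int64)
    edges[0] = k_lo
    for i in range(1, n_channels + 1):
        edges[i] = max(int(round(ideal[i])), edges[i - 1] + 1)
    edges[-1] = k_hi + 1
    # backward pass: leave room for one bin per remaining channel
    for i in range(n_channels - 1, 0, -1):
        edges[i] = min(edges[i], edges[i + 1] - 1)
    if edges[0] != k_lo or np.any(np.diff(edges) < 1):
        raise FilterbankError("could not build a valid channel allocation")
    return edges
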