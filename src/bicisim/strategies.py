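"""Channel selection and compression: CIS, ACE and FACE.

CIS stimulates every active channel each cycle.  ACE applies the N-of-M
principle: only the ``n_maxima`` spectrally strongest of the M active
channels fire per cycle.  FACE extends ACE by reserving up to three channels
for the formant frequencies F1-F3 estimated with a 28th-order LPC model and
stabilized by a cycle-to-cycle continuity check; the remaining slots fall
back to the ACE maxima rule.

All strategies share the loudness-growth function

    c(x) = log(1 + b x) / log(1 + b),      b = 415.995

applied to envelopes normalized into [0, 1] by a fixed acoustic saturation
level, with a base level below which a channel emits no stimulation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_toeplitz

from .audio_io import DEFAULT_RATE
from .filterbank import ChannelWeights

logger = logging.getLogger("bicisim")

#: Loudness-growth compression constant (from clinical processor parameters).
DEFAULT_B = 415.995
#: Envelope power of a full-scale sinusoid at a channel centre: (L/4)^2.
DEFAULT_SATURATION = 1024.0
#: Acoustic input dynamic range below saturation, dB (power domain).
DEFAULT_DYNAMIC_RANGE_DB = 40.0
#: LPC model order for formant estimation.
DEFAULT_LPC_ORDER = 28

STRATEGIES = ("CIS", "ACE", "FACE")


class StrategyError(ValueError):
    """Raised for invalid strategy configurations or inputs."""


@dataclass
class StrategyConfig:
    """Configuration of one ear's coding strategy.

    Parameters
    ----------
    strategy
        One of ``CIS``, ``ACE``, ``FACE``.
    pps
        Per-channel stimulation rate in pulses per second.  The default of
        500 pps keeps 22 active channels under the 14400 Hz aggregate cap.
    n_maxima
        Channels selected per cycle for ACE/FACE (the "N" of N-of-M).
    b
        Compression constant of the loudness-growth function.
    active_channels
        1-based subset of the 22 analysis channels available for selection.
    env_saturation, dynamic_range_db
        Acoustic normalization: envelope power at which compression
        saturates, and the range below it (in dB) mapped to (0, 1]; quieter
        envelopes produce no stimulation.
    compress_cis
        Whether CIS applies the loudness-growth function (on by default so
        loudness growth is uniform across strategies).
    """

    strategy: str = "ACE"
    pps: float = 500.0
    n_maxima: int = 8
    b: float = DEFAULT_B
    active_channels: tuple[int, ...] = tuple(range(1, 23))
    env_saturation: float = DEFAULT_SATURATION
    dynamic_range_db: float = DEFAULT_DYNAMIC_RANGE_DB
    compress_cis: bool = True
    lpc_order: int = DEFAULT_LPC_ORDER
    formant_bw_ceiling: float = 200.0  # Hz, continuity acceptance window
    formant_max_bandwidth: float = 400.0  # Hz, LPC candidate rejection

    def __post_init__(self) -> None:
        self.strategy = self.strategy.upper()
        if self.strategy not in STRATEGIES:
            raise StrategyError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}"
            )
        self.active_channels = tuple(sorted(set(int(c) for c in self.active_channels)))
        if not self.active_channels:
            raise StrategyError("at least one active channel is required")
        if any(c < 1 or c > 22 for c in self.active_channels):
            raise StrategyError("active channels must lie in 1..22")
        if self.b <= 0:
            raise StrategyError(f"compression constant b must be > 0, got {self.b}")
        if not (1 <= self.n_maxima <= len(self.active_channels)):
            raise StrategyError(
                f"n_maxima={self.n_maxima} must be in [1, {len(self.active_channels)}]"
            )
        if not (150.0 <= self.formant_bw_ceiling <= 200.0):
            logger.warning(
                "formant continuity bandwidth %.0f Hz outside the usual 150-200 Hz",
                self.formant_bw_ceiling,
            )


@dataclass
class ChannelSelection:
    """Channels chosen for one stimulation cycle, base-to-apex order.

    ``channels`` are 1-based analysis-channel indices (ascending centre
    frequency); they are listed from base to apex, i.e. descending index.
    ``magnitudes`` are the matching compressed values in [0, 1].
    ``formant_channels`` records which entries FACE reserved for formants.
    """

    channels: np.ndarray
    magnitudes: np.ndarray
    formant_channels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.int64)
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        if self.channels.shape != self.magnitudes.shape:
            raise StrategyError("channels and magnitudes must align")
        if len(set(self.channels.tolist())) != self.channels.shape[0]:
            raise StrategyError("duplicate channels in selection")
        if np.any(self.magnitudes < 0) or np.any(self.magnitudes > 1):
            raise StrategyError("magnitudes must lie in [0, 1]")


@dataclass(frozen=True)
class FormantState:
    """Accepted formants F1-F3 (Hz) from the previous stimulation cycle."""

    formants: tuple = (None, None, None)

    @property
    def is_empty(self) -> bool:
        return all(f is None for f in self.formants)


def compress(x, b: float = DEFAULT_B):
    """Loudness-growth function log(1 + b x) / log(1 + b) on [0, 1].

    Strictly monotone, fixing 0 -> 0 and 1 -> 1.  Inputs outside [0, 1] are
    clipped with a warning.
    """
    if b <= 0:
        raise StrategyError(f"compression constant b must be > 0, got {b}")
    arr = np.asarray(x, dtype=np.float64)
    if np.any(arr < 0) or np.any(arr > 1):
        warnings.warn("compress input outside [0, 1]; clipping", stacklevel=2)
        arr = np.clip(arr, 0.0, 1.0)
    out = np.log1p(b * arr) / np.log1p(b)
    return float(out) if np.isscalar(x) else out


def normalize_envelope(z: np.ndarray, cfg: StrategyConfig) -> np.ndarray:
    """Map power-domain envelopes into the [0, 1] compression input range.

    Envelopes are divided by the saturation level and clipped at 1; values
    below the base level (``dynamic_range_db`` below saturation) map to
    exactly 0, coding "no stimulation".
    """
    x = np.asarray(z, dtype=np.float64) / cfg.env_saturation
    floor = 10.0 ** (-cfg.dynamic_range_db / 10.0)
    x = np.clip(x, 0.0, 1.0)
    x[x < floor] = 0.0
    return x


def _magnitudes(z: np.ndarray, cfg: StrategyConfig, apply_compression: bool) -> np.ndarray:
    x = normalize_envelope(z, cfg)
    if not apply_compression:
        return x
    mag = compress(x, cfg.b)
    mag[x == 0.0] = 0.0  # base level stays "no stimulation" after compression
    return mag


def _base_to_apex(channels: np.ndarray, magnitudes: np.ndarray):
    order = np.argsort(-channels, kind="stable")
    return channels[order], magnitudes[order]


def cis_select(z: np.ndarray, cfg: StrategyConfig) -> ChannelSelection:
    """CIS: every active channel fires each cycle."""
    if cfg.strategy != "CIS":
        raise StrategyError(f"cis_select called with strategy {cfg.strategy}")
    z = np.asarray(z, dtype=np.float64)
    channels = np.asarray(cfg.active_channels, dtype=np.int64)
    mags = _magnitudes(z[channels - 1], cfg, cfg.compress_cis)
    channels, mags = _base_to_apex(channels, mags)
    return ChannelSelection(channels=channels, magnitudes=mags)


def ace_select(z: np.ndarray, cfg: StrategyConfig) -> ChannelSelection:
    """ACE: the ``n_maxima`` largest-envelope active channels fire.

    Ties break toward the lower channel index.  If fewer than ``n_maxima``
    channels are nonzero, zero-magnitude channels are still selected (they
    emit no pulse downstream) and a diagnostic is logged.
    """
    if cfg.strategy not in ("ACE", "FACE"):
        raise StrategyError(f"ace_select called with strategy {cfg.strategy}")
    z = np.asarray(z, dtype=np.float64)
    channels = np.asarray(cfg.active_channels, dtype=np.int64)
    zc = z[channels - 1]
    # primary key: descending envelope; secondary: ascending channel index
    order = np.lexsort((channels, -zc))
    top = order[: cfg.n_maxima]
    if np.count_nonzero(zc) < cfg.n_maxima:
        logger.debug(
            "ACE selected %d channels but only %d are nonzero",
            cfg.n_maxima,
            int(np.count_nonzero(zc)),
        )
    sel_channels = channels[top]
    mags = _magnitudes(zc[top], cfg, apply_compression=True)
    sel_channels, mags = _base_to_apex(sel_channels, mags)
    return ChannelSelection(channels=sel_channels, magnitudes=mags)


# ---------------------------------------------------------------------------
# Formant track (FACE)
# ---------------------------------------------------------------------------

def estimate_formants(
    frame: np.ndarray,
    rate: float = DEFAULT_RATE,
    order: int = DEFAULT_LPC_ORDER,
    max_bandwidth: float = 400.0,
) -> list:
    """LPC formant candidates from a windowed time-domain frame.

    Autocorrelation-method LPC of the given order; candidates are the
    complex pole angles converted to Hz with bandwidths derived from pole
    radii, sorted ascending.  Only poles between 90 Hz and Nyquist - 90 Hz
    with bandwidth below ``max_bandwidth`` are returned.

    Returns a list of ``(frequency_hz, bandwidth_hz)`` pairs; empty for an
    all-zero frame.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if order >= frame.shape[0]:
        raise StrategyError(f"LPC order {order} >= frame length {frame.shape[0]}")
    if not np.any(frame):
        return []
    r = np.correlate(frame, frame, mode="full")[frame.shape[0] - 1 :][: order + 1]
    r = r.copy()
    r[0] *= 1.0 + 1e-6  # white-noise ridge keeps the Toeplitz solve stable
    try:
        a = solve_toeplitz((r[:-1], r[:-1]), -r[1:])
    except np.linalg.LinAlgError:
        return []
    poly = np.concatenate([[1.0], a])
    roots = np.roots(poly)
    roots = roots[roots.imag > 0]
    freqs = np.angle(roots) * rate / (2.0 * np.pi)
    radii = np.abs(roots)
    with np.errstate(divide="ignore"):
        bandwidths = -np.log(np.clip(radii, 1e-12, None)) * rate / np.pi
    keep = (
        (freqs > 90.0)
        & (freqs < rate / 2.0 - 90.0)
        & (bandwidths > 0.0)
        & (bandwidths < max_bandwidth)
    )
    candidates = sorted(zip(freqs[keep], bandwidths[keep]))
    return _merge_candidates([(float(f), float(bw)) for f, bw in candidates])


def _merge_candidates(candidates: list, gap: float = 175.0) -> list:
    """Fuse pole clusters belonging to one resonance.

    On voiced frames the LPC poles lock onto individual harmonics, so a
    single formant appears as a pair of candidates straddling it one
    harmonic apart.  Candidates closer than ``gap`` Hz are replaced by
    their inverse-bandwidth-weighted mean frequency with the narrowest
    bandwidth of the cluster.
    """
    merged: list = []
    cluster: list = []
    for f, bw in candidates:
        if cluster and f - cluster[-1][0] > gap:
            merged.append(_fuse(cluster))
            cluster = []
        cluster.append((f, bw))
    if cluster:
        merged.append(_fuse(cluster))
    return merged


def _fuse(cluster: list) -> tuple:
    weights = [1.0 / max(bw, 1.0) for _, bw in cluster]
    freq = sum(w * f for w, (f, _) in zip(weights, cluster)) / sum(weights)
    return (freq, min(bw for _, bw in cluster))


def continuity_filter(
    candidates: list,
    prev: FormantState,
    bw_ceiling: float = 200.0,
) -> FormantState:
    """Cycle-to-cycle formant continuity check.

    Candidates with bandwidth above ``bw_ceiling`` are rejected.  On a cold
    start (no previous formants) the three lowest surviving candidates are
    accepted outright.  Otherwise each previous formant accepts the nearest
    candidate within ``bw_ceiling`` Hz of it; with no candidate in the
    window the previous value is carried forward one cycle, keeping the
    vowel track fluid.
    """
    pool = [(f, bw) for f, bw in candidates if bw <= bw_ceiling]
    if prev.is_empty:
        # cold start: keep the three sharpest resonances, lowest first
        by_bw = sorted(pool, key=lambda c: c[1])[:3]
        accepted = sorted(f for f, _ in by_bw)
        accepted += [None] * (3 - len(accepted))
        return FormantState(formants=tuple(accepted))
    new = []
    for f_prev in prev.formants:
        if f_prev is None:
            new.append(None)
            continue
        in_window = [(abs(f - f_prev), i) for i, (f, _) in enumerate(pool) if abs(f - f_prev) <= bw_ceiling]
        if in_window:
            _, best = min(in_window)
            new.append(pool.pop(best)[0])
        else:
            new.append(f_prev)
    # fill formant slots never initialized (partial cold start)
    for i, f in enumerate(new):
        if f is None and pool:
            new[i] = pool.pop(0)[0]
    return FormantState(formants=tuple(new))


def face_select(
    frame: np.ndarray,
    z: np.ndarray,
    prev: FormantState,
    cfg: StrategyConfig,
    cw: ChannelWeights,
) -> tuple[ChannelSelection, FormantState]:
    """FACE: formant channels first, then ACE maxima for the rest.

    The windowed time frame feeds the LPC formant estimator; accepted
    formants F1-F3 map to channels through the filterbank band edges
    (boundary ties go to the lower channel) and those channels are selected
    first.  The remaining ``n_maxima - 3`` slots (fewer if formant channels
    coincide) are filled by the ACE maxima rule over the unselected active
    channels.  Missing formant slots fall back to maxima selection.
    """
    if cfg.strategy != "FACE":
        raise StrategyError(f"face_select called with strategy {cfg.strategy}")
    z = np.asarray(z, dtype=np.float64)
    candidates = estimate_formants(
        frame, rate=cw.bin_spacing * 2 * cw.n_bins, order=cfg.lpc_order,
        max_bandwidth=cfg.formant_max_bandwidth,
    )
    state = continuity_filter(candidates, prev, cfg.formant_bw_ceiling)
    active = set(cfg.active_channels)
    formant_channels: list[int] = []
    for f in state.formants:
        if f is None:
            continue
        ch = cw.channel_for_frequency(f)
        if ch in active and ch not in formant_channels:
            formant_channels.append(ch)
    if len(formant_channels) < 3:
        logger.debug(
            "FACE found %d formant channels; remaining slots fall back to maxima",
            len(formant_channels),
        )
    formant_channels = formant_channels[: cfg.n_maxima]
    n_rest = cfg.n_maxima - len(formant_channels)
    rest_channels = np.asarray(
        sorted(active - set(formant_channels)), dtype=np.int64
    )
    if n_rest > 0 and rest_channels.size:
        zc = z[rest_channels - 1]
        order = np.lexsort((rest_channels, -zc))
        maxima = rest_channels[order[:n_rest]]
    else:
        maxima = np.empty(0, dtype=np.int64)
    channels = np.concatenate([np.asarray(formant_channels, dtype=np.int64), maxima])
    mags = _magnitudes(z[channels - 1], cfg, apply_compression=True)
    channels, mags = _base_to_apex(channels, mags)
    selection = ChannelSelection(
        channels=channels,
        magnitudes=mags,
        formant_channels=tuple(formant_channels),
    )
    return selection, state
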