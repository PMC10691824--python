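"""Bilateral processing and the output-buffer synchronization contract.

Each ear runs its own full coding chain (possibly different strategies).
The two output buffers are released against a common clock: a block is
streamed only when BOTH ears have produced it, so the faster-processed ear
is stalled by the processing-time mismatch dT = |T1 - T2|.  Stalling never
touches the stimulation timeline itself — an external interaural offset
(from direction of arrival) therefore passes through unchanged, while the
internal mismatch is absorbed entirely by the release schedule.

Processing latency here is a configurable model, not a measurement: it
exists to exercise the stall logic, and may be set anywhere from zero to
many seconds (offline-scale strategies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio_io import (
    AudioInputError,
    AudioSignal,
    FrameSpec,
    FRAME_LENGTH,
    fractional_delay,
    frame_stream,
    hop_for_rate,
)
from .filterbank import (
    ChannelWeights,
    channel_envelopes,
    default_weights,
    hann_window,
    power_spectrum,
)
from .mapping import Electrodogram, MapParameters, schedule_pulses, validate_config
from .strategies import (
    ChannelSelection,
    FormantState,
    StrategyConfig,
    ace_select,
    cis_select,
    face_select,
)

logger = logging.getLogger("bicisim")

#: Output-buffer block size in seconds (8 ms of pulses per release).
BLOCK_S = 0.008


@dataclass(frozen=True)
class LatencyModel:
    """Per-ear processing delays T1 (left) and T2 (right), in seconds.

    ``jitter`` adds a non-negative random perturbation (standard deviation
    in seconds) to each block's completion time, drawn from the run seed.
    """

    left_delay: float = 0.0
    right_delay: float = 0.0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.left_delay < 0 or self.right_delay < 0 or self.jitter < 0:
            raise ValueError("latency delays and jitter must be >= 0")

    @property
    def mismatch(self) -> float:
        """The internal processing mismatch dT = T1 - T2, seconds."""
        return self.left_delay - self.right_delay


@dataclass
class SyncedOutput:
    """Synchronized bilateral output.

    ``release_times`` is the common per-block release schedule (seconds);
    both ears stream each 8 ms block at the same instant, so the slower
    ear's block count equals the faster ear's at every release.
    """

    left: Electrodogram
    right: Electrodogram
    release_times: np.ndarray
    release_time: float

    @property
    def n_blocks(self) -> int:
        return self.release_times.shape[0]

    @property
    def throughput(self) -> float:
        """Mean block release delay relative to block arrival, seconds."""
        arrivals = (np.arange(self.n_blocks) + 1) * BLOCK_S
        return float(np.mean(self.release_times - arrivals))


def process_ear(
    audio: AudioSignal,
    cfg: StrategyConfig,
    map_params: MapParameters | None = None,
    cw: ChannelWeights | None = None,
) -> Electrodogram:
    """Run one ear's complete chain: frames -> spectrum -> selection -> pulses."""
    if audio.is_stereo:
        raise AudioInputError("process_ear expects a mono signal")
    if map_params is None:
        map_params = MapParameters.default()
    if cw is None:
        cw = default_weights(rate=audio.rate)
    validate_config(cfg, map_params)
    spec = FrameSpec(
        length=FRAME_LENGTH, hop=hop_for_rate(audio.rate, cfg.pps), rate=audio.rate
    )
    window = hann_window(spec.length)
    state = FormantState()
    selections: list[ChannelSelection] = []
    for frame in frame_stream(audio, spec):
        wf = frame * window
        z = channel_envelopes(power_spectrum(wf, audio.rate), cw)
        if cfg.strategy == "CIS":
            selections.append(cis_select(z, cfg))
        elif cfg.strategy == "ACE":
            selections.append(ace_select(z, cfg))
        else:
            selection, state = face_select(wf, z, state, cfg, cw)
            selections.append(selection)
    return schedule_pulses(selections, cfg, map_params, duration=audio.duration)


def process_bilateral(
    left_audio: AudioSignal,
    right_audio: AudioSignal,
    left_cfg: StrategyConfig,
    right_cfg: StrategyConfig,
    lat: LatencyModel = LatencyModel(),
    left_map: MapParameters | None = None,
    right_map: MapParameters | None = None,
    seed: int | None = None,
) -> SyncedOutput:
    """Process both ears independently and synchronize their outputs.

    Block i of each ear completes at its arrival time plus that ear's
    modelled delay (plus jitter); the block is released at the later of the
    two completion times, never earlier than the previous release.  The
    stimulation timelines inside the electrodograms are untouched, so any
    interaural offset present at the input appears unchanged at the output.
    """
    if left_audio.n_samples != right_audio.n_samples:
        raise AudioInputError("left and right audio must have equal length")
    if left_audio.rate != right_audio.rate:
        raise AudioInputError("left and right audio must share a sampling rate")
    left = process_ear(left_audio, left_cfg, left_map)
    right = process_ear(right_audio, right_cfg, right_map)
    n_blocks = max(1, int(np.ceil(left_audio.duration / BLOCK_S)))
    arrivals = (np.arange(n_blocks) + 1) * BLOCK_S
    rng = np.random.default_rng(seed)
    jit_l = np.abs(rng.standard_normal(n_blocks)) * lat.jitter
    jit_r = np.abs(rng.standard_normal(n_blocks)) * lat.jitter
    done_left = arrivals + lat.left_delay + jit_l
    done_right = arrivals + lat.right_delay + jit_r
    release = np.maximum.accumulate(np.maximum(done_left, done_right))
    return SyncedOutput(
        left=left,
        right=right,
        release_times=release,
        release_time=float(release[-1]),
    )


def inject_offset(
    audio: AudioSignal, offset_s: float, lead_s: float = 0.05
) -> AudioSignal:
    """Build a stereo signal whose right ear lags the left by ``offset_s``.

    The delay is applied with a windowed-sinc fractional-delay filter so
    offsets need not be integer multiples of the sample period.  A positive
    offset means the left ear leads (source on the left).

    Both ears are padded with ``lead_s`` of leading silence and enough
    trailing silence to hold the delayed copy, so the onset and offset
    transients — which carry the timing cue through the envelope coding —
    are fully inside the buffer for both ears.
    """
    if audio.is_stereo:
        raise AudioInputError("inject_offset expects a mono signal")
    lead = int(round(lead_s * audio.rate))
    tail = int(np.ceil(offset_s * audio.rate)) + 81 + lead
    x = np.pad(audio.samples, (lead, tail))
    delayed = fractional_delay(x, offset_s * audio.rate)
    return AudioSignal(np.column_stack([x, delayed]), audio.rate)


def offset_sweep(
    audio: AudioSignal,
    cfg: StrategyConfig,
    offsets,
    lat: LatencyModel = LatencyModel(),
    right_cfg: StrategyConfig | None = None,
    map_params: MapParameters | None = None,
    electrode: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Measure offset preservation across a list of injected delays.

    For each offset (seconds, within [0, 25 ms]) the mono input is delayed
    into the right ear, processed bilaterally, and the interaural delay
    recovered from the synchronized electrodograms by cross-correlation.
    Returns a table of input vs output offsets, errors and throughput.
    """
    from .analysis import best_common_electrode, estimate_itd

    if right_cfg is None:
        right_cfg = cfg
    rows = []
    max_lag = max(max((float(o) for o in offsets), default=0.0) + 0.005, 0.002)
    for offset in offsets:
        offset = float(offset)
        if not 0.0 <= offset <= 0.025:
            raise AudioInputError(f"offset {offset} s outside [0, 25 ms]")
        stereo = inject_offset(audio, offset)
        sync = process_bilateral(
            stereo.channel(0), stereo.channel(1), cfg, right_cfg,
            lat=lat, left_map=map_params, right_map=map_params, seed=seed,
        )
        probe = electrode if electrode is not None else best_common_electrode(
            sync.left, sync.right
        )
        cue = estimate_itd(
            sync.left, sync.right, electrode=probe, max_lag=max_lag,
            left_map=map_params, right_map=map_params,
        )
        rows.append(
            {
                "input_offset_s": offset,
                "output_offset_s": cue.itd,
                "error_s": cue.itd - offset,
                "electrode": probe,
                "confidence": cue.confidence,
                "throughput_s": sync.throughput,
            }
        )
    columns = [
        "input_offset_s", "output_offset_s", "error_s",
        "electrode", "confidence", "throughput_s",
    ]
    return pd.DataFrame(rows, columns=columns)
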