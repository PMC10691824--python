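"""Electric mapping and interleaved biphasic-pulse scheduling.

Compressed channel magnitudes become clinical current levels through the
recipient's MAP — per-electrode threshold (T) and maximum-comfort (C)
levels: level = round(T + (C - T) * magnitude).  Within each stimulation
cycle of 1/pps seconds the selected electrodes fire sequentially from base
to apex, each biphasic pulse occupying 2 * pulse_width + interphase_gap
microseconds, so no two pulses ever overlap in time.

Rate safety: the aggregate stimulation rate pps * |active channels| may not
exceed 14400 Hz; with all 22 electrodes active the per-channel rate is
capped at 650 Hz (14400/22 rounded down), with rates above 600 Hz flagged.
The minimum per-channel rate is 125 pps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import yaml

from .strategies import ChannelSelection, StrategyConfig

logger = logging.getLogger("bicisim")

N_ELECTRODES = 22
#: Aggregate stimulation-rate ceiling across all active channels, Hz.
AGGREGATE_RATE_CAP = 14400.0
#: Per-channel cap with all 22 electrodes active (14400/22, rounded down).
PER_CHANNEL_CAP_22 = 650.0
#: Recommended per-channel ceiling; above it a warning is emitted.
PREFERRED_MAX_PPS = 600.0
#: Minimum per-channel stimulation rate (safety floor), pulses/s.
MIN_PPS = 125.0
#: Pulse-clock resolution: event times are integer microseconds.
PULSE_CLOCK_HZ = 1_000_000


class ConfigurationError(ValueError):
    """Raised when a strategy/MAP configuration violates platform limits."""


def electrode_for_channel(channel: int) -> int:
    """Map analysis channel (1 = lowest frequency) to electrode number.

    Electrode 1 is the most basal (high-frequency) contact and electrode 22
    the most apical, so channel n drives electrode 23 - n.
    """
    if not 1 <= channel <= N_ELECTRODES:
        raise ConfigurationError(f"channel {channel} outside 1..{N_ELECTRODES}")
    return N_ELECTRODES + 1 - channel


@dataclass
class MapParameters:
    """A recipient's clinical MAP: per-electrode T/C levels and pulse timing.

    Levels are clinical current units (integers 0-255) indexed by electrode
    1..22.  ``pulse_width_us`` is per phase; the full biphasic slot is
    2 * pulse_width + interphase_gap microseconds.
    """

    thresholds: np.ndarray
    comforts: np.ndarray
    pulse_width_us: float = 25.0
    interphase_gap_us: float = 8.0

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=np.int64)
        self.comforts = np.asarray(self.comforts, dtype=np.int64)
        if self.thresholds.shape != (N_ELECTRODES,) or self.comforts.shape != (
            N_ELECTRODES,
        ):
            raise ConfigurationError(
                f"T and C must each list {N_ELECTRODES} electrode levels"
            )
        for name, arr in (("T", self.thresholds), ("C", self.comforts)):
            if np.any(arr < 0) or np.any(arr > 255):
                raise ConfigurationError(f"{name} levels must lie in 0..255")
        if np.any(self.thresholds >= self.comforts):
            raise ConfigurationError("every threshold must be below its comfort level")
        if self.pulse_width_us <= 0 or self.interphase_gap_us < 0:
            raise ConfigurationError("pulse timing must be positive")

    @property
    def slot_us(self) -> float:
        """Duration one biphasic pulse occupies, microseconds."""
        return 2.0 * self.pulse_width_us + self.interphase_gap_us

    @classmethod
    def default(cls, threshold: int = 100, comfort: int = 200) -> "MapParameters":
        """Flat MAP with the same T/C on every electrode."""
        return cls(
            thresholds=np.full(N_ELECTRODES, threshold),
            comforts=np.full(N_ELECTRODES, comfort),
        )

    @classmethod
    def from_yaml(cls, path) -> "MapParameters":
        """Load a MAP file: per-electrode T/C table plus pulse timing.

        Expected layout::

            pulse_width_us: 25.0
            interphase_gap_us: 8.0
            electrodes:
              - {electrode: 1, t: 100, c: 200}
              ...
        """
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        thresholds = np.zeros(N_ELECTRODES, dtype=np.int64)
        comforts = np.full(N_ELECTRODES, 255, dtype=np.int64)
        seen = set()
        for row in doc.get("electrodes", []):
            e = int(row["electrode"])
            if not 1 <= e <= N_ELECTRODES:
                raise ConfigurationError(f"electrode {e} outside 1..{N_ELECTRODES}")
            thresholds[e - 1] = int(row["t"])
            comforts[e - 1] = int(row["c"])
            seen.add(e)
        if len(seen) != N_ELECTRODES:
            raise ConfigurationError(
                f"MAP file must list all {N_ELECTRODES} electrodes, got {len(seen)}"
            )
        return cls(
            thresholds=thresholds,
            comforts=comforts,
            pulse_width_us=float(doc.get("pulse_width_us", 25.0)),
            interphase_gap_us=float(doc.get("interphase_gap_us", 8.0)),
        )

    def to_yaml(self, path) -> None:
        doc = {
            "pulse_width_us": float(self.pulse_width_us),
            "interphase_gap_us": float(self.interphase_gap_us),
            "electrodes": [
                {"electrode": e + 1, "t": int(t), "c": int(c)}
                for e, (t, c) in enumerate(zip(self.thresholds, self.comforts))
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class Electrodogram:
    """Time-stamped stimulation events: (time s, electrode 1-22, level).

    Events are time-sorted; times are multiples of the 1 us pulse clock.
    """

    times: np.ndarray
    electrodes: np.ndarray
    levels: np.ndarray
    duration: float
    pps: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.electrodes = np.asarray(self.electrodes, dtype=np.int64)
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if not (self.times.shape == self.electrodes.shape == self.levels.shape):
            raise ConfigurationError("event arrays must align")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ConfigurationError("events must be time-sorted")

    @property
    def n_events(self) -> int:
        return self.times.shape[0]

    def on_electrode(self, electrode: int) -> tuple[np.ndarray, np.ndarray]:
        """(times, levels) of the events on one electrode."""
        mask = self.electrodes == electrode
        return self.times[mask], self.levels[mask]

    def scaled_levels(self, factor: float) -> "Electrodogram":
        """Copy with all levels scaled (used for injected-ILD analyses)."""
        return Electrodogram(
            times=self.times.copy(),
            electrodes=self.electrodes.copy(),
            levels=np.round(self.levels * factor).astype(np.int64),
            duration=self.duration,
            pps=self.pps,
        )


def validate_config(cfg: StrategyConfig, map_params: MapParameters) -> StrategyConfig:
    """Enforce the platform's stimulation-rate and cycle-packing limits.

    Raises :class:`ConfigurationError` when the aggregate rate
    pps * |active| exceeds 14400 Hz (the message names both the aggregate
    cap and, with 22 active channels, the 650 Hz per-channel cap), when pps
    is below the 125 pps safety floor, or when a cycle cannot hold one
    biphasic slot per active channel.  Rates above 600 pps warn.
    """
    n_active = len(cfg.active_channels)
    if cfg.pps < MIN_PPS:
        raise ConfigurationError(
            f"stimulation rate {cfg.pps:g} pps is below the minimum possible "
            f"rate of {MIN_PPS:g} pps (safety floor)"
        )
    aggregate = cfg.pps * n_active
    per_channel_cap = (
        PER_CHANNEL_CAP_22 if n_active == N_ELECTRODES else AGGREGATE_RATE_CAP / n_active
    )
    if aggregate > AGGREGATE_RATE_CAP or cfg.pps > per_channel_cap:
        raise ConfigurationError(
            f"{cfg.pps:g} pps on {n_active} channels gives an aggregate rate of "
            f"{aggregate:g} Hz; the platform caps the aggregate at "
            f"{AGGREGATE_RATE_CAP:g} Hz ({per_channel_cap:g} Hz per channel "
            f"with {n_active} active)"
        )
    if cfg.pps > PREFERRED_MAX_PPS:
        warnings.warn(
            f"{cfg.pps:g} pps exceeds the preferred {PREFERRED_MAX_PPS:g} pps "
            "ceiling; transfer-rate headroom is reduced",
            stacklevel=2,
        )
    cycle_us = 1e6 / cfg.pps
    if n_active * map_params.slot_us > cycle_us:
        raise ConfigurationError(
            f"{n_active} channels x {map_params.slot_us:g} us pulse slots do "
            f"not fit in the {cycle_us:g} us cycle at {cfg.pps:g} pps"
        )
    return cfg


def map_to_current(
    selection: ChannelSelection, map_params: MapParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Scale compressed magnitudes into each electrode's [T, C] range.

    Returns ``(electrodes, levels)`` in the selection's order.  A magnitude
    of exactly 0 emits no event (the channel is silent this cycle).
    """
    electrodes, levels = [], []
    for ch, mag in zip(selection.channels, selection.magnitudes):
        if mag <= 0.0:
            continue
        e = electrode_for_channel(int(ch))
        t = map_params.thresholds[e - 1]
        c = map_params.comforts[e - 1]
        levels.append(int(round(t + (c - t) * mag)))
        electrodes.append(e)
    return np.asarray(electrodes, dtype=np.int64), np.asarray(levels, dtype=np.int64)


def schedule_pulses(
    selections,
    cfg: StrategyConfig,
    map_params: MapParameters,
    duration: float | None = None,
) -> Electrodogram:
    """Interleave the per-cycle selections into a biphasic pulse schedule.

    Cycle c starts at c / pps seconds.  Within a cycle the selected
    electrodes fire sequentially base-to-apex (ascending electrode number),
    each occupying one slot of 2 * pulse_width + interphase_gap us, so no
    two events overlap.  Event times are quantized to the 1 us pulse clock.
    """
    validate_config(cfg, map_params)
    period_us = 1e6 / cfg.pps
    slot_us = map_params.slot_us
    times, electrodes, levels = [], [], []
    n_cycles = 0
    for c, selection in enumerate(selections):
        n_cycles += 1
        elecs, levs = map_to_current(selection, map_params)
        if elecs.size == 0:
            continue
        order = np.argsort(elecs, kind="stable")  # base (1) to apex (22)
        t0 = round(c * period_us)
        for j, idx in enumerate(order):
            times.append(round(t0 + j * slot_us) / 1e6)
            electrodes.append(int(elecs[idx]))
            levels.append(int(levs[idx]))
    if duration is None:
        duration = n_cycles / cfg.pps
    return Electrodogram(
        times=np.asarray(times, dtype=np.float64),
        electrodes=np.asarray(electrodes, dtype=np.int64),
        levels=np.asarray(levels, dtype=np.int64),
        duration=float(duration),
        pps=cfg.pps,
    )
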