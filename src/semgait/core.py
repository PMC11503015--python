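"""Shared domain types: gait phases, label series and the Recording container.

A walking cycle is divided into four phases, in temporal order

    SW (swing) -> IC (initial contact) -> MSt (mid stance) -> TSt (terminal stance)

The integer codes follow the S0..S3 convention used when reporting
classification results (S0=SW, S1=IC, S2=TSt, S3=MSt), which is *not* the
temporal order — use :data:`TEMPORAL_ORDER` when iterating over a cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .errors import DataError

__all__ = [
    "GaitPhase",
    "TEMPORAL_ORDER",
    "EMG_CHANNELS",
    "PRESSURE_CHANNELS",
    "ANGLE_CHANNELS",
    "GaitLabelSeries",
    "Recording",
]


class GaitPhase(IntEnum):
    """Four-phase walking gait code (S0..S3 reporting order)."""

    SW = 0   # swing: foot airborne
    IC = 1   # initial contact: heel strike
    TSt = 2  # terminal stance: heel-off / push-off
    MSt = 3  # mid stance: full foot support


#: The order in which phases occur within one gait cycle.
TEMPORAL_ORDER = (GaitPhase.SW, GaitPhase.IC, GaitPhase.MSt, GaitPhase.TSt)

#: sEMG electrode sites, right leg: rectus femoris, vastus lateralis/medialis,
#: biceps femoris, semitendinosus, tibialis anterior, lateral/medial gastrocnemius.
EMG_CHANNELS = ("RF", "VLO", "VMO", "BF", "ST", "TIA", "LGA", "MGA")

#: Plantar switch sites: heel, 5th metatarsal, 1st metatarsal, big toe — right
#: foot first (the instrumented side), then left.
PRESSURE_CHANNELS = (
    "R_heel", "R_met5", "R_met1", "R_toe",
    "L_heel", "L_met5", "L_met1", "L_toe",
)

ANGLE_CHANNELS = ("hip", "knee", "ankle")


@dataclass
class GaitLabelSeries:
    """Per-sample gait phase codes at a fixed sampling rate.

    Attributes
    ----------
    codes : ndarray of int8, shape (n_samples,)
        One :class:`GaitPhase` code per sample.
    sampling_rate : float
        Samples per second.
    """

    codes: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 1:
            raise DataError("label codes must be a 1-D array")
        valid = {int(p) for p in GaitPhase}
        present = set(np.unique(self.codes).tolist())
        if not present <= valid:
            raise DataError(f"invalid gait codes present: {sorted(present - valid)}")

    def __len__(self) -> int:
        return self.codes.shape[0]

    def cycle_starts(self) -> np.ndarray:
        """Indices where a new gait cycle begins (onset of a SW run)."""
        sw = self.codes == int(GaitPhase.SW)
        onset = sw & ~np.r_[False, sw[:-1]]
        return np.flatnonzero(onset)

    def cycle_index(self) -> np.ndarray:
        """Per-sample 0-based cycle number (samples before the first onset get 0)."""
        starts = self.cycle_starts()
        idx = np.searchsorted(starts, np.arange(len(self)), side="right") - 1
        return np.maximum(idx, 0)

    def cycle_position(self) -> np.ndarray:
        """Per-sample normalized position in [0, 1) within its gait cycle."""
        starts = self.cycle_starts()
        if starts.size == 0:
            raise DataError("no gait cycle onsets in label series")
        bounds = np.r_[starts, len(self)]
        pos = np.empty(len(self), dtype=float)
        # samples before the first onset: extrapolate backwards from cycle 0
        first_len = bounds[1] - bounds[0]
        pos[: bounds[0]] = (np.arange(bounds[0]) - bounds[0]) / first_len % 1.0
        for k in range(starts.size):
            s, e = bounds[k], bounds[k + 1]
            pos[s:e] = (np.arange(e - s)) / (e - s)
        return pos


@dataclass
class Recording:
    """One synchronized multi-channel walking session.

    semg : (n, 8) float array, mV-scale, channel order :data:`EMG_CHANNELS`
    pressure : (n, 8) float array, plantar switch traces, :data:`PRESSURE_CHANNELS`
    angles : (n, 3) float array, degrees, (hip, knee, ankle)
    labels : ground-truth :class:`GaitLabelSeries` (available for simulations) or None
    sampling_rate : Hz
    """

    semg: np.ndarray
    pressure: np.ndarray
    angles: np.ndarray
    sampling_rate: float
    labels: GaitLabelSeries | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.semg = np.asarray(self.semg, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.semg.shape[0]

    def validate(self) -> None:
        if self.semg.ndim != 2 or self.semg.shape[1] != len(EMG_CHANNELS):
            raise DataError(f"semg must be (n, {len(EMG_CHANNELS)})")
        if self.pressure.shape != (self.semg.shape[0], len(PRESSURE_CHANNELS)):
            raise DataError("pressure block shape mismatch")
        if self.angles.shape != (self.semg.shape[0], len(ANGLE_CHANNELS)):
            raise DataError("angles block shape mismatch")
        for name, block in (("semg", self.semg), ("pressure", self.pressure),
                            ("angles", self.angles)):
            if not np.all(np.isfinite(block)):
                raise DataError(f"{name} contains non-finite samples")
        if self.labels is not None and len(self.labels) != self.n_samples:
            raise DataError("label series length does not match signal blocks")
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")
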