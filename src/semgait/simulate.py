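"""Synthetic gait-sEMG session generator.

Emulates the statistical structure of treadmill walking recordings: a periodic
four-phase gait cycle (SW -> IC -> MSt -> TSt) with per-cycle duration jitter,
phase-dependent muscle activation envelopes modulating band-limited Gaussian
carriers (plus 50 Hz mains interference and measurement noise), binary plantar
switch traces consistent with foot-contact physiology, and smooth periodic
hip/knee/ankle trajectories confined to configured ranges of motion.

All randomness flows from ``SimConfig.seed`` through per-stage child streams,
so an identical config always produces a bit-identical session, and each
sub-generator is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .core import (
    ANGLE_CHANNELS,
    EMG_CHANNELS,
    PRESSURE_CHANNELS,
    TEMPORAL_ORDER,
    GaitLabelSeries,
    GaitPhase,
    Recording,
)
from .errors import ConfigurationError

__all__ = [
    "SimConfig",
    "DEFAULT_ACTIVATION",
    "RIGHT_FOOT_CONTACT",
    "generate_phase_sequence",
    "generate_angles",
    "generate_semg",
    "generate_pressure",
    "generate_session",
    "activation_envelopes",
]

# Default activation amplitudes, rows = EMG_CHANNELS, columns = GaitPhase code
# order (SW, IC, TSt, MSt).  Thigh muscles (RF..ST) are strong in swing and at
# initial contact, when the hip and knee are driven; calf muscles (TIA..MGA)
# carry stance (IC, MSt, TSt), providing support and ankle torque.  Entries are
# deliberately distinct across channels so the 8-dim envelope is informative
# about where in the cycle a window sits.
DEFAULT_ACTIVATION = np.array(
    [
        # SW    IC    TSt   MSt
        [0.90, 0.70, 0.20, 0.10],  # RF
        [0.80, 0.80, 0.15, 0.20],  # VLO
        [0.70, 0.90, 0.25, 0.15],  # VMO
        [0.85, 0.60, 0.30, 0.10],  # BF
        [0.75, 0.65, 0.20, 0.25],  # ST
        [0.15, 0.80, 0.60, 0.90],  # TIA
        [0.10, 0.60, 0.90, 0.70],  # LGA
        [0.20, 0.70, 0.85, 0.80],  # MGA
    ]
)

# Which right-foot switches are loaded in each phase (heel, met5, met1, toe),
# indexed by GaitPhase code.  The same table drives phase extraction in
# :mod:`semgait.preprocess`.
RIGHT_FOOT_CONTACT = {
    GaitPhase.SW: (0, 0, 0, 0),   # foot airborne
    GaitPhase.IC: (1, 0, 0, 0),   # heel strike, heel only
    GaitPhase.MSt: (1, 1, 1, 0),  # full-foot support: heel + forefoot
    GaitPhase.TSt: (0, 1, 1, 1),  # heel-off: forefoot and toe push-off
}

# Per-joint trajectory shape: (phase of 1st harmonic peak, phase of 2nd
# harmonic peak, 2nd/1st harmonic amplitude ratio), in cycle fraction.  Hip
# flexion peaks in late swing, knee flexion mid-swing with a small
# loading-response bump, ankle dorsiflexion peaks in late stance before
# plantarflexion at push-off.
_ANGLE_SHAPES = {
    "hip": (0.30, 0.10, 0.25),
    "knee": (0.20, 0.55, 0.35),
    "ankle": (0.80, 0.15, 0.40),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic walking-session generator.

    Notes
    -----
    ``phase_fractions`` are indexed in *temporal* order SW, IC, MSt, TSt (the
    GaitPhase integer codes order TSt before MSt, following the S0..S3
    reporting convention).  ``activation_matrix`` rows follow
    :data:`~semgait.core.EMG_CHANNELS` and columns follow the GaitPhase code
    order SW, IC, TSt, MSt.
    """

    sampling_rate: float = 1500.0
    n_cycles: int = 200
    #: seconds per gait cycle; ~1 s corresponds to brisk treadmill walking (4 km/h)
    cycle_duration: float = 1.0
    #: temporal-order (SW, IC, MSt, TSt) proportions of the cycle, sum to 1
    phase_fractions: tuple[float, float, float, float] = (0.40, 0.20, 0.20, 0.20)
    activation_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_ACTIVATION.copy()
    )
    #: band of the sEMG carrier noise, Hz (dominant physiological band)
    emg_band: tuple[float, float] = (20.0, 150.0)
    #: amplitude of injected 50 Hz interference, relative units
    mains_amplitude: float = 0.05
    #: (low, high) degrees for hip, knee, ankle
    angle_ranges: tuple[tuple[float, float], ...] = (
        (-15.0, 30.0),
        (-12.0, 45.0),
        (-20.0, 8.0),
    )
    #: additive white-noise SD on every sEMG channel
    measurement_noise_sd: float = 0.05
    #: multiplicative per-cycle duration jitter (0.05 = +-5%)
    cycle_jitter: float = 0.05
    #: scale on angle excursions about the mid-range; 0 gives constant angles
    angle_amplitude: float = 1.0
    #: additive noise SD on the plantar switch traces
    pressure_noise_sd: float = 0.05
    #: SD (seconds) of random shifts applied to switch on/off edges
    pressure_edge_jitter_s: float = 0.010
    #: raised-cosine smoothing span at phase boundaries, fraction of phase length
    envelope_smooth_frac: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_cycles <= 0:
            raise ConfigurationError("n_cycles must be positive")
        if self.cycle_duration <= 0:
            raise ConfigurationError("cycle_duration must be positive")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        fr = np.asarray(self.phase_fractions, dtype=float)
        if fr.shape != (4,) or np.any(fr <= 0):
            raise ConfigurationError("phase_fractions must be 4 positive values")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ConfigurationError("phase_fractions must sum to 1 within 1e-9")
        act = np.asarray(self.activation_matrix, dtype=float)
        if act.shape != (len(EMG_CHANNELS), 4):
            raise ConfigurationError("activation_matrix must be 8 x 4")
        if np.any(act < 0) or np.any(act > 1):
            raise ConfigurationError("activation amplitudes must lie in [0, 1]")
        lo, hi = self.emg_band
        if not 0 < lo < hi:
            raise ConfigurationError("emg_band must satisfy 0 < low < high")
        if self.sampling_rate <= 2 * hi:
            raise ConfigurationError(
                f"sampling_rate {self.sampling_rate} must exceed twice the "
                f"emg_band upper edge {hi} (Nyquist)"
            )
        if len(self.angle_ranges) != 3 or any(r[0] >= r[1] for r in self.angle_ranges):
            raise ConfigurationError("angle_ranges must be 3 (low, high) pairs")

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic child stream for one generator stage."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, stage]))


# stage ids for the per-stage random streams
_STAGE_PHASES, _STAGE_ANGLES, _STAGE_SEMG, _STAGE_PRESSURE = 0, 1, 2, 3


def generate_phase_sequence(cfg: SimConfig) -> GaitLabelSeries:
    """Build the per-sample gait phase label stream.

    Cycles follow the temporal order SW -> IC -> MSt -> TSt with per-cycle
    multiplicative duration jitter; jittered durations are renormalized so the
    total length is exactly ``round(n_cycles * cycle_duration * sampling_rate)``.
    """
    cfg.validate()
    rng = cfg.rng(_STAGE_PHASES)
    total = int(round(cfg.n_cycles * cfg.cycle_duration * cfg.sampling_rate))
    durations = 1.0 + cfg.cycle_jitter * rng.uniform(-1.0, 1.0, size=cfg.n_cycles)
    bounds = np.round(np.r_[0.0, np.cumsum(durations)] / durations.sum() * total).astype(int)
    fr = np.asarray(cfg.phase_fractions, dtype=float)
    codes = np.empty(total, dtype=np.int8)
    for k in range(cfg.n_cycles):
        s, e = bounds[k], bounds[k + 1]
        span = e - s
        edges = s + np.round(np.r_[0.0, np.cumsum(fr)] * span).astype(int)
        for p, phase in enumerate(TEMPORAL_ORDER):
            codes[edges[p]: edges[p + 1]] = int(phase)
    return GaitLabelSeries(codes=codes, sampling_rate=cfg.sampling_rate)


def _two_harmonic_shape(pos: np.ndarray, p1: float, p2: float, ratio: float) -> np.ndarray:
    return np.cos(2 * np.pi * (pos - p1)) + ratio * np.cos(4 * np.pi * (pos - p2))


def generate_angles(labels: GaitLabelSeries, cfg: SimConfig) -> np.ndarray:
    """Smooth periodic hip/knee/ankle trajectories phase-locked to the cycle.

    Each joint follows a two-harmonic Fourier series of the normalized cycle
    position, affinely mapped so its extremes touch the configured range
    (scaled by ``angle_amplitude`` about the mid-range).  Harmonic placement is
    perturbed slightly per session so realizations differ across seeds while
    remaining inside their ranges.

    Returns an (n_samples, 3) array in degrees.
    """
    cfg.validate()
    if len(labels) == 0:
        raise ConfigurationError("label series is empty")
    rng = cfg.rng(_STAGE_ANGLES)
    pos = labels.cycle_position()
    out = np.empty((len(labels), 3), dtype=float)
    grid = np.linspace(0.0, 1.0, 20001)
    for j, joint in enumerate(ANGLE_CHANNELS):
        p1, p2, ratio = _ANGLE_SHAPES[joint]
        p1 = p1 + rng.uniform(-0.02, 0.02)
        p2 = p2 + rng.uniform(-0.02, 0.02)
        ratio = ratio * (1.0 + rng.uniform(-0.10, 0.10))
        ref = _two_harmonic_shape(grid, p1, p2, ratio)
        smin, smax = ref.min(), ref.max()
        lo, hi = cfg.angle_ranges[j]
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        s = _two_harmonic_shape(pos, p1, p2, ratio)
        unit = 2.0 * (s - smin) / (smax - smin) - 1.0  # [-1, 1] over the cycle
        out[:, j] = np.clip(mid + cfg.angle_amplitude * half * unit, lo, hi)
    return out


def _run_lengths(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(start index, length) of every constant-label run."""
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.r_[0, change]
    lengths = np.diff(np.r_[starts, codes.size])
    return starts, lengths


def activation_envelopes(labels: GaitLabelSeries, cfg: SimConfig) -> np.ndarray:
    """Smoothed per-channel activation envelope, shape (n_samples, 8).

    The piecewise-constant activation (matrix entry of the current phase) is
    convolved with a raised-cosine (Hann) kernel spanning
    ``envelope_smooth_frac`` of the mean phase length, so amplitude transitions
    at phase boundaries are gradual, as in real EMG.
    """
    codes = labels.codes
    act = np.asarray(cfg.activation_matrix, dtype=float)
    step = act[:, codes].T  # (n, 8)
    _, lengths = _run_lengths(codes)
    width = max(3, int(round(cfg.envelope_smooth_frac * lengths.mean())))
    if width % 2 == 0:
        width += 1
    kernel = np.hanning(width + 2)[1:-1]
    kernel /= kernel.sum()
    half = width // 2
    padded = np.pad(step, ((half, half), (0, 0)), mode="edge")
    out = np.empty_like(step)
    for c in range(step.shape[1]):
        out[:, c] = np.convolve(padded[:, c], kernel, mode="valid")
    return out


def generate_semg(labels: GaitLabelSeries, cfg: SimConfig) -> np.ndarray:
    """Synthesize the 8-channel sEMG block, shape (n_samples, 8).

    Per channel: a band-limited Gaussian carrier (``emg_band``, unit RMS)
    amplitude-modulated by the smoothed activation envelope, plus a 50 Hz
    mains sinusoid (random phase per channel) and white measurement noise.
    """
    cfg.validate()
    if len(labels) == 0:
        raise ConfigurationError("label series is empty")
    rng = cfg.rng(_STAGE_SEMG)
    n = len(labels)
    env = activation_envelopes(labels, cfg)
    white = rng.standard_normal((n, len(EMG_CHANNELS)))
    sos = sps.butter(4, cfg.emg_band, btype="bandpass", fs=cfg.sampling_rate, output="sos")
    carrier = sps.sosfiltfilt(sos, white, axis=0)
    rms = np.sqrt(np.mean(carrier**2, axis=0))
    carrier = carrier / np.where(rms > 0, rms, 1.0)
    t = np.arange(n) / cfg.sampling_rate
    mains_phase = rng.uniform(0, 2 * np.pi, size=len(EMG_CHANNELS))
    mains = cfg.mains_amplitude * np.sin(2 * np.pi * 50.0 * t[:, None] + mains_phase)
    noise = cfg.measurement_noise_sd * rng.standard_normal((n, len(EMG_CHANNELS)))
    return env * carrier + mains + noise


def generate_pressure(labels: GaitLabelSeries, cfg: SimConfig) -> np.ndarray:
    """Plantar switch traces, shape (n_samples, 8), right foot then left.

    Right-foot switches follow :data:`RIGHT_FOOT_CONTACT` for the labeled
    phase; the left foot repeats the pattern shifted by half a cycle.  Each
    on/off edge is shifted by Gaussian jitter (``pressure_edge_jitter_s``) and
    Gaussian amplitude noise is added, so recovering the labels from pressure
    is non-trivial unless both are zero.
    """
    cfg.validate()
    if len(labels) == 0:
        raise ConfigurationError("label series is empty")
    rng = cfg.rng(_STAGE_PRESSURE)
    codes = labels.codes
    n = codes.size
    contact = np.zeros((4, 4))
    for phase, row in RIGHT_FOOT_CONTACT.items():
        contact[int(phase)] = row

    def foot_traces(phase_codes: np.ndarray) -> np.ndarray:
        ideal = contact[phase_codes]  # (n, 4)
        if cfg.pressure_edge_jitter_s <= 0:
            return ideal.copy()
        out = np.empty_like(ideal)
        max_shift = int(round(3 * cfg.pressure_edge_jitter_s * cfg.sampling_rate))
        for c in range(4):
            trace = ideal[:, c]
            edges = np.flatnonzero(np.diff(trace)) + 1
            shifts = np.clip(
                np.round(rng.normal(0, cfg.pressure_edge_jitter_s * cfg.sampling_rate,
                                    size=edges.size)).astype(int),
                -max_shift, max_shift,
            )
            new_edges = np.clip(edges + shifts, 1, n - 1)
            new_edges.sort()
            rebuilt = np.empty(n)
            prev = 0
            val = trace[0]
            for e in new_edges:
                rebuilt[prev:e] = val
                val = 1.0 - val
                prev = e
            rebuilt[prev:] = val
            out[:, c] = rebuilt
        return out

    right = foot_traces(codes)
    shift = int(round(0.5 * n / max(1, cfg.n_cycles)))
    left = foot_traces(np.roll(codes, shift))
    pressure = np.hstack([right, left])
    if cfg.pressure_noise_sd > 0:
        pressure = pressure + cfg.pressure_noise_sd * rng.standard_normal(pressure.shape)
    return pressure


def generate_session(cfg: SimConfig) -> Recording:
    """Compose the four generators into one fully reproducible Recording."""
    cfg.validate()
    labels = generate_phase_sequence(cfg)
    angles = generate_angles(labels, cfg)
    semg = generate_semg(labels, cfg)
    pressure = generate_pressure(labels, cfg)
    return Recording(
        semg=semg,
        pressure=pressure,
        angles=angles,
        labels=labels,
        sampling_rate=cfg.sampling_rate,
        meta={"seed": int(cfg.seed), "n_cycles": int(cfg.n_cycles)},
    )


def noiseless(cfg: SimConfig) -> SimConfig:
    """Copy of ``cfg`` with pressure noise and edge jitter switched off."""
    return replace(cfg, pressure_noise_sd=0.0, pressure_edge_jitter_s=0.0)
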