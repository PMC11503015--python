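"""Signal conditioning and gait labeling.

sEMG conditioning follows the standard offline chain for walking studies:
second-order Butterworth 20-300 Hz band-pass (muscle energy band) and
49-51 Hz band-stop (mains), applied forward-backward for zero phase lag, then
per-channel zero standardization.  Plantar pressure is moving-average smoothed
and converted to the four-phase gait label stream by thresholding the
right-foot switches and mapping their contact pattern:

    no contact            -> SW
    heel only             -> IC
    heel + forefoot       -> MSt
    forefoot/toe, no heel -> TSt

followed by a minimum-phase-duration debounce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import EMG_CHANNELS, GaitLabelSeries, GaitPhase
from .errors import ConfigurationError, DataError

__all__ = [
    "FilterSpec",
    "EMG_BANDPASS",
    "MAINS_BANDSTOP",
    "butterworth_filter",
    "filter_emg",
    "standardize",
    "smooth_pressure",
    "extract_gait_phases",
]


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth band filter.

    ``order`` is the analog prototype order (2 by default).  With
    ``zero_phase`` the filter runs forward and backward (scipy ``sosfiltfilt``
    with its default odd-reflection padding), which cancels phase distortion
    and squares the magnitude response — the effective attenuation is
    |H(f)|^2.
    """

    kind: str  # "bandpass" | "bandstop"
    low_hz: float
    high_hz: float
    order: int = 2
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if self.kind not in ("bandpass", "bandstop"):
            raise ConfigurationError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ConfigurationError("filter order must be >= 1")
        if not 0 < self.low_hz < self.high_hz:
            raise ConfigurationError("need 0 < low_hz < high_hz")
        if self.high_hz >= fs / 2:
            raise ConfigurationError(
                f"high cutoff {self.high_hz} Hz is at or above Nyquist ({fs / 2} Hz)"
            )

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        return sps.butter(self.order, (self.low_hz, self.high_hz),
                          btype=self.kind, fs=fs, output="sos")

    def response(self, freqs_hz, fs: float) -> np.ndarray:
        """|H(f)| of a single pass, from the designed transfer function."""
        _, h = sps.sosfreqz(self.sos(fs), worN=np.atleast_1d(freqs_hz), fs=fs)
        mag = np.abs(h)
        return mag**2 if self.zero_phase else mag


#: 20-300 Hz pass band covering the dominant sEMG energy.
EMG_BANDPASS = FilterSpec("bandpass", 20.0, 300.0)
#: 49-51 Hz stop band removing mains interference.
MAINS_BANDSTOP = FilterSpec("bandstop", 49.0, 51.0)


def butterworth_filter(signal: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Apply ``spec`` to each column of ``signal`` (samples x channels).

    Zero-phase mode is the offline default; ``zero_phase=False`` gives the
    causal single pass for streaming use.  Length is preserved.
    """
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("signal contains NaN or infinite samples")
    sos = spec.sos(fs)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    if spec.zero_phase:
        y = sps.sosfiltfilt(sos, x, axis=0)
    else:
        y = sps.sosfilt(sos, x, axis=0)
    return y[:, 0] if one_d else y


def filter_emg(signal: np.ndarray, fs: float,
               bandpass: FilterSpec = EMG_BANDPASS,
               bandstop: FilterSpec = MAINS_BANDSTOP) -> np.ndarray:
    """Standard sEMG chain: band-pass, then mains band-stop."""
    return butterworth_filter(butterworth_filter(signal, bandpass, fs), bandstop, fs)


def standardize(signal: np.ndarray) -> np.ndarray:
    """Zero standardization: per-channel (x - mean) / SD, SD with the N-1
    (sample) denominator.

    Raises :class:`DataError` naming the first offending channel if any
    channel has zero variance.
    """
    x = np.asarray(signal, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    sd = x.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        c = int(bad[0])
        name = EMG_CHANNELS[c] if c < len(EMG_CHANNELS) and x.shape[1] == len(EMG_CHANNELS) else str(c)
        raise DataError(f"channel {name} has zero variance; cannot standardize")
    y = (x - x.mean(axis=0)) / sd
    return y[:, 0] if one_d else y


def smooth_pressure(pressure: np.ndarray, window_s: float, fs: float) -> np.ndarray:
    """Centered moving average per channel; edges use a shrinking window."""
    x = np.asarray(pressure, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    w = max(1, int(round(window_s * fs)))
    if w >= x.shape[0]:
        raise ConfigurationError("smoothing window must be shorter than the signal")
    kernel = np.ones(w)
    counts = np.convolve(np.ones(x.shape[0]), kernel, mode="same")
    y = np.empty_like(x)
    for c in range(x.shape[1]):
        y[:, c] = np.convolve(x[:, c], kernel, mode="same") / counts
    return y[:, 0] if one_d else y


def _debounce(codes: np.ndarray, min_len: int) -> np.ndarray:
    """Absorb label runs shorter than ``min_len`` into their left neighbour
    (the first run, if short, joins the run after it)."""
    codes = codes.copy()
    while True:
        change = np.flatnonzero(np.diff(codes)) + 1
        starts = np.r_[0, change]
        lengths = np.diff(np.r_[starts, codes.size])
        if lengths.size <= 1:
            return codes
        short = np.flatnonzero(lengths < min_len)
        if short.size == 0:
            return codes
        k = int(short[0])
        s, e = starts[k], starts[k] + lengths[k]
        if k == 0:
            codes[s:e] = codes[e] if e < codes.size else codes[s]
        else:
            codes[s:e] = codes[s - 1]


def extract_gait_phases(pressure: np.ndarray, fs: float,
                        threshold: float = 0.5,
                        min_phase_s: float = 0.05) -> GaitLabelSeries:
    """Threshold the (smoothed) right-foot switches into the 4-phase stream.

    ``threshold`` is a fraction of each channel's 95th percentile.  Channels
    whose 95th percentile is zero are treated as never in contact.  Output is
    debounced with a ``min_phase_s`` minimum phase duration.
    """
    x = np.asarray(pressure, dtype=float)
    if x.ndim != 2 or x.shape[1] < 4:
        raise DataError("pressure must be (samples, >=4 channels), right foot first")
    if not 0 < threshold < 1:
        raise ConfigurationError("threshold must be a fraction in (0, 1)")
    right = x[:, :4]
    p95 = np.percentile(right, 95, axis=0)
    if np.all(p95 <= 0):
        raise DataError("pressure is flat at zero; no gait detectable")
    thr = threshold * np.where(p95 > 0, p95, np.inf)
    on = right > thr
    heel = on[:, 0]
    fore = on[:, 1] | on[:, 2] | on[:, 3]
    codes = np.full(x.shape[0], int(GaitPhase.SW), dtype=np.int8)
    codes[heel & ~fore] = int(GaitPhase.IC)
    codes[heel & fore] = int(GaitPhase.MSt)
    codes[~heel & fore] = int(GaitPhase.TSt)
    codes = _debounce(codes, max(1, int(round(min_phase_s * fs))))
    return GaitLabelSeries(codes=codes, sampling_rate=fs)
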