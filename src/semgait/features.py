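"""Windowing and the two sEMG feature representations.

For every analysis window (default 320 samples = 213 ms at 1.5 kHz) two
descriptions are computed per channel:

* the classical time-domain feature vector — waveform length (WL), mean
  absolute value (MAV), variance (VAR), root mean square (RMS) and the
  thresholded zero-crossing count (ZC) — stacked into a 5 x 8 matrix
  (rows WL, MAV, VAR, RMS, ZC; columns RF..MGA);
* a short-time Fourier spectrogram: Hann-windowed 64-point DFT magnitudes at
  hop 32, giving 33 one-sided bins (0-750 Hz at fs=1500) per frame and 9
  frames per 320-sample window, of which the first 9 rows (0-187.5 Hz, where
  most sEMG energy lives) are retained — a 9 x 9 x 8 tensor
  (frequency x time x channel).

The 320-sample window length is the unique length for which the 64/32 STFT
yields exactly 9 frames, matching the 9 x 9 x 8 tensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

from .core import GaitPhase, Recording
from .errors import ConfigurationError, DataError

__all__ = [
    "WindowSpec",
    "STFTConfig",
    "SegmentSample",
    "FeatureSet",
    "TD_ROWS",
    "wave_length",
    "variance",
    "mean_absolute_value",
    "root_mean_square",
    "zero_crossings",
    "time_domain_matrix",
    "stft_spectrogram",
    "stft_bin_frequencies",
    "segment",
]

#: Row order of the time-domain feature matrix.
TD_ROWS = ("WL", "MAV", "VAR", "RMS", "ZC")

#: Default ZC amplitude threshold; signals are standardized (unit SD), so this
#: is ~1% of the channel SD.
DEFAULT_ZC_EPS = 0.01


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window segmentation parameters."""

    length_samples: int = 320
    stride_samples: int = 160
    label_rule: str = "majority"  # or "center"

    def validate(self) -> None:
        if self.length_samples < 64:
            raise ConfigurationError("window must be >= 64 samples (STFT frame)")
        if self.stride_samples < 1:
            raise ConfigurationError("stride must be >= 1")
        if self.label_rule not in ("majority", "center"):
            raise ConfigurationError(f"unknown label_rule {self.label_rule!r}")


@dataclass(frozen=True)
class STFTConfig:
    """Spectrogram parameters: 64-point Hann frames, 32-sample hop, keep the
    lowest 9 frequency rows, linear magnitude."""

    n_fft: int = 64
    hop: int = 32
    window: str = "hann"
    retain_rows: int = 9
    magnitude_scale: str = "linear"  # or "log"

    def validate(self) -> None:
        if self.retain_rows > self.n_fft // 2 + 1:
            raise ConfigurationError("retain_rows exceeds one-sided bin count")
        if self.hop < 1 or self.n_fft < 2:
            raise ConfigurationError("invalid STFT geometry")
        if self.magnitude_scale not in ("linear", "log"):
            raise ConfigurationError("magnitude_scale must be linear or log")

    @property
    def full_bins(self) -> int:
        """One-sided bin count of the real DFT."""
        return self.n_fft // 2 + 1


@dataclass
class SegmentSample:
    """One analysis window with its features and targets."""

    raw: np.ndarray            # (length, 8) standardized sEMG
    td: np.ndarray             # (5, 8)
    spec: np.ndarray           # (9, 9, 8)
    gait: int                  # GaitPhase code
    angles: np.ndarray         # (3,) degrees at the window's final sample
    start: int = 0             # start index in the source recording
    cycle: int = 0             # gait cycle the window starts in


@dataclass
class FeatureSet:
    """Column-oriented store of all windows from one session."""

    raw: np.ndarray            # (n, length, 8)
    td: np.ndarray             # (n, 5, 8)
    spec: np.ndarray           # (n, 9, 9, 8)
    gait: np.ndarray           # (n,) int8
    angles: np.ndarray         # (n, 3)
    window_start: np.ndarray   # (n,)
    cycle_index: np.ndarray    # (n,)
    sampling_rate: float
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.raw.shape[0]

    def __getitem__(self, i: int) -> SegmentSample:
        return SegmentSample(
            raw=self.raw[i], td=self.td[i], spec=self.spec[i],
            gait=int(self.gait[i]), angles=self.angles[i],
            start=int(self.window_start[i]), cycle=int(self.cycle_index[i]),
        )

    def subset(self, idx: np.ndarray) -> "FeatureSet":
        return FeatureSet(
            raw=self.raw[idx], td=self.td[idx], spec=self.spec[idx],
            gait=self.gait[idx], angles=self.angles[idx],
            window_start=self.window_start[idx], cycle_index=self.cycle_index[idx],
            sampling_rate=self.sampling_rate, meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# time-domain features


def _check_series(y: np.ndarray, min_len: int = 2) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < min_len:
        raise DataError(f"need a 1-D series of at least {min_len} samples")
    return y


def wave_length(y: np.ndarray) -> float:
    """WL: total variation sum |y_n - y_{n-1}|, n = 2..N."""
    y = _check_series(y)
    return float(np.sum(np.abs(np.diff(y))))


def variance(y: np.ndarray) -> float:
    """VAR: sum (y_n - mean)^2 / (N - 1)."""
    y = _check_series(y)
    return float(y.var(ddof=1))


def mean_absolute_value(y: np.ndarray) -> float:
    """MAV: mean of |y_n|."""
    y = _check_series(y, min_len=1)
    return float(np.mean(np.abs(y)))


def root_mean_square(y: np.ndarray) -> float:
    """RMS: sqrt(mean of y_n^2)."""
    y = _check_series(y, min_len=1)
    return float(np.sqrt(np.mean(y**2)))


def zero_crossings(y: np.ndarray, eps: float = DEFAULT_ZC_EPS) -> int:
    """ZC: count of sign changes whose step |y_n - y_{n-1}| is at least ``eps``."""
    if eps < 0:
        raise ConfigurationError("zero-crossing threshold must be >= 0")
    y = _check_series(y)
    sign_change = y[1:] * y[:-1] < 0
    big_enough = np.abs(np.diff(y)) >= eps
    return int(np.count_nonzero(sign_change & big_enough))


def time_domain_matrix(raw: np.ndarray, eps: float = DEFAULT_ZC_EPS) -> np.ndarray:
    """Stack the five features per channel into the 5 x 8 matrix
    (rows :data:`TD_ROWS`, columns in electrode order)."""
    x = np.asarray(raw, dtype=float)
    if x.ndim != 2:
        raise DataError("segment must be (length, channels)")
    n, c = x.shape
    if n < 2:
        raise DataError("segment too short for time-domain features")
    out = np.empty((5, c))
    d = np.diff(x, axis=0)
    out[0] = np.sum(np.abs(d), axis=0)                          # WL
    out[1] = np.mean(np.abs(x), axis=0)                         # MAV
    out[2] = x.var(axis=0, ddof=1)                              # VAR
    out[3] = np.sqrt(np.mean(x**2, axis=0))                     # RMS
    out[4] = np.count_nonzero((x[1:] * x[:-1] < 0) & (np.abs(d) >= eps), axis=0)  # ZC
    return out


# ---------------------------------------------------------------------------
# spectrogram


def stft_bin_frequencies(cfg: STFTConfig, fs: float, retained: bool = True) -> np.ndarray:
    """Center frequencies k * fs / n_fft of the (retained) spectrogram rows."""
    k = np.arange(cfg.retain_rows if retained else cfg.full_bins)
    return k * fs / cfg.n_fft


def stft_frames(raw: np.ndarray, cfg: STFTConfig) -> np.ndarray:
    """Full one-sided magnitude spectrogram, shape (full_bins, n_frames, C)."""
    cfg.validate()
    x = np.asarray(raw, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if n < cfg.n_fft:
        raise DataError(f"segment of {n} samples is shorter than n_fft={cfg.n_fft}")
    frames = sliding_window_view(x, cfg.n_fft, axis=0)[:: cfg.hop]  # (F, C, n_fft)
    win = get_window(cfg.window, cfg.n_fft, fftbins=True)
    mag = np.abs(np.fft.rfft(frames * win, axis=-1))  # (F, C, bins)
    return mag.transpose(2, 0, 1)  # (bins, frames, channels)


def stft_spectrogram(raw: np.ndarray, cfg: STFTConfig = STFTConfig()) -> np.ndarray:
    """Retained spectrogram tensor (retain_rows x n_frames x C).

    With the defaults and a 320-sample 8-channel window this is 9 x 9 x 8.
    """
    full = stft_frames(raw, cfg)
    kept = full[: cfg.retain_rows]
    if cfg.magnitude_scale == "log":
        kept = np.log1p(kept)
    return kept


# ---------------------------------------------------------------------------
# segmentation


def segment(recording: Recording, spec: WindowSpec = WindowSpec(),
            stft_cfg: STFTConfig = STFTConfig(),
            zc_eps: float = DEFAULT_ZC_EPS) -> FeatureSet:
    """Slide windows over a preprocessed, labeled recording and fill features.

    The gait label follows ``spec.label_rule`` (majority vote over the window
    or the center sample); the angle target is the angle at the window's
    *final* sample — the state being predicted "now".
    """
    spec.validate()
    stft_cfg.validate()
    if recording.labels is None:
        raise DataError("recording has no gait labels; run phase extraction first")
    n = recording.n_samples
    L, S = spec.length_samples, spec.stride_samples
    if n < L:
        raise DataError(f"recording of {n} samples is shorter than one window ({L})")
    starts = np.arange(0, n - L + 1, S)
    codes = recording.labels.codes
    cycles = recording.labels.cycle_index()
    n_win = starts.size
    raw = np.empty((n_win, L, recording.semg.shape[1]))
    td = np.empty((n_win, 5, recording.semg.shape[1]))
    spc = None
    gait = np.empty(n_win, dtype=np.int8)
    angles = np.empty((n_win, 3))
    for i, s in enumerate(starts):
        w = recording.semg[s: s + L]
        raw[i] = w
        td[i] = time_domain_matrix(w, eps=zc_eps)
        sp = stft_spectrogram(w, stft_cfg)
        if spc is None:
            spc = np.empty((n_win,) + sp.shape)
        spc[i] = sp
        if spec.label_rule == "majority":
            gait[i] = np.bincount(codes[s: s + L], minlength=len(GaitPhase)).argmax()
        else:
            gait[i] = codes[s + L // 2]
        angles[i] = recording.angles[s + L - 1]
    return FeatureSet(
        raw=raw, td=td, spec=spc, gait=gait, angles=angles,
        window_start=starts, cycle_index=cycles[starts],
        sampling_rate=recording.sampling_rate,
        meta={"window": L, "stride": S, "label_rule": spec.label_rule},
    )
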