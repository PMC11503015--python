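"""Time-domain features, STFT spectrogram and windowing.

The five window features are checked against independent brute-force loops
and hand-computed examples; the spectrogram against DFT bin arithmetic and a
Parseval energy balance.
"""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from semgait.core import GaitPhase, Recording
from semgait.errors import DataError
from semgait.features import (
    STFTConfig,
    TD_ROWS,
    WindowSpec,
    mean_absolute_value,
    root_mean_square,
    segment,
    stft_bin_frequencies,
    stft_frames,
    stft_spectrogram,
    time_domain_matrix,
    variance,
    wave_length,
    zero_crossings,
)
from semgait.simulate import generate_session, noiseless

# ---------------------------------------------------------------------------
# independent brute-force oracles (plain Python loops)


def wl_oracle(y):
    return sum(abs(y[n] - y[n - 1]) for n in range(1, len(y)))


def var_oracle(y):
    m = sum(y) / len(y)
    return sum((v - m) ** 2 for v in y) / (len(y) - 1)


def mav_oracle(y):
    return sum(abs(v) for v in y) / len(y)


def rms_oracle(y):
    return (sum(v * v for v in y) / len(y)) ** 0.5


def zc_oracle(y, eps):
    return sum(1 for n in range(1, len(y))
               if y[n] * y[n - 1] < 0 and abs(y[n] - y[n - 1]) >= eps)


class TestTimeDomainFeatures:
    def test_hand_examples(self):
        assert wave_length(np.array([0.0, 1.0, 0.0, 1.0])) == pytest.approx(3.0)
        assert wave_length(np.full(10, 2.2)) == 0.0
        y = np.array([1.0, -1.0, 1.0, -1.0])
        assert variance(y) == pytest.approx(4.0 / 3.0)
        assert mean_absolute_value(y) == pytest.approx(1.0)
        assert root_mean_square(np.array([3.0, 4.0])) == pytest.approx(np.sqrt(12.5))
        assert root_mean_square(np.full(5, -2.0)) == pytest.approx(2.0)
        assert zero_crossings(y, eps=0.0) == 3
        assert zero_crossings(y, eps=3.0) == 0  # all steps have |delta| = 2 < 3
        assert zero_crossings(np.array([0.5, 1.5, 0.2, 2.0]), eps=0.0) == 0

    def test_wl_homogeneity(self, rng):
        y = rng.standard_normal(50)
        assert wave_length(-3.0 * y) == pytest.approx(3.0 * wave_length(y))

    def test_rms_variance_identity(self, rng):
        y = rng.standard_normal(64)
        n = y.size
        assert root_mean_square(y) ** 2 >= variance(y) * (n - 1) / n - 1e-12

    def test_matches_brute_force_on_random_vectors(self):
        """All five features agree with independent loops to 1e-10 relative
        on 1,000 random vectors."""
        master = np.random.default_rng(20240917)
        for _ in range(1000):
            n = int(master.integers(2, 40))
            y = master.standard_normal(n) * master.uniform(0.1, 10)
            eps = float(master.uniform(0, 0.5))
            yl = y.tolist()
            assert wave_length(y) == pytest.approx(wl_oracle(yl), rel=1e-10)
            assert variance(y) == pytest.approx(var_oracle(yl), rel=1e-10, abs=1e-12)
            assert mean_absolute_value(y) == pytest.approx(mav_oracle(yl), rel=1e-10)
            assert root_mean_square(y) == pytest.approx(rms_oracle(yl), rel=1e-10)
            assert zero_crossings(y, eps) == zc_oracle(yl, eps)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(arrays(np.float64, st.integers(2, 30),
                  elements=st.floats(-100, 100, allow_nan=False)))
    def test_feature_properties(self, y):
        assert wave_length(y) >= 0
        assert variance(y) >= 0
        assert mean_absolute_value(y) >= abs(np.mean(y)) - 1e-9
        assert 0 <= zero_crossings(y, 0.0) <= y.size - 1

    def test_series_too_short_rejected(self):
        with pytest.raises(DataError):
            wave_length(np.array([1.0]))


class TestTimeDomainMatrix:
    def test_shape_and_row_order(self, rng):
        raw = rng.standard_normal((320, 8))
        td = time_domain_matrix(raw)
        assert td.shape == (5, 8)
        assert TD_ROWS == ("WL", "MAV", "VAR", "RMS", "ZC")

    def test_all_zero_segment(self):
        assert np.all(time_domain_matrix(np.zeros((100, 8))) == 0)

    def test_columns_equal_per_channel_scalars(self, rng):
        raw = rng.standard_normal((64, 8))
        td = time_domain_matrix(raw, eps=0.05)
        for c in range(8):
            y = raw[:, c]
            col = [wave_length(y), mean_absolute_value(y), variance(y),
                   root_mean_square(y), zero_crossings(y, 0.05)]
            assert np.allclose(td[:, c], col, rtol=1e-12)


class TestSpectrogram:
    def test_default_geometry(self, rng):
        cfg = STFTConfig()
        spec = stft_spectrogram(rng.standard_normal((320, 8)), cfg)
        assert spec.shape == (9, 9, 8)
        assert cfg.full_bins == 33

    def test_full_one_sided_bin_count(self, rng):
        full = stft_frames(rng.standard_normal((320, 8)), STFTConfig())
        assert full.shape[0] == 64 // 2 + 1 == 33

    def test_retained_row_frequencies(self):
        freqs = stft_bin_frequencies(STFTConfig(), fs=1500.0)
        assert np.allclose(freqs, np.arange(9) * 1500.0 / 64)
        assert freqs[-1] == 187.5
        full = stft_bin_frequencies(STFTConfig(), fs=1500.0, retained=False)
        assert full[-1] == 750.0  # one-sided band edge

    def test_pure_tone_lands_in_its_bin(self):
        # 46.875 Hz = bin 2 center at fs=1500, n_fft=64
        t = np.arange(320) / 1500.0
        raw = np.zeros((320, 8))
        raw[:, 3] = np.sin(2 * np.pi * 46.875 * t)
        spec = stft_spectrogram(raw, STFTConfig())
        energy = spec[:, :, 3] ** 2
        rows = energy.sum(axis=1)
        assert rows.argmax() == 2
        # Hann coefficients (0.25, 0.5, 0.25) put 2/3 of the energy in the
        # center bin and ~all of it within center +-1
        assert rows[1:4].sum() >= 0.99 * rows.sum()
        assert rows[2] == pytest.approx(2.0 / 3.0 * rows.sum(), rel=0.01)
        # untouched channels stay silent
        assert np.all(spec[:, :, [0, 1, 2, 4, 5, 6, 7]] < 1e-12)

    def test_all_zero_input(self):
        assert np.all(stft_spectrogram(np.zeros((320, 8))) == 0)

    def test_too_short_segment_rejected(self):
        with pytest.raises(DataError):
            stft_spectrogram(np.zeros((32, 8)))

    def test_parseval_energy_balance(self, rng):
        """For a band-limited (<187.5 Hz) signal the retained spectrogram
        energy accounts for the Hann-windowed time-domain energy of the tiled
        frames within 5%."""
        from scipy.signal import butter, sosfiltfilt

        x = rng.standard_normal(2048)
        sos = butter(8, 150, btype="lowpass", fs=1500.0)
        x = sosfiltfilt(butter(8, 150, btype="lowpass", fs=1500.0, output="sos"), x)
        x = x[864: 864 + 320]
        cfg = STFTConfig()
        full = stft_frames(x[:, None], cfg)[:, :, 0]  # (33, 9)
        # one-sided Parseval: double interior bins
        w = np.r_[1.0, 2 * np.ones(31), 1.0]
        spec_energy = (w[:, None] * full**2).sum() / cfg.n_fft
        win = np.hanning(cfg.n_fft + 1)[:-1]
        frames = np.lib.stride_tricks.sliding_window_view(x, 64)[::32]
        time_energy = ((frames * win) ** 2).sum()
        assert spec_energy == pytest.approx(time_energy, rel=1e-9)
        retained = (w[:9, None] * full[:9] ** 2).sum() / cfg.n_fft
        assert retained == pytest.approx(time_energy, rel=0.05)


class TestSegment:
    def _recording(self, n, fs=1500.0, seed=0):
        rng = np.random.default_rng(seed)
        from semgait.core import GaitLabelSeries

        codes = (np.arange(n) * 4 // n).astype(np.int8)
        return Recording(
            semg=rng.standard_normal((n, 8)),
            pressure=np.zeros((n, 8)),
            angles=rng.standard_normal((n, 3)),
            labels=GaitLabelSeries(codes=codes, sampling_rate=fs),
            sampling_rate=fs,
        )

    def test_window_count_arithmetic(self):
        feats = segment(self._recording(1000), WindowSpec(320, 160))
        assert len(feats) == (1000 - 320) // 160 + 1 == 5

    def test_majority_label_rule(self):
        rec = self._recording(320)
        # 60% of the window is MSt -> majority label MSt
        rec.labels.codes[:] = int(GaitPhase.SW)
        rec.labels.codes[128:] = int(GaitPhase.MSt)
        feats = segment(rec, WindowSpec(320, 320))
        assert feats.gait[0] == int(GaitPhase.MSt)

    def test_non_overlapping_tiling_covers_each_sample_once(self):
        feats = segment(self._recording(960), WindowSpec(320, 320))
        starts = feats.window_start
        covered = np.concatenate([np.arange(s, s + 320) for s in starts])
        assert covered.size == np.unique(covered).size == 960

    def test_angle_target_is_window_end(self):
        rec = self._recording(640)
        feats = segment(rec, WindowSpec(320, 160))
        assert np.allclose(feats.angles[0], rec.angles[319])
        assert np.allclose(feats.angles[-1], rec.angles[639])

    def test_recording_shorter_than_window_rejected(self):
        with pytest.raises(DataError):
            segment(self._recording(200), WindowSpec(320, 160))

    def test_features_filled_on_simulated_session(self, small_session):
        feats = segment(small_session, WindowSpec(320, 320))
        assert feats.td.shape[1:] == (5, 8)
        assert feats.spec.shape[1:] == (9, 9, 8)
        assert np.all(np.isfinite(feats.td)) and np.all(np.isfinite(feats.spec))
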