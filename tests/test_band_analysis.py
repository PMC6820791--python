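"""Decidecade bands, TOL computation, weighting, ambient statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from coastnoise.band_analysis import (
    ambient_level,
    band_correlation,
    compute_tol_series,
    cutoff_frequency,
    find_band,
    m_weighted_level,
    m_weighting_gain_db,
    psd_spectrogram,
    tol_bands,
)
from coastnoise.io_calibration import ConfigError
from tests.conftest import make_recording, make_tol_series, sine_recording


class TestTolBands:
    def test_single_band_at_1khz(self):
        bands = tol_bands(1000.0, 1000.0)
        assert len(bands) == 1
        assert bands[0].nominal_centre == 1000.0
        assert bands[0].exact_centre == pytest.approx(1000.0)

    def test_study_band_count_63hz_to_125khz(self):
        """The 0.063–125 kHz analysis range holds exactly 34 decidecades."""
        bands = tol_bands(63.0, 125_000.0)
        assert len(bands) == 34
        assert bands[0].nominal_centre == 63.0
        assert bands[-1].nominal_centre == 125_000.0

    def test_no_nominal_centre_in_gap(self):
        assert tol_bands(64.0, 79.0) == []

    def test_band_edge_ratio_is_decidecade(self):
        for b in tol_bands(63.0, 125_000.0):
            assert b.f_high / b.f_low == pytest.approx(10 ** (1 / 10), rel=1e-12)
            assert b.f_low < b.exact_centre < b.f_high

    def test_named_analysis_centres_present(self):
        bands = tol_bands(63.0, 125_000.0)
        for c in (125.0, 2000.0, 16_000.0):
            assert find_band(bands, c).nominal_centre == c


class TestComputeTol:
    def test_sine_level_recovered_and_leakage_bounded(self):
        """1 kHz tone at 120 dB: its band reads 120 ± 0.1 dB, bands two or
        more octaves away stay ≥ 40 dB down."""
        fs = 48_000
        rec = sine_recording(1000.0, 120.0, fs, dur_s=3.0)
        bands = tol_bands(63.0, 16_000.0)
        tols = compute_tol_series(rec, bands)
        assert tols.levels.shape[0] == 3
        assert tols.band_levels(1000.0) == pytest.approx(120.0, abs=0.1)
        for far in (125.0, 250.0, 4000.0, 8000.0):
            assert np.all(tols.band_levels(far) <= 80.0)

    def test_white_noise_matches_psd_plus_bandwidth(self):
        """Flat PSD L: each band's level is L + 10·log10(bandwidth) ± 0.5 dB."""
        fs = 16_384
        rng = np.random.default_rng(42)
        psd_db = 40.0  # dB re 1 µPa²/Hz
        sigma = np.sqrt(10 ** (psd_db / 10.0) * fs / 2.0)
        rec = make_recording(rng.normal(0.0, sigma, fs * 30), fs)
        bands = tol_bands(125.0, 4000.0)
        tols = compute_tol_series(rec, bands)
        mean_lin = (10 ** (tols.levels / 10.0)).mean(axis=0)
        for j, b in enumerate(bands):
            expected = psd_db + 10 * np.log10(b.bandwidth)
            assert 10 * np.log10(mean_lin[j]) == pytest.approx(expected, abs=0.5)

    def test_silence_flagged_below_floor(self):
        rec = make_recording(np.zeros(8000), 8000)
        tols = compute_tol_series(rec, tol_bands(125.0, 1000.0))
        assert np.all(tols.below_floor())

    def test_band_above_nyquist_rejected(self):
        rec = make_recording(np.zeros(8000), 8000)
        with pytest.raises(ConfigError):
            compute_tol_series(rec, tol_bands(125.0, 16_000.0))

    def test_trailing_partial_window_dropped(self):
        rec = make_recording(np.random.default_rng(0).normal(size=8000 * 2 + 123), 8000)
        tols = compute_tol_series(rec, tol_bands(125.0, 1000.0))
        assert tols.levels.shape[0] == 2

    def test_block_boundary_determinism(self):
        """TOLs depend only on each window's samples, not on what follows."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=8000 * 3)
        bands = tol_bands(125.0, 1000.0)
        a = compute_tol_series(make_recording(x, 8000), bands)
        b = compute_tol_series(make_recording(x[:16000], 8000), bands)
        np.testing.assert_allclose(a.levels[:2], b.levels)

    def test_energy_consistency_over_covering_bands(self):
        """Band powers of white noise sum to the total power in the covered
        passband within 5%."""
        fs = 16_384
        rng = np.random.default_rng(7)
        rec = make_recording(rng.normal(0.0, 100.0, fs * 10), fs)
        bands = tol_bands(125.0, 4000.0)
        tols = compute_tol_series(rec, bands)
        band_sum = (10 ** (tols.levels / 10.0)).sum(axis=1).mean()
        f_lo, f_hi = bands[0].f_low, bands[-1].f_high
        spec = np.fft.rfft(rec.samples.reshape(10, fs), axis=1)
        freqs = np.fft.rfftfreq(fs, 1 / fs)
        p = 2 * np.abs(spec) ** 2 / fs**2
        total = p[:, (freqs >= f_lo) & (freqs < f_hi)].sum(axis=1).mean()
        assert band_sum == pytest.approx(total, rel=0.05)


class TestPsdSpectrogram:
    def test_tone_peak_density(self):
        """Tone PSD peak = level − 10·log10(ENBW in Hz) for the Hann window."""
        fs = 8192
        rec = sine_recording(1000.0, 120.0, fs, 4.0)
        f, t, psd = psd_spectrogram(rec, window_s=1.0, overlap=0.0)
        peak = psd[:, 0].max()
        enbw_hz = 1.5 * fs / fs  # Hann ENBW = 1.5 bins; bin width 1 Hz here
        assert peak == pytest.approx(120.0 - 10 * np.log10(enbw_hz), abs=0.2)

    def test_white_noise_flat(self):
        fs = 8192
        rng = np.random.default_rng(11)
        psd_db = 40.0
        sigma = np.sqrt(10 ** (psd_db / 10.0) * fs / 2.0)
        rec = make_recording(rng.normal(0, sigma, fs * 20), fs)
        f, t, psd = psd_spectrogram(rec, window_s=1.0, overlap=0.5)
        mean_lin = (10 ** (psd / 10.0)).mean(axis=1)
        sel = (f > 100) & (f < 4000)
        # smooth over 64-bin frequency blocks so the chi-square scatter of
        # single bins does not mask a genuine tilt
        x = mean_lin[sel]
        n_blk = x.size // 64
        smoothed = 10 * np.log10(x[: n_blk * 64].reshape(n_blk, 64).mean(axis=1))
        assert np.all(np.abs(smoothed - psd_db) < 1.0)

    def test_silence_floor_and_bad_overlap(self):
        rec = make_recording(np.zeros(8192 * 2), 8192)
        _, _, psd = psd_spectrogram(rec, 1.0, 0.0)
        assert np.all(np.isneginf(psd) | (psd < -200))
        with pytest.raises(ValueError):
            psd_spectrogram(rec, 1.0, 1.0)


class TestMWeighting:
    def test_gain_never_positive_and_plateau_flat(self):
        f = np.logspace(0, 5.5, 500)
        g = m_weighting_gain_db(f)
        assert np.all(g <= 1e-12)
        assert abs(m_weighting_gain_db(np.sqrt(200.0 * 180_000.0))) < 1e-9

    def test_rolloff_monotone_outside_plateau(self):
        low = m_weighting_gain_db(np.logspace(0, 2, 100))  # 1–100 Hz
        high = m_weighting_gain_db(np.logspace(5.5, 6.5, 100))
        assert np.all(np.diff(low) > 0)
        assert np.all(np.diff(high) < 0)

    def test_plateau_tone_unchanged(self):
        fs = 48_000
        rec = sine_recording(2000.0, 120.0, fs, 40.0)
        wls = m_weighted_level(rec, f_lo=25.0, f_hi=20_000.0, window_s=30.0)
        assert wls.levels[0] == pytest.approx(120.0, abs=0.2)

    def test_low_frequency_tone_attenuated_by_formula(self):
        fs = 8000
        rec = sine_recording(100.0, 120.0, fs, 35.0)
        wls = m_weighted_level(rec, f_lo=25.0, f_hi=3000.0, window_s=30.0)
        expected = 120.0 + m_weighting_gain_db(100.0)
        assert wls.levels[0] == pytest.approx(expected, abs=0.2)

    def test_constant_signal_gives_constant_windows(self):
        fs = 4000
        rec = sine_recording(500.0, 110.0, fs, 45.0)
        wls = m_weighted_level(rec, f_lo=25.0, f_hi=1500.0, window_s=30.0)
        assert np.ptp(wls.levels) < 1e-6

    def test_window_longer_than_recording_warns_empty(self):
        rec = sine_recording(500.0, 110.0, 4000, 5.0)
        with pytest.warns(UserWarning):
            wls = m_weighted_level(rec, f_lo=25.0, f_hi=1500.0, window_s=30.0)
        assert wls.levels.size == 0


class TestAmbient:
    def test_constant_series(self):
        tols = make_tol_series(np.full((50, 3), 80.0))
        assert ambient_level(tols, 2000.0) == 80.0

    def test_percentile_against_sort_oracle(self):
        """1..100 dB one epoch each: 5th percentile by linear interpolation
        between order statistics."""
        levels = np.tile(np.arange(1.0, 101.0)[:, None], (1, 3))
        tols = make_tol_series(levels)
        # oracle: numpy-independent linear interpolation between sorted values
        x = np.sort(levels[:, 0])
        h = 0.05 * (len(x) - 1)
        lo = int(np.floor(h))
        oracle = x[lo] + (h - lo) * (x[lo + 1] - x[lo])
        assert ambient_level(tols, 125.0) == pytest.approx(oracle)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        levels = rng.normal(80, 5, (200, 3))
        a = ambient_level(make_tol_series(levels), 2000.0)
        b = ambient_level(make_tol_series(levels + 10.0), 2000.0)
        assert b == pytest.approx(a + 10.0)

    def test_ambient_below_median(self):
        rng = np.random.default_rng(6)
        levels = rng.normal(80, 5, (500, 3))
        tols = make_tol_series(levels)
        assert ambient_level(tols, 125.0) <= np.median(levels[:, 0])

    def test_short_series_warns_empty_raises(self):
        with pytest.warns(UserWarning):
            ambient_level(make_tol_series(np.full((5, 3), 70.0)), 125.0)
        with pytest.raises(ValueError):
            ambient_level(make_tol_series(np.full((3, 3), -np.inf)), 125.0)


class TestBandCorrelation:
    def test_identical_and_negated(self):
        rng = np.random.default_rng(8)
        x = rng.normal(80, 4, 100)
        tols = make_tol_series(np.column_stack([x, x, 160 - x]))
        assert band_correlation(tols, 125.0, 2000.0) == pytest.approx(1.0)
        assert band_correlation(tols, 125.0, 16000.0) == pytest.approx(-1.0)

    def test_bivariate_normal_rho_recovered(self):
        rng = np.random.default_rng(9)
        n = 10_000
        z = rng.multivariate_normal([80, 75], [[9, 0.6 * 9], [0.6 * 9, 9]], size=n)
        tols = make_tol_series(np.column_stack([z[:, 0], z[:, 1], z[:, 1]]))
        assert band_correlation(tols, 125.0, 2000.0) == pytest.approx(0.6, abs=0.03)

    def test_zero_variance_flagged_nan(self):
        levels = np.column_stack([np.full(10, 80.0), np.arange(10.0), np.arange(10.0)])
        tols = make_tol_series(levels)
        with pytest.warns(UserWarning):
            assert np.isnan(band_correlation(tols, 125.0, 2000.0))


class TestCutoffFrequency:
    def test_rigid_bottom_limit(self):
        assert cutoff_frequency(20.0, 1500.0) == pytest.approx(18.75)

    def test_soft_bottom_value_found_by_root_solve(self):
        """Find c_bottom giving f0 = 135 Hz numerically, then confirm the
        closed form returns it."""
        target = 135.0
        cb = brentq(lambda c: cutoff_frequency(20.0, 1500.0, c) - target, 1500.5, 3000.0)
        assert cutoff_frequency(20.0, 1500.0, cb) == pytest.approx(target, abs=1e-9)
        # sanity: soft sediment speed only slightly above water speed
        assert 1500.0 < cb < 1600.0

    @given(depth=st.floats(1.0, 200.0), cb=st.floats(1550.0, 5000.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_doubling_depth_halves_cutoff(self, depth, cb):
        f1 = cutoff_frequency(depth, 1500.0, cb)
        f2 = cutoff_frequency(2 * depth, 1500.0, cb)
        assert f2 == pytest.approx(f1 / 2.0, rel=1e-9)

    def test_no_cutoff_when_bottom_slower(self):
        with pytest.warns(UserWarning):
            assert np.isnan(cutoff_frequency(20.0, 1500.0, 1400.0))
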