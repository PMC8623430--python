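"""Frequency-domain predictors against independent DSP oracles."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import epikin as ek
from epikin.errors import DegenerateSignalError
from epikin.spectral_features import FEATURE_COLUMNS, PowerSpectrum

FS = 200.0


def tone(freq, n=1000, amplitude=1.0, phase=0.0, fs=FS):
    t = np.arange(n) / fs
    return amplitude * np.sin(2 * np.pi * freq * t + phase)


def flat_spectrum(m=256, value=1.0):
    freqs = np.linspace(0.0, FS / 2, m)
    return PowerSpectrum(freqs, np.full(m, value), ("kaiser", 38.0), 1.0, 2 * m, 1.0)


class TestPsdEstimate:
    def test_peak_at_bin_centered_tone(self):
        sp = ek.psd_estimate(tone(20.0), FS)  # 20 Hz = bin 100 exactly
        assert sp.frequencies[np.argmax(sp.psd)] == pytest.approx(20.0, abs=sp.df)

    def test_parseval_noiseless(self):
        x = tone(7.4, amplitude=2.3) - (-1.0)  # arbitrary offset, removed internally
        sp = ek.psd_estimate(x, FS)
        w = np.kaiser(x.size, 38.0)
        xc = x - x.mean()
        windowed_ms = np.sum((w * xc) ** 2) / np.sum(w**2)
        assert sp.total_power == pytest.approx(windowed_ms, rel=1e-6)

    def test_white_noise_power_integral(self):
        x = np.random.default_rng(0).normal(0.0, 1.5, 10_000)
        sp = ek.psd_estimate(x, FS)
        assert sp.total_power == pytest.approx(1.5**2, rel=0.05)

    def test_zero_signal_gives_zero_psd(self):
        sp = ek.psd_estimate(np.zeros(1000), FS)
        assert not sp.psd.any()

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            ek.psd_estimate(np.ones(32), FS)


class TestBandPower:
    def test_unit_sine_half(self):
        assert ek.band_power(tone(2.0)) == pytest.approx(0.5, abs=1e-3)

    def test_constant_signal(self):
        assert ek.band_power(np.full(100, 3.0)) == pytest.approx(9.0)

    def test_additivity_with_noise(self):
        rng = np.random.default_rng(1)
        x = tone(5.0) + rng.normal(0.0, 0.2, 1000)
        assert ek.band_power(x) == pytest.approx(0.5 + 0.04, rel=0.1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ek.band_power([])


class TestFundamentalEstimate:
    def test_tone_frequency_within_bin(self):
        sp = ek.psd_estimate(tone(1.5), FS)
        f0, _ = ek.fundamental_estimate(sp)
        assert f0 == pytest.approx(1.5, abs=sp.df)

    def test_tone_power_is_half_amplitude_squared(self):
        sp = ek.psd_estimate(tone(10.0, amplitude=2.0), FS)
        _, power = ek.fundamental_estimate(sp)
        assert power == pytest.approx(2.0, rel=0.02)

    def test_argmax_picks_larger_tone(self):
        sp = ek.psd_estimate(tone(10.0) + tone(40.0, amplitude=0.3), FS)
        f0, _ = ek.fundamental_estimate(sp)
        assert f0 == pytest.approx(10.0, abs=sp.df)

    def test_degenerate_spectrum_rejected(self):
        with pytest.raises(DegenerateSignalError):
            ek.fundamental_estimate(ek.psd_estimate(np.zeros(1000), FS))


class TestSnrSinad:
    def test_known_decomposition_oracle(self):
        """sin(A=1) + noise(sd=0.1): SNR and SINAD ~ 10 log10(0.5/0.01)."""
        expected = 10 * np.log10(0.5 / 0.01)
        snrs, sinads = [], []
        for s in range(100):
            x = tone(1.5) + np.random.default_rng(s).normal(0.0, 0.1, 1000)
            snrs.append(ek.snr_db(x, FS))
            sinads.append(ek.sinad_db(x, FS))
        assert np.median(snrs) == pytest.approx(expected, abs=1.0)
        assert np.median(sinads) == pytest.approx(expected, abs=1.0)

    @pytest.mark.parametrize("c", [0.01, 3.0, 1e4])
    def test_scale_invariance(self, c):
        x = tone(1.5) + np.random.default_rng(2).normal(0.0, 0.1, 1000)
        assert ek.snr_db(c * x, FS) == pytest.approx(ek.snr_db(x, FS), abs=1e-9)
        assert ek.sinad_db(c * x, FS) == pytest.approx(ek.sinad_db(x, FS), abs=1e-9)
        assert ek.sfdr_db(c * x, FS) == pytest.approx(ek.sfdr_db(x, FS), abs=1e-9)

    def test_harmonic_excluded_from_snr_but_not_sinad(self):
        """A -20 dB 3rd harmonic caps SINAD near 20 dB but leaves SNR high."""
        snrs, sinads = [], []
        for s in range(20):
            x = tone(10.0) + tone(30.0, amplitude=0.1) + np.random.default_rng(s).normal(0, 0.006, 1000)
            snrs.append(ek.snr_db(x, FS))
            sinads.append(ek.sinad_db(x, FS))
        assert np.median(snrs) >= 40.0
        assert np.median(sinads) < 20.0

    def test_noiseless_two_tone_sinad(self):
        x = tone(10.0) + tone(30.0, amplitude=0.1)
        assert ek.sinad_db(x, FS) == pytest.approx(20 * np.log10(1 / 0.1), abs=0.5)

    def test_sinad_never_exceeds_snr_on_random_recordings(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            params = ek.MotionModelParams(
                fundamental_freq=rng.uniform(1.0, 3.0),
                amplitudes_x=tuple(rng.uniform(0.5, 8.0) * 0.4 ** np.arange(3)),
                amplitudes_y=tuple(rng.uniform(0.5, 8.0) * 0.4 ** np.arange(3)),
                phases_x=tuple(rng.uniform(0, 2 * np.pi, 3)),
                phases_y=tuple(rng.uniform(0, 2 * np.pi, 3)),
                noise_sd=rng.uniform(0.01, 1.0),
            )
            rec = ek.simulate_trajectory(params, FS, 1.28, seed=rng)
            assert ek.sinad_db(rec.x, FS) <= ek.snr_db(rec.x, FS) + 1e-9

    def test_snr_decreases_with_generator_noise(self):
        medians = []
        for sd in (0.05, 0.1, 0.2, 0.4, 0.8):
            vals = [
                ek.snr_db(tone(1.5) + np.random.default_rng(s).normal(0, sd, 1000), FS)
                for s in range(15)
            ]
            medians.append(np.median(vals))
        assert all(a > b for a, b in zip(medians, medians[1:]))


class TestSfdr:
    @pytest.mark.parametrize("a2,expected", [(0.1, 20.0), (0.5, 20 * np.log10(2.0))])
    def test_two_tone_oracle(self, a2, expected):
        x = tone(10.0) + tone(37.0, amplitude=a2)
        assert ek.sfdr_db(x, FS) == pytest.approx(expected, abs=0.5)


class TestPowerBandwidth:
    def test_windowed_tone_matches_window_3db_width(self):
        n = 1000
        sp = ek.psd_estimate(tone(20.0, n=n), FS)
        # oracle: 3 dB width of the Kaiser(38) transform, computed directly
        mag2 = np.abs(np.fft.rfft(np.kaiser(n, 38.0), 32 * n)) ** 2
        half = mag2[0] / 2
        i = int(np.argmax(mag2 < half))
        frac = (mag2[i - 1] - half) / (mag2[i - 1] - mag2[i])
        oracle = 2 * ((i - 1 + frac) / 32) * (FS / n)
        assert ek.power_bandwidth(sp) == pytest.approx(oracle, abs=FS / n)

    def test_white_noise_is_broadband(self):
        sp = ek.psd_estimate(np.random.default_rng(0).normal(0, 1, 10_000), FS)
        assert ek.power_bandwidth(sp) >= 0  # defined; order of magnitude only
        assert ek.occupied_bandwidth(sp) >= 0.5 * sp.nyquist

    def test_resolution_scaling(self):
        bw_long = ek.power_bandwidth(ek.psd_estimate(tone(20.0, n=2000), FS))
        bw_short = ek.power_bandwidth(ek.psd_estimate(tone(20.0, n=1000), FS))
        assert bw_short == pytest.approx(2 * bw_long, rel=0.2)

    def test_flat_spectrum_full_band_with_warning(self):
        with pytest.warns(RuntimeWarning):
            bw = ek.power_bandwidth(flat_spectrum())
        assert bw == pytest.approx(FS / 2)


class TestOccupiedBandwidth:
    def test_white_noise_99_percent(self):
        sp = ek.psd_estimate(np.random.default_rng(4).normal(0, 1, 10_000), FS)
        assert ek.occupied_bandwidth(sp) == pytest.approx(0.99 * 100.0, rel=0.02)

    def test_pure_tone_is_narrow(self):
        sp = ek.psd_estimate(tone(20.0), FS)
        assert ek.occupied_bandwidth(sp) <= 10 * sp.df

    def test_fraction_one_spans_full_band(self):
        sp = flat_spectrum()
        full = sp.frequencies[-1] - sp.frequencies[0]
        assert ek.occupied_bandwidth(sp, fraction=1.0) == pytest.approx(full)

    def test_zero_power_rejected(self):
        with pytest.raises(DegenerateSignalError):
            ek.occupied_bandwidth(flat_spectrum(value=0.0))


class TestSpectralEntropy:
    def test_flat_spectrum_is_one(self):
        assert ek.spectral_entropy(flat_spectrum()) == pytest.approx(1.0)

    def test_single_bin_is_zero(self):
        sp = flat_spectrum(value=0.0)
        psd = sp.psd.copy()
        psd[40] = 5.0
        single = PowerSpectrum(sp.frequencies, psd, sp.window, 1.0, sp.n_samples, 1.0)
        assert ek.spectral_entropy(single) == 0.0

    def test_white_noise_is_near_one(self):
        vals = [
            ek.spectral_entropy(ek.psd_estimate(np.random.default_rng(s).normal(0, 1, 10_000), FS))
            for s in range(100)
        ]
        assert np.median(vals) >= 0.9

    def test_bounds_on_cohort(self, feature_table):
        assert (feature_table["spectral_entropy_x"].between(0, 1)).all()
        assert (feature_table["spectral_entropy_y"].between(0, 1)).all()


class TestFeatureVector:
    def test_column_order_and_shape(self, feature_table):
        assert feature_table.shape == (86, 18)
        assert not feature_table[list(FEATURE_COLUMNS)].isna().any().any()
        assert list(feature_table.columns[3:17]) == list(FEATURE_COLUMNS)

    def test_deterministic(self, cohort):
        a = ek.extract_feature_vector(cohort[0])
        b = ek.extract_feature_vector(cohort[0])
        assert (a == b).all()

    def test_degenerate_axis_is_identified(self):
        rec = ek.TrajectoryRecording("d", "unknown", FS, tone(1.5), np.zeros(1000), recording_id="deg")
        with pytest.raises(DegenerateSignalError, match="axis y"):
            ek.extract_feature_vector(rec)

    def test_translation_moves_only_band_power(self, cohort):
        rec = cohort[2]
        shifted = ek.TrajectoryRecording(rec.patient_id, rec.phase, rec.sampling_rate,
                                         rec.x + 250.0, rec.y + 250.0)
        a, b = ek.extract_feature_vector(rec), ek.extract_feature_vector(shifted)
        for col in FEATURE_COLUMNS:
            if col.startswith("band_power"):
                assert b[col] > a[col]  # raw-signal power is offset-sensitive
            else:
                assert b[col] == pytest.approx(a[col], rel=1e-9, abs=1e-9)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(
        freq=st.floats(1.0, 40.0),
        amp=st.floats(0.5, 20.0),
        sd=st.floats(0.01, 0.5),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_db_metrics_scale_invariant_property(self, freq, amp, sd, seed):
        x = tone(freq, amplitude=amp) + np.random.default_rng(seed).normal(0, sd, 1000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            assert ek.snr_db(10 * x, FS) == pytest.approx(ek.snr_db(x, FS), abs=1e-8)
            assert ek.sinad_db(x, FS) <= ek.snr_db(x, FS) + 1e-9
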