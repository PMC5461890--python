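"""Feature extraction: oracle agreement, analytic cases, and invariances."""

import numpy as np
import pytest

from neoburst.features import (
    DEFAULT_BANDS,
    FEATURE_FS,
    TOTAL_BAND,
    bandpass,
    default_feature_set,
    downsample,
    edo,
    envelope,
    expand_to_samples,
    extract_features,
    frame_count,
    frame_signal,
    higuchi_fd,
    instantaneous_frequency,
    line_length,
    loglog_psd_fit,
    mean_frequency,
    nleo,
    relative_psd_power,
    transform_and_zscore,
)

import _oracles as orc


def tone(f, fs, dur, amp=1.0, phase=0.0):
    return amp * np.sin(2 * np.pi * f * np.arange(int(dur * fs)) / fs + phase)


# ---------------------------------------------------------------------------
# Vectorised implementations match literal brute-force definitions
# ---------------------------------------------------------------------------

N_ORACLE_WINDOWS = 10  # the acceptance suite runs the full 100-window sweep


@pytest.fixture(scope="module")
def windows64():
    r = np.random.default_rng(11)
    return [r.standard_normal(128) for _ in range(N_ORACLE_WINDOWS)]


@pytest.fixture(scope="module")
def windows256():
    r = np.random.default_rng(12)
    return [r.standard_normal(512) for _ in range(N_ORACLE_WINDOWS)]


class TestOracleAgreement:
    """Each feature equals its loop-over-definition oracle on random windows."""

    def test_envelope(self, windows64):
        for w in windows64:
            np.testing.assert_allclose(envelope(w), orc.envelope_oracle(w), atol=1e-9)

    @pytest.mark.parametrize("band", DEFAULT_BANDS)
    def test_relative_power(self, windows64, band):
        for w in windows64:
            assert relative_psd_power(w, 64.0, band) == pytest.approx(
                orc.relative_power_oracle(w, 64.0, band), abs=1e-9
            )

    @pytest.mark.parametrize("band", DEFAULT_BANDS)
    def test_loglog_fit(self, windows64, band):
        for w in windows64:
            s, r2 = loglog_psd_fit(w, 64.0, band)
            so, r2o = orc.loglog_fit_oracle(w, 64.0, band)
            assert s == pytest.approx(so, abs=1e-9)
            assert r2 == pytest.approx(r2o, abs=1e-9)

    def test_mean_frequency(self, windows64):
        for w in windows64:
            assert mean_frequency(w, 64.0) == pytest.approx(
                orc.mean_frequency_oracle(w, 64.0), abs=1e-9
            )

    def test_instantaneous_frequency(self, windows64):
        for w in windows64:
            np.testing.assert_allclose(
                instantaneous_frequency(w, 64.0),
                orc.instantaneous_frequency_oracle(w, 64.0),
                atol=1e-9,
            )

    def test_higuchi(self, windows64):
        for w in windows64:
            assert higuchi_fd(w[:64], 8) == pytest.approx(
                orc.higuchi_oracle(w[:64], 8), abs=1e-9
            )

    def test_nleo(self, windows256):
        for w in windows256:
            np.testing.assert_allclose(nleo(w), orc.nleo_oracle(w), atol=1e-9)

    def test_line_length(self, windows256):
        for w in windows256:
            assert line_length(w) == pytest.approx(
                orc.line_length_oracle(w), abs=1e-9
            )

    @pytest.mark.parametrize("printed_sign", [False, True])
    def test_edo(self, windows256, printed_sign):
        for w in windows256:
            np.testing.assert_allclose(
                edo(w, printed_sign), orc.edo_oracle(w, printed_sign), atol=1e-9
            )


# ---------------------------------------------------------------------------
# Analytic cases
# ---------------------------------------------------------------------------

class TestAnalyticSignals:
    def test_envelope_of_tone_is_amplitude_squared(self):
        a = envelope(tone(5, 64, 10, amp=3.0))[64:-64]
        np.testing.assert_allclose(a, 9.0, rtol=0.01)

    def test_envelope_of_zero(self):
        assert np.all(envelope(np.zeros(256)) == 0)

    def test_envelope_tracks_slow_modulation(self):
        fs = 64.0
        t = np.arange(int(20 * fs)) / fs
        amp = 2.0 + np.sin(2 * np.pi * 0.1 * t)
        x = amp * np.sin(2 * np.pi * 8 * t)
        a = envelope(x)[128:-128]
        np.testing.assert_allclose(a, amp[128:-128] ** 2, rtol=0.05)

    def test_edo_tone_gives_amplitude_frequency_product(self):
        fs, f0, A = 256.0, 4.0, 3.0
        w = 2 * np.pi * f0 / fs
        g = edo(A * np.cos(w * np.arange(2560)))[256:-256]
        np.testing.assert_allclose(g, A**2 * np.sin(w) ** 2, rtol=0.01)

    def test_edo_monotone_in_frequency(self):
        fs = 256.0
        vals = []
        for f0 in [1, 2, 4, 6, 8, 9.5]:
            g = edo(np.cos(2 * np.pi * f0 / fs * np.arange(2560)))[256:-256]
            vals.append(np.median(g))
        assert np.all(np.diff(vals) > 0)

    def test_nleo_of_constant_is_zero(self):
        assert np.all(nleo(np.full(100, 5.0)) == 0)

    def test_nleo_tone_matches_direct_summation(self):
        fs = 256.0
        x = np.cos(2 * np.pi * 5 / fs * np.arange(512))
        np.testing.assert_allclose(nleo(x), orc.nleo_oracle(x), atol=1e-9)

    def test_line_length_step_sequence(self):
        assert line_length([0, 1, 0, 1]) == 3.0

    def test_line_length_constant(self):
        assert line_length(np.full(50, 2.5)) == 0.0

    def test_mean_frequency_recovers_tone(self):
        w = tone(10, 64, 2)
        assert mean_frequency(w, 64.0) == pytest.approx(10.0, abs=0.5)

    def test_mean_frequency_two_tones_circular_mean(self):
        w = tone(9, 64, 2) + tone(11, 64, 2)
        assert mean_frequency(w, 64.0) == pytest.approx(10.0, abs=0.5)

    def test_instantaneous_frequency_of_tone(self):
        f = instantaneous_frequency(tone(5, 64, 4), 64.0)
        np.testing.assert_allclose(f[16:-16], 5.0, atol=1e-3)

    def test_instantaneous_frequency_sign_invariance(self):
        x = bandpass(np.random.default_rng(3).standard_normal(1024), 64.0, (3, 8))
        np.testing.assert_allclose(
            instantaneous_frequency(x, 64.0),
            instantaneous_frequency(-x, 64.0),
            atol=1e-9,
        )

    def test_chirp_median_instantaneous_frequency(self):
        from scipy.signal import chirp

        fs = 64.0
        t = np.arange(int(2 * fs)) / fs
        x = chirp(t, f0=2, f1=8, t1=2.0)
        f = instantaneous_frequency(x, fs)
        assert np.median(f) == pytest.approx(5.0, abs=0.5)


# ---------------------------------------------------------------------------
# Spectral shape
# ---------------------------------------------------------------------------

def exact_power_law_window(n=128, exponent=-2.0):
    """Signal whose DFT magnitude-squared is exactly k^exponent."""
    mag = np.zeros(n // 2 + 1)
    k = np.arange(1, n // 2 + 1)
    mag[1:] = k ** (exponent / 2)
    return np.fft.irfft(mag, n)


class TestSpectralShape:
    @pytest.mark.parametrize("band", DEFAULT_BANDS)
    def test_exact_power_law_slope(self, band):
        s, r2 = loglog_psd_fit(exact_power_law_window(), 64.0, band)
        assert s == pytest.approx(-2.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_flat_spectrum_degenerate_r2(self):
        s, r2 = loglog_psd_fit(exact_power_law_window(exponent=0.0), 64.0, (3, 8))
        assert s == pytest.approx(0.0, abs=1e-9)
        assert r2 == 1.0

    def test_band_powers_tile_to_one(self, rng):
        x = rng.standard_normal(128)
        total = sum(relative_psd_power(x, 64.0, b) for b in DEFAULT_BANDS)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_tone_power_concentrates_in_its_band(self):
        w = tone(5, 64, 2)
        powers = [relative_psd_power(w, 64.0, b) for b in DEFAULT_BANDS]
        assert powers[1] >= 0.95
        assert all(p <= 0.05 for i, p in enumerate(powers) if i != 1)

    def test_coloured_noise_slope_recovery(self):
        rng = np.random.default_rng(5)
        slopes = []
        for _ in range(200):
            X = (np.random.default_rng(rng.integers(2**31)).standard_normal(65)
                 + 0j)
            f = np.arange(65, dtype=float)
            f[0] = 1
            x = np.fft.irfft(X * f ** (-0.75), 128)
            slopes.append(loglog_psd_fit(x, 64.0, (3, 8))[0])
        assert np.median(slopes) == pytest.approx(-1.5, abs=0.3)

    def test_too_few_bins_raises(self):
        with pytest.raises(ValueError, match="bins"):
            loglog_psd_fit(np.random.default_rng(0).standard_normal(32), 64.0, (0.5, 1))

    def test_higuchi_line(self):
        assert higuchi_fd(np.arange(64.0)) == pytest.approx(1.0, abs=0.05)

    def test_higuchi_white_noise(self):
        r = np.random.default_rng(6)
        d = np.median([higuchi_fd(r.standard_normal(64)) for _ in range(100)])
        assert d == pytest.approx(2.0, abs=0.15)

    def test_higuchi_sinusoid_near_one(self):
        d = higuchi_fd(tone(2, 64, 1))
        assert 1.0 <= d <= 1.3

    def test_higuchi_constant_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(higuchi_fd(np.ones(64)))


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

class TestBandpass:
    def test_dc_rejected(self):
        y = bandpass(np.full(1024, 10.0), 64.0, (0.5, 3))
        assert np.abs(y.mean()) < 1e-6 * 10.0

    def test_passband_centre_preserved(self):
        x = tone(5.0, 64.0, 30)
        y = bandpass(x, 64.0, (3, 8))
        mid = slice(320, -320)
        rms_ratio = np.std(y[mid]) / np.std(x[mid])
        assert rms_ratio == pytest.approx(1.0, abs=0.01)

    def test_zero_phase_shift_on_tone(self):
        # forward-backward filtering leaves the passband phase untouched
        fs, f0 = 64.0, 5.0
        x = tone(f0, fs, 30)
        y = bandpass(x, fs, (3, 8))
        seg = slice(320, 320 + 1024)
        k = int(f0 * 1024 / fs)
        phase_in = np.angle(np.fft.fft(x[seg])[k])
        phase_out = np.angle(np.fft.fft(y[seg])[k])
        assert abs(phase_out - phase_in) < 1e-3

    def test_time_reversal_symmetry_away_from_edges(self):
        x = np.random.default_rng(1).standard_normal(2048)
        y_fwd = bandpass(x, 64.0, (3, 8))
        y_rev = bandpass(x[::-1], 64.0, (3, 8))[::-1]
        np.testing.assert_allclose(y_fwd[512:-512], y_rev[512:-512], atol=1e-9)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(256), 64.0, (15, 40))


# ---------------------------------------------------------------------------
# Framing and the 64 Hz grid
# ---------------------------------------------------------------------------

class TestFraming:
    def test_window_count_10s(self):
        # 2 s window, 75% overlap -> 0.5 s hop: floor((10-2)/0.5) + 1
        assert frame_count(640, 64.0, 2.0) == 17

    def test_constant_feature_expands_constant(self):
        vals = np.full(33, 3.14)
        out = expand_to_samples(vals, 640, 64.0, 2.0)
        assert np.all(out == 3.14)

    def test_expansion_length_matches_record(self, short_record):
        rec, _ = short_record
        fm = extract_features(rec.samples[0], rec.fs)
        assert fm.values.shape[0] == int(rec.duration_s * FEATURE_FS)

    def test_too_short_record_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            frame_signal(np.zeros(64), 64.0, 2.0)


# ---------------------------------------------------------------------------
# Full extraction pipeline
# ---------------------------------------------------------------------------

class TestExtraction:
    def test_default_bands_tile_total_band(self):
        from neoburst.features import BandSet

        assert BandSet().tiles_total
        assert not BandSet(((0.5, 3), (4, 8))).tiles_total
        with pytest.raises(ValueError):
            BandSet(((3, 0.5),))

    def test_default_set_has_26_features(self):
        specs = default_feature_set()
        assert len(specs) == 26
        by_name: dict = {}
        for s in specs:
            by_name.setdefault(s.name, []).append(s)
        assert len(by_name["edo"]) == 1
        assert len(by_name["fd"]) == 1
        for fam in ("envelope", "rel_power", "mean_freq", "inst_freq",
                    "psd_slope", "psd_r2"):
            assert len(by_name[fam]) == 4
            assert sorted(s.band for s in by_name[fam]) == [0, 1, 2, 3]
        # window structure: spectral families 2 s, amplitude / FD 1 s
        assert by_name["fd"][0].window_s == 1.0
        assert all(s.window_s == 1.0 for s in by_name["envelope"])
        for fam in ("rel_power", "mean_freq", "inst_freq", "psd_slope", "psd_r2"):
            assert all(s.window_s == 2.0 for s in by_name[fam])

    def test_matrix_is_nan_free(self, short_record):
        rec, _ = short_record
        fm = extract_features(rec.samples[0], rec.fs)
        assert np.isfinite(fm.values).all()

    def test_amplitude_scaling_behaviour(self, short_record):
        """Energy features scale with amplitude², shape features not at all."""
        rec, _ = short_record
        x = rec.samples[0][: 256 * 30]
        a = extract_features(x, 256.0)
        b = extract_features(10.0 * x, 256.0)
        for j, spec in enumerate(a.specs):
            if spec.name in ("edo", "envelope"):
                np.testing.assert_allclose(
                    b.values[:, j], 100.0 * a.values[:, j], rtol=1e-9,
                    err_msg=spec.column,
                )
            else:  # fd, rel_power, mean_freq, inst_freq, psd_slope, psd_r2
                np.testing.assert_allclose(
                    b.values[:, j], a.values[:, j], atol=1e-9,
                    err_msg=spec.column,
                )

    def test_edo_stream_non_negative(self, rng):
        from neoburst.features import edo_stream

        for _ in range(25):
            x = rng.standard_normal(1024) * rng.uniform(0.5, 50)
            assert edo_stream(x, 256.0).min() >= -1e-12

    def test_edo_operator_non_negative_many(self, rng):
        for _ in range(1000):
            x = rng.standard_normal(64) * rng.uniform(0.1, 100)
            assert edo(x).min() >= -1e-12

    def test_downsample_factor(self):
        x = np.random.default_rng(2).standard_normal(1024)
        assert downsample(x, 256.0, 64.0).size == 256


class TestTransform:
    def test_zscore_normalises(self, short_record):
        rec, _ = short_record
        fm = extract_features(rec.samples[0], rec.fs)
        z, (mean, sd) = transform_and_zscore(fm)
        np.testing.assert_allclose(z.values.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(z.values.std(axis=0), 1, atol=1e-9)

    def test_training_stats_reproduce_self_normalisation(self, short_record):
        rec, _ = short_record
        fm = extract_features(rec.samples[0], rec.fs)
        z1, stats = transform_and_zscore(fm)
        z2, _ = transform_and_zscore(fm, stats)
        np.testing.assert_array_equal(z1.values, z2.values)

    def test_log_of_unit_envelope_is_zero(self):
        from neoburst.features import FeatureMatrix, FeatureSpec

        spec = [FeatureSpec("envelope", 0, 1.0, "MEDIAN", True),
                FeatureSpec("fd", None, 1.0, "SCALAR", False)]
        vals = np.column_stack([np.ones(100), np.linspace(1, 2, 100)])
        fm = FeatureMatrix(vals, spec)
        z, (mean, sd) = transform_and_zscore(fm, (np.array([0.0, 0.0]),
                                                  np.array([1.0, 1.0])))
        assert np.all(z.values[:, 0] == 0)

    def test_zero_variance_column_rejected(self):
        from neoburst.features import FeatureMatrix, FeatureSpec

        spec = [FeatureSpec("fd", None, 1.0, "SCALAR", False)]
        fm = FeatureMatrix(np.ones((50, 1)), spec)
        with pytest.raises(ValueError, match="fd"):
            transform_and_zscore(fm)
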