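"""Spectral preprocessing: filters, channel QC, Morlet decomposition."""

import numpy as np
import pytest

from netlag.preprocess import (BAND_TABLE, BandEnvelope, band_average,
                               common_average_reference, lognorm,
                               morlet_frequencies, notch_filter, qc_channels,
                               smooth_envelope, wavelet_power)
from netlag.synth import Recording


def make_rec(data, fs=1000.0):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return Recording(data, fs, [f"ch{i}" for i in range(data.shape[0])])


FS = 1000.0
T = np.arange(int(20 * FS)) / FS


class TestNotch:
    def test_line_component_removed(self):
        rec = make_rec(np.sin(2 * np.pi * 60.0 * T))
        out = notch_filter(rec, 60.0)
        rms_in = np.sqrt(np.mean(rec.data ** 2))
        rms_out = np.sqrt(np.mean(out.data[0, 1000:-1000] ** 2))
        assert rms_out < 0.05 * rms_in

    def test_passband_preserved(self):
        rec = make_rec(np.sin(2 * np.pi * 10.0 * T))
        out = notch_filter(rec, 60.0)
        rms_in = np.sqrt(np.mean(rec.data ** 2))
        rms_out = np.sqrt(np.mean(out.data[0, 1000:-1000] ** 2))
        assert abs(rms_out - rms_in) / rms_in < 0.01

    def test_zero_in_zero_out(self):
        out = notch_filter(make_rec(np.zeros_like(T)), 60.0)
        assert np.allclose(out.data, 0.0)

    def test_harmonics_above_nyquist_rejected(self):
        rec = make_rec(np.zeros(3000), fs=300.0)
        with pytest.raises(ValueError):
            notch_filter(rec, 60.0)   # 183 Hz stop band vs 150 Hz Nyquist


class TestQCAndCAR:
    def test_high_variance_channel_flagged(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((10, 5000))
        data[3] *= 10.0
        qc = qc_channels(make_rec(data))
        assert qc.excluded[3] and "variance" in qc.reasons[3]
        assert np.sum(qc.excluded) == 1

    def test_jumpy_channel_flagged(self):
        rng = np.random.default_rng(1)
        data = 5.0 * rng.standard_normal((8, 5000))
        # baseline: 2 jumps on every channel so the median count is nonzero
        for i in range(8):
            data[i, 100 + i] += 150.0
            data[i, 300 + i] += 150.0
        for k in range(7):      # 3x median (=2) + 1 extra on channel 5
            data[5, 500 + 40 * k] += 150.0
        qc = qc_channels(make_rec(data))
        assert qc.excluded[5] and "jumps" in qc.reasons[5]

    def test_homogeneous_channels_pass(self):
        rng = np.random.default_rng(2)
        qc = qc_channels(make_rec(rng.standard_normal((6, 4000))))
        assert not qc.excluded.any()

    def test_pathology_list_respected(self):
        rng = np.random.default_rng(3)
        qc = qc_channels(make_rec(rng.standard_normal((4, 1000))),
                         pathology_list=("ch2",))
        assert qc.excluded[2] and qc.reasons[2] == ("pathology",)

    def test_car_zeroes_included_mean(self):
        rng = np.random.default_rng(4)
        rec = make_rec(rng.standard_normal((6, 2000)))
        qc = qc_channels(rec)
        out = common_average_reference(rec, qc)
        assert np.allclose(out.data[qc.included()].mean(axis=0), 0, atol=1e-12)

    def test_excluded_channel_does_not_leak(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((5, 2000))
        data[0] *= 20.0
        rec = make_rec(data)
        qc = qc_channels(rec)
        assert qc.excluded[0]
        out = common_average_reference(rec, qc)
        manual = data[1] - data[1:].mean(axis=0)
        assert np.allclose(out.data[1], manual)

    def test_all_excluded_errors(self):
        rec = make_rec(np.random.default_rng(6).standard_normal((3, 500)))
        qc = qc_channels(rec, pathology_list=("ch0", "ch1", "ch2"))
        with pytest.raises(ValueError):
            common_average_reference(rec, qc)


class TestWavelet:
    def test_sinusoid_peaks_at_nearest_bin(self):
        rec = make_rec(2.5 * np.sin(2 * np.pi * 10.0 * T))
        amp, freqs, valid = wavelet_power(rec)
        interior = amp[0][:, valid]
        profile = interior.mean(axis=1)
        assert np.argmax(profile) == np.argmin(np.abs(freqs - 10.0))

    def test_on_grid_sinusoid_amplitude_recovered(self):
        freqs = morlet_frequencies()
        f0 = freqs[np.argmin(np.abs(freqs - 10.0))]
        rec = make_rec(2.5 * np.sin(2 * np.pi * f0 * T))
        amp, _, valid = wavelet_power(rec)
        profile = amp[0][:, valid].mean(axis=1)
        assert profile.max() == pytest.approx(2.5, rel=0.02)

    def test_zero_signal_zero_power(self):
        amp, _, _ = wavelet_power(make_rec(np.zeros_like(T)))
        assert np.allclose(amp, 0.0, atol=1e-10)

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError):
            wavelet_power(make_rec(np.zeros(2000)))   # 2 s < 7 s support at 1 Hz

    def test_edge_samples_flagged(self):
        rec = make_rec(np.random.default_rng(0).standard_normal(len(T)))
        _, freqs, valid = wavelet_power(rec)
        half = int(np.ceil(0.5 * 7.0 / freqs.min() * FS))
        assert not valid[:half].any() and not valid[-half:].any()
        assert valid[half:-half].all()


class TestLognorm:
    def test_constant_series_maps_to_zero(self):
        out = lognorm(np.full((2, 3, 100), 7.0))
        assert np.allclose(out, 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0.5, 2.0, size=(2, 4, 200))
        assert np.allclose(lognorm(x), lognorm(3.7 * x))

    def test_hand_computed_alternating_series(self):
        x = np.tile([1.0, 2.0], 50)[None, None, :]
        out = lognorm(x)[0, 0]
        assert out[0] == pytest.approx(np.log10(1 / 1.5))
        assert out[1] == pytest.approx(np.log10(2 / 1.5))

    def test_ratio_mode_mean_power_identity(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0.1, 5.0, size=(3, 5, 400))
        out = lognorm(x, mode="ratio")
        assert np.allclose((10.0 ** out).mean(axis=-1), 1.0)

    def test_log_mean_mode_zero_time_mean(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0.1, 5.0, size=(3, 5, 400))
        out = lognorm(x, mode="log_mean")
        assert np.allclose(out.mean(axis=-1), 0.0, atol=1e-12)

    def test_double_normalization_differs(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(0.5, 2.0, size=(1, 2, 300))
        once = lognorm(x)
        with pytest.raises(ValueError):
            lognorm(once)    # output spans negative values -> caught

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            lognorm(np.zeros((1, 1, 10)))


class TestBandAverage:
    def test_constant_tensor(self):
        freqs = morlet_frequencies()
        tensor = np.full((2, len(freqs), 50), 3.3)
        out, names = band_average(tensor, freqs)
        assert names == tuple(BAND_TABLE)
        assert np.allclose(out, 3.3)

    def test_default_grid_band_membership(self):
        freqs = morlet_frequencies()
        counts = {}
        for name, (lo, hi) in BAND_TABLE.items():
            counts[name] = int(np.sum((freqs >= lo) & (freqs <= hi)))
        # independent oracle: recompute the log-spaced grid and scan
        oracle = 10 ** np.linspace(0, np.log10(170), 38)
        for name, (lo, hi) in BAND_TABLE.items():
            assert counts[name] == np.sum((oracle >= lo) & (oracle <= hi))
            assert counts[name] >= 1
        # no frequency belongs to more than one band (intervals are disjoint;
        # grid points falling in the gaps between band edges belong to none)
        per_freq = np.zeros(len(freqs), dtype=int)
        for lo, hi in BAND_TABLE.values():
            per_freq += ((freqs >= lo) & (freqs <= hi)).astype(int)
        assert per_freq.max() == 1

    def test_missing_band_rejected(self):
        with pytest.raises(ValueError):
            band_average(np.ones((1, 3, 10)), np.array([50.0, 60.0, 65.0]))


class TestSmoothing:
    def _env(self, data, fs=1000.0):
        data = np.asarray(data, dtype=float)[None, None, :]
        return BandEnvelope(data, fs, ["ch0"], ("hfb",))

    def test_constant_preserved(self):
        out = smooth_envelope(self._env(np.full(2000, 1.7)), 50.0)
        assert np.allclose(out.data, 1.7)

    def test_impulse_mass_preserved(self):
        x = np.zeros(2001)
        x[1000] = 1.0
        out = smooth_envelope(self._env(x), 50.0)
        assert out.data.sum() == pytest.approx(1.0, abs=1e-9)
        assert out.data.max() < 1.0

    def test_sinusoid_attenuation_matches_gaussian_transfer(self):
        fs = 1000.0
        f = 0.5
        tt = np.arange(int(40 * fs)) / fs
        out = smooth_envelope(self._env(np.sin(2 * np.pi * f * tt), fs), 50.0)
        sigma_s = 0.05 / (2 * np.sqrt(2 * np.log(2)))
        expected = np.exp(-2 * (np.pi * sigma_s * f) ** 2)
        measured = out.data[0, 0, 2000:-2000].std() * np.sqrt(2)
        assert measured == pytest.approx(expected, rel=0.01)
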