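"""Welch estimator, dB normalisation and band-feature construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurodrive.spectral import (BandFeatures, BandPowerVectorizer, PSDNormalizer,
                                 WelchConfig, WelchPSD, band_bin_indices,
                                 combined_band_vector, extract_bands,
                                 periodogram_oracle, psd_to_db_norm, welch_psd,
                                 window_norm_factor, segment_data, PSDMatrix)


class TestSegmentation:
    @pytest.mark.parametrize("N,M,overlap,expected", [
        (6, 3, 0.0, 2),
        (100, 50, 0.5, 3),
        (7, 7, 0.0, 1),
    ])
    def test_segment_count(self, N, M, overlap, expected):
        cfg = WelchConfig(M=M, overlap=overlap, window="rectangular")
        x = np.arange(N, dtype=float)
        segs = segment_data(x, cfg)
        assert segs.shape == (expected, M)
        # exhaustive enumeration oracle
        step = cfg.step
        starts = [s for s in range(0, N - M + 1, step)]
        assert len(starts) == expected
        for i, s in enumerate(starts):
            np.testing.assert_array_equal(segs[i], x[s:s + M])

    def test_single_segment_equals_input(self):
        x = np.arange(5.0)
        segs = segment_data(x, WelchConfig(M=5))
        np.testing.assert_array_equal(segs[0], x)

    def test_segment_longer_than_input_errors(self):
        with pytest.raises(ValueError):
            segment_data(np.zeros(3), WelchConfig(M=5))


class TestWindowNorm:
    @pytest.mark.parametrize("M", [1, 7, 100])
    def test_rectangular_is_one(self, M):
        assert window_norm_factor("rectangular", M) == pytest.approx(1.0)

    @pytest.mark.parametrize("window,M", [("hanning", 100), ("hamming", 64)])
    def test_matches_naive_sum(self, window, M):
        from neurodrive.spectral import window_weights

        w = window_weights(window, M)
        naive = sum(float(w[n]) ** 2 for n in range(M)) / M
        assert window_norm_factor(window, M) == pytest.approx(naive, abs=1e-12)

    def test_unknown_window_errors(self):
        with pytest.raises(ValueError):
            window_norm_factor("blackmanharris9000", 10)


class TestWelch:
    def test_rectangular_single_segment_is_plain_periodogram(self, rng):
        x = rng.standard_normal(100)
        cfg = WelchConfig(M=100, window="rectangular")
        psd = welch_psd(x, 100.0, cfg).values[:, 0]
        # plain periodogram: |FFT|^2 / (M fs), one-sided doubling
        spec = np.abs(np.fft.rfft(x)) ** 2 / (100 * 100.0)
        spec[1:-1] *= 2
        np.testing.assert_allclose(psd, spec, atol=1e-12)

    def test_sinusoid_peak_at_10hz(self):
        t = np.arange(100) / 100.0
        x = np.sin(2 * np.pi * 10 * t)
        psd = welch_psd(x, 100.0, WelchConfig(M=100, window="rectangular"))
        assert psd.freqs[np.argmax(psd.values[:, 0])] == pytest.approx(10.0)

    def test_parseval_white_noise(self):
        """Integrated PSD approximates the signal variance (mean over seeds)."""
        ratios = []
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(100)
            psd = welch_psd(x, 100.0, WelchConfig())
            df = psd.freqs[1] - psd.freqs[0]
            ratios.append(psd.values[:, 0].sum() * df / x.var())
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    @pytest.mark.parametrize("cfg", [
        WelchConfig(M=100, window="hanning"),
        WelchConfig(M=50, overlap=0.5, window="hamming"),
        WelchConfig(M=64, overlap=0.25, window="rectangular", nfft=128),
    ])
    def test_equals_naive_periodogram_averaging(self, cfg, rng):
        x = rng.standard_normal(200)
        mine = welch_psd(x, 100.0, cfg).values[:, 0]
        np.testing.assert_allclose(mine, periodogram_oracle(x, 100.0, cfg),
                                   atol=1e-10)

    def test_matches_scipy(self, rng):
        from scipy.signal import welch as scipy_welch
        from neurodrive.spectral import window_weights

        x = rng.standard_normal(300)
        cfg = WelchConfig(M=100, overlap=0.5, window="hanning")
        mine = welch_psd(x, 100.0, cfg).values[:, 0]
        _, ref = scipy_welch(x, fs=100.0, window=window_weights("hanning", 100),
                             nperseg=100, noverlap=50, detrend=False,
                             scaling="density")
        np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_nonnegative_and_quadratic_in_amplitude(self, rng):
        x = rng.standard_normal((3, 100))
        p1 = welch_psd(x, 100.0).values
        p2 = welch_psd(2 * x, 100.0).values
        assert (p1 >= 0).all()
        np.testing.assert_allclose(p2, 4 * p1, rtol=1e-10)


class TestDbNormalisation:
    def test_zero_mean_unit_sd_per_channel(self, rng):
        psd = welch_psd(rng.standard_normal((5, 100)), 100.0)
        out = psd_to_db_norm(psd)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.values.std(axis=0), 1.0, atol=1e-10)

    def test_power_scale_invariance(self, rng):
        psd = welch_psd(rng.standard_normal((2, 100)), 100.0)
        scaled = PSDMatrix(psd.values * 100.0, psd.freqs)
        np.testing.assert_allclose(psd_to_db_norm(psd).values,
                                   psd_to_db_norm(scaled).values, atol=1e-10)

    def test_manual_toy_matrix(self):
        # 3 bins x 2 channels, hand-computed
        vals = np.array([[1.0, 10.0], [10.0, 100.0], [100.0, 1000.0]])
        psd = PSDMatrix(vals, np.array([0.0, 1.0, 2.0]))
        out = psd_to_db_norm(psd)
        # dB columns are [0,10,20] and [10,20,30]: mean 10/20, sd sqrt(200/3)
        sd = np.sqrt(200.0 / 3.0)
        expected = np.array([[-10.0, -10.0], [0.0, 0.0], [10.0, 10.0]]) / sd
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_degenerate_channel_zero_filled(self):
        vals = np.array([[1.0, 2.0], [1.0, 4.0], [1.0, 8.0]])
        out = psd_to_db_norm(PSDMatrix(vals, np.arange(3.0)))
        assert out.degenerate_channels == [0]
        np.testing.assert_array_equal(out.values[:, 0], 0.0)

    def test_double_conversion_rejected(self):
        psd = PSDMatrix(np.ones((3, 1)), np.arange(3.0), in_db=True)
        with pytest.raises(ValueError):
            psd_to_db_norm(psd)


class TestBands:
    def _psd59(self, fill=0.0):
        freqs = np.fft.rfftfreq(100, 0.01)
        return PSDMatrix(np.full((51, 59), fill), freqs)

    def test_block_shapes_5_6_23(self):
        bands = extract_bands(self._psd59(1.0))
        assert bands.theta.shape == (5, 59)
        assert bands.alpha.shape == (6, 59)
        assert bands.beta.shape == (23, 59)

    def test_10hz_line_lands_in_alpha(self):
        psd = self._psd59()
        psd.values[10, :] = 1.0
        bands = extract_bands(psd)
        assert bands.alpha.sum() == pytest.approx(59.0)
        assert bands.theta.sum() == 0.0
        assert bands.beta.sum() == 0.0

    def test_shared_edge_bins_double_counted(self, rng):
        psd = self._psd59()
        psd.values[:] = rng.random((51, 59))
        bands = extract_bands(psd)
        total = bands.theta.sum() + bands.alpha.sum() + bands.beta.sum()
        direct = psd.values[4:36].sum() + psd.values[8].sum() + psd.values[13].sum()
        assert total == pytest.approx(direct, rel=1e-12)

    def test_band_beyond_grid_errors(self):
        freqs = np.arange(10.0)  # tops out at 9 Hz; beta needs 35
        with pytest.raises(ValueError):
            band_bin_indices(freqs, "beta")

    def test_combined_vector_length_177(self):
        vec = combined_band_vector(extract_bands(self._psd59(1.0)))
        assert vec.shape == (177,)

    def test_constant_psd_gives_constant_vector(self):
        vec = combined_band_vector(extract_bands(self._psd59(3.5)))
        np.testing.assert_allclose(vec, 3.5)

    def test_reduced_toy_case_matches_hand_means(self):
        bands = BandFeatures(theta=np.array([[1.0, 2.0], [3.0, 4.0]]),
                             alpha=np.array([[10.0, 20.0]]),
                             beta=np.array([[0.0, 6.0], [2.0, 0.0]]))
        np.testing.assert_allclose(combined_band_vector(bands),
                                   [2.0, 3.0, 10.0, 20.0, 1.0, 3.0])


class TestTransformers:
    def test_welch_transformer_shape(self, rng):
        X = rng.standard_normal((4, 59, 100))
        out = WelchPSD(fs=100.0).transform(X)
        assert out.shape == (4, 51, 59)

    def test_normalizer_matches_single_sample_path(self, rng):
        X = rng.standard_normal((3, 5, 100))
        psds = WelchPSD(fs=100.0).transform(X)
        batch = PSDNormalizer().transform(psds)
        freqs = np.fft.rfftfreq(100, 0.01)
        for i in range(3):
            single = psd_to_db_norm(PSDMatrix(psds[i], freqs)).values
            np.testing.assert_allclose(batch[i], single, atol=1e-12)

    def test_vectorizer_three_vs_full_widths(self, rng):
        psd = rng.random((2, 51, 59))
        assert BandPowerVectorizer(bands="three").transform(psd).shape == (2, 177)
        assert BandPowerVectorizer(bands="full").transform(psd).shape == (2, 51 * 59)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(amp=st.floats(0.1, 10.0), seed=st.integers(0, 1000))
def test_psd_amplitude_scaling_property(amp, seed):
    """Scaling the signal by a scales every PSD bin by a^2 (pre-dB)."""
    x = np.random.default_rng(seed).standard_normal(100)
    base = welch_psd(x, 100.0).values
    scaled = welch_psd(amp * x, 100.0).values
    np.testing.assert_allclose(scaled, amp ** 2 * base, rtol=1e-8)
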