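"""Spectral estimator oracles: brute-force DFTs, analytic systems, surrogates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cohdecode import (ValidationError, apply_filterbank, coherence,
                       cross_spectra, random_phase_threshold, wiener_filter)

from conftest import make_features, make_targets


def naive_windowed_spectra(x, y, w, fs):
    """Independent O(n^2) DFT-and-average oracle for the trial-as-window
    estimator (explicit exponential sums, no FFT)."""
    K, J, L = x.shape
    F = L // 2 + 1
    n = np.arange(L)
    E = np.exp(-2j * np.pi * np.outer(np.arange(F), n) / L)   # (F, L)
    X = np.einsum("fl,kjl->kjf", E, x * w)
    Y = np.einsum("fl,kl->kf", E, y * w)
    scale = np.full(F, 2.0 / (fs * (w ** 2).sum()))
    scale[0] = scale[0] / 2
    if L % 2 == 0:
        scale[-1] = scale[-1] / 2
    Pxx = (np.abs(X) ** 2).mean(axis=0) * scale
    Pyy = (np.abs(Y) ** 2).mean(axis=0) * scale
    Pxy = (np.conj(X) * Y[:, None, :]).mean(axis=0) * scale
    return Pxx, Pyy, Pxy


class TestCrossSpectra:
    def test_self_spectra_real_nonnegative(self, rng):
        d = rng.standard_normal((5, 3, 64))
        x = make_features(d)
        y = make_targets(d[:, 1, :])
        S = cross_spectra(x, y)
        assert np.allclose(S.Pxy[1].imag, 0.0, atol=1e-12)
        assert np.allclose(S.Pxy[1].real, S.Pxx[1])

    def test_matches_brute_force_dft_oracle(self, rng):
        fs = 200.0
        t = np.arange(400) / fs
        tone = np.sin(2 * np.pi * 10 * t)
        d = np.tile(tone, (8, 2, 1)) + 0.1 * rng.standard_normal((8, 2, 400))
        yv = np.tile(tone, (8, 1)) + 0.1 * rng.standard_normal((8, 400))
        S = cross_spectra(make_features(d, fs), make_targets(yv, fs))
        from scipy.signal.windows import hamming
        Pxx, Pyy, Pxy = naive_windowed_spectra(d, yv, hamming(400, sym=False), fs)
        ref = np.max(np.abs(Pxy))
        assert np.allclose(S.Pxy, Pxy, atol=1e-9 * ref)
        assert np.allclose(S.Pxx, Pxx, atol=1e-9 * np.max(Pxx))
        assert np.allclose(S.Pyy, Pyy, atol=1e-9 * np.max(Pyy))
        # tone power concentrates at the 10 Hz bin
        assert S.freqs[np.argmax(np.abs(S.Pxy[0]))] == pytest.approx(10.0)

    def test_single_trial_rejected(self, rng):
        x = make_features(rng.standard_normal((1, 2, 32)))
        y = make_targets(rng.standard_normal((1, 32)))
        with pytest.raises(ValidationError, match="one realization"):
            cross_spectra(x, y)

    def test_length_mismatch_rejected(self, rng):
        x = make_features(rng.standard_normal((3, 2, 32)))
        y = make_targets(rng.standard_normal((3, 30)))
        with pytest.raises(ValidationError, match="mismatch"):
            cross_spectra(x, y)

    def test_null_coherence_bias_is_one_over_k(self, rng):
        """Independent white signals: E|C|^2 equals the 1/K small-sample bias."""
        K, L = 200, 256
        x = make_features(rng.standard_normal((K, 1, L)))
        y = make_targets(rng.standard_normal((K, L)))
        C = coherence(cross_spectra(x, y))
        coh2 = np.abs(C.C[0]) ** 2
        # Hamming tapering correlates adjacent bins: halve the effective count
        se = coh2.std() / np.sqrt(len(coh2) / 2)
        assert abs(coh2.mean() - 1.0 / K) < 3 * se


class TestCoherence:
    def test_self_coherence_is_one(self, rng):
        d = rng.standard_normal((4, 2, 64))
        C = coherence(cross_spectra(make_features(d), make_targets(d[:, 0, :])))
        assert np.allclose(np.abs(C.C[0]) ** 2, 1.0, atol=1e-9)

    def test_two_trial_toy_matches_naive_dft(self):
        x = np.array([[[1.0, 2.0, 0.0, -1.0]], [[0.0, 1.0, 1.0, 0.0]]])
        y = np.array([[2.0, 0.0, 1.0, 1.0], [1.0, 1.0, 0.0, 2.0]])
        S = cross_spectra(make_features(x, 4.0), make_targets(y, 4.0),
                          window="boxcar")
        C = coherence(S)
        Pxx, Pyy, Pxy = naive_windowed_spectra(x, y, np.ones(4), 4.0)
        expected = Pxy / np.sqrt(Pxx * Pyy[None, :])
        assert np.allclose(C.C, expected, atol=1e-12)

    def test_zero_power_bins_flagged_not_nan(self, rng):
        # a silent channel has zero power everywhere: C is 0 and flagged
        L = 64
        x = np.zeros((4, 2, L))
        x[:, 1, :] = rng.standard_normal((4, L))
        y = rng.standard_normal((4, L))
        C = coherence(cross_spectra(make_features(x), make_targets(y)))
        assert np.all(np.isfinite(np.abs(C.C)))
        assert C.zero_power[0].all() and not C.zero_power[1].any()
        assert np.all(np.abs(C.C[0]) == 0)

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_magnitude_bounded_by_one(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 8))
        L = int(rng.integers(8, 64))
        J = int(rng.integers(1, 4))
        x = make_features(rng.standard_normal((K, J, L)))
        y = make_targets(rng.standard_normal((K, L)))
        S = cross_spectra(x, y)
        assert np.all(np.abs(S.Pxy) ** 2 <= S.Pxx * S.Pyy[None, :] * (1 + 1e-9))
        C = coherence(S)
        assert np.all(np.abs(C.C) ** 2 <= 1 + 1e-9)


class TestWienerFilter:
    def test_identity_system(self, rng):
        d = rng.standard_normal((8, 1, 64))
        S = cross_spectra(make_features(d), make_targets(d[:, 0, :]))
        fb = wiener_filter(S, eps_rel=1e-12)
        assert np.allclose(fb.H[0], 1.0, atol=1e-6)

    def test_circular_delay_yields_phase_ramp(self, rng):
        """y = x delayed by d (circular): H = exp(-i 2 pi k d / L)."""
        K, L, d = 16, 128, 5
        x = rng.standard_normal((K, 1, L))
        y = np.roll(x[:, 0, :], d, axis=-1)
        S = cross_spectra(make_features(x), make_targets(y), window="boxcar")
        fb = wiener_filter(S, eps_rel=0.0)
        k = np.arange(L // 2 + 1)
        assert np.allclose(fb.H[0], np.exp(-2j * np.pi * k * d / L), atol=1e-6)
        # equivalently h is a unit impulse at lag d
        assert fb.h[0, d] == pytest.approx(1.0, abs=1e-6)
        assert np.sum(np.abs(fb.h[0])) == pytest.approx(1.0, abs=1e-5)

    def test_three_tap_system_recovery(self, rng):
        """Known g recovered from 64 noiseless trials of white input."""
        g = np.array([1.0, -0.5, 0.25])
        L, K = 256, 64
        x = rng.standard_normal((K, 1, L))
        y = np.fft.irfft(np.fft.rfft(x[:, 0, :]) * np.fft.rfft(g, n=L), n=L)
        S = cross_spectra(make_features(x), make_targets(y), window="boxcar")
        fb = wiener_filter(S)
        err = np.linalg.norm(fb.h[0] - np.concatenate([g, np.zeros(L - 3)]))
        assert err / np.linalg.norm(g) < 1e-3

    def test_h_is_real(self, rng):
        x = make_features(rng.standard_normal((6, 2, 64)))
        y = make_targets(rng.standard_normal((6, 64)))
        fb = wiener_filter(cross_spectra(x, y))
        assert fb.h.dtype.kind == "f"
        assert np.isrealobj(fb.h)

    def test_estimate_converges_with_trial_count(self):
        """||H_hat - G|| decreases (in expectation) as trials accumulate."""
        g = np.array([0.8, -0.4, 0.2, 0.1])
        L = 128
        G = np.fft.rfft(g, n=L)
        errs = {K: [] for K in (4, 16, 64)}
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((64, 1, L))
            y = np.fft.irfft(np.fft.rfft(x[:, 0, :]) * G, n=L) \
                + 0.3 * rng.standard_normal((64, L))
            for K in errs:
                S = cross_spectra(make_features(x[:K]), make_targets(y[:K]))
                fb = wiener_filter(S)
                errs[K].append(np.linalg.norm(fb.H[0] - G))
        means = [np.mean(errs[K]) for K in (4, 16, 64)]
        assert means[0] > means[1] > means[2]


class TestApplyFilterbank:
    def test_identity_filter(self, rng):
        x = make_features(rng.standard_normal((3, 2, 64)))
        fb = wiener_filter(cross_spectra(x, make_targets(rng.standard_normal((3, 64)))))
        fb.H = np.ones_like(fb.H)
        out = apply_filterbank(x, fb)
        assert np.allclose(out, x.data, atol=1e-10)

    def test_null_filter(self, rng):
        x = make_features(rng.standard_normal((3, 2, 64)))
        fb = wiener_filter(cross_spectra(x, make_targets(rng.standard_normal((3, 64)))))
        fb.H = np.zeros_like(fb.H)
        assert np.allclose(apply_filterbank(x, fb), 0.0)

    def test_equals_time_domain_circular_convolution(self, rng):
        """Frequency-domain product vs direct O(L^2) circular convolution."""
        L = 64
        x = make_features(rng.standard_normal((2, 2, L)))
        y = make_targets(rng.standard_normal((2, L)))
        fb = wiener_filter(cross_spectra(x, y))
        out = apply_filterbank(x, fb)
        for k in range(2):
            for j in range(2):
                direct = np.array([
                    sum(x.data[k, j, tau] * fb.h[j, (t - tau) % L] for tau in range(L))
                    for t in range(L)])
                assert np.allclose(out[k, j], direct, atol=1e-10)

    def test_length_mismatch_rejected(self, rng):
        x = make_features(rng.standard_normal((3, 1, 64)))
        fb = wiener_filter(cross_spectra(x, make_targets(rng.standard_normal((3, 64)))))
        bad = make_features(rng.standard_normal((3, 1, 32)))
        with pytest.raises(ValidationError):
            apply_filterbank(bad, fb)


class TestScaleCovariance:
    def test_filter_compensates_feature_scaling(self, rng):
        d = rng.standard_normal((10, 2, 64))
        yv = rng.standard_normal((10, 64))
        S1 = cross_spectra(make_features(d), make_targets(yv))
        H1 = wiener_filter(S1, eps_rel=1e-12).H
        scaled = d.copy()
        scaled[:, 0, :] *= 7.0
        S2 = cross_spectra(make_features(scaled), make_targets(yv))
        H2 = wiener_filter(S2, eps_rel=1e-12).H
        assert np.allclose(H2[0], H1[0] / 7.0, rtol=1e-9)
        assert np.allclose(H2[1], H1[1], rtol=1e-9)

    def test_filter_scales_with_target(self, rng):
        d = rng.standard_normal((10, 2, 64))
        yv = rng.standard_normal((10, 64))
        H1 = wiener_filter(cross_spectra(make_features(d), make_targets(yv)),
                           eps_rel=1e-12).H
        H2 = wiener_filter(cross_spectra(make_features(d), make_targets(3.0 * yv)),
                           eps_rel=1e-12).H
        assert np.allclose(H2, 3.0 * H1, rtol=1e-9)


class TestRandomPhaseThreshold:
    def test_maximal_coherence_exceeds_threshold(self, rng):
        d = rng.standard_normal((6, 1, 64))
        x = make_features(d)
        y = make_targets(d[:, 0, :])
        thresh = random_phase_threshold(x, y, alpha=0.05, n_surrogates=100, seed=0)
        coh2 = np.abs(coherence(cross_spectra(x, y)).C) ** 2
        powered = coh2 > 0.5
        assert np.all(coh2[powered] > thresh[powered])

    def test_thresholds_bounded(self, rng):
        x = make_features(rng.standard_normal((5, 2, 64)))
        y = make_targets(rng.standard_normal((5, 64)))
        thresh = random_phase_threshold(x, y, n_surrogates=50, seed=1)
        assert np.all((thresh >= 0) & (thresh <= 1))

    def test_reproducible_under_seed(self, rng):
        x = make_features(rng.standard_normal((5, 1, 32)))
        y = make_targets(rng.standard_normal((5, 32)))
        a = random_phase_threshold(x, y, n_surrogates=50, seed=9)
        b = random_phase_threshold(x, y, n_surrogates=50, seed=9)
        assert np.array_equal(a, b)

    def test_all_zero_target_rejected(self, rng):
        x = make_features(rng.standard_normal((5, 1, 32)))
        with pytest.raises(ValidationError, match="zero"):
            random_phase_threshold(x, make_targets(np.zeros((5, 32))), seed=0)

    def test_too_few_surrogates_rejected(self, rng):
        x = make_features(rng.standard_normal((5, 1, 32)))
        y = make_targets(rng.standard_normal((5, 32)))
        with pytest.raises(ValidationError, match="surrogates"):
            random_phase_threshold(x, y, alpha=0.01, n_surrogates=50, seed=0)

    def test_false_positive_rate_near_alpha(self):
        """On independent white signals the test rejects at about its level."""
        rng = np.random.default_rng(77)
        K, J, L = 20, 4, 256
        x = make_features(rng.standard_normal((K, J, L)))
        y = make_targets(rng.standard_normal((K, L)))
        coh2 = np.abs(coherence(cross_spectra(x, y)).C) ** 2
        thresh = random_phase_threshold(x, y, alpha=0.05, n_surrogates=500, seed=0)
        rate = float((coh2 > thresh).mean())
        n = coh2.size
        half = 2.576 * np.sqrt(0.05 * 0.95 / n)
        assert 0.05 - half < rate < 0.05 + half
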