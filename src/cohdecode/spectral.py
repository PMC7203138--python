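"""Cross-trial spectral estimation, complex coherence, and Wiener filters.

The estimator treats every trial as one realization of the same random
process: instead of splitting a single record into overlapping segments
(classic Welch), each trial is one window.  The window length equals the
trial length, the taper is a Hamming window, and the overlap is zero.  This
relaxes within-trial stationarity: only the *cross-trial* consistency of
the phase difference between brain features and the target matters.

With one-sided spectral densities

    Pxx[j,f] = <|X_kj(f)|^2>_k,   Pyy[f] = <|Y_k(f)|^2>_k,
    Pxy[j,f] = <conj(X_kj(f)) Y_k(f)>_k,

the complex coherence is C = Pxy / sqrt(Pxx Pyy) (its magnitude squared is
the per-frequency squared correlation between feature and target), and the
per-feature Wiener filter is H_j(f) = Pxy[j,f] / Pxx[j,f] -- the
least-squares-optimal linear map from feature j to the target, whose phase
encodes the per-frequency lag between the two signals.  Prediction is
circular convolution with the inverse transform h_j(t), computed as a
frequency-domain product.

Significance of an observed coherence is assessed with a random-phase
surrogate test: the target's per-trial Fourier phases are replaced by
i.i.d. uniform phases (amplitudes kept, Hermitian symmetry enforced) and
the coherence magnitude recomputed; the empirical (1 - alpha) quantile over
surrogates is the per-bin threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hamming

from .dataio import TargetSet, ValidationError
from .preprocess import FeatureTensor

__all__ = [
    "SpectraSet",
    "CoherenceSpectrum",
    "FilterBank",
    "cross_spectra",
    "coherence",
    "wiener_filter",
    "apply_filterbank",
    "random_phase_threshold",
]


@dataclass
class SpectraSet:
    """One-sided auto/cross spectral densities averaged across trials."""

    freqs: np.ndarray            # (L_f,)
    Pxx: np.ndarray              # (n_features, L_f), real >= 0
    Pyy: np.ndarray              # (L_f,), real >= 0
    Pxy: np.ndarray              # (n_features, L_f), complex
    n_trials_used: int
    window: str
    fs: float
    n_samples: int               # transform length (trial length)

    def validate(self) -> None:
        if self.n_trials_used < 2:
            raise ValidationError("coherence undefined from one realization")
        if np.any(self.Pxx < -1e-15) or np.any(self.Pyy < -1e-15):
            raise ValidationError("auto-spectra must be non-negative")
        bound = self.Pxx * self.Pyy[np.newaxis, :]
        if np.any(np.abs(self.Pxy) ** 2 > bound * (1 + 1e-9) + 1e-300):
            raise ValidationError("Cauchy-Schwarz violated: |Pxy|^2 > Pxx*Pyy")


@dataclass
class CoherenceSpectrum:
    """Complex coherence per feature and frequency; |C|^2 lies in [0, 1]."""

    freqs: np.ndarray
    C: np.ndarray                # (n_features, L_f), complex
    zero_power: np.ndarray       # bool mask of bins with no power (C set to 0)


@dataclass
class FilterBank:
    """Per-feature spectral filters H_j(f) and their impulse responses h_j(t)."""

    freqs: np.ndarray
    H: np.ndarray                # (n_features, L_f), complex, one-sided
    h: np.ndarray                # (n_features, n_samples), real
    fs: float
    n_samples: int

    @property
    def n_features(self) -> int:
        return self.H.shape[0]


def _window(name: str, n: int) -> np.ndarray:
    if name == "hamming":
        return hamming(n, sym=False)
    if name in ("boxcar", "rect", "none"):
        return np.ones(n)
    raise ValidationError(f"unknown window {name!r}")


def _windowed_rfft(data: np.ndarray, w: np.ndarray) -> np.ndarray:
    return np.fft.rfft(data * w, axis=-1)


def _onesided_scale(fs: float, w: np.ndarray, n: int) -> np.ndarray:
    """Density scaling per rfft bin: 1/(fs*sum w^2), doubled off DC/Nyquist."""
    scale = np.full(n // 2 + 1, 2.0 / (fs * np.sum(w ** 2)))
    scale[0] = 1.0 / (fs * np.sum(w ** 2))
    if n % 2 == 0:
        scale[-1] = 1.0 / (fs * np.sum(w ** 2))
    return scale


def cross_spectra(x: FeatureTensor, y: TargetSet, window: str = "hamming") -> SpectraSet:
    """Trial-as-window estimate of Pxx, Pyy and Pxy.

    Every trial contributes one tapered full-length window; spectra are the
    across-trial means, normalized to one-sided power spectral densities
    (per Hz).  The normalization cancels in coherence and in the Wiener
    quotient but makes the set a valid PSD on its own.
    """
    if x.n_trials != y.n_trials:
        raise ValidationError(
            f"feature/target trial mismatch: {x.n_trials} vs {y.n_trials}")
    if x.n_samples != y.n_samples:
        raise ValidationError(
            f"feature/target length mismatch: {x.n_samples} vs {y.n_samples}")
    if x.fs != y.fs:
        raise ValidationError(f"feature/target rate mismatch: {x.fs} vs {y.fs}")
    if x.n_trials < 2:
        raise ValidationError("coherence undefined from one realization")

    n = x.n_samples
    w = _window(window, n)
    X = _windowed_rfft(x.data, w)                 # (K, J, F)
    Y = _windowed_rfft(y.data, w)                 # (K, F)
    scale = _onesided_scale(x.fs, w, n)

    Pxx = np.mean(np.abs(X) ** 2, axis=0) * scale
    Pyy = np.mean(np.abs(Y) ** 2, axis=0) * scale
    Pxy = np.mean(np.conj(X) * Y[:, np.newaxis, :], axis=0) * scale
    freqs = np.fft.rfftfreq(n, d=1.0 / x.fs)
    S = SpectraSet(freqs=freqs, Pxx=Pxx, Pyy=Pyy, Pxy=Pxy,
                   n_trials_used=x.n_trials, window=window, fs=x.fs, n_samples=n)
    S.validate()
    return S


def coherence(S: SpectraSet) -> CoherenceSpectrum:
    """Complex coherence C = Pxy / sqrt(Pxx * Pyy); zero-power bins -> 0."""
    S.validate()
    denom2 = S.Pxx * S.Pyy[np.newaxis, :]
    zero = denom2 <= 0
    denom = np.sqrt(np.where(zero, 1.0, denom2))
    C = np.where(zero, 0.0, S.Pxy / denom)
    return CoherenceSpectrum(freqs=S.freqs, C=C, zero_power=zero)


def wiener_filter(S: SpectraSet, eps_rel: float = 1e-8) -> FilterBank:
    """Per-feature Wiener filter H_j = Pxy / (Pxx + eps_rel * max_f Pxx).

    The relative Tikhonov floor ``eps_rel`` stabilizes bins where the
    feature has essentially no power (stop-bands after preprocessing).  The
    impulse response ``h`` is the inverse DFT of the Hermitian-extended H
    and is real by construction.
    """
    S.validate()
    if eps_rel < 0:
        raise ValidationError("eps_rel must be non-negative")
    floor = eps_rel * np.max(S.Pxx, axis=1, keepdims=True)
    denom = S.Pxx + floor
    dead = denom <= 0
    H = np.where(dead, 0.0, S.Pxy / np.where(dead, 1.0, denom))
    h = np.fft.irfft(H, n=S.n_samples, axis=-1)
    return FilterBank(freqs=S.freqs, H=H, h=h, fs=S.fs, n_samples=S.n_samples)


def apply_filterbank(x: FeatureTensor, fb: FilterBank) -> np.ndarray:
    """Filter every trial/feature: irfft(rfft(x) * H), circular convolution.

    Returns a real array of shape (n_trials, n_features, n_samples).
    """
    if x.n_samples != fb.n_samples:
        raise ValidationError(
            f"trial length {x.n_samples} != filter transform length {fb.n_samples}")
    if x.fs != fb.fs:
        raise ValidationError(f"rate mismatch: {x.fs} vs {fb.fs}")
    if x.n_features != fb.n_features:
        raise ValidationError(
            f"feature count {x.n_features} != filter count {fb.n_features}")
    X = np.fft.rfft(x.data, axis=-1)
    return np.fft.irfft(X * fb.H[np.newaxis, :, :], n=fb.n_samples, axis=-1)


def _surrogate_phases(rng: np.random.Generator, shape: tuple, n: int) -> np.ndarray:
    """Uniform phase factors for rfft bins, real at DC (and Nyquist if n even)."""
    ph = np.exp(1j * rng.uniform(0.0, 2.0 * np.pi, size=shape))
    ph[..., 0] = rng.choice([-1.0, 1.0], size=shape[:-1])
    if n % 2 == 0:
        ph[..., -1] = rng.choice([-1.0, 1.0], size=shape[:-1])
    return ph


def random_phase_threshold(x: FeatureTensor, y: TargetSet, alpha: float = 0.05,
                           n_surrogates: int = 1000, seed: int = 0,
                           window: str = "hamming") -> np.ndarray:
    """Per-bin |C|^2 significance thresholds from random-phase surrogates.

    For each surrogate the target's per-trial windowed spectrum keeps its
    amplitudes but receives i.i.d. uniform phases; the coherence magnitude
    squared is recomputed, and the empirical (1 - alpha) quantile across
    surrogates is the threshold.  Observed bins exceeding their threshold
    are deemed significant at level alpha.

    Returns an array of shape (n_features, L_f) with values in [0, 1].
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if n_surrogates < int(np.ceil(1.0 / alpha)):
        raise ValidationError(
            f"need at least {int(np.ceil(1.0 / alpha))} surrogates for alpha={alpha}")
    if not np.any(y.data):
        raise ValidationError("degenerate all-zero target")
    if x.n_trials != y.n_trials or x.n_samples != y.n_samples:
        raise ValidationError("feature/target shape mismatch")

    rng = np.random.default_rng(seed)
    n = x.n_samples
    w = _window(window, n)
    X = _windowed_rfft(x.data, w)                  # (K, J, F)
    Y = _windowed_rfft(y.data, w)                  # (K, F)
    K = x.n_trials
    absY = np.abs(Y)
    Pxx = np.mean(np.abs(X) ** 2, axis=0)          # (J, F)
    Pyy = np.mean(absY ** 2, axis=0)               # (F,)
    denom2 = Pxx * Pyy[np.newaxis, :]
    dead = denom2 <= 0

    coh2 = np.empty((n_surrogates, x.n_features, X.shape[-1]))
    # chunk surrogates to bound memory: phases are (chunk, K, F) complex
    chunk = max(1, int(2e7 // (K * X.shape[-1])))
    done = 0
    Xc = np.conj(X)
    while done < n_surrogates:
        m = min(chunk, n_surrogates - done)
        ph = _surrogate_phases(rng, (m, K, X.shape[-1]), n)
        Ys = absY[np.newaxis, :, :] * ph                       # (m, K, F)
        Pxy_s = np.einsum("kjf,mkf->mjf", Xc, Ys) / K           # (m, J, F)
        c2 = np.abs(Pxy_s) ** 2 / np.where(dead, 1.0, denom2)[np.newaxis]
        c2[:, dead] = 0.0
        coh2[done:done + m] = c2
        done += m
    thresh = np.quantile(coh2, 1.0 - alpha, axis=0)
    return np.clip(thresh, 0.0, 1.0)
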