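"""Synthetic datasets with known ground truth.

Generators at two levels:

* **feature level** -- white-noise features x_j, a target built as
  ``y = sum_j b*_j (g*_j circ x_j) + noise`` with known smooth FIR filters
  g*_j and spatial weights b*_j: the exact generative reading of the
  decoding model, so fitted filters/weights can be compared to truth.

* **raw level** -- multichannel "recordings" at 1000 Hz with a
  quasi-periodic finger-flexion-like target: a smoothed pulse train whose
  cycle lengths jitter around 1/flexion_rate (10% coefficient of
  variation, emulating freely paced movement).  Coupled channels carry the
  target twice, the way ECoG does: additively in the low-frequency band
  (through a channel-specific smooth FIR, at a controlled in-band SNR
  against a pink-noise background), and as amplitude modulation of a
  70-170 Hz noise carrier.  The full preprocessing chain then recovers the
  coupling in both the LFC and the HFBE features, with the coherence peak
  at the flexion rate.

* **condition sets** -- several conditions sharing filters but with
  condition-specific spatial weights whose cluster centers are a chosen
  distance apart, exercising the K-means/LDA discriminability pipeline
  end-to-end (separation 0 is the null).

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .dataio import TargetSet, TrialSet, ValidationError
from .preprocess import FeatureTensor

__all__ = [
    "SyntheticGroundTruth",
    "simulate_feature_level",
    "simulate_raw_level",
    "simulate_condition_set",
    "simulate_weight_observations",
]


@dataclass
class SyntheticGroundTruth:
    true_h: np.ndarray            # (n_features, filter_len) coupling FIRs
    true_b: np.ndarray            # (n_features,) spatial weights / gains
    snr_db: float
    flexion_rate_hz: float | None
    seed: int
    fs: float


def smooth_fir(rng: np.random.Generator, length: int, smooth: int = 7) -> np.ndarray:
    """Random smooth FIR: white taps smoothed with a Hann kernel, unit L2 norm."""
    taps = rng.standard_normal(length)
    kernel = signal.windows.hann(smooth)
    kernel /= kernel.sum()
    taps = np.convolve(taps, kernel, mode="same")
    return taps / np.linalg.norm(taps)


def _circconv(x: np.ndarray, g: np.ndarray, n: int) -> np.ndarray:
    """Circular convolution along the last axis at length n."""
    return np.fft.irfft(np.fft.rfft(x, n=n) * np.fft.rfft(g, n=n), n=n)


def simulate_feature_level(n_trials: int = 30, n_features: int = 8,
                           trial_len: int = 400, fs: float = 200.0,
                           snr_db: float = 10.0, filter_len: int = 25,
                           seed: int = 0, true_b: np.ndarray | None = None,
                           true_h: np.ndarray | None = None):
    """Feature-level dataset: the decoder's generative model, inverted.

    Features are i.i.d. standard normal; the target is the weighted sum of
    circularly filtered features plus white noise scaled so the realized
    signal-to-noise variance ratio equals ``snr_db`` exactly
    (``snr_db=inf`` adds no noise).  ``true_b`` defaults to distinct random
    magnitudes in [0.5, 1.5] with random signs.

    Returns ``(FeatureTensor, TargetSet, SyntheticGroundTruth)``.
    """
    if trial_len <= filter_len:
        raise ValidationError("trial_len must exceed filter_len")
    if n_trials < 1 or n_features < 1:
        raise ValidationError("invalid sizes")
    rng = np.random.default_rng(seed)
    if true_h is None:
        g = np.stack([smooth_fir(rng, filter_len) for _ in range(n_features)])
    else:
        g = np.asarray(true_h, dtype=np.float64)
        if g.shape[0] != n_features or g.shape[1] > trial_len:
            raise ValidationError("true_h must be (n_features, len <= trial_len)")
    if true_b is None:
        true_b = rng.uniform(0.5, 1.5, size=n_features) * rng.choice([-1, 1], n_features)
    true_b = np.asarray(true_b, dtype=np.float64)
    if true_b.shape != (n_features,):
        raise ValidationError("true_b must have one entry per feature")

    x = rng.standard_normal((n_trials, n_features, trial_len))
    filtered = np.stack([_circconv(x[:, j, :], g[j], trial_len)
                         for j in range(n_features)], axis=1)
    clean = np.einsum("kjt,j->kt", filtered, true_b)
    if np.isinf(snr_db):
        y = clean
    else:
        noise = rng.standard_normal(clean.shape)
        snr_lin = 10.0 ** (snr_db / 10.0)
        noise *= np.sqrt(clean.var() / (noise.var() * snr_lin))
        y = clean + noise
    feats = FeatureTensor(data=x, fs=fs,
                          feature_ids=[(f"ch{j:02d}", "LFC") for j in range(n_features)])
    targets = TargetSet(data=y, fs=fs, modality="synthetic")
    truth = SyntheticGroundTruth(true_h=g, true_b=true_b, snr_db=snr_db,
                                 flexion_rate_hz=None, seed=seed, fs=fs)
    return feats, targets, truth


def _flexion_trace(rng: np.random.Generator, n_samples: int, fs: float,
                   rate_hz: float, jitter_cv: float = 0.1) -> np.ndarray:
    """Quasi-periodic flexion trace: smoothed pulse train with jittered cycles.

    Cycle periods are drawn i.i.d. with the given coefficient of variation
    and then rescaled so every trial completes the same number of flexions
    (the cue fixes the trial's duration, the patient paces freely within
    it); this keeps the per-trial mean stable while the cycle-to-cycle
    timing jitters.
    """
    period = fs / rate_hz
    n_pulses = max(1, int(round(n_samples / period))) + 2
    periods = period * np.maximum(0.2, 1.0 + jitter_cv * rng.standard_normal(n_pulses))
    periods *= (n_samples + 2 * period) / periods.sum()
    centers = np.cumsum(periods) - periods[0] * rng.uniform(0.5, 1.0) - period
    # full-period pulses overlap into a sinusoid-like trace: repetitive
    # flexion concentrates its power at the fundamental, harmonics arise
    # only from the cycle jitter
    width = int(round(period))
    pulse = signal.windows.hann(max(width, 3))
    half = len(pulse) // 2
    pad = len(pulse)
    y = np.zeros(n_samples + 2 * pad)
    for c in centers:
        i = int(round(c)) - half + pad
        if 0 <= i and i + len(pulse) <= len(y):
            y[i:i + len(pulse)] += pulse
    return y[pad:pad + n_samples]


def _pink_noise(rng: np.random.Generator, shape: tuple, fs: float) -> np.ndarray:
    """1/f-amplitude noise, unit variance, flattened below 1 Hz."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    spec = amp * (rng.standard_normal(shape[:-1] + (len(freqs),))
                  + 1j * rng.standard_normal(shape[:-1] + (len(freqs),)))
    spec[..., 0] = 0.0
    x = np.fft.irfft(spec, n=n, axis=-1)
    return x / x.std()


def _band_var(x: np.ndarray, band, fs: float) -> float:
    sos = signal.butter(4, band, btype="bandpass", output="sos", fs=fs)
    return float(signal.sosfiltfilt(sos, x, axis=-1).var())


def simulate_raw_level(n_trials: int = 30, n_channels: int = 8,
                       trial_len: int = 2000, fs: float = 1000.0,
                       snr_db: float = 10.0, flexion_rate_hz: float = 1.5,
                       n_coupled: int | None = None, am_depth: float = 0.8,
                       hfb_carrier_snr_db: float | None = None,
                       seed: int = 0):
    """Raw multichannel dataset with LFC and HFB coupling to a flexion target.

    Coupled channels receive ``gain * (g_j circ y)`` (band-limited additive
    coupling; ``gain`` is set so the coupled component's variance in the
    0.5-40 Hz band is ``snr_db`` above the pink background's) plus a
    70-170 Hz noise carrier amplitude-modulated by a rectified filtered
    copy of the target.  Uncoupled channels are pink noise only
    (``n_coupled=0`` gives a fully null dataset).

    Returns ``(TrialSet, TargetSet, SyntheticGroundTruth)`` at the raw rate.
    """
    if not 0 < flexion_rate_hz < 40:
        raise ValidationError("flexion rate must lie inside the LFC band (0, 40) Hz")
    if n_coupled is None:
        n_coupled = n_channels
    if not 0 <= n_coupled <= n_channels:
        raise ValidationError("n_coupled out of range")
    rng = np.random.default_rng(seed)

    y = np.stack([_flexion_trace(rng, trial_len, fs, flexion_rate_hz)
                  for _ in range(n_trials)])
    data = _pink_noise(rng, (n_trials, n_channels, trial_len), fs)

    filter_len = max(3, int(round(25 * fs / 200.0)))
    smooth = max(3, int(round(7 * fs / 200.0)))
    g_lfc = np.stack([smooth_fir(rng, filter_len, smooth) for _ in range(n_channels)])
    # modulation kernels are positive (random smooth shape, magnitude taken):
    # the rectified modulator then keeps the flexion fundamental undistorted
    g_hfb = np.stack([np.abs(smooth_fir(rng, filter_len, smooth))
                      for _ in range(n_channels)])
    g_hfb /= np.linalg.norm(g_hfb, axis=1, keepdims=True)
    true_b = np.zeros(n_channels)
    true_b[:n_coupled] = 1.0

    snr_lin = 10.0 ** (snr_db / 10.0)
    lfc_band = (0.5, 40.0)
    if n_coupled > 0:
        coupled = np.stack([_circconv(y, g_lfc[j], trial_len)
                            for j in range(n_coupled)], axis=1)
        # per-channel gain: every coupled channel gets the requested in-band SNR
        for j in range(n_coupled):
            sig_var = _band_var(coupled[:, j], lfc_band, fs)
            noise_var = _band_var(data[:, j], lfc_band, fs)
            coupled[:, j] *= np.sqrt(snr_lin * noise_var / sig_var)
        data[:, :n_coupled] += coupled

        # HFB amplitude modulation: carrier power likewise snr-scaled in-band
        hfb_lin = snr_lin if hfb_carrier_snr_db is None \
            else 10.0 ** (hfb_carrier_snr_db / 10.0)
        sos_hfb = signal.butter(4, (70.0, 170.0), btype="bandpass", output="sos", fs=fs)
        carrier = signal.sosfiltfilt(
            sos_hfb, rng.standard_normal((n_trials, n_coupled, trial_len)), axis=-1)
        mod = np.stack([_circconv(y, g_hfb[j], trial_len)
                        for j in range(n_coupled)], axis=1)
        mod = np.maximum(mod, 0.0)
        # per-channel RMS normalization: uniform, non-vanishing modulation depth
        rms = np.sqrt((mod ** 2).mean(axis=(0, 2), keepdims=True))
        mod = np.divide(mod, rms, out=np.zeros_like(mod), where=rms > 0)
        hfb_bg_var = _band_var(data[:, :n_coupled], (70.0, 170.0), fs)
        carrier *= np.sqrt(hfb_lin * hfb_bg_var / carrier.var())
        data[:, :n_coupled] += carrier * (1.0 + am_depth * mod)

    trials = TrialSet(data=data, fs=fs,
                      labels=["flex"] * n_trials,
                      channel_ids=[f"ch{j:02d}" for j in range(n_channels)])
    targets = TargetSet(data=y, fs=fs, modality="synthetic")
    truth = SyntheticGroundTruth(true_h=g_lfc, true_b=true_b, snr_db=snr_db,
                                 flexion_rate_hz=flexion_rate_hz, seed=seed, fs=fs)
    return trials, targets, truth


def simulate_condition_set(n_conditions: int = 5, n_trials_per: int = 30,
                           n_features: int = 8, trial_len: int = 256,
                           fs: float = 200.0, snr_db: float = 10.0,
                           separation: float = 1.0, n_discriminative: int = 2,
                           filter_len: int = 25, seed: int = 0):
    """Multi-condition feature-level dataset with planted weight structure.

    All conditions share the coupling filters; each condition's true weight
    vector differs from the common base only on ``n_discriminative``
    electrodes, where the condition centers are spread ``separation`` apart
    (separation 0 makes the conditions indistinguishable -- the null for
    the discriminability analysis).

    Returns ``(FeatureTensor, TargetSet, labels, {condition: truth})``.
    """
    if n_conditions < 2:
        raise ValidationError("need at least 2 conditions")
    if separation < 0:
        raise ValidationError("separation must be non-negative")
    if n_discriminative > n_features:
        raise ValidationError("n_discriminative exceeds n_features")
    rng = np.random.default_rng(seed)
    base_b = rng.uniform(0.8, 1.2, size=n_features)
    shared_g = np.stack([smooth_fir(rng, filter_len) for _ in range(n_features)])
    # distinct per-condition offsets on the discriminative electrodes
    ramp = np.linspace(-1.0, 1.0, n_conditions)
    offsets = np.zeros((n_conditions, n_features))
    for d in range(n_discriminative):
        offsets[:, d] = ramp[rng.permutation(n_conditions)]

    feats_list, y_list, labels, truths = [], [], [], {}
    for c in range(n_conditions):
        name = f"cond{c}"
        b_c = base_b + separation * offsets[c]
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        f, t, truth = simulate_feature_level(
            n_trials=n_trials_per, n_features=n_features, trial_len=trial_len,
            fs=fs, snr_db=snr_db, filter_len=filter_len, seed=sub_seed,
            true_b=b_c, true_h=shared_g)
        feats_list.append(f.data)
        y_list.append(t.data)
        labels += [name] * n_trials_per
        truths[name] = truth
    feats = FeatureTensor(data=np.concatenate(feats_list, axis=0), fs=fs,
                          feature_ids=[(f"ch{j:02d}", "LFC") for j in range(n_features)])
    targets = TargetSet(data=np.concatenate(y_list, axis=0), fs=fs,
                        modality="synthetic")
    return feats, targets, labels, truths


def simulate_weight_observations(n_conditions: int = 5, n_folds: int = 5,
                                 n_electrodes: int = 8, separation: float = 1.0,
                                 noise_sd: float = 0.1, n_discriminative: int = 2,
                                 seed: int = 0):
    """Planted per-(condition, fold) weight observations for the
    discriminability analysis, without running the decoder.

    Discriminative electrodes carry condition-specific centers spaced
    ``separation`` apart plus N(0, noise_sd) fold noise; the rest are pure
    i.i.d. noise around a common level.

    Returns ``(W, condition_labels, fold_ids)`` with W of shape
    (n_conditions * n_folds, n_electrodes).
    """
    if separation < 0:
        raise ValidationError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    centers = np.ones((n_conditions, n_electrodes))
    ramp = np.arange(n_conditions, dtype=float)
    for d in range(n_discriminative):
        centers[:, d] += separation * ramp[rng.permutation(n_conditions)]
    W = np.repeat(centers, n_folds, axis=0) \
        + noise_sd * rng.standard_normal((n_conditions * n_folds, n_electrodes))
    conds = np.repeat([f"cond{c}" for c in range(n_conditions)], n_folds)
    fold_ids = np.tile(np.arange(n_folds), n_conditions)
    return W, conds, fold_ids
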