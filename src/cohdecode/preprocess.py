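"""Preprocessing and feature extraction for intracranial recordings.

The chain mirrors standard ECoG decoding practice: broadband conditioning
(zero-phase Butterworth band-pass 0.1-200 Hz plus a 60 Hz line-noise notch),
common average reference (CAR), then two feature bands per electrode:

* **LFC** -- low-frequency components, the signal band-passed 0.5-40 Hz,
  carrying phase-informative slow dynamics;
* **HFBE** -- high-frequency band envelope, the magnitude of the analytic
  signal of the 70-170 Hz band, low-passed at 40 Hz; a proxy for local
  population firing.

Both features are decimated to a common analysis rate (200 Hz by default).
All filters are applied forward-backward (``sosfiltfilt``), so a 4th-order
design acts with an 8th-order magnitude response and zero phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import signal

from .dataio import TargetSet, TrialSet, ValidationError

__all__ = [
    "PreprocessConfig",
    "FeatureTensor",
    "broadband_condition",
    "car",
    "extract_lfc",
    "extract_hfbe",
    "resample_to",
    "build_features",
]


@dataclass
class PreprocessConfig:
    """Band definitions and analysis rate; defaults follow common ECoG usage."""

    broadband: tuple[float, float] = (0.1, 200.0)
    notch_hz: float = 60.0
    notch_q: float = 30.0
    lfc_band: tuple[float, float] = (0.5, 40.0)
    hfb_band: tuple[float, float] = (70.0, 170.0)
    envelope_lp_hz: float = 40.0
    order: int = 4
    analysis_fs: float = 200.0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FeatureTensor:
    """Per-trial, per-electrode feature time series at the analysis rate.

    ``feature_ids`` is a list of ``(channel_id, band)`` tuples with band in
    {"LFC", "HFBE"}; when both bands are extracted the LFC block precedes the
    HFBE block and ``n_features == 2 * n_channels``.
    """

    data: np.ndarray  # (n_trials, n_features, n_samples)
    fs: float
    feature_ids: Sequence[tuple[str, str]]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(f"feature data must be 3-d, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("feature data contains non-finite values")
        self.feature_ids = [(str(c), str(b)) for c, b in self.feature_ids]
        if len(self.feature_ids) != self.data.shape[1]:
            raise ValidationError("feature_ids length does not match feature axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select_trials(self, idx) -> "FeatureTensor":
        return FeatureTensor(self.data[np.asarray(idx)], self.fs, list(self.feature_ids))


def _check_band(band, fs) -> tuple[float, float]:
    lo, hi = float(band[0]), float(band[1])
    if not (0 < lo < hi):
        raise ValidationError(f"invalid band {band}")
    if hi >= fs / 2:
        raise ValidationError(f"band edge {hi} Hz at or above Nyquist ({fs / 2} Hz)")
    return lo, hi


def _sos_bandpass(band, order, fs):
    return signal.butter(order, band, btype="bandpass", output="sos", fs=fs)


def _filtfilt_trials(data: np.ndarray, sos) -> np.ndarray:
    # trials/channels on leading axes; filter the last (time) axis.
    # Full-length reflection padding: slow corners (0.1 Hz high-pass) and
    # high-Q notches settle over many seconds, far beyond filtfilt's default.
    return signal.sosfiltfilt(sos, data, axis=-1, padlen=data.shape[-1] - 1)


def broadband_condition(trials: TrialSet, band=(0.1, 200.0), notch_hz: float = 60.0,
                        order: int = 4, notch_q: float = 30.0) -> TrialSet:
    """Zero-phase broadband band-pass followed by a line-noise notch.

    The notch is a second-order IIR design (quality factor ``notch_q``)
    applied forward-backward like every other filter in the chain.
    """
    lo, hi = _check_band(band, trials.fs)
    if not notch_hz < trials.fs / 2:
        raise ValidationError(f"notch at {notch_hz} Hz at or above Nyquist")
    sos = _sos_bandpass((lo, hi), order, trials.fs)
    out = _filtfilt_trials(trials.data, sos)
    b, a = signal.iirnotch(notch_hz, notch_q, fs=trials.fs)
    out = signal.filtfilt(b, a, out, axis=-1, padlen=out.shape[-1] - 1)
    return trials.with_data(out)


def car(trials: TrialSet) -> TrialSet:
    """Common average reference: subtract the instantaneous cross-channel mean."""
    mean = trials.data.mean(axis=1, keepdims=True)
    return trials.with_data(trials.data - mean)


def extract_lfc(trials: TrialSet, band=(0.5, 40.0), order: int = 4) -> TrialSet:
    """Low-frequency components: zero-phase Butterworth band-pass."""
    lo, hi = _check_band(band, trials.fs)
    sos = _sos_bandpass((lo, hi), order, trials.fs)
    return trials.with_data(_filtfilt_trials(trials.data, sos))


def extract_hfbe(trials: TrialSet, band=(70.0, 170.0), lp_cutoff: float = 40.0,
                 order: int = 4) -> TrialSet:
    """High-frequency band envelope.

    Band-pass to ``band``, take the magnitude of the analytic signal
    (Hilbert transform), then low-pass the envelope at ``lp_cutoff`` to
    remove rapid amplitude fluctuations.
    """
    lo, hi = _check_band(band, trials.fs)
    sos = _sos_bandpass((lo, hi), order, trials.fs)
    bp = _filtfilt_trials(trials.data, sos)
    env = np.abs(signal.hilbert(bp, axis=-1))
    sos_lp = signal.butter(order, lp_cutoff, btype="lowpass", output="sos", fs=trials.fs)
    env = _filtfilt_trials(env, sos_lp)
    return trials.with_data(env)


def resample_to(x: TrialSet | TargetSet, fs_out: float):
    """Polyphase anti-aliased resampling to ``fs_out`` (<= current rate).

    Output length is ``round(n_samples * fs_out / fs)``; the rate ratio must
    be rational (it always is for the integer rates used in practice).
    """
    if fs_out <= 0:
        raise ValidationError(f"fs_out must be positive, got {fs_out}")
    if fs_out > x.fs:
        raise ValidationError(f"refusing to upsample {x.fs} -> {fs_out} Hz")
    if fs_out == x.fs:
        return x
    from fractions import Fraction

    frac = Fraction(fs_out / x.fs).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(x.data, up, down, axis=-1)
    n_expect = int(round(x.data.shape[-1] * fs_out / x.fs))
    out = out[..., :n_expect]
    if isinstance(x, TrialSet):
        return x.with_data(out, fs=fs_out)
    return TargetSet(data=out, fs=fs_out, modality=x.modality)


def build_features(trials: TrialSet, bands=("LFC", "HFBE"),
                   config: PreprocessConfig | None = None) -> FeatureTensor:
    """Extract the requested feature bands and stack them at the analysis rate.

    ``trials`` is expected to be broadband-conditioned and CAR-referenced
    already (compose :func:`broadband_condition` and :func:`car` first, or
    use :func:`preprocess_trials`).  Feature order is all LFC channels, then
    all HFBE channels.
    """
    cfg = config or PreprocessConfig()
    bands = tuple(bands)
    if not bands:
        raise ValidationError("at least one band (LFC, HFBE) is required")
    for b in bands:
        if b not in ("LFC", "HFBE"):
            raise ValidationError(f"unknown band {b!r}")
    blocks, ids = [], []
    if "LFC" in bands:
        lfc = resample_to(extract_lfc(trials, cfg.lfc_band, cfg.order), cfg.analysis_fs)
        blocks.append(lfc.data)
        ids += [(c, "LFC") for c in trials.channel_ids]
    if "HFBE" in bands:
        hfb = resample_to(
            extract_hfbe(trials, cfg.hfb_band, cfg.envelope_lp_hz, cfg.order),
            cfg.analysis_fs,
        )
        blocks.append(hfb.data)
        ids += [(c, "HFBE") for c in trials.channel_ids]
    return FeatureTensor(data=np.concatenate(blocks, axis=1), fs=cfg.analysis_fs,
                         feature_ids=ids)


def preprocess_trials(trials: TrialSet, bands=("LFC", "HFBE"),
                      config: PreprocessConfig | None = None) -> FeatureTensor:
    """Full chain: broadband band-pass -> notch -> CAR -> features -> resample."""
    cfg = config or PreprocessConfig()
    conditioned = broadband_condition(trials, cfg.broadband, cfg.notch_hz, cfg.order,
                                      cfg.notch_q)
    referenced = car(conditioned)
    return build_features(referenced, bands, cfg)
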