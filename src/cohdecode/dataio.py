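"""Containers and I/O for trial-aligned multichannel recordings and targets.

A recording session is represented as a :class:`TrialSet`: a dense tensor of
``n_trials x n_channels x n_samples`` with a sampling rate and one condition
label per trial (the finger moved, the word heard, ...).  The signal to be
decoded (data-glove trace, speech amplitude envelope) lives in a
:class:`TargetSet` aligned trial-by-trial with the recordings.

Datasets are stored one-per-file in an HDF5 container with groups
``/trials`` (tensor), ``/targets`` (matrix) and ``/meta`` (sampling rate,
labels, channel ids).  A directory of per-trial CSV files (samples x
channels, header row = channel ids) and mono PCM WAV files for audio targets
are supported as plain-text/interchange alternatives.

Sample indexing is 0-based throughout and epochs are half-open
``[start, start + length)`` windows, so contiguous epochs concatenate back
to the source recording exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "TrialSet",
    "TargetSet",
    "ValidationError",
    "read_trialset",
    "write_trialset",
    "read_target_wav",
    "epoch",
]


class ValidationError(ValueError):
    """A container invariant was violated (ragged trials, bad labels, ...)."""


def _as_float_array(a, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(a, dtype=np.float64)
    if arr.ndim != ndim:
        raise ValidationError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise ValidationError(f"{name} contains non-finite values (first at index {tuple(bad)})")
    return arr


@dataclass
class TrialSet:
    """Trial-aligned multichannel recordings.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal amplitude in arbitrary units (the decoding method is
        scale-covariant, so units are never interpreted).
    fs : float
        Sampling rate in Hz.
    labels : sequence of str
        Condition identifier per trial.
    channel_ids : sequence of str, optional
        One id per channel; defaults to ``ch00, ch01, ...``.
    """

    data: np.ndarray
    fs: float
    labels: Sequence[str]
    channel_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = _as_float_array(self.data, "data", 3)
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        self.fs = float(self.fs)
        if self.data.shape[0] < 1:
            raise ValidationError("TrialSet requires at least one trial")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.n_trials:
            raise ValidationError(
                f"label/trial count mismatch: {len(self.labels)} labels for {self.n_trials} trials"
            )
        if self.channel_ids is None:
            self.channel_ids = [f"ch{j:02d}" for j in range(self.n_channels)]
        else:
            self.channel_ids = [str(c) for c in self.channel_ids]
        if len(self.channel_ids) != self.n_channels:
            raise ValidationError(
                f"channel_ids/channel count mismatch: {len(self.channel_ids)} ids "
                f"for {self.n_channels} channels"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "TrialSet":
        """Return a copy with new sample data (same labels/channels)."""
        return replace(self, data=data, fs=self.fs if fs is None else fs)

    def select_trials(self, idx) -> "TrialSet":
        idx = np.asarray(idx)
        return TrialSet(
            data=self.data[idx],
            fs=self.fs,
            labels=[self.labels[i] for i in idx],
            channel_ids=list(self.channel_ids),
        )


@dataclass
class TargetSet:
    """Per-trial target signal (what the decoder predicts).

    ``modality`` tags the provenance: ``glove`` for finger-position traces,
    ``envelope`` for speech amplitude envelopes, ``synthetic`` for generated
    ground-truth targets.
    """

    data: np.ndarray
    fs: float
    modality: str = "synthetic"

    def __post_init__(self) -> None:
        self.data = _as_float_array(self.data, "data", 2)
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        self.fs = float(self.fs)
        if self.modality not in ("glove", "envelope", "synthetic"):
            raise ValidationError(f"unknown modality {self.modality!r}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_trials(self, idx) -> "TargetSet":
        idx = np.asarray(idx)
        return TargetSet(data=self.data[idx], fs=self.fs, modality=self.modality)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_trialset(path, trials: TrialSet, targets: TargetSet | None = None) -> None:
    """Write a dataset to the HDF5 container (groups /trials, /targets, /meta)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("trials/data", data=trials.data)
        meta = f.create_group("meta")
        meta.attrs["fs"] = trials.fs
        str_dt = "S64"
        meta.create_dataset("labels", data=np.array(trials.labels, dtype=str_dt))
        meta.create_dataset("channel_ids", data=np.array(trials.channel_ids, dtype=str_dt))
        if targets is not None:
            f.create_dataset("targets/data", data=targets.data)
            meta.attrs["target_fs"] = targets.fs
            meta.attrs["target_modality"] = targets.modality


def _read_hdf5(path) -> tuple[TrialSet, TargetSet | None]:
    import h5py

    with h5py.File(path, "r") as f:
        data = np.asarray(f["trials/data"])
        meta = f["meta"]
        labels = [s.decode() for s in meta["labels"][()]]
        channel_ids = [s.decode() for s in meta["channel_ids"][()]]
        trials = TrialSet(data=data, fs=float(meta.attrs["fs"]), labels=labels,
                          channel_ids=channel_ids)
        targets = None
        if "targets" in f:
            targets = TargetSet(
                data=np.asarray(f["targets/data"]),
                fs=float(meta.attrs["target_fs"]),
                modality=str(meta.attrs["target_modality"]),
            )
    return trials, targets


def _read_csvdir(path) -> TrialSet:
    """Directory of per-trial CSVs, samples x channels, header = channel ids.

    Trial order is the lexicographic file order; a file named
    ``<anything>__<label>.csv`` carries its condition label after the final
    double underscore, otherwise the label is the file stem.
    """
    import pandas as pd

    files = sorted(Path(path).glob("*.csv"))
    if not files:
        raise ValidationError(f"no CSV trials found in {path}")
    mats, labels, channel_ids = [], [], None
    for i, fp in enumerate(files):
        df = pd.read_csv(fp)
        if channel_ids is None:
            channel_ids = list(df.columns)
        elif list(df.columns) != channel_ids:
            raise ValidationError(f"trial {i} ({fp.name}): channel header mismatch")
        mats.append(df.to_numpy(dtype=np.float64).T)  # -> channels x samples
        stem = fp.stem
        labels.append(stem.rsplit("__", 1)[-1] if "__" in stem else stem)
    lengths = {m.shape[1] for m in mats}
    if len(lengths) > 1:
        ragged = [i for i, m in enumerate(mats) if m.shape[1] != mats[0].shape[1]]
        raise ValidationError(
            f"ragged trial lengths {sorted(lengths)}; offending trial indices {ragged}"
        )
    fs_file = Path(path) / "fs.txt"
    fs = float(fs_file.read_text().strip()) if fs_file.exists() else 1.0
    return TrialSet(data=np.stack(mats), fs=fs, labels=labels, channel_ids=channel_ids)


def read_trialset(path, format: str = "hdf5") -> TrialSet:
    """Read a TrialSet from ``path``.

    Parameters
    ----------
    path : path-like
        HDF5 container file, or a directory of per-trial CSVs.
    format : {"hdf5", "csvdir"}
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such dataset: {path}")
    if format == "hdf5":
        trials, _ = _read_hdf5(path)
        return trials
    if format == "csvdir":
        return _read_csvdir(path)
    raise ValueError(f"unknown format {format!r}")


def read_dataset(path) -> tuple[TrialSet, TargetSet | None]:
    """Read trials and (if present) targets from an HDF5 container."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such dataset: {path}")
    return _read_hdf5(path)


# ---------------------------------------------------------------------------
# WAV targets
# ---------------------------------------------------------------------------

def read_target_wav(path) -> TargetSet:
    """Read a mono WAV file as a single-trial TargetSet scaled to [-1, 1].

    Integer PCM is scaled by the full-scale value of its width; float WAV is
    taken as-is.  Multi-channel files are rejected: targets are scalar
    time series ("mono required").
    """
    from scipy.io import wavfile

    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValidationError(f"mono required: file has {data.shape[1]} channels")
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        x = data.astype(np.float64)
    else:
        raise ValidationError(f"unsupported WAV encoding {data.dtype}")
    return TargetSet(data=x[np.newaxis, :], fs=float(fs), modality="envelope")


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch(continuous: np.ndarray, fs: float, onsets: Sequence[int],
          duration: float, labels: Sequence[str] | None = None,
          channel_ids: Sequence[str] | None = None) -> TrialSet:
    """Cut a continuous multichannel recording into fixed-length trials.

    Each onset (0-based sample index) yields the half-open window
    ``[onset, onset + round(duration * fs))``.

    Parameters
    ----------
    continuous : ndarray, shape (n_channels, n_total)
    fs : float
    onsets : sequence of int
    duration : float
        Trial duration in seconds.
    """
    continuous = _as_float_array(continuous, "continuous", 2)
    n_total = continuous.shape[1]
    n_len = int(round(duration * fs))
    if n_len <= 0:
        raise ValidationError("empty window: duration must span at least one sample")
    onsets = [int(o) for o in onsets]
    for o in onsets:
        if o < 0 or o + n_len > n_total:
            raise ValidationError(
                f"window [{o}, {o + n_len}) exceeds recording of {n_total} samples"
            )
    data = np.stack([continuous[:, o:o + n_len] for o in onsets])
    if labels is None:
        labels = [f"trial{i:03d}" for i in range(len(onsets))]
    return TrialSet(data=data, fs=fs, labels=labels, channel_ids=channel_ids)
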