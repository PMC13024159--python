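"""Signal conditioning: resampling, band-pass filtering, patch segmentation, splits."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = ["RawRecording", "PreprocessConfig", "PatchedTrial", "resample",
           "bandpass", "segment_patches", "unpatch", "split_subjects",
           "split_trials", "preprocess"]


@dataclass
class RawRecording:
    """A C-by-T multichannel recording in microvolts."""

    signals: np.ndarray
    sfreq: float
    channel_names: list[str]

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValueError(f"signals must be 2-D (C, T), got {self.signals.shape}")
        c, t = self.signals.shape
        if c != len(self.channel_names):
            raise ValueError(
                f"{c} signal rows but {len(self.channel_names)} channel names")
        if t < 1:
            raise ValueError("recording must contain at least one sample")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq


@dataclass(frozen=True)
class PreprocessConfig:
    target_sfreq: float = 200.0
    band: tuple[float, float] | None = (0.3, 75.0)
    apply_bandpass: bool = False
    patch_size: int = 200

    def __post_init__(self):
        if self.target_sfreq <= 0:
            raise ValueError("target_sfreq must be positive")
        if self.patch_size < 2:
            raise ValueError("patch_size must be >= 2")
        if self.band is not None:
            lo, hi = self.band
            if not (0.0 < lo < hi < self.target_sfreq / 2.0):
                raise ValueError(
                    f"band {self.band} must satisfy 0 < low < high < "
                    f"target_sfreq/2 = {self.target_sfreq / 2}")


@dataclass
class PatchedTrial:
    """Non-overlapping segmentation of a trial into (C, N, P)."""

    patches: np.ndarray
    sfreq: float

    def __post_init__(self):
        self.patches = np.asarray(self.patches, dtype=np.float64)
        if self.patches.ndim != 3:
            raise ValueError(f"patches must be (C, N, P), got {self.patches.shape}")

    @property
    def n_patches(self) -> int:
        return self.patches.shape[1]

    @property
    def patch_size(self) -> int:
        return self.patches.shape[2]


def resample(rec: RawRecording, target_sfreq: float) -> RawRecording:
    """Polyphase rational resampling with built-in anti-aliasing."""
    if target_sfreq <= 0:
        raise ValueError("target_sfreq must be positive")
    if target_sfreq == rec.sfreq:
        return RawRecording(rec.signals.copy(), rec.sfreq, list(rec.channel_names))
    if target_sfreq > rec.sfreq:
        warnings.warn(
            f"upsampling from {rec.sfreq} Hz to {target_sfreq} Hz adds no "
            "information", stacklevel=2)
    frac = Fraction(target_sfreq / rec.sfreq).limit_denominator(10000)
    y = sps.resample_poly(rec.signals, frac.numerator, frac.denominator, axis=-1)
    want = int(round(rec.n_samples * target_sfreq / rec.sfreq))
    if y.shape[-1] > want:
        y = y[:, :want]
    elif y.shape[-1] < want:
        y = np.pad(y, ((0, 0), (0, want - y.shape[-1])), mode="edge")
    return RawRecording(y, target_sfreq, list(rec.channel_names))


def bandpass(rec: RawRecording, low: float, high: float) -> RawRecording:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward)."""
    nyq = rec.sfreq / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) must satisfy 0 < low < high < Nyquist {nyq}")
    sos = sps.butter(4, (low, high), btype="bandpass", fs=rec.sfreq, output="sos")
    y = sps.sosfiltfilt(sos, rec.signals, axis=-1)
    return RawRecording(y, rec.sfreq, list(rec.channel_names))


def segment_patches(rec: RawRecording, patch_size: int) -> PatchedTrial:
    """Reshape a (C, T) trial to (C, N, P) with N = floor(T/P).

    Trailing ``T mod P`` samples are discarded; patches never overlap, so
    ``patches[c, n, p] == signals[c, n*P + p]``.
    """
    p = int(patch_size)
    if p < 1:
        raise ValueError("patch size must be positive")
    t = rec.n_samples
    if t < p:
        raise ValueError(f"trial length {t} shorter than patch size {p}")
    n = t // p
    patches = rec.signals[:, :n * p].reshape(rec.n_channels, n, p)
    return PatchedTrial(patches=patches.copy(), sfreq=rec.sfreq)


def unpatch(pt: PatchedTrial, channel_names: list[str] | None = None) -> RawRecording:
    """Concatenate patches back into a (C, N*P) recording."""
    c, n, p = pt.patches.shape
    names = channel_names or [f"CH{i:02d}" for i in range(c)]
    return RawRecording(pt.patches.reshape(c, n * p), pt.sfreq, names)


def _partition_by_order(ids: np.ndarray, n_train: int, n_val: int,
                        what: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    distinct = list(dict.fromkeys(ids.tolist()))  # order of first appearance
    if n_train + n_val >= len(distinct):
        raise ValueError(
            f"n_train + n_val = {n_train + n_val} leaves no {what} for "
            f"testing out of {len(distinct)}")
    train_ids = set(distinct[:n_train])
    val_ids = set(distinct[n_train:n_train + n_val])
    idx = np.arange(len(ids))
    train = idx[[i in train_ids for i in ids]]
    val = idx[[i in val_ids for i in ids]]
    test = idx[[(i not in train_ids and i not in val_ids) for i in ids]]
    return train, val, test


def split_subjects(subject_ids, n_train: int, n_val: int):
    """Partition trial indices by subject: first ``n_train`` subjects (in order
    of first appearance) train, next ``n_val`` validate, the rest test."""
    ids = np.asarray(subject_ids)
    return _partition_by_order(ids, n_train, n_val, "subjects")


def split_trials(trial_ids, n_train: int, n_val: int):
    """Same contract as :func:`split_subjects` but keyed on per-subject trial
    numbers (the session-wise protocol: first trials train, next validate)."""
    ids = np.asarray(trial_ids)
    return _partition_by_order(ids, n_train, n_val, "trials")


def preprocess(rec: RawRecording, cfg: PreprocessConfig) -> PatchedTrial:
    """Full conditioning pipeline: resample, optional band-pass, segment."""
    out = resample(rec, cfg.target_sfreq)
    if cfg.apply_bandpass and cfg.band is not None:
        out = bandpass(out, *cfg.band)
    return segment_patches(out, cfg.patch_size)
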