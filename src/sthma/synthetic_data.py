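"""Synthetic multichannel EEG-like data with controllable spectral structure.

Each trial is ``mixing @ (1/f^alpha background + class-conditional band-limited
oscillation)``.  The background is synthesized in the frequency domain
(amplitude proportional to f^(-alpha/2), uniform random phases) so the
spectral slope is exact by construction.  The class oscillation is band-pass
filtered white noise, scaled so its in-band power is ``effect_size`` times the
background power in the same band — random phase across trials prevents a
single FFT bin from trivially solving the task.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .preprocessing import RawRecording

__all__ = ["SyntheticTaskSpec", "LabeledDataset", "generate_trial",
           "make_dataset", "write_fixture", "read_fixture", "band_power"]


@dataclass(frozen=True)
class SyntheticTaskSpec:
    """Recipe for a labeled synthetic EEG classification task."""

    n_channels: int = 8
    n_classes: int = 2
    sfreq: float = 200.0
    duration: float = 10.0
    noise_exponent: float = 1.0
    class_bands: tuple[tuple[float, float], ...] = ((8.0, 13.0), (30.0, 45.0))
    effect_size: float = 2.0
    mixing: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if len(self.class_bands) < self.n_classes:
            raise ValueError(
                f"need a band per class: {len(self.class_bands)} bands "
                f"for {self.n_classes} classes")
        nyq = self.sfreq / 2.0
        for lo, hi in self.class_bands:
            if not (0.0 < lo < hi < nyq):
                raise ValueError(
                    f"class band ({lo}, {hi}) must satisfy 0 < low < high < {nyq}")
        if self.mixing is not None:
            m = np.asarray(self.mixing, dtype=float)
            if m.shape != (self.n_channels, self.n_channels):
                raise ValueError(
                    f"mixing must be {self.n_channels}x{self.n_channels}, "
                    f"got {m.shape}")
            object.__setattr__(self, "mixing", m)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sfreq))


@dataclass
class LabeledDataset:
    trials: list[RawRecording]
    labels: np.ndarray
    subject_ids: np.ndarray
    spec: SyntheticTaskSpec | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=np.int64)
        if not (len(self.trials) == len(self.labels) == len(self.subject_ids)):
            raise ValueError("trials, labels and subject_ids must align")
        shapes = {t.signals.shape for t in self.trials}
        rates = {t.sfreq for t in self.trials}
        if len(shapes) > 1 or len(rates) > 1:
            raise ValueError("all trials must share shape and sfreq")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def signal_stack(self) -> np.ndarray:
        """All trials as one (n_trials, C, T) array."""
        return np.stack([t.signals for t in self.trials])


def _pink_background(rng: np.random.Generator, n_channels: int, n_samples: int,
                     sfreq: float, alpha: float) -> np.ndarray:
    """1/f^alpha Gaussian noise via frequency-domain shaping, unit variance."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    amp = np.ones_like(freqs)
    nz = freqs > 0
    amp[nz] = freqs[nz] ** (-alpha / 2.0)
    amp[0] = 0.0  # no DC offset
    phases = rng.uniform(0.0, 2.0 * np.pi, (n_channels, freqs.size))
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _band_oscillation(rng: np.random.Generator, n_channels: int, n_samples: int,
                      sfreq: float, band: tuple[float, float]) -> np.ndarray:
    """Band-pass filtered white noise, unit variance per channel."""
    sos = sps.butter(4, band, btype="bandpass", fs=sfreq, output="sos")
    white = rng.standard_normal((n_channels, n_samples + int(2 * sfreq)))
    y = sps.sosfiltfilt(sos, white, axis=-1)[:, int(sfreq):int(sfreq) + n_samples]
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def band_power(x: np.ndarray, sfreq: float, band: tuple[float, float]) -> np.ndarray:
    """Mean Welch PSD power in ``band``, averaged over channels.

    x: (C, T) or (..., C, T); returns scalar per leading index.
    """
    nper = min(x.shape[-1], int(2 * sfreq))
    freqs, psd = sps.welch(x, fs=sfreq, nperseg=nper, axis=-1)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return psd[..., sel].mean(axis=(-2, -1))


def generate_trial(spec: SyntheticTaskSpec, class_id: int, seed: int) -> RawRecording:
    """One C-by-T recording for ``class_id``; deterministic given ``seed``."""
    if not 0 <= class_id < spec.n_classes:
        raise ValueError(
            f"class_id {class_id} out of range [0, {spec.n_classes})")
    n = spec.n_samples
    rng = np.random.default_rng(seed)
    bg = _pink_background(rng, spec.n_channels, n, spec.sfreq, spec.noise_exponent)
    x = bg
    if spec.effect_size > 0:
        band = spec.class_bands[class_id]
        osc = _band_oscillation(rng, spec.n_channels, n, spec.sfreq, band)
        # scale oscillation so its band power is effect_size x background's
        p_bg = band_power(bg, spec.sfreq, band)
        p_osc = band_power(osc, spec.sfreq, band)
        gain = np.sqrt(spec.effect_size * p_bg / p_osc)
        x = bg + gain * osc
    else:
        # keep the RNG stream aligned so effect_size=0 reuses the same background
        pass
    if spec.mixing is not None:
        x = spec.mixing @ x
    names = [f"CH{i:02d}" for i in range(spec.n_channels)]
    return RawRecording(signals=x, sfreq=spec.sfreq, channel_names=names)


def _trial_seed(master_seed: int, trial_index: int) -> int:
    """Independent per-trial stream derived from (seed, index)."""
    ss = np.random.SeedSequence([master_seed, trial_index])
    return int(ss.generate_state(1)[0])


def make_dataset(spec: SyntheticTaskSpec, n_trials_per_class: int,
                 n_subjects: int, seed: int | None = None) -> LabeledDataset:
    """Balanced labeled dataset; subjects assigned round-robin over trials."""
    if n_trials_per_class < 1:
        raise ValueError("n_trials_per_class must be >= 1")
    total = n_trials_per_class * spec.n_classes
    if n_subjects > total:
        raise ValueError(
            f"n_subjects={n_subjects} exceeds total trials {total}")
    master = spec.seed if seed is None else seed
    trials, labels, subjects = [], [], []
    idx = 0
    for cls in range(spec.n_classes):
        for _ in range(n_trials_per_class):
            trials.append(generate_trial(spec, cls, _trial_seed(master, idx)))
            labels.append(cls)
            subjects.append(idx % n_subjects)
            idx += 1
    return LabeledDataset(trials=trials, labels=np.array(labels),
                          subject_ids=np.array(subjects), spec=spec)


_REQUIRED_FIELDS = ("signals", "labels", "subject_ids", "sfreq", "channel_names")


def write_fixture(ds: LabeledDataset, path) -> None:
    """Save as a compressed array archive (lossless float64 round-trip)."""
    if len(ds.trials):
        signals = ds.signal_stack()
        names = np.array(ds.trials[0].channel_names)
        sfreq = ds.trials[0].sfreq
    else:
        signals = np.zeros((0, 0, 0))
        names = np.array([], dtype=str)
        sfreq = ds.spec.sfreq if ds.spec is not None else 0.0
    np.savez_compressed(path, signals=signals, labels=ds.labels,
                        subject_ids=ds.subject_ids, sfreq=np.float64(sfreq),
                        channel_names=names)


class FixtureFormatError(ValueError):
    pass


def read_fixture(path) -> LabeledDataset:
    try:
        with np.load(path, allow_pickle=False) as arc:
            missing = [f for f in _REQUIRED_FIELDS if f not in arc.files]
            if missing:
                raise FixtureFormatError(
                    f"fixture archive missing field(s): {missing}")
            signals = arc["signals"]
            labels = arc["labels"]
            subject_ids = arc["subject_ids"]
            sfreq = float(arc["sfreq"])
            names = [str(c) for c in arc["channel_names"]]
    except (zipfile.BadZipFile, OSError, io.UnsupportedOperation) as e:
        raise FixtureFormatError(f"not a readable fixture archive: {e}") from e
    trials = [RawRecording(signals=signals[i], sfreq=sfreq, channel_names=names)
              for i in range(signals.shape[0])]
    return LabeledDataset(trials=trials, labels=labels, subject_ids=subject_ids)
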