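"""Dual-domain patch embedding: temporal convolution + log-magnitude spectrum.

Both streams map a patched batch (B, C, N, P) to a latent (B, C, N, D); the
fused embedding adds a learnable positional table over the (C, N) grid.

The spectral stream is phase-blind by construction — it sees only rFFT
magnitudes — while the temporal stream sees the raw waveform; the two are
therefore complementary rather than redundant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, as_tensor
from .nn import GroupNorm, Linear, Module, Parameter, depthwise_conv_same

__all__ = ["EmbeddingConfig", "TemporalStream", "SpectralStream",
           "DualDomainEmbedding", "log_magnitude_spectrum", "fuse"]


@dataclass(frozen=True)
class EmbeddingConfig:
    embed_dim: int = 32
    patch_size: int = 64
    conv_kernel: int = 7
    gn_groups: int = 4
    pos_init_std: float = 0.02

    def __post_init__(self):
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if self.conv_kernel % 2 != 1:
            raise ValueError("conv_kernel must be odd (symmetric same padding)")
        if self.embed_dim % self.gn_groups != 0:
            raise ValueError("gn_groups must divide embed_dim")

    @property
    def freq_bins(self) -> int:
        return self.patch_size // 2 + 1


class TemporalStream(Module):
    """Depthwise-separable conv along the intra-patch axis, GN, GELU, mean-pool.

    Depthwise kernel (shared across EEG channels) filters each patch waveform;
    a pointwise projection lifts it to D feature maps; GroupNorm runs over the
    D maps at each (c, n) location before the GELU.
    """

    def __init__(self, cfg: EmbeddingConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        rng = rng or np.random.default_rng()
        k = cfg.conv_kernel
        self.depthwise = Parameter(rng.normal(0.0, 1.0 / np.sqrt(k), (1, k)))
        self.pointwise = Linear(1, cfg.embed_dim, bias=True, rng=rng)
        self.norm = GroupNorm(cfg.gn_groups, cfg.embed_dim)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        b, c, n, p = x.shape
        if p < self.cfg.conv_kernel:
            raise ValueError(
                f"patch size {p} shorter than conv kernel {self.cfg.conv_kernel}")
        d = self.cfg.embed_dim
        h = x.reshape((b, c, n, 1, p))
        h = depthwise_conv_same(h, self.depthwise)          # (B, C, N, 1, P)
        h = h.transpose((0, 1, 2, 4, 3))                     # (B, C, N, P, 1)
        h = self.pointwise(h)                                # (B, C, N, P, D)
        h = self.norm(h)
        h = h.gelu()
        return h.mean(axis=3)                                # pool over P


def log_magnitude_spectrum(x: np.ndarray) -> np.ndarray:
    """log(1 + |rFFT|) over the last axis: (..., P) -> (..., P//2 + 1)."""
    return np.log1p(np.abs(np.fft.rfft(np.asarray(x, dtype=np.float64), axis=-1)))


class SpectralStream(Module):
    """Bias-free linear projection of the per-patch log-magnitude spectrum.

    The FFT acts on raw input (no gradient flows through it), so the stream's
    only learnables are the projection weights.
    """

    def __init__(self, cfg: EmbeddingConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        rng = rng or np.random.default_rng()
        self.proj = Linear(cfg.freq_bins, cfg.embed_dim, bias=False, rng=rng)

    def features(self, x) -> np.ndarray:
        """Pre-projection log-magnitude features (B, C, N, P//2+1)."""
        arr = x.data if isinstance(x, Tensor) else np.asarray(x)
        return log_magnitude_spectrum(arr)

    def forward(self, x) -> Tensor:
        feats = self.features(x)
        if feats.shape[-1] != self.cfg.freq_bins:
            raise ValueError(
                f"expected patches of size {self.cfg.patch_size} "
                f"({self.cfg.freq_bins} bins), got {feats.shape[-1]} bins")
        return self.proj(Tensor(feats))


def fuse(etime: Tensor, efreq: Tensor, pos) -> Tensor:
    """Elementwise sum of the streams plus the positional table (no scaling)."""
    etime, efreq, pos = as_tensor(etime), as_tensor(efreq), as_tensor(pos)
    try:
        np.broadcast_shapes(etime.shape, efreq.shape, pos.shape)
    except ValueError as e:
        raise ValueError(f"stream shapes not broadcastable: {e}") from e
    return etime + efreq + pos


class DualDomainEmbedding(Module):
    """Fused embedding H0 = temporal + spectral + positional."""

    def __init__(self, cfg: EmbeddingConfig, n_channels: int, n_patches: int,
                 rng: np.random.Generator | None = None,
                 use_temporal: bool = True, use_spectral: bool = True):
        super().__init__()
        if not (use_temporal or use_spectral):
            raise ValueError("at least one embedding stream must be enabled")
        self.cfg = cfg
        rng = rng or np.random.default_rng()
        self.temporal = TemporalStream(cfg, rng) if use_temporal else None
        self.spectral = SpectralStream(cfg, rng) if use_spectral else None
        self.pos = Parameter(rng.normal(
            0.0, cfg.pos_init_std, (n_channels, n_patches, cfg.embed_dim)))

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        b, c, n, p = x.shape
        if (c, n) != self.pos.shape[:2]:
            raise ValueError(
                f"input grid ({c}, {n}) does not match positional table "
                f"{self.pos.shape[:2]}")
        zero = Tensor(np.zeros((b, c, n, self.cfg.embed_dim)))
        et = self.temporal(x) if self.temporal is not None else zero
        ef = self.spectral(x) if self.spectral is not None else zero
        return fuse(et, ef, self.pos)


class LinearPatchEmbedding(Module):
    """Plain learned projection of raw patches (the no-dual-domain ablation)."""

    def __init__(self, cfg: EmbeddingConfig, n_channels: int, n_patches: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        rng = rng or np.random.default_rng()
        self.proj = Linear(cfg.patch_size, cfg.embed_dim, rng=rng)
        self.pos = Parameter(rng.normal(
            0.0, cfg.pos_init_std, (n_channels, n_patches, cfg.embed_dim)))

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        return self.proj(x) + self.pos
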