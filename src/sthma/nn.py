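"""Neural-network building blocks (layers, init, optimizer) on the autograd core."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from ._autograd import Tensor, concatenate

__all__ = [
    "Parameter", "Module", "Linear", "LayerNorm", "GroupNorm", "Dropout",
    "MultiHeadSelfAttention", "depthwise_conv_same", "causal_depthwise_conv",
    "AdamW",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Lightweight container with parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def parameters(self) -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield name, value
            elif isinstance(value, Module):
                for sub, p in value.parameters():
                    yield f"{name}.{sub}", p
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, p in item.parameters():
                            yield f"{name}.{i}.{sub}", p
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def n_parameters(self) -> int:
        return sum(p.size for _, p in self.parameters())

    def zero_grad(self) -> None:
        for _, p in self.parameters():
            p.grad = None

    def train(self) -> "Module":
        self._set_mode(True)
        return self

    def eval(self) -> "Module":
        self._set_mode(False)
        return self

    def _set_mode(self, flag: bool) -> None:
        self.training = flag
        for value in vars(self).values():
            if isinstance(value, Module):
                value._set_mode(flag)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item._set_mode(flag)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return xn * self.gamma + self.beta


class GroupNorm(Module):
    """Normalizes groups of the trailing feature axis; batch independent."""

    def __init__(self, n_groups: int, dim: int, eps: float = 1e-5):
        super().__init__()
        if dim % n_groups != 0:
            raise ValueError(f"n_groups={n_groups} must divide dim={dim}")
        self.n_groups = n_groups
        self.dim = dim
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        lead = x.shape[:-1]
        g = self.n_groups
        xg = x.reshape(lead + (g, self.dim // g))
        mu = xg.mean(axis=-1, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = (xc / (var + self.eps).sqrt()).reshape(lead + (self.dim,))
        return xn * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * mask


def depthwise_conv_same(x: Tensor, kernel: Tensor, bias: Tensor | None = None) -> Tensor:
    """Depthwise 1-D convolution over the last axis with 'same' zero padding.

    x: (..., M, T) with M input maps; kernel: (M, k) with k odd.
    """
    m, k = kernel.shape
    if k % 2 != 1:
        raise ValueError("kernel size must be odd for symmetric same padding")
    t = x.shape[-1]
    if t < k:
        raise ValueError(f"signal length {t} shorter than kernel {k}")
    half = k // 2
    xp = x.pad_axis(-1, half, half)
    y = None
    for j in range(k):
        term = xp[..., j:j + t] * kernel[:, j:j + 1]
        y = term if y is None else y + term
    if bias is not None:
        y = y + bias.reshape((m, 1))
    return y


def causal_depthwise_conv(x: Tensor, kernel: Tensor, bias: Tensor | None = None) -> Tensor:
    """Depthwise 1-D convolution over axis -2 (sequence) with left-only padding.

    x: (..., L, M); kernel: (M, k).  Output at position t sees x[t-k+1 .. t];
    kernel[:, -1] is the current-position tap.
    """
    m, k = kernel.shape
    el = x.shape[-2]
    xp = x.pad_axis(-2, k - 1, 0)
    y = None
    for j in range(k):
        term = xp[..., j:j + el, :] * kernel[:, j]
        y = term if y is None else y + term
    if bias is not None:
        y = y + bias
    return y


class MultiHeadSelfAttention(Module):
    """Pre-softmax scaled dot-product attention over the token axis.

    Input/output: (B, L, D).  No positional encoding is added here.
    """

    def __init__(self, dim: int, n_heads: int, attn_dropout: float = 0.1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError(f"dim={dim} not divisible by n_heads={n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        rng = rng or np.random.default_rng()
        self.qkv = Linear(dim, 3 * dim, rng=rng)
        self.out_proj = Linear(dim, dim, rng=rng)
        self.drop = Dropout(attn_dropout, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        b, el, d = x.shape
        h, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x)                                    # (B, L, 3D)
        q = qkv[..., :d].reshape((b, el, h, hd)).transpose((0, 2, 1, 3))
        k = qkv[..., d:2 * d].reshape((b, el, h, hd)).transpose((0, 2, 1, 3))
        v = qkv[..., 2 * d:].reshape((b, el, h, hd)).transpose((0, 2, 1, 3))
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(hd))
        attn = scores.softmax(axis=-1)
        attn = self.drop(attn)
        ctx = attn @ v                                       # (B, H, L, hd)
        ctx = ctx.transpose((0, 2, 1, 3)).reshape((b, el, d))
        return self.out_proj(ctx)

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """Softmax attention map (B, H, L, L); diagnostic, no dropout."""
        b, el, d = x.shape
        h, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x).data
        q = qkv[..., :d].reshape(b, el, h, hd).transpose(0, 2, 1, 3)
        k = qkv[..., d:2 * d].reshape(b, el, h, hd).transpose(0, 2, 1, 3)
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(hd)
        e = np.exp(scores - scores.max(axis=-1, keepdims=True))
        return e / e.sum(axis=-1, keepdims=True)


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[tuple[str, Parameter]], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {name: np.zeros_like(p.data) for name, p in self.params}
        self._v = {name: np.zeros_like(p.data) for name, p in self.params}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for name, p in self.params:
            if p.grad is None:
                continue
            g = p.grad
            m = self._m[name] = b1 * self._m[name] + (1 - b1) * g
            v = self._v[name] = b2 * self._v[name] + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.grad = None
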