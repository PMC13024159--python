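"""Classification head: global attention recalibration, MLP, smoothed loss."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, as_tensor
from .nn import Dropout, LayerNorm, Linear, Module, MultiHeadSelfAttention

__all__ = ["HeadConfig", "Prediction", "GlobalRecalibration", "ClassifierHead",
           "label_smoothing_ce"]


@dataclass(frozen=True)
class HeadConfig:
    n_classes: int = 2
    n_attn_heads: int = 4
    mlp_hidden: tuple[int, int] = (256, 64)
    dropout: tuple[float, float] = (0.5, 0.3)
    smoothing: float = 0.1
    attn_dropout: float = 0.1

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0.0 <= self.smoothing < 1.0:
            raise ValueError("smoothing must lie in [0, 1)")
        if len(self.mlp_hidden) != 2 or len(self.dropout) != 2:
            raise ValueError("the MLP has three linear layers: two hidden widths"
                             " and two dropout rates are required")


@dataclass
class Prediction:
    logits: np.ndarray
    probabilities: np.ndarray
    predicted_class: np.ndarray

    def __post_init__(self):
        rs = self.probabilities.sum(axis=-1)
        if not np.allclose(rs, 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        if not np.array_equal(self.predicted_class,
                              self.logits.argmax(axis=-1)):
            raise ValueError("predicted_class inconsistent with logits")

    @classmethod
    def from_logits(cls, logits: np.ndarray) -> "Prediction":
        logits = np.asarray(logits, dtype=np.float64)
        shifted = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        probs = e / e.sum(axis=-1, keepdims=True)
        return cls(logits=logits, probabilities=probs,
                   predicted_class=logits.argmax(axis=-1))


class GlobalRecalibration(Module):
    """Pre-norm multi-head self-attention over all C*N tokens plus residual.

    Operates on the flattened (B, C*N, D) view and restores (B, C, N, D).
    No positional encoding is re-added: positions were injected once at the
    embedding stage.
    """

    def __init__(self, dim: int, n_heads: int, attn_dropout: float = 0.1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.norm = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, attn_dropout, rng=rng)

    def forward(self, h: Tensor) -> Tensor:
        h = as_tensor(h)
        b, c, n, d = h.shape
        tokens = h.reshape((b, c * n, d))
        out = self.attn(self.norm(tokens)) + tokens
        return out.reshape((b, c, n, d))


class ClassifierHead(Module):
    """Three linear layers with ELU and dropout; emits K logits."""

    def __init__(self, in_features: int, cfg: HeadConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        h1, h2 = cfg.mlp_hidden
        self.fc1 = Linear(in_features, h1, rng=rng)
        self.fc2 = Linear(h1, h2, rng=rng)
        self.fc3 = Linear(h2, cfg.n_classes, rng=rng)
        self.drop1 = Dropout(cfg.dropout[0], rng=rng)
        self.drop2 = Dropout(cfg.dropout[1], rng=rng)
        self.in_features = in_features

    def forward(self, h: Tensor) -> Tensor:
        h = as_tensor(h)
        b = h.shape[0]
        flat = h.reshape((b, -1))
        if flat.shape[1] != self.in_features:
            raise ValueError(
                f"flattened width {flat.shape[1]} != head width {self.in_features}")
        z = self.drop1(self.fc1(flat).elu())
        z = self.drop2(self.fc2(z).elu())
        return self.fc3(z)

    def predict(self, h: Tensor) -> Prediction:
        return Prediction.from_logits(self.forward(h).data)


def label_smoothing_ce(logits: Tensor, y: np.ndarray, smoothing: float) -> Tensor:
    """Mean label-smoothing cross-entropy over the batch.

    loss_b = -sum_i [ (1 - eps) * onehot_i + eps / K ] * log p_i
    """
    if not 0.0 <= smoothing < 1.0:
        raise ValueError(f"smoothing must lie in [0, 1), got {smoothing}")
    logits = as_tensor(logits)
    y = np.asarray(y, dtype=np.int64)
    b, k = logits.shape
    if y.shape != (b,):
        raise ValueError(f"labels shape {y.shape} does not match batch {b}")
    if y.min() < 0 or y.max() >= k:
        raise ValueError(f"labels must lie in [0, {k - 1}]")
    target = np.full((b, k), smoothing / k)
    target[np.arange(b), y] += 1.0 - smoothing
    logp = logits.log_softmax(axis=-1)
    return -(logp * target).sum(axis=-1).mean()


def smoothed_entropy_floor(k: int, smoothing: float) -> float:
    """Lower bound of the smoothed loss: entropy of the smoothed target."""
    w_true = (1.0 - smoothing) + smoothing / k
    w_rest = smoothing / k
    floor = -w_true * np.log(w_true)
    if w_rest > 0:
        floor -= (k - 1) * w_rest * np.log(w_rest)
    return float(floor)
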