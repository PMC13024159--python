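"""Full classifier: dual-domain embedding -> SSM backbone -> attention -> MLP."""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from ._autograd import Tensor, as_tensor, no_grad
from .backbone import Backbone, BackboneConfig, SSDConfig
from .embedding import DualDomainEmbedding, EmbeddingConfig, LinearPatchEmbedding
from .head import ClassifierHead, GlobalRecalibration, HeadConfig, Prediction
from .nn import Module

__all__ = ["ModelConfig", "STHMAModel", "build_model", "load_preset",
           "available_presets", "VARIANTS"]

VARIANTS = ("full", "no_temporal_stream", "no_spectral_stream",
            "no_dual_domain", "no_backbone", "pure_mamba2")


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed to build the classifier for a fixed input grid."""

    n_channels: int = 8
    n_patches: int = 4
    patch_size: int = 64
    n_classes: int = 2
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    ssd: SSDConfig = field(default_factory=SSDConfig)
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    variant: str = "full"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.embedding.patch_size != self.patch_size:
            object.__setattr__(self, "embedding",
                               EmbeddingConfig(**{**asdict(self.embedding),
                                                  "patch_size": self.patch_size}))
        if self.head.n_classes != self.n_classes:
            object.__setattr__(self, "head",
                               HeadConfig(**{**asdict(self.head),
                                             "n_classes": self.n_classes}))

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key, sub in (("embedding", EmbeddingConfig), ("ssd", SSDConfig),
                         ("backbone", BackboneConfig), ("head", HeadConfig)):
            if key in d and isinstance(d[key], dict):
                sd = dict(d[key])
                for tkey in ("schedule", "mlp_hidden", "dropout", "a_init",
                             "class_bands", "band"):
                    if tkey in sd and isinstance(sd[tkey], list):
                        sd[tkey] = tuple(
                            tuple(v) if isinstance(v, list) else v
                            for v in sd[tkey])
                d[key] = sub(**sd)
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    def with_variant(self, variant: str) -> "ModelConfig":
        return ModelConfig(**{**asdict(self), "variant": variant,
                              "embedding": self.embedding, "ssd": self.ssd,
                              "backbone": self.backbone, "head": self.head})


class STHMAModel(Module):
    """The hybrid state-space/attention EEG classifier.

    Ablation variants rewire the same skeleton:

    - ``no_temporal_stream`` / ``no_spectral_stream``: drop one embedding stream
    - ``no_dual_domain``: plain linear patch projection instead of both streams
    - ``no_backbone``: remove the SSM stack (embedding -> attention -> head)
    - ``pure_mamba2``: remove the global attention (embedding -> backbone -> head)
    """

    def __init__(self, cfg: ModelConfig, seed: int | None = None):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        d = cfg.embedding.embed_dim
        variant = cfg.variant
        if variant == "no_dual_domain":
            self.embedding = LinearPatchEmbedding(
                cfg.embedding, cfg.n_channels, cfg.n_patches, rng)
        else:
            self.embedding = DualDomainEmbedding(
                cfg.embedding, cfg.n_channels, cfg.n_patches, rng,
                use_temporal=variant != "no_temporal_stream",
                use_spectral=variant != "no_spectral_stream")
        self.backbone = (None if variant == "no_backbone"
                         else Backbone(d, cfg.ssd, cfg.backbone, rng))
        self.recalibration = (None if variant == "pure_mamba2"
                              else GlobalRecalibration(
                                  d, cfg.head.n_attn_heads,
                                  cfg.head.attn_dropout, rng))
        self.head = ClassifierHead(cfg.n_channels * cfg.n_patches * d,
                                   cfg.head, rng)

    @property
    def n_channels(self) -> int:
        return self.cfg.n_channels

    def latent(self, x) -> Tensor:
        """Representation just before the classifier MLP."""
        x = as_tensor(x)
        if x.ndim == 3:
            x = x.reshape((1,) + x.shape)
        b, c, n, p = x.shape
        if c != self.cfg.n_channels:
            raise ValueError(
                f"expected {self.cfg.n_channels} channels, got {c}")
        if n != self.cfg.n_patches or p != self.cfg.patch_size:
            raise ValueError(
                f"expected grid ({self.cfg.n_patches}, {self.cfg.patch_size}),"
                f" got ({n}, {p})")
        h = self.embedding(x)
        if self.backbone is not None:
            h = self.backbone(h)
        if self.recalibration is not None:
            h = self.recalibration(h)
        return h

    def forward(self, x) -> Tensor:
        return self.head(self.latent(x))

    def predict(self, x) -> Prediction:
        mode = self.training
        self.eval()
        try:
            with no_grad():
                logits = self.forward(x).data
        finally:
            self._set_mode(mode)
        return Prediction.from_logits(logits)

    # ------------------------------------------------------------ checkpoint
    def save_checkpoint(self, path) -> None:
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            yaml.safe_dump(self.cfg.to_dict()).encode(), dtype=np.uint8)
        np.savez_compressed(path, **state)

    @classmethod
    def load_checkpoint(cls, path) -> "STHMAModel":
        with np.load(path, allow_pickle=False) as arc:
            cfg = ModelConfig.from_dict(
                yaml.safe_load(bytes(arc["__config__"]).decode()))
            state = {k: arc[k] for k in arc.files if k != "__config__"}
        model = cls(cfg, seed=0)
        model.load_state_dict(state)
        return model


def build_model(cfg: ModelConfig, seed: int | None = None,
                variant: str = "full") -> STHMAModel:
    if variant != "full":
        cfg = cfg.with_variant(variant)
    return STHMAModel(cfg, seed=seed)


def available_presets() -> list[str]:
    root = importlib.resources.files("sthma.presets")
    return sorted(p.name.removesuffix(".yaml") for p in root.iterdir()
                  if p.name.endswith(".yaml"))


def load_preset(name: str) -> dict:
    """Load a named preset; returns the raw dict with ``model``,
    ``preprocess`` and ``train`` sections (``model`` parsed on demand via
    :meth:`ModelConfig.from_dict`)."""
    root = importlib.resources.files("sthma.presets")
    res = root / f"{name}.yaml"
    if not res.is_file():
        raise KeyError(
            f"unknown preset {name!r}; available: {available_presets()}")
    return yaml.safe_load(res.read_text())


def model_from_preset(name: str, seed: int | None = None,
                      variant: str = "full") -> STHMAModel:
    return build_model(ModelConfig.from_dict(load_preset(name)["model"]),
                       seed=seed, variant=variant)
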