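import numpy as np
import pytest

from sthma.backbone import BackboneConfig, SSDConfig
from sthma.embedding import EmbeddingConfig
from sthma.head import HeadConfig
from sthma.model import ModelConfig
from sthma.synthetic_data import SyntheticTaskSpec, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """Small config used across model/training tests (C=4, N=4, P=64, D=16)."""
    return ModelConfig(
        n_channels=4, n_patches=4, patch_size=64, n_classes=2,
        embedding=EmbeddingConfig(embed_dim=16, patch_size=64,
                                  conv_kernel=7, gn_groups=4),
        ssd=SSDConfig(d_state=8, n_heads=2, head_dim=16, expand=2),
        backbone=BackboneConfig(depth=2),
        head=HeadConfig(n_classes=2, n_attn_heads=4,
                        mlp_hidden=(64, 32), dropout=(0.3, 0.2)))


@pytest.fixture(scope="session")
def alpha_task_spec():
    """2-class task separable by alpha-band (8-13 Hz) power, effect size 4."""
    return SyntheticTaskSpec(
        n_channels=4, n_classes=2, sfreq=128.0, duration=2.0,
        noise_exponent=1.0, class_bands=((8.0, 13.0), (30.0, 45.0)),
        effect_size=4.0, seed=3)


@pytest.fixture(scope="session")
def alpha_dataset(alpha_task_spec):
    return make_dataset(alpha_task_spec, n_trials_per_class=100,
                        n_subjects=10, seed=3)


def random_scan_instance(rng, el=12, h=2, dh=3, s=4, lead=()):
    """A random, numerically tame selective-scan problem."""
    return dict(
        x=rng.standard_normal((*lead, el, h, dh)),
        dt=rng.uniform(0.01, 0.5, (*lead, el, h)),
        a=-rng.uniform(0.3, 3.0, h),
        b_seq=rng.standard_normal((*lead, el, s)),
        c_seq=rng.standard_normal((*lead, el, s)),
        d_skip=rng.standard_normal((h, dh)),
    )


def dense_scan_oracle(x, dt, a, b_seq, c_seq, d_skip=None):
    """O(L^2) brute force: materialize the lower-triangular causal operator."""
    el, h, dh = x.shape
    abar = np.exp(dt * a)
    y = np.zeros_like(x)
    for hh in range(h):
        kern = np.zeros((el, el))
        for t in range(el):
            for tau in range(t + 1):
                decay = np.prod(abar[tau + 1:t + 1, hh])
                kern[t, tau] = decay * (c_seq[t] @ b_seq[tau]) * dt[tau, hh]
        for d in range(dh):
            y[:, hh, d] = kern @ x[:, hh, d]
            if d_skip is not None:
                y[:, hh, d] += d_skip[hh, d] * x[:, hh, d]
    return y
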