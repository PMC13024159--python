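"""Selective state-space backbone with decoupled spatial/temporal serialization.

The normative scan is a sequential zero-order-hold recurrence

    h_t = exp(dt_t * A) * h_{t-1} + dt_t * outer(B_t, x_t)
    y_t = C_t . h_t + D_skip * x_t

with a scalar decay per head (A < 0 for stability), data-dependent dt/B/C,
and a per-channel skip.  ``ssd_scan_reference`` is the plain numpy version
used as an oracle target; ``SSDScan`` wraps the same recurrence with a
hand-derived backward pass for training; ``ssd_scan_chunked`` is an optional
chunked evaluation path that must agree with the reference numerically.

Serialization between the (B, C, N, D) latent grid and (B, L, D) token
sequences is done by ``unfold``/``fold``: the spatial-first layout places the
C channels in the inner loop (token n*C + c), the temporal-first layout the
N patches (token c*N + n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from ._autograd import Tensor, as_tensor
from .nn import LayerNorm, Linear, Module, Parameter, causal_depthwise_conv

__all__ = ["SSDConfig", "BackboneConfig", "SequenceView", "ssd_scan_reference",
           "ssd_scan_chunked", "unfold", "fold", "MambaBlock",
           "bidirectional_forward", "Backbone", "SPATIAL_FIRST", "TEMPORAL_FIRST"]

SPATIAL_FIRST = "spatial_first"
TEMPORAL_FIRST = "temporal_first"
Layout = Literal["spatial_first", "temporal_first"]


class NumericalError(FloatingPointError):
    pass


@dataclass(frozen=True)
class SSDConfig:
    d_state: int = 16
    n_heads: int = 4
    head_dim: int = 16
    expand: int = 2
    conv_kernel: int = 4
    dt_min: float = 1e-3
    dt_max: float = 1e-1
    a_init: tuple[float, float] = (1.0, 16.0)  # A ~ -Uniform[range]

    def __post_init__(self):
        for name in ("d_state", "n_heads", "head_dim", "expand", "conv_kernel"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.dt_min < self.dt_max:
            raise ValueError("dt_min must be < dt_max")
        if self.a_init[0] <= 0:
            raise ValueError("a_init range must be positive (A = -a is negative)")

    @property
    def d_inner(self) -> int:
        return self.n_heads * self.head_dim


@dataclass(frozen=True)
class BackboneConfig:
    depth: int = 4
    schedule: tuple[str, ...] | None = None  # default: alternating from spatial
    bidirectional: bool = True
    residual: bool = True

    def resolved_schedule(self) -> tuple[str, ...]:
        if self.schedule is None:
            return tuple(SPATIAL_FIRST if i % 2 == 0 else TEMPORAL_FIRST
                         for i in range(self.depth))
        if len(self.schedule) != self.depth:
            raise ValueError(
                f"schedule length {len(self.schedule)} != depth {self.depth}")
        for lay in self.schedule:
            if lay not in (SPATIAL_FIRST, TEMPORAL_FIRST):
                raise ValueError(f"unknown layout {lay!r}")
        return tuple(self.schedule)


# --------------------------------------------------------------------- scan

def _check_scan_args(x, dt, a, b_seq, c_seq):
    if np.any(a >= 0):
        raise ValueError("per-head decay A must be strictly negative")
    for name, arr in (("x", x), ("dt", dt), ("A", a), ("B", b_seq), ("C", c_seq)):
        if not np.all(np.isfinite(arr)):
            raise NumericalError(f"non-finite values in scan input {name}")


def ssd_scan_reference(x: np.ndarray, dt: np.ndarray, a: np.ndarray,
                       b_seq: np.ndarray, c_seq: np.ndarray,
                       d_skip: np.ndarray | None = None) -> np.ndarray:
    """Sequential selective-scan recurrence (numpy, no gradients).

    Shapes (leading batch dims ``...`` allowed):
      x: (..., L, H, Dh); dt: (..., L, H); a: (H,);
      b_seq, c_seq: (..., L, S); d_skip: (H, Dh) or None.
    Returns y with the shape of x.  Strictly causal in t.
    """
    x = np.asarray(x, dtype=np.float64)
    dt = np.asarray(dt, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    b_seq = np.asarray(b_seq, dtype=np.float64)
    c_seq = np.asarray(c_seq, dtype=np.float64)
    _check_scan_args(x, dt, a, b_seq, c_seq)
    *lead, el, h, dh = x.shape
    s = b_seq.shape[-1]
    abar = np.exp(dt * a)                                  # (..., L, H)
    hstate = np.zeros((*lead, h, dh, s))
    y = np.empty_like(x)
    for t in range(el):
        dbx = (dt[..., t, :, None, None] * x[..., t, :, :, None]
               * b_seq[..., t, None, None, :])             # (..., H, Dh, S)
        hstate = abar[..., t, :, None, None] * hstate + dbx
        if not np.all(np.isfinite(hstate)):
            raise NumericalError(f"scan state overflow at step {t}")
        y[..., t, :, :] = np.einsum("...hds,...s->...hd", hstate,
                                    c_seq[..., t, :])
    if d_skip is not None:
        y = y + d_skip * x
    return y


def ssd_scan_chunked(x, dt, a, b_seq, c_seq, d_skip=None,
                     chunk: int = 64) -> np.ndarray:
    """Chunk-parallel evaluation of the same recurrence.

    Within each chunk the causal kernel is materialized densely; chunks are
    stitched with the carried state.  Agrees with the reference to float
    round-off.
    """
    x = np.asarray(x, dtype=np.float64)
    dt = np.asarray(dt, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    b_seq = np.asarray(b_seq, dtype=np.float64)
    c_seq = np.asarray(c_seq, dtype=np.float64)
    _check_scan_args(x, dt, a, b_seq, c_seq)
    *lead, el, h, dh = x.shape
    s = b_seq.shape[-1]
    log_abar = dt * a                                      # (..., L, H)
    y = np.empty_like(x)
    hstate = np.zeros((*lead, h, dh, s))
    for lo in range(0, el, chunk):
        hi = min(lo + chunk, el)
        la = log_abar[..., lo:hi, :]                       # (..., m, H)
        csum = np.cumsum(la, axis=-2)
        # decay from input step j (exclusive) to output step t: exp(csum_t - csum_j)
        decay = np.exp(csum[..., :, None, :] - csum[..., None, :, :])
        tril = np.tril(np.ones((hi - lo, hi - lo)))
        kern = decay * tril[..., None]                     # (..., t, j, H)
        dbx = (dt[..., lo:hi, :, None, None] * x[..., lo:hi, :, :, None]
               * b_seq[..., lo:hi, None, None, :])         # (..., m, H, Dh, S)
        # intra-chunk: y_t = sum_j<=t C_t . (decay_tj * dbx_j)
        hs = np.einsum("...tjh,...jhds->...thds", kern, dbx)
        # carried state from previous chunks
        hs = hs + np.exp(csum)[..., :, :, None, None] * hstate[..., None, :, :, :]
        y[..., lo:hi, :, :] = np.einsum("...thds,...ts->...thd",
                                        hs, c_seq[..., lo:hi, :])
        hstate = hs[..., -1, :, :, :]
    if d_skip is not None:
        y = y + d_skip * x
    return y


class SSDScan:
    """Autograd wrapper for the scan with a hand-derived backward pass."""

    @staticmethod
    def apply(x: Tensor, dt: Tensor, a: Tensor, b_seq: Tensor, c_seq: Tensor,
              d_skip: Tensor | None = None) -> Tensor:
        xd, dtd = x.data, dt.data
        ad, bd, cd = a.data, b_seq.data, c_seq.data
        _check_scan_args(xd, dtd, ad, bd, cd)
        *lead, el, h, dh = xd.shape
        s = bd.shape[-1]
        abar = np.exp(dtd * ad)                            # (..., L, H)
        hs = np.empty((*lead, el, h, dh, s))
        hstate = np.zeros((*lead, h, dh, s))
        for t in range(el):
            dbx = (dtd[..., t, :, None, None] * xd[..., t, :, :, None]
                   * bd[..., t, None, None, :])
            hstate = abar[..., t, :, None, None] * hstate + dbx
            hs[..., t, :, :, :] = hstate
        if not np.all(np.isfinite(hs)):
            finite_t = np.isfinite(hs).reshape(-1, el, h * dh * s)
            bad = int(np.argmax(~finite_t.all(axis=(0, 2))))
            raise NumericalError(f"scan state overflow at step {bad}")
        y = np.einsum("...lhds,...ls->...lhd", hs, cd)
        if d_skip is not None:
            y = y + d_skip.data * xd

        parents = [p for p in (x, dt, a, b_seq, c_seq, d_skip) if p is not None]
        out = Tensor(y, any(p.requires_grad for p in parents), parents)
        if not out.requires_grad:
            return out

        def _bw(gy):
            lam = np.zeros((*lead, h, dh, s))
            gx = np.zeros_like(xd)
            gdt = np.zeros_like(dtd)
            ga = np.zeros_like(ad)
            gb = np.zeros_like(bd)
            gc = np.zeros_like(cd)
            for t in range(el - 1, -1, -1):
                h_t = hs[..., t, :, :, :]
                h_prev = (hs[..., t - 1, :, :, :] if t > 0
                          else np.zeros((*lead, h, dh, s)))
                dy_t = gy[..., t, :, :]
                # y_t = sum_s C_ts h_tds
                gc[..., t, :] += np.einsum("...hd,...hds->...s", dy_t, h_t)
                lam += dy_t[..., :, :, None] * cd[..., t, None, None, :]
                # h_t = abar_t h_{t-1} + dt_t x_t B_t
                dabar = np.einsum("...hds,...hds->...h", lam, h_prev)
                gdt[..., t, :] += dabar * ad * abar[..., t, :]
                ga += (dabar * dtd[..., t, :] * abar[..., t, :]).sum(
                    axis=tuple(range(len(lead))))
                gdt[..., t, :] += np.einsum(
                    "...hds,...hd,...s->...h", lam, xd[..., t, :, :],
                    bd[..., t, :])
                gx[..., t, :, :] += dtd[..., t, :, None] * np.einsum(
                    "...hds,...s->...hd", lam, bd[..., t, :])
                gb[..., t, :] += np.einsum(
                    "...hds,...hd,...h->...s", lam, xd[..., t, :, :],
                    dtd[..., t, :])
                lam = abar[..., t, :, None, None] * lam
            if d_skip is not None:
                gx += d_skip.data * gy
                if d_skip.requires_grad:
                    prod = (gy * xd).reshape(-1, el, h, dh)
                    d_skip._accumulate(prod.sum(axis=(0, 1)))
            if x.requires_grad:
                x._accumulate(gx)
            if dt.requires_grad:
                dt._accumulate(gdt)
            if a.requires_grad:
                a._accumulate(ga)
            if b_seq.requires_grad:
                b_seq._accumulate(gb)
            if c_seq.requires_grad:
                c_seq._accumulate(gc)
        out._backward = _bw
        return out


# --------------------------------------------------------- serialization

@dataclass
class SequenceView:
    """A (B, L, D) serialization of a (B, C, N, D) latent tensor."""

    tokens: Tensor
    layout: str
    c_dim: int
    n_dim: int

    def __post_init__(self):
        if self.layout not in (SPATIAL_FIRST, TEMPORAL_FIRST):
            raise ValueError(f"unknown layout {self.layout!r}")
        el = self.tokens.shape[1]
        if el != self.c_dim * self.n_dim:
            raise ValueError(
                f"token count {el} != c_dim*n_dim = {self.c_dim * self.n_dim}")


def unfold(h, layout: str) -> SequenceView:
    """Serialize (B, C, N, D) to (B, L, D).

    spatial_first: token n*C + c  (channels in the inner loop — N segments of
    C channel tokens each); temporal_first: token c*N + n (C independent time
    series laid end to end).
    """
    h = as_tensor(h)
    b, c, n, d = h.shape
    if layout == SPATIAL_FIRST:
        tokens = h.transpose((0, 2, 1, 3)).reshape((b, n * c, d))
    elif layout == TEMPORAL_FIRST:
        tokens = h.reshape((b, c * n, d))
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return SequenceView(tokens=tokens, layout=layout, c_dim=c, n_dim=n)


def fold(v: SequenceView) -> Tensor:
    """Exact inverse of :func:`unfold` back to (B, C, N, D)."""
    c, n = v.c_dim, v.n_dim
    b, el, d = v.tokens.shape
    if el != c * n:
        raise ValueError(f"inconsistent metadata: L={el}, C*N={c * n}")
    if v.layout == SPATIAL_FIRST:
        return v.tokens.reshape((b, n, c, d)).transpose((0, 2, 1, 3))
    return v.tokens.reshape((b, c, n, d))


def flip_view(v: SequenceView) -> SequenceView:
    return SequenceView(tokens=v.tokens.flip(1), layout=v.layout,
                        c_dim=v.c_dim, n_dim=v.n_dim)


# --------------------------------------------------------------- block

def _softplus_inverse(y: np.ndarray) -> np.ndarray:
    return y + np.log(-np.expm1(-y))


class MambaBlock(Module):
    """Gated selective-scan block: in-proj, causal conv, dt/B/C selectivity,
    SSD scan, gate, out-proj.  Shape-preserving on (B, L, D) tokens."""

    def __init__(self, dim: int, cfg: SSDConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        di = cfg.d_inner
        if di % cfg.n_heads != 0:
            raise ValueError("expanded width must be divisible by n_heads")
        if cfg.expand * dim != di:
            # head layout wins; expand is advisory when inconsistent
            pass
        self.dim = dim
        self.cfg = cfg
        rng = rng or np.random.default_rng()
        self.in_proj = Linear(dim, 2 * di, bias=False, rng=rng)
        self.conv_weight = Parameter(
            rng.normal(0.0, 1.0 / np.sqrt(cfg.conv_kernel), (di, cfg.conv_kernel)))
        self.conv_bias = Parameter(np.zeros(di))
        self.bc_proj = Linear(di, 2 * cfg.d_state, bias=False, rng=rng)
        self.dt_proj = Linear(di, cfg.n_heads, bias=False, rng=rng)
        dt_init = np.exp(rng.uniform(np.log(cfg.dt_min), np.log(cfg.dt_max),
                                     cfg.n_heads))
        self.dt_bias = Parameter(_softplus_inverse(dt_init))
        self.a_log = Parameter(np.log(rng.uniform(*cfg.a_init, cfg.n_heads)))
        self.d_skip = Parameter(np.ones((cfg.n_heads, cfg.head_dim)))
        self.out_proj = Linear(di, dim, bias=False, rng=rng)
        # small output init keeps residual stacks near-identity at start
        self.out_proj.weight.data *= 0.1

    def forward(self, u: Tensor) -> Tensor:
        u = as_tensor(u)
        b, el, d = u.shape
        if d != self.dim:
            raise ValueError(f"token width {d} != block width {self.dim}")
        cfg = self.cfg
        di = cfg.d_inner
        zx = self.in_proj(u)
        z, xb = zx[..., :di], zx[..., di:]
        xb = causal_depthwise_conv(xb, self.conv_weight, self.conv_bias).silu()
        bc = self.bc_proj(xb)
        b_seq, c_seq = bc[..., :cfg.d_state], bc[..., cfg.d_state:]
        dt = (self.dt_proj(xb) + self.dt_bias).softplus().clip(cfg.dt_min,
                                                               cfg.dt_max)
        a = -self.a_log.exp()
        xh = xb.reshape((b, el, cfg.n_heads, cfg.head_dim))
        y = SSDScan.apply(xh, dt, a, b_seq, c_seq, self.d_skip)
        y = y.reshape((b, el, di))
        y = y * z.silu()
        return self.out_proj(y)


def bidirectional_forward(v: SequenceView, block: Module) -> SequenceView:
    """Sum of a forward scan and a flipped scan of the flipped sequence,
    with shared block parameters."""
    fwd = block(v.tokens)
    bwd = block(v.tokens.flip(1)).flip(1)
    return SequenceView(tokens=fwd + bwd, layout=v.layout,
                        c_dim=v.c_dim, n_dim=v.n_dim)


class Backbone(Module):
    """Stack of pre-norm (bidirectional) Mamba layers, each scanning the
    latent grid in the layout its schedule entry dictates."""

    def __init__(self, dim: int, ssd: SSDConfig, cfg: BackboneConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        self.schedule = cfg.resolved_schedule()
        rng = rng or np.random.default_rng()
        self.norms = [LayerNorm(dim) for _ in range(cfg.depth)]
        self.blocks = [MambaBlock(dim, ssd, rng) for _ in range(cfg.depth)]

    def forward(self, h: Tensor) -> Tensor:
        h = as_tensor(h)
        for layout, norm, block in zip(self.schedule, self.norms, self.blocks):
            v = unfold(h, layout)
            v = SequenceView(tokens=norm(v.tokens), layout=layout,
                             c_dim=v.c_dim, n_dim=v.n_dim)
            if self.cfg.bidirectional:
                v = bidirectional_forward(v, block)
            else:
                v = SequenceView(tokens=block(v.tokens), layout=layout,
                                 c_dim=v.c_dim, n_dim=v.n_dim)
            out = fold(v)
            h = h + out if self.cfg.residual else out
        return h
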