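"""State-space encoder pathway.

A 7x7/stride-2/48-channel stem followed by four units of
{stride-2 subsampling -> block of (gated spatial convolution ->
tri-directional selective scan -> MLP)}.  The unit outputs are projected
with 1x1 convolutions so the pyramid is channel-matched, level by level,
to the deformable pathway.

The tri-directional scan flattens a 2-D feature map into three
sequences: forward raster order, its reversal, and the transposed
(column-major) raster order; each sequence runs through its own
selective-scan layer, is un-flattened in its own ordering, and the
three grids are summed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    BatchNorm2d, Conv2d, Identity, LayerNorm2d, Linear, MLP2d, Module,
    Parameter, ReLU, Sequential, Tensor, selective_scan_op,
)

__all__ = [
    "ScanParams", "selective_scan", "directional_sequences",
    "Mamba1D", "GSC", "ToM", "TSMambaBlock", "SSMStem", "SSMPathway",
    "SSMConfig",
]


@dataclass
class ScanParams:
    """Explicit parameters for the functional selective scan.

    ``A``: (C, N) per-channel/state decay rates; ``delta``: (T, C)
    positive step sizes; ``B``, ``C_out``: (T, N) input/output maps.
    """

    A: np.ndarray
    delta: np.ndarray
    B: np.ndarray
    C_out: np.ndarray

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=np.float64))
        self.delta = np.atleast_2d(np.asarray(self.delta, dtype=np.float64))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=np.float64))
        self.C_out = np.atleast_2d(np.asarray(self.C_out, dtype=np.float64))
        if np.any(self.delta <= 0):
            raise ValueError("delta must be strictly positive")


def selective_scan(x_seq: np.ndarray, params: ScanParams) -> np.ndarray:
    """Causal linear recurrence on a (T, C) sequence:

        h_t = exp(delta_t * A) h_{t-1} + delta_t B_t x_t,   y_t = <C_t, h_t>

    computed per channel with h_0 = 0; output length equals input length.
    """
    x_seq = np.atleast_2d(np.asarray(x_seq, dtype=np.float64))
    if x_seq.shape[0] == 0:
        raise ValueError("selective_scan requires a nonempty sequence")
    out = selective_scan_op(
        Tensor(x_seq[None]), Tensor(np.broadcast_to(params.delta, x_seq.shape)[None]),
        Tensor(params.A), Tensor(params.B[None]), Tensor(params.C_out[None]))
    return out.data[0]


def directional_sequences(f: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward-raster, reverse-raster and column-major flattenings of a
    (C, H, W) map, each as a (H*W, C) sequence of channel vectors."""
    C, H, W = f.shape
    fwd = f.reshape(C, H * W).T
    rev = fwd[::-1]
    sliced = f.transpose(0, 2, 1).reshape(C, H * W).T
    return fwd, rev, sliced


class Mamba1D(Module):
    """Selective-scan sequence layer with input-dependent step/maps and a
    multiplicative gate branch.  Operates on (B, T, C) sequences."""

    def __init__(self, channels: int, state_dim: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.channels = channels
        self.state_dim = state_dim
        self.delta_proj = Linear(channels, channels, rng=rng)
        self.delta_proj.bias.data[:] = np.log(np.expm1(1.0))  # softplus^-1(1)
        self.B_proj = Linear(channels, state_dim, rng=rng)
        self.C_proj = Linear(channels, state_dim, rng=rng)
        self.gate_proj = Linear(channels, channels, rng=rng)
        self.out_proj = Linear(channels, channels, rng=rng)
        # A = -exp(A_log) keeps the recurrence stable (decay < 1)
        self.A_log = Parameter(np.log(
            np.broadcast_to(np.arange(1, state_dim + 1, dtype=np.float64),
                            (channels, state_dim)).copy()))

    def forward(self, x: Tensor) -> Tensor:
        delta = self.delta_proj(x).softplus()
        A = -self.A_log.exp()
        Bm = self.B_proj(x)
        Cm = self.C_proj(x)
        y = selective_scan_op(x, delta, A, Bm, Cm)
        y = y * self.gate_proj(x).silu()
        return self.out_proj(y)


class GSC(Module):
    """Gated spatial convolution:  f + C3x3( C3x3(f) * C1x1(f) ), the two
    inner branches each with normalisation and nonlinearity."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.branch3 = Sequential(
            Conv2d(channels, channels, 3, padding=1, rng=rng),
            BatchNorm2d(channels), ReLU())
        self.branch1 = Sequential(
            Conv2d(channels, channels, 1, rng=rng),
            BatchNorm2d(channels), ReLU())
        self.outer = Conv2d(channels, channels, 3, padding=1, rng=rng)

    def forward(self, f: Tensor) -> Tensor:
        return f + self.outer(self.branch3(f) * self.branch1(f))


class ToM(Module):
    """Tri-directional scan: flatten three ways, scan each with its own
    parameters, un-flatten in the matching ordering, and sum."""

    def __init__(self, channels: int, state_dim: int = 16,
                 shared_directions: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if shared_directions:
            shared = Mamba1D(channels, state_dim, rng=rng)
            self.branches = [shared, shared, shared]
        else:
            self.branches = [Mamba1D(channels, state_dim, rng=rng) for _ in range(3)]

    def forward(self, f: Tensor) -> Tensor:
        B, C, H, W = f.shape
        fwd = f.reshape(B, C, H * W).transpose(0, 2, 1)            # (B, T, C)
        rev = fwd.flip(1)
        sliced = f.transpose(0, 1, 3, 2).reshape(B, C, H * W).transpose(0, 2, 1)
        y_f = self.branches[0](fwd)
        y_r = self.branches[1](rev)
        y_s = self.branches[2](sliced)
        g_f = y_f.transpose(0, 2, 1).reshape(B, C, H, W)
        g_r = y_r.flip(1).transpose(0, 2, 1).reshape(B, C, H, W)
        g_s = y_s.transpose(0, 2, 1).reshape(B, C, W, H).transpose(0, 1, 3, 2)
        return g_f + g_r + g_s


class TSMambaBlock(Module):
    """Block composition:

        g   = GSC(f)
        u   = LN(g) + g
        out = MLP( LN( ToM(u) + ToM(LN(u)) ) )

    Shape-preserving.
    """

    def __init__(self, channels: int, state_dim: int = 16,
                 shared_directions: bool = False, mlp_ratio: float = 4.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.gsc = GSC(channels, rng=rng)
        self.norm1 = LayerNorm2d(channels)
        self.norm2 = LayerNorm2d(channels)
        self.norm3 = LayerNorm2d(channels)
        self.tom = ToM(channels, state_dim, shared_directions, rng=rng)
        self.mlp = MLP2d(channels, hidden_ratio=mlp_ratio, rng=rng)

    def forward(self, f: Tensor) -> Tensor:
        g = self.gsc(f)
        u = self.norm1(g) + g
        return self.mlp(self.norm3(self.tom(u) + self.tom(self.norm2(u))))


class SSMStem(Module):
    """7x7 convolution, padding 3, stride 2, to ``stem_channels`` channels."""

    def __init__(self, stem_channels: int = 48,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(3, stem_channels, 7, stride=2, padding=3, rng=rng)

    def forward(self, image: Tensor) -> Tensor:
        return self.conv(image)


@dataclass(frozen=True)
class SSMConfig:
    stem_channels: int = 48
    state_dim: int = 16
    shared_directions: bool = False
    mlp_ratio: float = 4.0


class SSMPathway(Module):
    """Stem (stride 2) + four {subsample x2 -> TSMamba} units, with 1x1
    projections to ``out_channels`` so levels match the deformable pyramid."""

    def __init__(self, out_channels: tuple[int, ...] = (64, 128, 256, 512),
                 config: SSMConfig = SSMConfig(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.config = config
        self.stem = SSMStem(config.stem_channels, rng=rng)
        widths = [config.stem_channels * 2 ** (i + 1) for i in range(4)]
        self.subsamples: list[Module] = []
        self.blocks: list[TSMambaBlock] = []
        self.projections: list[Module] = []
        prev = config.stem_channels
        for width, out_ch in zip(widths, out_channels):
            self.subsamples.append(Conv2d(prev, width, 3, stride=2, padding=1, rng=rng))
            self.blocks.append(TSMambaBlock(
                width, config.state_dim, config.shared_directions,
                config.mlp_ratio, rng=rng))
            self.projections.append(Conv2d(width, out_ch, 1, rng=rng))
            prev = width

    def forward(self, image: Tensor) -> list[Tensor]:
        x = self.stem(image)
        pyramid = []
        for sub, block, proj in zip(self.subsamples, self.blocks, self.projections):
            x = block(sub(x))
            pyramid.append(proj(x))
        return pyramid
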