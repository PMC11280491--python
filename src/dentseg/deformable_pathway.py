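"""Adaptive deformable encoder pathway.

A stem with two stride-2 convolutions followed by four stages of base
blocks whose core operator is a grouped deformable convolution: each
output pixel is a softmax-modulated weighted sum of K bilinearly sampled
points whose offsets are predicted per pixel by a 3x3 convolution over
the block input.  Stage outputs form a four-level feature pyramid at
strides 4/8/16/32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Conv2d, DropPath, GELU, LayerNorm2d, MLP2d, Module, Parameter,
    Sequential, Tensor, concat, gather_bilinear, stack,
)

__all__ = [
    "SamplingSpec", "StageConfig", "bilinear_sample", "dcn_v3",
    "DCNv3", "BaseBlock", "AdaptiveStem", "DeformablePathway",
]


def base_grid_offsets(points: int) -> np.ndarray:
    """The K fixed integer displacements p_k (square grid, e.g. 3x3 for K=9)."""
    side = int(round(np.sqrt(points)))
    if side * side != points:
        raise ValueError(f"points must be a perfect square, got {points}")
    half = (side - 1) // 2
    rr, cc = np.mgrid[-half:side - half, -half:side - half]
    return np.stack([rr.ravel(), cc.ravel()], axis=-1).astype(np.float64)


@dataclass
class SamplingSpec:
    """Explicit sampling parameters of the deformable operator.

    ``offset_field``: (G, K, H, W, 2) per-pixel/group/point displacements;
    ``modulation_logits``: (G, K, H, W), softmax-normalised over K.
    """

    groups: int
    points: int
    offset_field: np.ndarray
    modulation_logits: np.ndarray
    base_offsets: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.groups < 1 or self.points < 1:
            raise ValueError("groups and points must be >= 1")
        if self.base_offsets is None:
            self.base_offsets = base_grid_offsets(self.points)

    def modulation_weights(self) -> np.ndarray:
        """Softmax of the modulation logits over the K points."""
        z = self.modulation_logits - self.modulation_logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class StageConfig:
    depths: tuple[int, ...] = (2, 2, 2, 2)
    channels: tuple[int, ...] = (64, 128, 256, 512)
    groups: int = 4
    points: int = 9
    droppath_rate: float = 0.1
    use_layer_scale: bool = True
    mlp_ratio: float = 4.0

    def __post_init__(self):
        if len(self.depths) != 4 or len(self.channels) != 4:
            raise ValueError("exactly four stages are required")
        if any(c2 < c1 for c1, c2 in zip(self.channels, self.channels[1:])):
            raise ValueError("channels must be non-decreasing across stages")
        if any(d < 1 for d in self.depths):
            raise ValueError("stage depths must be >= 1")


def bilinear_sample(feature: np.ndarray, location: tuple[float, float]) -> np.ndarray:
    """Bilinearly interpolate a (C, H, W) feature map at a fractional
    (row, col) location; locations outside the grid read as zero."""
    C, H, W = feature.shape
    r, c = float(location[0]), float(location[1])
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    fr, fc = r - r0, c - c0
    out = np.zeros(C, dtype=np.float64)
    for dr, wr in ((0, 1.0 - fr), (1, fr)):
        for dc, wc in ((0, 1.0 - fc), (1, fc)):
            ri, ci = r0 + dr, c0 + dc
            if 0 <= ri < H and 0 <= ci < W and wr * wc != 0.0:
                out += wr * wc * feature[:, ri, ci]
    return out


def dcn_v3(feature: np.ndarray, projection_weights: np.ndarray,
           spec: SamplingSpec) -> np.ndarray:
    """Functional deformable convolution on a single (C, H, W) map.

    Output pixel p = sum_g sum_k  w_g . m_gk . x_g(p + p_k + dp_gk), where
    x_g is the g-th channel slice, m_gk the softmax-normalised modulation,
    and sampling is bilinear with zero padding.  ``projection_weights`` is
    (G, Cg, Cg): one per-group projection applied to the aggregated sample;
    group outputs are concatenated along channels.
    """
    C, H, W = feature.shape
    G, K = spec.groups, spec.points
    if C % G:
        raise ValueError(f"channels ({C}) not divisible by groups ({G})")
    Cg = C // G
    f = Tensor(feature.reshape(1, G, Cg, H, W))
    rr, cc = np.mgrid[0:H, 0:W].astype(np.float64)
    base = np.stack([rr, cc], axis=-1)                     # (H, W, 2)
    coords = (base[None, None] + spec.base_offsets[None, :, None, None, :]
              + spec.offset_field)                        # (G, K, H, W, 2)
    sampled = gather_bilinear(f, Tensor(coords[None])).data[0]  # (G, K, Cg, H, W)
    m = spec.modulation_weights()                          # (G, K, H, W)
    agg = (sampled * m[:, :, None]).sum(axis=1)            # (G, Cg, H, W)
    out = np.einsum("gdc,gchw->gdhw", projection_weights, agg)
    return out.reshape(C, H, W)


class DCNv3(Module):
    """Learned deformable convolution: offsets and modulation logits are
    predicted per pixel by 3x3 convolutions over the input."""

    def __init__(self, channels: int, groups: int = 4, points: int = 9,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % groups:
            raise ValueError(f"channels ({channels}) not divisible by groups ({groups})")
        rng = rng or np.random.default_rng()
        self.channels = channels
        self.groups = groups
        self.points = points
        self.base_offsets = base_grid_offsets(points)
        self.offset_conv = Conv2d(channels, 2 * groups * points, 3, padding=1, rng=rng)
        # zero-init so training starts from the regular 3x3 grid
        self.offset_conv.weight.data[:] = 0.0
        self.modulation_conv = Conv2d(channels, groups * points, 3, padding=1, rng=rng)
        self.modulation_conv.weight.data[:] = 0.0
        cg = channels // groups
        self.projection = Parameter(
            rng.standard_normal((groups, cg, cg)) / np.sqrt(cg))

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        G, K, Cg = self.groups, self.points, C // self.groups
        offsets = self.offset_conv(x).reshape(B, G, K, 2, H, W).transpose(0, 1, 2, 4, 5, 3)
        logits = self.modulation_conv(x).reshape(B, G, K, H, W)
        m = logits.softmax(axis=2)
        rr, cc = np.mgrid[0:H, 0:W].astype(np.float64)
        base = (np.stack([rr, cc], axis=-1)[None, None, None]
                + self.base_offsets[None, None, :, None, None, :])
        coords = offsets + Tensor(base)
        f = x.reshape(B, G, Cg, H, W)
        sampled = gather_bilinear(f, coords)               # (B, G, K, Cg, H, W)
        agg = (sampled * m.reshape(B, G, K, 1, H, W)).sum(axis=2)  # (B, G, Cg, H, W)
        # per-group projection w_g, groups concatenated along channels
        a = agg.transpose(0, 1, 3, 4, 2)                   # (B, G, H, W, Cg)
        w_t = self.projection.transpose(0, 2, 1)           # (G, Cg_in, Cg_out)
        out = a.reshape(B, G, H * W, Cg) @ w_t.reshape(G, Cg, Cg)
        out = out.reshape(B, G, H, W, Cg).transpose(0, 1, 4, 2, 3)
        return out.reshape(B, C, H, W)


class BaseBlock(Module):
    """Residual deformable block:

        d   = DCN(f)
        out = LN( DropPath(scale * MLP(LN(d) + f)) + LN(d) )

    with GELU inside the MLP, optional per-channel feature scaling, and
    DropPath active only in training mode.
    """

    def __init__(self, channels: int, groups: int = 4, points: int = 9,
                 droppath_rate: float = 0.0, use_layer_scale: bool = True,
                 mlp_ratio: float = 4.0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.dcn = DCNv3(channels, groups, points, rng=rng)
        self.norm_dcn = LayerNorm2d(channels)
        self.norm_out = LayerNorm2d(channels)
        self.mlp = MLP2d(channels, hidden_ratio=mlp_ratio, rng=rng)
        self.droppath = DropPath(droppath_rate, rng=rng)
        self.scale = Parameter(np.ones(channels)) if use_layer_scale else None

    def forward(self, f: Tensor) -> Tensor:
        d = self.norm_dcn(self.dcn(f))
        branch = self.mlp(d + f)
        if self.scale is not None:
            branch = branch * self.scale.reshape(1, -1, 1, 1)
        return self.norm_out(self.droppath(branch) + d)


class AdaptiveStem(Module):
    """Two stride-2 convolutions with normalisation and GELU (stride 4 out)."""

    def __init__(self, out_channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        mid = max(out_channels // 2, 8)
        self.net = Sequential(
            Conv2d(3, mid, 3, stride=2, padding=1, rng=rng),
            LayerNorm2d(mid), GELU(),
            Conv2d(mid, out_channels, 3, stride=2, padding=1, rng=rng),
            LayerNorm2d(out_channels),
        )

    def forward(self, image: Tensor) -> Tensor:
        if image.shape[1] != 3:
            raise ValueError("stem expects a 3-channel input")
        return self.net(image)


class DeformablePathway(Module):
    """Stem + four stages; returns the stride 4/8/16/32 feature pyramid."""

    def __init__(self, config: StageConfig = StageConfig(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.config = config
        self.stem = AdaptiveStem(config.channels[0], rng=rng)
        total = sum(config.depths)
        rates = np.linspace(0.0, config.droppath_rate, total) if total > 1 \
            else np.zeros(1)
        self.blocks: list[BaseBlock] = []   # flat; stage i spans depths[:i] sums
        self.downsamples: list[Module] = []
        idx = 0
        for i, (depth, ch) in enumerate(zip(config.depths, config.channels)):
            for _ in range(depth):
                self.blocks.append(BaseBlock(
                    ch, config.groups, config.points,
                    droppath_rate=float(rates[idx]),
                    use_layer_scale=config.use_layer_scale,
                    mlp_ratio=config.mlp_ratio, rng=rng))
                idx += 1
            if i < 3:
                self.downsamples.append(Sequential(
                    Conv2d(ch, config.channels[i + 1], 3, stride=2, padding=1, rng=rng),
                    LayerNorm2d(config.channels[i + 1]),
                ))

    def forward(self, image: Tensor) -> list[Tensor]:
        x = self.stem(image)
        pyramid = []
        start = 0
        for i, depth in enumerate(self.config.depths):
            for block in self.blocks[start:start + depth]:
                x = block(x)
            start += depth
            pyramid.append(x)  # stage output, before inter-stage downsampling
            if i < 3:
                x = self.downsamples[i](x)
        return pyramid
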