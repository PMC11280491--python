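"""Hierarchical decoder with gated skip fusion.

Starting from the fused deep representation, each decoder level
upsamples by a 2x2/stride-2 transposed convolution, blends the two
encoder skip features of that level through a sigmoid attention gate
(a convex, pixelwise combination), concatenates the blend with the
decoder stream, and refines with a convolution.  A 1x1 head produces a
single-channel logit map that is bilinearly upsampled to the input
resolution.  The deepest level consumes the fused deep features alone,
so a four-level decoder has exactly three gated fusion sites.
"""

from __future__ import annotations

import numpy as np

from .nn import (
    BatchNorm2d, Conv2d, ConvTranspose2x2, GELU, LayerNorm2d, Module,
    ReLU, Sequential, Tensor, bilinear_upsample, concat, global_avg_pool,
)

__all__ = ["LocalAttention", "GlobalAttention", "TAFI", "HierarchicalDecoder"]


class LocalAttention(Module):
    """Pointwise bottleneck: 1x1 conv -> BN -> ReLU -> 1x1 conv -> BN."""

    def __init__(self, channels: int, ratio: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        mid = max(channels // ratio, 1)
        self.net = Sequential(
            Conv2d(channels, mid, 1, rng=rng), BatchNorm2d(mid), ReLU(),
            Conv2d(mid, channels, 1, rng=rng), BatchNorm2d(channels))

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class GlobalAttention(Module):
    """Global average pool to 1x1, same bottleneck stack, broadcast back."""

    def __init__(self, channels: int, ratio: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        mid = max(channels // ratio, 1)
        self.net = Sequential(
            Conv2d(channels, mid, 1, rng=rng), BatchNorm2d(mid), ReLU(),
            Conv2d(mid, channels, 1, rng=rng), BatchNorm2d(channels))

    def forward(self, x: Tensor) -> Tensor:
        pooled = self.net(global_avg_pool(x))             # (B, C, 1, 1)
        return pooled * Tensor(np.ones((1, 1) + x.shape[2:]))


class TAFI(Module):
    """Gated convex blend of two skip features, concatenated with the
    decoder stream:

        s = X + Y;  g = sigmoid(LoAtt(s) + GlAtt(s))
        out = Cat(X*g + Y*(1-g), f)

    ``gate_override`` (None | float) is a test hook forcing the gate.
    """

    def __init__(self, channels: int, ratio: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.local_att = LocalAttention(channels, ratio, rng=rng)
        self.global_att = GlobalAttention(channels, ratio, rng=rng)
        self.gate_override: float | None = None

    def gate(self, x: Tensor, y: Tensor) -> Tensor:
        s = x + y
        return (self.local_att(s) + self.global_att(s)).sigmoid()

    def fused(self, x: Tensor, y: Tensor) -> Tensor:
        if x.shape != y.shape:
            raise ValueError(f"skip features differ in shape: {x.shape} vs {y.shape}")
        if self.gate_override is not None:
            g = Tensor(np.full(x.shape, float(self.gate_override)))
        else:
            g = self.gate(x, y)
        return x * g + y * (1.0 - g)

    def forward(self, x: Tensor, y: Tensor, f: Tensor) -> Tensor:
        if f.shape[2:] != x.shape[2:]:
            raise ValueError(
                f"decoder stream {f.shape[2:]} not aligned with skips {x.shape[2:]}")
        return concat([self.fused(x, y), f], axis=1)


class HierarchicalDecoder(Module):
    """Four decoder levels over a stride-4/8/16/32 skip pyramid.

    ``encoder_channels`` are the per-level skip widths (shallow->deep);
    ``disable_tafi`` lists levels (1-based, 1 = shallowest fusion site)
    where gated fusion is replaced by plain concatenation of X, Y and f.
    """

    def __init__(self, encoder_channels: tuple[int, ...] = (64, 128, 256, 512),
                 attention_ratio: int = 4,
                 disable_tafi: tuple[int, ...] = (),
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        ch = encoder_channels
        self.encoder_channels = ch
        self.disable_tafi = tuple(disable_tafi)
        self.deep_refine = Sequential(
            Conv2d(ch[3], ch[3], 3, padding=1, rng=rng),
            LayerNorm2d(ch[3]), GELU())
        self.upsamples: list[Module] = []
        self.tafis: list[Module] = []
        self.refines: list[Module] = []
        # levels 3, 2, 1 (deep -> shallow); level n fuses pyramid index n-1
        for level in (3, 2, 1):
            c_in = ch[level]       # decoder stream channels before upsampling
            c_skip = ch[level - 1]
            self.upsamples.append(ConvTranspose2x2(c_in, c_skip, rng=rng))
            use_tafi = level not in self.disable_tafi
            self.tafis.append(TAFI(c_skip, attention_ratio, rng=rng) if use_tafi
                              else None)
            cat_ch = 2 * c_skip if use_tafi else 3 * c_skip
            self.refines.append(Sequential(
                Conv2d(cat_ch, c_skip, 3, padding=1, rng=rng),
                LayerNorm2d(c_skip), GELU()))
        self.head = Conv2d(ch[0], 1, 1, rng=rng)

    def num_tafi_sites(self) -> int:
        return sum(1 for t in self.tafis if t is not None)

    def forward(self, pyramid_x: list[Tensor], pyramid_y: list[Tensor],
                deep: Tensor) -> Tensor:
        if len(pyramid_x) != 4 or len(pyramid_y) != 4:
            raise ValueError("both pyramids must have four levels")
        for n, (px, py) in enumerate(zip(pyramid_x, pyramid_y), start=1):
            if px.shape != py.shape:
                raise ValueError(f"pyramid level {n} misaligned: "
                                 f"{px.shape} vs {py.shape}")
        if deep.shape[2:] != pyramid_x[3].shape[2:]:
            raise ValueError("deep features must sit at the stride-32 level")
        f = self.deep_refine(deep)
        for i, level in enumerate((3, 2, 1)):
            f = self.upsamples[i](f)
            x_n, y_n = pyramid_x[level - 1], pyramid_y[level - 1]
            tafi = self.tafis[i]
            if tafi is not None:
                cat = tafi(x_n, y_n, f)
            else:
                cat = concat([x_n, y_n, f], axis=1)
            f = self.refines[i](cat)
        logits = self.head(f)                # stride 4, single channel
        return bilinear_upsample(logits, 4)
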