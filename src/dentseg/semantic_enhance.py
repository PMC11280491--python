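"""Deep-feature fusion: concatenate the two deepest encoder outputs,
refine with a 7x7 Conv-BN-ReLU, then enrich in parallel with a global
per-pixel MLP branch and a learnable-codebook branch, concatenated.

The codebook branch soft-assigns every pixel's channel vector to K
learned codewords (softmax over ``alpha_k * ||x - mu_k||^2``), aggregates
the assignment-weighted squared residuals per channel, and turns the
response into a residual multiplicative gate ``F + F * sigmoid(conv(r))``.

By default the assignment exponent grows with distance; the
``negate_distance`` switch flips its sign to the convention of standard
codebook encoders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    BatchNorm2d, Conv2d, MLP2d, Module, Parameter, ReLU, Sequential,
    Tensor, concat,
)

__all__ = ["Codebook", "CBRFuse", "LVCEncoder", "MLPBranch", "SEM",
           "lvc_encode", "soft_assignments", "SEMConfig"]


@dataclass
class Codebook:
    """K learnable codewords (K, D) with per-codeword scales (K,)."""

    codewords: np.ndarray
    scales: np.ndarray

    def __post_init__(self):
        self.codewords = np.atleast_2d(np.asarray(self.codewords, dtype=np.float64))
        self.scales = np.asarray(self.scales, dtype=np.float64).reshape(-1)
        if self.codewords.shape[0] != self.scales.shape[0]:
            raise ValueError("one scale per codeword required")
        if self.codewords.shape[0] < 1:
            raise ValueError("codebook needs at least one codeword")


@dataclass(frozen=True)
class SEMConfig:
    fused_channels: int = 512
    codewords: int = 64
    negate_distance: bool = False
    mlp_ratio: float = 4.0


def soft_assignments(x: np.ndarray, codebook: Codebook,
                     negate_distance: bool = False) -> np.ndarray:
    """Per-pixel softmax over codewords of alpha_k * ||x_i - mu_k||^2.

    x: (D, H, W) -> (K, H, W); weights sum to 1 over K at every pixel.
    """
    D, H, W = x.shape
    mu = codebook.codewords                     # (K, D)
    d2 = ((x[None] - mu[:, :, None, None]) ** 2).sum(axis=1)  # (K, H, W)
    logits = codebook.scales[:, None, None] * d2
    if negate_distance:
        logits = -logits
    logits = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=0, keepdims=True)


class CBRFuse(Module):
    """Channel concat -> 7x7 convolution -> batch norm -> ReLU."""

    def __init__(self, in_channels_x: int, in_channels_y: int,
                 fused_channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.net = Sequential(
            Conv2d(in_channels_x + in_channels_y, fused_channels, 7,
                   padding=3, rng=rng),
            BatchNorm2d(fused_channels), ReLU())

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        if x.shape[2:] != y.shape[2:]:
            raise ValueError(
                f"spatial mismatch between fused inputs: {x.shape[2:]} vs {y.shape[2:]}")
        return self.net(concat([x, y], axis=1))


class LVCEncoder(Module):
    """Learnable-codeword branch with a residual sigmoid gate."""

    def __init__(self, channels: int, codewords: int = 64,
                 negate_distance: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.negate_distance = negate_distance
        self.codewords = Parameter(rng.standard_normal((codewords, channels))
                                   / np.sqrt(channels))
        init = -0.5 if negate_distance else 0.5
        self.scales = Parameter(np.full(codewords, init))
        self.gate_conv = Conv2d(channels, channels, 1, rng=rng)

    def forward(self, f: Tensor) -> Tensor:
        B, D, H, W = f.shape
        K = self.codewords.shape[0]
        x = f.reshape(B, D, H * W).transpose(0, 2, 1)      # (B, P, D)
        diff = x.reshape(B, H * W, 1, D) - self.codewords.reshape(1, 1, K, D)
        d2 = (diff * diff).sum(axis=3)                     # (B, P, K)
        logits = d2 * self.scales.reshape(1, 1, K)
        if self.negate_distance:
            logits = -logits
        w = logits.softmax(axis=2)                         # (B, P, K)
        resp = (w.reshape(B, H * W, K, 1) * diff * diff).sum(axis=2)  # (B, P, D)
        r = resp.transpose(0, 2, 1).reshape(B, D, H, W)
        gate = self.gate_conv(r).sigmoid()
        return f + f * gate


def lvc_encode(F_in: np.ndarray, codebook: Codebook, gate_weight: np.ndarray,
               gate_bias: np.ndarray, negate_distance: bool = False) -> np.ndarray:
    """Functional codebook gating on a single (D, H, W) map with explicit
    parameters (1x1 conv weight (D, D) and bias (D,)); mirrors
    :class:`LVCEncoder` exactly."""
    D, H, W = F_in.shape
    w = soft_assignments(F_in, codebook, negate_distance)           # (K, H, W)
    diff = F_in[None] - codebook.codewords[:, :, None, None]        # (K, D, H, W)
    resp = (w[:, None] * diff * diff).sum(axis=0)                   # (D, H, W)
    conv = np.einsum("od,dhw->ohw", gate_weight, resp) + gate_bias[:, None, None]
    gate = 1.0 / (1.0 + np.exp(-conv))
    return F_in + F_in * gate


class MLPBranch(Module):
    """Per-pixel channel MLP with residual connection (global branch)."""

    def __init__(self, channels: int, mlp_ratio: float = 4.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.mlp = MLP2d(channels, hidden_ratio=mlp_ratio, rng=rng)

    def forward(self, f: Tensor) -> Tensor:
        return f + self.mlp(f)


class SEM(Module):
    """Fuse deepest features, run both branches, concatenate, and project
    to the decoder's deepest channel width.

    ``use_mlp`` / ``use_lvc`` are ablation hooks; disabling a branch
    shrinks the concatenated channel count accordingly.
    """

    def __init__(self, in_channels_x: int, in_channels_y: int,
                 out_channels: int, config: SEMConfig = SEMConfig(),
                 use_mlp: bool = True, use_lvc: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if not (use_mlp or use_lvc):
            raise ValueError("at least one branch must be enabled")
        rng = rng or np.random.default_rng()
        fused = config.fused_channels
        self.fuse = CBRFuse(in_channels_x, in_channels_y, fused, rng=rng)
        self.mlp_branch = MLPBranch(fused, config.mlp_ratio, rng=rng) if use_mlp else None
        self.lvc_branch = LVCEncoder(fused, config.codewords,
                                     config.negate_distance, rng=rng) if use_lvc else None
        n_branches = int(use_mlp) + int(use_lvc)
        self.proj = Conv2d(fused * n_branches, out_channels, 1, rng=rng)

    def branch_concat(self, x: Tensor, y: Tensor) -> Tensor:
        """Concatenated branch outputs (before the output projection)."""
        f_in = self.fuse(x, y)
        outs = []
        if self.mlp_branch is not None:
            outs.append(self.mlp_branch(f_in))
        if self.lvc_branch is not None:
            outs.append(self.lvc_branch(f_in))
        return outs[0] if len(outs) == 1 else concat(outs, axis=1)

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        return self.proj(self.branch_concat(x, y))
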