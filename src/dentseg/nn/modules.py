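"""Layer library built on the autodiff core.

Conventions: feature maps are (B, C, H, W) float64 tensors; every module
takes an explicit ``numpy.random.Generator`` at construction so builds
are reproducible end to end.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .ops import unfold
from .tensor import Parameter, Tensor, concat

__all__ = [
    "Module", "Sequential", "Identity", "Conv2d", "ConvTranspose2x2",
    "Linear", "LayerNorm2d", "BatchNorm2d", "GELU", "ReLU", "SiLU",
    "MLP2d", "DropPath", "global_avg_pool",
]


class Module:
    """Base class: parameter discovery, train/eval mode, call protocol."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self) -> Iterator["Module"]:
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def modules(self) -> Iterator["Module"]:
        yield self
        for child in self._children():
            yield from child.modules()

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for mod in self.modules():
            for value in mod.__dict__.values():
                if isinstance(value, Parameter):
                    params.append(value)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, value in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((path, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=path + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{path}.{i}."))
        return out

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True) -> "Module":
        for mod in self.modules():
            mod.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- flat state dict of raw arrays (parameters + buffers) ---------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        for i, mod in enumerate(self.modules()):
            if isinstance(mod, BatchNorm2d):
                state[f"__bn{i}.running_mean"] = mod.running_mean
                state[f"__bn{i}.running_var"] = mod.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=np.float64)
        for i, mod in enumerate(self.modules()):
            if isinstance(mod, BatchNorm2d):
                mod.running_mean = np.array(state[f"__bn{i}.running_mean"])
                mod.running_var = np.array(state[f"__bn{i}.running_var"])


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class GELU(Module):
    def forward(self, x):
        return x.gelu()


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class SiLU(Module):
    def forward(self, x):
        return x.silu()


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = math.sqrt(3.0) / math.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Conv2d(Module):
    """2-D convolution via im2col; supports stride, zero padding, groups."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        self.weight = Parameter(_kaiming(
            rng, (out_channels, in_channels // groups, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        k, s, p, G = self.kernel_size, self.stride, self.padding, self.groups
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        cols = unfold(x, k, stride=s, padding=p)       # (B, C*k*k, L)
        if G == 1:
            w = self.weight.reshape(self.out_channels, (C // G) * k * k)
            out = w @ cols
        else:
            cols = cols.reshape(B, G, (C // G) * k * k, Ho * Wo)
            outs = []
            cg = self.out_channels // G
            for g in range(G):
                wg = self.weight[g * cg:(g + 1) * cg].reshape(cg, (C // G) * k * k)
                outs.append(wg @ cols[:, g])
            out = concat(outs, axis=1)
        out = out.reshape(B, self.out_channels, Ho, Wo)
        if self.bias is not None:
            out = out + self.bias.reshape(1, self.out_channels, 1, 1)
        return out


class ConvTranspose2x2(Module):
    """Transposed convolution with kernel 2, stride 2 (exact x2 upsampling)."""

    def __init__(self, in_channels: int, out_channels: int,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Parameter(_kaiming(rng, (in_channels, out_channels * 4), in_channels))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        Co = self.out_channels
        xr = x.reshape(B, C, H * W).transpose(0, 2, 1)       # (B, HW, C)
        m = xr @ self.weight                                 # (B, HW, Co*4)
        m = m.reshape(B, H, W, Co, 2, 2)
        m = m.transpose(0, 3, 1, 4, 2, 5)                    # (B, Co, H, 2, W, 2)
        out = m.reshape(B, Co, 2 * H, 2 * W)
        if self.bias is not None:
            out = out + self.bias.reshape(1, Co, 1, 1)
        return out


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_kaiming(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm2d(Module):
    """Layer normalisation across the channel axis of (B, C, H, W) maps."""

    def __init__(self, channels: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        xn = xc * (var + self.eps).pow(-0.5)
        C = self.gamma.shape[0]
        return xn * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        C = self.gamma.shape[0]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(C))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(C))
            xn = xc * (var + self.eps).pow(-0.5)
        else:
            mu = self.running_mean.reshape(1, C, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, C, 1, 1)
            xn = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xn * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)


class MLP2d(Module):
    """Per-pixel channel MLP (two 1x1 convolutions with GELU between)."""

    def __init__(self, channels: int, hidden_ratio: float = 4.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = max(1, int(channels * hidden_ratio))
        self.fc1 = Conv2d(channels, hidden, 1, rng=rng)
        self.fc2 = Conv2d(hidden, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class DropPath(Module):
    """Stochastic depth: drop the whole residual branch per sample."""

    def __init__(self, drop_rate: float = 0.0, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= drop_rate < 1.0:
            raise ValueError("drop_rate must be in [0, 1)")
        self.drop_rate = drop_rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.drop_rate == 0.0:
            return x
        keep = 1.0 - self.drop_rate
        B = x.shape[0]
        mask = (self.rng.random(B) < keep).astype(np.float64) / keep
        return x * Tensor(mask.reshape((B,) + (1,) * (x.ndim - 1)))


def global_avg_pool(x: Tensor) -> Tensor:
    """Adaptive average pooling of (B, C, H, W) to (B, C, 1, 1)."""
    return x.mean(axis=(2, 3), keepdims=True)
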