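"""Neural-network modules built on the autodiff tensor.

Initialisation follows the GAN-community convention: conv and linear weights
drawn from N(0, 0.02), biases zero.  Every module takes an explicit
`numpy.random.Generator` so builds are reproducible end to end.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

INIT_STD = 0.02


class Module:
    """Base class: named-parameter discovery by attribute walking."""

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{key}.{i}", item))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(p.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape, std: float = INIT_STD) -> Tensor:
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32), requires_grad=True)


def _zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape, dtype=np.float32), requires_grad=True)


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 padding: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.c_in, self.c_out = c_in, c_out
        self.weight = _param(rng, (c_out, c_in, kernel, kernel, kernel))
        self.bias = _zeros((c_out,))

    def forward(self, x: Tensor) -> Tensor:
        return T.conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose3d(Module):
    """Transposed 3D convolution, realised as zero-insertion + flipped conv.

    With kernel k, stride s and padding p the output size is
    (D-1)*s - 2p + k, matching the usual transposed-conv contract.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 4, stride: int = 2,
                 padding: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.c_in, self.c_out = c_in, c_out
        self.weight = _param(rng, (c_in, c_out, kernel, kernel, kernel))
        self.bias = _zeros((c_out,))

    def forward(self, x: Tensor) -> Tensor:
        up = T.zero_insert3d(x, self.stride)
        w = T.flip_spatial(self.weight).transpose(1, 0, 2, 3, 4)
        return T.conv3d(up, w, self.bias, stride=1, padding=self.kernel - 1 - self.padding)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = _param(rng, (d_in, d_out))
        self.bias = _zeros((d_out,))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalisation over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1, 1), dtype=np.float32), requires_grad=True)
        self.beta = _zeros((1, channels, 1, 1, 1))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3, 4), keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class BatchNorm3d(Module):
    """Batch-statistics normalisation over (N, spatial) per channel.

    Batch statistics are used in both training and inference: with the
    batch sizes used here (1-2 volumes) running averages are noisier than
    the batch itself, and using batch statistics keeps the forward pass a
    pure function of the input, which the determinism contract requires.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1, 1), dtype=np.float32), requires_grad=True)
        self.beta = _zeros((1, channels, 1, 1, 1))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(0, 2, 3, 4), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(0, 2, 3, 4), keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones((dim,), dtype=np.float32), requires_grad=True)
        self.beta = _zeros((dim,))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class LeakyReLU(Module):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x):
        return T.leaky_relu(x, self.alpha)


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class Tanh(Module):
    def forward(self, x):
        return T.tanh(x)
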