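"""Three 3D U-Net-like generator graphs for T1ce → T1nce translation.

* ``res``  — encoder of strided conv + instance norm + LeakyReLU(0.2) blocks,
  each followed by a residual module of 1-3 conv+LeakyReLU blocks with an
  additive skip; decoder of transposed conv + ReLU blocks with additive long
  skips; final upsample ×2 + conv + tanh.
* ``att``  — encoder of double conv + batch norm + ReLU blocks with 2×
  average-pool downsampling; decoder of trilinear upsample ×2 + conv +
  ReLU, an attention gate on the skip features, concatenation and two
  conv + ReLU blocks; 1³ conv + tanh head, optionally predicting an
  additive correction to the input (``global_residual``).
* ``trans`` — strided convolutional encoder, a linear projection of the
  bottleneck features to tokens, four transformer layers (multi-head
  self-attention + feed-forward with residual connections and pre-layer
  norm), reshape, and a deconvolutional decoder with long skips; conv + tanh
  head (an intensity-regression head rather than a softmax, which is
  degenerate for a single output channel).

Depth and width are configurable so the 128³ full-scale layout (depth 5 for
res/att, 4 for trans) and a CPU-trainable desk-scale layout share one
implementation.  Networks map volumes in [-1, 1] to volumes in [-1, 1]
(tanh); `translate_volume` handles the affine maps from/to the [0, 1]
intensity convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nn import tensor as T
from .nn.layers import (BatchNorm3d, Conv3d, ConvTranspose3d, InstanceNorm3d,
                        LayerNorm, Linear, Module)
from .nn.tensor import Tensor
from .types import Volume3D

MAX_CHANNEL_MULT = 8


@dataclass(frozen=True)
class GeneratorConfig:
    variant: str = "att"                      # {res, att, trans}
    depth: int = 5                            # descending blocks (trans: 4)
    base_channels: int = 32
    residual_blocks_per_level: int = 1        # res variant, 1-3
    n_transformer_layers: int = 4             # trans variant
    n_attention_heads: int = 4
    embed_dim: int = 128
    max_tokens: int = 1024
    input_shape: tuple[int, int, int] = (128, 128, 128)
    alpha: float = 0.2                        # LeakyReLU negative slope
    global_residual: bool = False             # att: head predicts a correction
    seed: int = 0

    def __post_init__(self):
        if self.variant not in ("res", "att", "trans"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.residual_blocks_per_level not in (1, 2, 3):
            raise ValueError("residual_blocks_per_level must be 1, 2 or 3")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.embed_dim % self.n_attention_heads:
            raise ValueError("embed_dim must be divisible by n_attention_heads")
        step = 2 ** self.depth
        if any(s % step for s in self.input_shape):
            raise ValueError(
                f"input_shape {self.input_shape} not divisible by 2^depth={step}"
            )


def desk_config(variant: str = "att", grid: int = 32, seed: int = 0) -> GeneratorConfig:
    """CPU-trainable configuration on a `grid`³ volume (minutes, not days)."""
    return GeneratorConfig(variant=variant, depth=3, base_channels=4,
                           embed_dim=32, max_tokens=512,
                           input_shape=(grid, grid, grid),
                           global_residual=(variant == "att"), seed=seed)


def _channels(cfg: GeneratorConfig, level: int) -> int:
    return cfg.base_channels * min(2 ** level, MAX_CHANNEL_MULT)


# ---------------------------------------------------------------------------
# Res-U-Net

class _ResidualModule(Module):
    """1-3 conv+LeakyReLU blocks with an additive skip around the stack."""

    def __init__(self, ch: int, n_blocks: int, alpha: float, rng):
        self.alpha = alpha
        self.convs = [Conv3d(ch, ch, 3, 1, 1, rng=rng) for _ in range(n_blocks)]

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for c in self.convs:
            h = T.leaky_relu(c(h), self.alpha)
        return x + h


class ResUNet(Module):
    def __init__(self, cfg: GeneratorConfig):
        rng = np.random.default_rng(cfg.seed)
        self.config = cfg
        d = cfg.depth
        self.down, self.down_norm, self.down_res = [], [], []
        c_in = 1
        for l in range(d):
            c_out = _channels(cfg, l)
            self.down.append(Conv3d(c_in, c_out, 4, 2, 1, rng=rng))
            self.down_norm.append(InstanceNorm3d(c_out))
            self.down_res.append(_ResidualModule(c_out, cfg.residual_blocks_per_level,
                                                 cfg.alpha, rng))
            c_in = c_out
        self.up, self.up_res = [], []
        for l in range(d - 2, -1, -1):
            c_out = _channels(cfg, l)
            self.up.append(ConvTranspose3d(c_in, c_out, 4, 2, 1, rng=rng))
            self.up_res.append(_ResidualModule(c_out, cfg.residual_blocks_per_level,
                                               cfg.alpha, rng))
            c_in = c_out
        self.final_conv = Conv3d(c_in, 1, 3, 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        skips = []
        for conv, norm, res in zip(self.down, self.down_norm, self.down_res):
            x = res(T.leaky_relu(norm(conv(x)), cfg.alpha))
            skips.append(x)
        for i, (up, res) in enumerate(zip(self.up, self.up_res)):
            x = T.relu(up(x))
            x = x + skips[len(self.down) - 2 - i]  # additive long skip
            x = res(x)
        x = T.upsample_trilinear3d(x)
        return T.tanh(self.final_conv(x))


# ---------------------------------------------------------------------------
# Att-U-Net

class AttentionGate(Module):
    """Sigmoid-bounded multiplicative gating of skip features.

    coefficients = sigmoid(psi(ReLU(W_x x + W_g g))); output = x ⊙ coefficients.
    """

    def __init__(self, ch_x: int, ch_g: int, ch_int: int, rng):
        self.ch_x, self.ch_g = ch_x, ch_g
        self.w_x = Conv3d(ch_x, ch_int, 1, 1, 0, rng=rng)
        self.w_g = Conv3d(ch_g, ch_int, 1, 1, 0, rng=rng)
        self.psi = Conv3d(ch_int, 1, 1, 1, 0, rng=rng)

    def coefficients(self, x: Tensor, g: Tensor) -> Tensor:
        if x.shape[1] != self.ch_x or g.shape[1] != self.ch_g:
            raise ValueError(
                f"attention gate channel mismatch: got x={x.shape[1]}, g={g.shape[1]}, "
                f"expected x={self.ch_x}, g={self.ch_g}"
            )
        if x.shape[2:] != g.shape[2:]:
            raise ValueError("attention gate inputs must be spatially aligned")
        return T.sigmoid(self.psi(T.relu(self.w_x(x) + self.w_g(g))))

    def forward(self, x: Tensor, g: Tensor) -> Tensor:
        return x * self.coefficients(x, g)


class _DoubleConv(Module):
    def __init__(self, c_in: int, c_out: int, rng):
        self.c1 = Conv3d(c_in, c_out, 3, 1, 1, rng=rng)
        self.n1 = BatchNorm3d(c_out)
        self.c2 = Conv3d(c_out, c_out, 3, 1, 1, rng=rng)
        self.n2 = BatchNorm3d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        x = T.relu(self.n1(self.c1(x)))
        return T.relu(self.n2(self.c2(x)))


class AttUNet(Module):
    def __init__(self, cfg: GeneratorConfig):
        rng = np.random.default_rng(cfg.seed)
        self.config = cfg
        d = cfg.depth
        self.enc = []
        c_in = 1
        for l in range(d):
            c_out = _channels(cfg, l)
            self.enc.append(_DoubleConv(c_in, c_out, rng))
            c_in = c_out
        self.up_conv, self.gates, self.dec = [], [], []
        for l in range(d - 2, -1, -1):
            c_skip = _channels(cfg, l)
            self.up_conv.append(Conv3d(c_in, c_skip, 3, 1, 1, rng=rng))
            self.gates.append(AttentionGate(c_skip, c_skip, max(c_skip // 2, 1), rng))
            self.dec.append(_DoubleConv(2 * c_skip, c_skip, rng))
            c_in = c_skip
        self.head = Conv3d(c_in, 1, 1, 1, 0, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        inp = x
        feats = []
        for i, block in enumerate(self.enc):
            if i > 0:
                x = T.avg_pool3d(x, 2)
            x = block(x)
            feats.append(x)
        for i, (up, gate, dec) in enumerate(zip(self.up_conv, self.gates, self.dec)):
            g = T.relu(up(T.upsample_trilinear3d(x)))
            skip = feats[len(self.enc) - 2 - i]
            gated = gate(skip, g)
            x = dec(T.concat([g, gated], axis=1))
        out = T.tanh(self.head(x))
        if self.config.global_residual:
            # head predicts an additive correction to the input image:
            # the identity (zero correction) is the natural starting point,
            # which keeps small structures like ventricles intact
            out = T.clip(out + inp, -1.0, 1.0)
        return out


# ---------------------------------------------------------------------------
# Trans-U-Net

class _TransformerLayer(Module):
    def __init__(self, dim: int, heads: int, rng):
        self.heads = heads
        self.ln1 = LayerNorm(dim)
        self.q = Linear(dim, dim, rng=rng)
        self.k = Linear(dim, dim, rng=rng)
        self.v = Linear(dim, dim, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(dim, 2 * dim, rng=rng)
        self.ff2 = Linear(2 * dim, dim, rng=rng)

    def attention_weights(self, x: Tensor) -> Tensor:
        """(N, heads, T, T) softmax-normalised attention matrix."""
        n, t, dim = x.shape
        dk = dim // self.heads
        h = self.ln1(x)
        q = self.q(h).reshape(n, t, self.heads, dk).transpose(0, 2, 1, 3)
        k = self.k(h).reshape(n, t, self.heads, dk).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dk))
        return T.softmax(scores, axis=-1)

    def forward(self, x: Tensor) -> Tensor:
        n, t, dim = x.shape
        dk = dim // self.heads
        h = self.ln1(x)
        q = self.q(h).reshape(n, t, self.heads, dk).transpose(0, 2, 1, 3)
        k = self.k(h).reshape(n, t, self.heads, dk).transpose(0, 2, 1, 3)
        v = self.v(h).reshape(n, t, self.heads, dk).transpose(0, 2, 1, 3)
        att = T.softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dk)), axis=-1)
        ctx = (att @ v).transpose(0, 2, 1, 3).reshape(n, t, dim)
        x = x + self.proj(ctx)
        h = self.ln2(x)
        return x + self.ff2(T.relu(self.ff1(h)))


class TransUNet(Module):
    def __init__(self, cfg: GeneratorConfig):
        rng = np.random.default_rng(cfg.seed)
        self.config = cfg
        d = cfg.depth
        self.enc_conv, self.enc_norm = [], []
        c_in = 1
        for l in range(d):
            c_out = _channels(cfg, l)
            self.enc_conv.append(Conv3d(c_in, c_out, 4, 2, 1, rng=rng))
            self.enc_norm.append(BatchNorm3d(c_out))
            c_in = c_out
        n_tokens = int(np.prod([s // 2 ** d for s in cfg.input_shape]))
        if n_tokens > cfg.max_tokens:
            raise ValueError(
                f"{n_tokens} bottleneck tokens exceed max_tokens={cfg.max_tokens}"
            )
        self.n_tokens = n_tokens
        self.bottleneck_channels = c_in
        self.to_tokens = Linear(c_in, cfg.embed_dim, rng=rng)
        self.pos = Tensor(rng.normal(0, 0.02, (1, n_tokens, cfg.embed_dim)).astype(np.float32),
                          requires_grad=True)
        self.layers = [_TransformerLayer(cfg.embed_dim, cfg.n_attention_heads, rng)
                       for _ in range(cfg.n_transformer_layers)]
        self.from_tokens = Linear(cfg.embed_dim, c_in, rng=rng)
        self.dec_up, self.dec_conv, self.dec_norm = [], [], []
        for l in range(d - 2, -1, -1):
            c_out = _channels(cfg, l)
            self.dec_up.append(ConvTranspose3d(c_in, c_out, 4, 2, 1, rng=rng))
            self.dec_conv.append(Conv3d(2 * c_out, c_out, 3, 1, 1, rng=rng))
            self.dec_norm.append(BatchNorm3d(c_out))
            c_in = c_out
        self.final_up = ConvTranspose3d(c_in, c_in, 4, 2, 1, rng=rng)
        self.head = Conv3d(c_in, 1, 3, 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        feats = []
        for conv, norm in zip(self.enc_conv, self.enc_norm):
            x = T.relu(norm(conv(x)))
            feats.append(x)
        n = x.shape[0]
        c = self.bottleneck_channels
        spatial = x.shape[2:]
        tokens = x.reshape(n, c, self.n_tokens).transpose(0, 2, 1)
        tokens = self.to_tokens(tokens) + self.pos
        for layer in self.layers:
            tokens = layer(tokens)
        x = self.from_tokens(tokens).transpose(0, 2, 1).reshape(n, c, *spatial)
        for i, (up, conv, norm) in enumerate(zip(self.dec_up, self.dec_conv, self.dec_norm)):
            x = T.relu(up(x))
            skip = feats[len(self.enc_conv) - 2 - i]
            x = T.relu(norm(conv(T.concat([x, skip], axis=1))))
        x = T.relu(self.final_up(x))
        return T.tanh(self.head(x))


# ---------------------------------------------------------------------------

_BUILDERS = {"res": ResUNet, "att": AttUNet, "trans": TransUNet}


def build_res_unet(cfg: GeneratorConfig) -> ResUNet:
    if cfg.variant != "res":
        raise ValueError("config variant must be 'res'")
    return ResUNet(cfg)


def build_att_unet(cfg: GeneratorConfig) -> AttUNet:
    if cfg.variant != "att":
        raise ValueError("config variant must be 'att'")
    return AttUNet(cfg)


def build_trans_unet(cfg: GeneratorConfig) -> TransUNet:
    if cfg.variant != "trans":
        raise ValueError("config variant must be 'trans'")
    return TransUNet(cfg)


def build_generator(cfg: GeneratorConfig) -> Module:
    return _BUILDERS[cfg.variant](cfg)


def to_model_range(values: np.ndarray) -> np.ndarray:
    """[0, 1] intensities → [-1, 1] network convention."""
    return values.astype(np.float32) * 2.0 - 1.0


def from_model_range(values: np.ndarray) -> np.ndarray:
    return np.clip((values + 1.0) / 2.0, 0.0, 1.0)


def translate_volume(generator: Module, vol: Volume3D) -> Volume3D:
    """Run one [0,1]-intensity volume through a generator."""
    x = Tensor(to_model_range(vol.values)[None, None])
    y = generator(x).numpy()[0, 0]
    return vol.with_values(from_model_range(y).astype(np.float64))
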