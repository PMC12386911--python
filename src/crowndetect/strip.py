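"""Strip-convolution residual block and its split/process/fuse container.

Tree crowns photographed obliquely are tall and narrow; square kernels
spend most of their support off-target.  The StripBlock factors spatial
mixing into directional depthwise convolutions — a 5x5 local aggregate,
then a horizontal 1xk and a vertical kx1 strip (k = 10 by default) — whose
output gates the block input multiplicatively (Strip Attention).  A
pointwise-expand / depthwise-3x3 / GELU / pointwise-reduce branch (Strip
MLP) mixes channels.  Both branches hang off the input through a parallel
dual residual with per-channel learnable layer scales:

    out = x + gamma1 * Attn(BN1(x)) + gamma2 * MLP(BN2(x))

With even k, "same" padding is asymmetric: floor((k-1)/2) leading and
ceil((k-1)/2) trailing on each strip axis, so spatial shape is preserved
exactly for any input size.

``C3k2Strip`` hosts n such blocks inside the split–transform–concat–fuse
container pattern used throughout the YOLO11-family backbones: a pointwise
convolution splits the input into two partial streams, one stream runs the
StripBlocks sequentially, and a pointwise fusion recombines them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm2d, Conv2d, DepthwiseConv2d, Dropout2d, Module,
                 Parameter, Tensor, concat)

__all__ = ["StripBlockConfig", "StripAttention", "StripMLP", "StripBlock",
           "C3k2Strip"]


@dataclass(frozen=True)
class StripBlockConfig:
    """channels: feature width; k: strip kernel length (>= 2); mlp_expansion:
    hidden-width ratio of the channel-mixing branch; drop_rate: channelwise
    dropout inside the MLP; layer_scale_init: initial value of the residual
    scales gamma1, gamma2."""

    channels: int
    k: int = 10
    mlp_expansion: int = 4
    drop_rate: float = 0.0
    layer_scale_init: float = 1e-2

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.k < 2:
            raise ValueError("strip kernel length k must be >= 2")
        if not (0.0 <= self.drop_rate < 1.0):
            raise ValueError("drop_rate must lie in [0, 1)")


def _check_channels(x: Tensor, channels: int):
    if x.shape[1] != channels:
        raise ValueError(f"expected {channels} channels, got {x.shape[1]}")


class StripAttention(Module):
    """x * Conv1x1(DWConv_kx1(DWConv_1xk(DWConv_5x5(x)))) — multiplicative gate.

    The 1xk strip is applied first, then kx1, following the block's defining
    composition (the neighbouring attention unit uses the opposite order)."""

    def __init__(self, cfg: StripBlockConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c = cfg.channels
        self.dw5 = DepthwiseConv2d(c, 5, 5, rng=rng)
        self.dw_h = DepthwiseConv2d(c, 1, cfg.k, rng=rng)
        self.dw_v = DepthwiseConv2d(c, cfg.k, 1, rng=rng)
        self.proj = Conv2d(c, c, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        _check_channels(x, self.cfg.channels)
        gate = self.proj(self.dw_v(self.dw_h(self.dw5(x))))
        return x * gate


class StripMLP(Module):
    """Conv1x1 expand -> DWConv3x3 -> GELU -> Dropout -> Conv1x1 reduce."""

    def __init__(self, cfg: StripBlockConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c, hidden = cfg.channels, cfg.channels * cfg.mlp_expansion
        self.expand = Conv2d(c, hidden, 1, rng=rng)
        self.dw3 = DepthwiseConv2d(hidden, 3, 3, rng=rng)
        self.drop = Dropout2d(cfg.drop_rate, rng=rng)
        self.reduce = Conv2d(hidden, c, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        _check_channels(x, self.cfg.channels)
        return self.reduce(self.drop(self.dw3(self.expand(x)).gelu()))


class StripBlock(Module):
    """Parallel dual-residual block with learnable per-channel layer scales."""

    def __init__(self, cfg: StripBlockConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c = cfg.channels
        self.bn1 = BatchNorm2d(c)
        self.bn2 = BatchNorm2d(c)
        self.attn = StripAttention(cfg, rng)
        self.mlp = StripMLP(cfg, rng)
        self.gamma1 = Parameter(np.full((1, c, 1, 1), cfg.layer_scale_init))
        self.gamma2 = Parameter(np.full((1, c, 1, 1), cfg.layer_scale_init))

    def forward(self, x: Tensor) -> Tensor:
        _check_channels(x, self.cfg.channels)
        return x + self.gamma1 * self.attn(self.bn1(x)) + self.gamma2 * self.mlp(self.bn2(x))


class C3k2Strip(Module):
    """Split/transform/concat/fuse container around n StripBlocks.

    A pointwise convolution maps the input to two hidden streams of
    c_out // 2 channels each; the second stream passes through the blocks
    sequentially; both are concatenated and fused back to c_out by a second
    pointwise convolution (SiLU after each pointwise, as in the host
    architecture family).
    """

    def __init__(self, c_in: int, c_out: int, n_blocks: int = 1,
                 k: int = 10, mlp_expansion: int = 4, drop_rate: float = 0.0,
                 layer_scale_init: float = 1e-2,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        rng = rng or np.random.default_rng()
        hidden = max(1, c_out // 2)
        self.hidden = hidden
        self.split = Conv2d(c_in, 2 * hidden, 1, rng=rng)
        cfg = StripBlockConfig(hidden, k=k, mlp_expansion=mlp_expansion,
                               drop_rate=drop_rate, layer_scale_init=layer_scale_init)
        self.blocks = [StripBlock(cfg, rng) for _ in range(n_blocks)]
        self.fuse = Conv2d(2 * hidden, c_out, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        s = self.split(x).silu()
        a = s[:, :self.hidden]
        b = s[:, self.hidden:]
        for blk in self.blocks:
            b = blk(b)
        return self.fuse(concat([a, b], axis=1)).silu()
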