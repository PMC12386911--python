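"""Channel-aware context attention (CAA) and its concat-fusion container.

A CAA unit builds a sigmoid gate from a locally pooled, directionally
convolved view of the feature map:

    CAA(x) = x * sigmoid(Conv1x1(DW_kx1(DW_1xk(Conv1x1(AvgPool_7x7(x))))))

The 7x7 average pool is stride-1 with symmetric padding 3 — a local
context squeeze that keeps spatial resolution (a global pool would
collapse the map and leave nothing for the directional strips to act on).
The vertical strip is applied after the horizontal one, per the unit's
defining composition.  Because the gate is a sigmoid, the unit can only
attenuate: |CAA(x)| <= |x| elementwise for any weights.

``C3k2CAA`` fuses the input with n parallel CAA views through one
pointwise convolution:  y = Conv1x1(Concat(x, CAA_1(x), ..., CAA_n(x))).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, DepthwiseConv2d, Module, Tensor, avg_pool2d, concat

__all__ = ["CAAConfig", "CAA", "C3k2CAA"]


@dataclass(frozen=True)
class CAAConfig:
    """channels: feature width; k: strip kernel length; pool_size: local
    average-pool window (odd); n_units: CAA units in the container."""

    channels: int
    k: int = 10
    pool_size: int = 7
    n_units: int = 1

    def __post_init__(self):
        if self.pool_size < 3 or self.pool_size % 2 == 0:
            raise ValueError("pool_size must be odd and >= 3")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.channels < 1:
            raise ValueError("channels must be >= 1")


class CAA(Module):
    """Single channel-aware attention unit (sigmoid-gated reweighting)."""

    def __init__(self, cfg: CAAConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c = cfg.channels
        self.pre = Conv2d(c, c, 1, rng=rng)
        self.dw_h = DepthwiseConv2d(c, 1, cfg.k, rng=rng)
        self.dw_v = DepthwiseConv2d(c, cfg.k, 1, rng=rng)
        self.post = Conv2d(c, c, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(f"expected {self.cfg.channels} channels, got {x.shape[1]}")
        ctx = avg_pool2d(x, self.cfg.pool_size)
        gate = self.post(self.dw_v(self.dw_h(self.pre(ctx)))).sigmoid()
        return x * gate


class C3k2CAA(Module):
    """Concat-fusion container: pointwise fusion of the input with n CAA views.

    The fusion convolution sees (n_units + 1) * c_in channels and emits
    c_out.
    """

    def __init__(self, c_in: int, c_out: int, n_units: int = 1, k: int = 10,
                 pool_size: int = 7, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        cfg = CAAConfig(c_in, k=k, pool_size=pool_size, n_units=n_units)
        self.cfg = cfg
        self.units = [CAA(cfg, rng) for _ in range(n_units)]
        self.fuse = Conv2d((n_units + 1) * c_in, c_out, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        views = [x] + [u(x) for u in self.units]
        return self.fuse(concat(views, axis=1)).silu()
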