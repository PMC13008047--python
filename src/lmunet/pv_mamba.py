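"""Parallel vision Mamba (PV-Mamba).

A feature map is layer-normalised per spatial position, split into four
equal channel groups, and each group is run through a Mamba block over its
raster-scanned token sequence with an alpha-scaled residual:

    (Y1..Y4) = Split(LN(X))
    PV_Yi    = Mamba(Yi) + alpha_i * Yi
    Out      = Pro(LN(Cat(PV_Y1..PV_Y4)))

One Mamba block (width C/4) is shared across the four groups, so the four
streams can be evaluated as a single batched scan; alpha is a learnable
scalar per group.  ``Pro`` is a square per-token linear map C -> C, so the
block preserves both channel count and spatial size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .ssm import MambaBlock, SSMConfig
from .tensor import Tensor

__all__ = ["PVMambaConfig", "PVMamba", "grid_scan", "grid_unscan"]

NUM_GROUPS = 4


@dataclass(frozen=True)
class PVMambaConfig:
    channels: int
    alpha_init: float = 1.0
    ssm: SSMConfig | None = None

    def __post_init__(self):
        if self.channels % NUM_GROUPS:
            raise ValueError(
                f"PV-Mamba requires channels divisible by {NUM_GROUPS}, got {self.channels}")
        object.__setattr__(
            self, "ssm",
            self.ssm if self.ssm is not None else SSMConfig(model_dim=self.channels // NUM_GROUPS))
        if self.ssm.model_dim != self.channels // NUM_GROUPS:
            raise ValueError("ssm.model_dim must equal channels / 4")


def grid_scan(x: Tensor) -> Tensor:
    """Raster-flatten a (B, C, H, W) map into a (B, H*W, C) token sequence."""
    b, c, h, w = x.shape
    return x.reshape(b, c, h * w).transpose(0, 2, 1)


def grid_unscan(seq: Tensor, height: int, width: int) -> Tensor:
    """Exact inverse of :func:`grid_scan`."""
    b, length, c = seq.shape
    if length != height * width:
        raise ValueError(f"sequence length {length} != {height}x{width}")
    return seq.transpose(0, 2, 1).reshape(b, c, height, width)


class PVMamba(nn.Module):
    def __init__(self, cfg: PVMambaConfig | int, rng):
        super().__init__()
        if isinstance(cfg, int):
            cfg = PVMambaConfig(channels=cfg)
        self.cfg = cfg
        c = cfg.channels
        self.norm_in = nn.LayerNorm(c)
        self.mamba = MambaBlock(cfg.ssm, rng)
        self.alpha = nn.Parameter(np.full(NUM_GROUPS, cfg.alpha_init, np.float32))
        self.norm_out = nn.LayerNorm(c)
        self.proj = nn.Linear(c, c, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        if c != self.cfg.channels:
            raise ValueError(f"PV-Mamba built for {self.cfg.channels} channels, got {c}")
        cg = c // NUM_GROUPS
        seq = self.norm_in(grid_scan(x))                         # (B, L, C)
        groups = seq.reshape(b, h * w, NUM_GROUPS, cg)
        groups = groups.transpose(0, 2, 1, 3).reshape(b * NUM_GROUPS, h * w, cg)
        y = self.mamba(groups)                                   # one batched scan
        alpha = self.alpha.reshape(1, NUM_GROUPS, 1, 1)
        y = (y.reshape(b, NUM_GROUPS, h * w, cg)
             + alpha * groups.reshape(b, NUM_GROUPS, h * w, cg))
        cat = y.transpose(0, 2, 1, 3).reshape(b, h * w, c)
        out = self.proj(self.norm_out(cat))
        return grid_unscan(out, h, w)
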