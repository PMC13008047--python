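"""Attention units: EMA, multi-stage channel attention, multi-scale spatial attention.

EMA (efficient multi-scale attention) regroups channels and fuses three
parallel paths — directional (height/width) pooled gating, a group-normalised
cross-spatial descriptor, and a 3x3 local path — into one spatial weighting
per group.

MCA pools every skip stage to a channel descriptor, concatenates the
descriptors, mixes them locally with a 1-D convolution and globally with a
per-stage fully connected map, and recalibrates each stage channelwise with
a residual floor: Out_i = t_i + t_i * sigmoid(FC_i(Conv1D(cat GAP(t_j)))).

MMSA builds a per-stage spatial map from channelwise mean/max pooling and a
7x7 dilated (rate 3) convolution: F_out = F + F * sigmoid(DilatedConv(cat)).
"""

from __future__ import annotations

from .import nn
from .tensor import Tensor, concatenate

__all__ = ["EMA", "MCA", "MMSA"]


class EMA(nn.Module):
    """Efficient multi-scale attention over ``groups`` channel groups."""

    def __init__(self, channels, rng, groups=8):
        super().__init__()
        if groups < 1 or channels % groups:
            raise ValueError(f"EMA: groups ({groups}) must divide channels ({channels})")
        self.channels, self.groups = channels, groups
        cg = channels // groups
        self.conv1x1 = nn.Conv2d(cg, cg, 1, rng)
        self.conv3x3 = nn.Conv2d(cg, cg, 3, rng, padding=1)
        self.gn = nn.GroupNorm(cg, cg)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        if c != self.channels:
            raise ValueError(f"EMA built for {self.channels} channels, got {c}")
        g, cg = self.groups, c // self.groups
        gx = x.reshape(b * g, cg, h, w)

        # paths 1+2: directional pooling -> shared 1x1 mix -> sigmoid gates
        ph = gx.mean(axis=3, keepdims=True)                      # (bg, cg, H, 1)
        pw = gx.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)  # (bg, cg, W, 1)
        mixed = self.conv1x1(concatenate([ph, pw], axis=2))
        gh = mixed[:, :, :h].sigmoid()
        gw = mixed[:, :, h:].transpose(0, 1, 3, 2).sigmoid()
        x1 = self.gn(gx * gh * gw)

        # path 3: local 3x3 features
        x2 = self.conv3x3(gx)

        # cross-spatial fusion in both directions
        d1 = x1.mean(axis=(2, 3)).softmax(axis=1).reshape(b * g, 1, cg)
        d2 = x2.mean(axis=(2, 3)).softmax(axis=1).reshape(b * g, 1, cg)
        m1 = d1 @ x2.reshape(b * g, cg, h * w)
        m2 = d2 @ x1.reshape(b * g, cg, h * w)
        weights = (m1 + m2).reshape(b * g, 1, h, w).sigmoid()
        return (gx * weights).reshape(b, c, h, w)


class MCA(nn.Module):
    """Multi-stage channel attention across the skip stages."""

    def __init__(self, stage_channels, rng, kernel_size=3):
        super().__init__()
        if not stage_channels:
            raise ValueError("MCA needs at least one stage")
        self.stage_channels = tuple(stage_channels)
        total = sum(stage_channels)
        self.conv1d = nn.ChannelConv1d(kernel_size, rng)
        self.fcs = [nn.Linear(total, c, rng) for c in stage_channels]

    def forward(self, stages):
        if not stages:
            raise ValueError("MCA received an empty stage list")
        if len(stages) != len(self.fcs):
            raise ValueError(f"MCA built for {len(self.fcs)} stages, got {len(stages)}")
        descs = [t.mean(axis=(2, 3)) for t in stages]            # GAP per stage
        mixed = self.conv1d(concatenate(descs, axis=1))
        out = []
        for t, fc in zip(stages, self.fcs):
            att = fc(mixed).sigmoid()
            b, c = att.shape
            out.append(t + t * att.reshape(b, c, 1, 1))
        return out


class MMSA(nn.Module):
    """Multi-scale spatial attention with a dilated 7x7 convolution.

    Padding 9 with dilation 3 preserves spatial size (effective receptive
    field 19x19).
    """

    def __init__(self, rng, kernel_size=7, dilation=3):
        super().__init__()
        pad = dilation * (kernel_size - 1) // 2
        self.conv = nn.Conv2d(2, 1, kernel_size, rng, dilation=dilation, padding=pad)

    def forward(self, x: Tensor) -> Tensor:
        favg = x.mean(axis=1, keepdims=True)
        fmax = x.max(axis=1, keepdims=True)
        att = self.conv(concatenate([favg, fmax], axis=1)).sigmoid()
        return x + x * att
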