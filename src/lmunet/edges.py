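"""Edge feature extraction (EFE) and edge feature fusion (EFF).

EFE distils one edge prior map from the shallow encoder stage (f2: rich
edge detail at high resolution) and the deepest stage (f6: abstract
semantics): each is run through PV-Mamba, f6 is upsampled bilinearly to
f2's grid, the pair is concatenated and refined by two 3x3 convolutions and
a PV-Mamba before a 1x1 sigmoid head emits a single-channel map in (0, 1).

EFF injects that prior into each skip stage i:

    F     = f_i + f_i * U(f_e)          (channel-broadcast edge gating)
    F_PV  = PV(conv3x3(F))
    F_s   = sigmoid(Conv1D(GAP(conv3x3(F))))
    out   = F_PV * F_s

U is bilinear resampling of the edge map to f_i's resolution.  The block
preserves f_i's shape.
"""

from __future__ import annotations

from . import nn
from .pv_mamba import PVMamba
from .tensor import Tensor, bilinear_resize, concatenate

__all__ = ["EFE", "EFF"]


class EFE(nn.Module):
    def __init__(self, shallow_channels, deep_channels, rng, mid_channels=16):
        super().__init__()
        self.pv_shallow = PVMamba(shallow_channels, rng)
        self.pv_deep = PVMamba(deep_channels, rng)
        self.conv1 = nn.Conv2d(shallow_channels + deep_channels, mid_channels, 3, rng, padding=1)
        self.conv2 = nn.Conv2d(mid_channels, mid_channels, 3, rng, padding=1)
        self.pv_out = PVMamba(mid_channels, rng)
        self.head = nn.Conv2d(mid_channels, 1, 1, rng)

    def forward(self, f2: Tensor, f6: Tensor) -> Tensor:
        if f2.shape[0] != f6.shape[0]:
            raise ValueError(f"EFE: batch sizes differ ({f2.shape[0]} vs {f6.shape[0]})")
        target = (f2.shape[2], f2.shape[3])
        a = self.pv_shallow(f2)
        b = bilinear_resize(self.pv_deep(f6), target)
        x = concatenate([a, b], axis=1)
        x = self.conv1(x).relu()
        x = self.conv2(x).relu()
        x = self.pv_out(x)
        return self.head(x).sigmoid()


class EFF(nn.Module):
    def __init__(self, channels, rng, kernel_size=3):
        super().__init__()
        self.conv = nn.Conv2d(channels, channels, 3, rng, padding=1)
        self.pv = PVMamba(channels, rng)
        self.channel_conv = nn.ChannelConv1d(kernel_size, rng)

    @staticmethod
    def inject(f_i: Tensor, f_e: Tensor) -> Tensor:
        """Edge gating with residual floor: f_i + f_i * U(f_e)."""
        up = bilinear_resize(f_e, (f_i.shape[2], f_i.shape[3]))
        return f_i + f_i * up

    def forward(self, f_i: Tensor, f_e: Tensor) -> Tensor:
        fused = self.conv(self.inject(f_i, f_e))
        gated = self.pv(fused)
        b, c = fused.shape[0], fused.shape[1]
        scale = self.channel_conv(fused.mean(axis=(2, 3))).sigmoid()
        return gated * scale.reshape(b, c, 1, 1)
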