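"""Re-Calibration FPN-P345: the SBA/RAU neck.

A Re-calibration Attention Unit (RAU) reduces a semantic (deep) feature and a
boundary (shallow) feature to 32 channels each with 1x1 convs, upsamples the
lower-resolution input to match the higher, and fuses them with a gate W
computed from the reduced semantic feature:

    out = refine( W * F_s' + (1 - W) * F_b' ),   W = sigmoid(g(F_s'))

— the "(1 - W)" factor is the reverse operation that re-routes attention to
the boundary stream wherever the semantic stream abstains.  The Selective
Boundary Aggregation (SBA) block runs two RAUs in opposite directions,
concatenates their 32-channel outputs (64 channels) and fuses with a
3x3 conv + batch norm + ReLU.

The neck pairs pyramid levels deep-to-shallow: N3 = SBA(P4, P3),
N4 = SBA(P5, P4), N5 = conv(P5), preserving strides (8, 16, 32).
"""

from __future__ import annotations

from . import autodiff as ad
from . import nn

RAU_CHANNELS = 32


class RAU(nn.Module):
    def __init__(self, c_sem: int, c_bnd: int):
        super().__init__()
        self.reduce_s = nn.ConvBnAct(c_sem, RAU_CHANNELS, 1)
        self.reduce_b = nn.ConvBnAct(c_bnd, RAU_CHANNELS, 1)
        self.gate = nn.Conv2d(RAU_CHANNELS, RAU_CHANNELS, 1)
        self.refine = nn.ConvBnAct(RAU_CHANNELS, RAU_CHANNELS, 3)

    def forward(self, f_sem, f_bnd):
        fs = self.reduce_s(f_sem)
        fb = self.reduce_b(f_bnd)
        target = (max(fs.shape[2], fb.shape[2]), max(fs.shape[3], fb.shape[3]))
        if fs.shape[2:] != target:
            fs = ad.resize_nearest(fs, target)
        if fb.shape[2:] != target:
            fb = ad.resize_nearest(fb, target)
        w = ad.sigmoid(self.gate(fs))
        return self.refine(w * fs + (1.0 - w) * fb)


class SBA(nn.Module):
    def __init__(self, c_sem: int, c_bnd: int, c_out: int):
        super().__init__()
        self.rau_sb = RAU(c_sem, c_bnd)
        self.rau_bs = RAU(c_bnd, c_sem)
        self.fuse = nn.ConvBnAct(2 * RAU_CHANNELS, c_out, 3, act="relu")

    def forward(self, f_sem, f_bnd):
        a = self.rau_sb(f_sem, f_bnd)
        b = self.rau_bs(f_bnd, f_sem)
        return self.fuse(ad.concat([a, b], axis=1))


class ReCalibrationFPN(nn.Module):
    """SBA-based neck over (P3, P4, P5); output channels match the input."""

    def __init__(self, channels: tuple[int, int, int]):
        super().__init__()
        c3, c4, c5 = channels
        self.sba3 = SBA(c4, c3, c3)
        self.sba4 = SBA(c5, c4, c4)
        self.conv5 = nn.ConvBnAct(c5, c5, 3)

    def forward(self, pyramid):
        if len(pyramid) != 3:
            raise ValueError("neck expects exactly three pyramid levels")
        p3, p4, p5 = pyramid
        return [self.sba3(p4, p3), self.sba4(p5, p4), self.conv5(p5)]


class PANFPN(nn.Module):
    """Stock top-down + bottom-up path-aggregation neck (ablation baseline)."""

    def __init__(self, channels: tuple[int, int, int]):
        super().__init__()
        c3, c4, c5 = channels
        self.t4 = nn.ConvBnAct(c5 + c4, c4, 1)
        self.t3 = nn.ConvBnAct(c4 + c3, c3, 1)
        self.d3 = nn.ConvBnAct(c3, c3, 3, stride=2)
        self.b4 = nn.ConvBnAct(c3 + c4, c4, 1)
        self.d4 = nn.ConvBnAct(c4, c4, 3, stride=2)
        self.b5 = nn.ConvBnAct(c4 + c5, c5, 1)
        self.up = nn.Upsample2x()

    def forward(self, pyramid):
        if len(pyramid) != 3:
            raise ValueError("neck expects exactly three pyramid levels")
        p3, p4, p5 = pyramid
        t4 = self.t4(ad.concat([self.up(p5), p4], axis=1))
        t3 = self.t3(ad.concat([self.up(t4), p3], axis=1))
        b4 = self.b4(ad.concat([self.d3(t3), t4], axis=1))
        b5 = self.b5(ad.concat([self.d4(b4), p5], axis=1))
        return [t3, b4, b5]
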