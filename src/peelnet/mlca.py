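"""Mixed Local Channel Attention (MLCA) and its host block C3k2-MLCA.

MLCA pools the feature map twice — a local average pool onto a coarse k-by-k
grid (LAP) and a global average pool (GAP) — runs the resulting length-C
channel vectors through a shared circular 1-D convolution, adds the global
branch onto the local one, gates with a sigmoid, de-pools (nearest-neighbour
resize) back to the input resolution, and multiplies with the input:

    out = F * sigmoid(depool(conv1d(LAP(F)) + conv1d(GAP(F))))

The add-then-gate-then-multiply ordering is this package's documented
convention (gating before the global add is an equally coherent variant);
see docs/methods.md.  The only learnable state is the
ks-tap 1-D kernel, so the parameter count is independent of the spatial size.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nn


def adaptive_kernel_size(channels: int) -> int:
    """Channel-adaptive odd kernel length: nearest odd to log2(C)/2 + 1/2, >= 3."""
    t = np.log2(channels) / 2.0 + 0.5
    k = int(round(t))
    if k % 2 == 0:
        k += 1
    return max(k, 3)


class MLCA(nn.Module):
    def __init__(self, channels: int, k: int = 5, ks: int | None = None):
        super().__init__()
        ks = ks or adaptive_kernel_size(channels)
        if ks % 2 == 0:
            raise ValueError(f"1-D conv kernel length must be odd, got {ks}")
        self.k = k
        self.channels = channels
        # centered-delta init: the gate starts near sigmoid(2 * channel mean)
        kernel = np.zeros(ks)
        kernel[ks // 2] = 1.0
        self.kernel = nn.Parameter(kernel)

    def forward(self, x):
        _, c, h, w = x.shape
        if self.k > min(h, w):
            raise ValueError(f"local grid {self.k} exceeds feature size {(h, w)}")
        lap = ad.avgpool_grid(x, self.k).transpose(0, 2, 3, 1)     # N,k,k,C
        gap = ad.global_avgpool(x).transpose(0, 2, 3, 1)           # N,1,1,C
        local = ad.conv1d_circular(lap, self.kernel)
        glob = ad.conv1d_circular(gap, self.kernel)
        gate = ad.sigmoid(local + glob).transpose(0, 3, 1, 2)      # N,C,k,k
        return x * ad.resize_nearest(gate, (h, w))

    def attention_map(self, x):
        """The de-pooled gate alone (values in (0,1)); used by diagnostics."""
        _, c, h, w = x.shape
        lap = ad.avgpool_grid(x, self.k).transpose(0, 2, 3, 1)
        gap = ad.global_avgpool(x).transpose(0, 2, 3, 1)
        gate = ad.sigmoid(ad.conv1d_circular(lap, self.kernel)
                          + ad.conv1d_circular(gap, self.kernel))
        return ad.resize_nearest(gate.transpose(0, 3, 1, 2), (h, w))


class Bottleneck(nn.Module):
    def __init__(self, c: int, shortcut: bool = True):
        super().__init__()
        self.cv1 = nn.ConvBnAct(c, c, 3)
        self.cv2 = nn.ConvBnAct(c, c, 3)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class C3k2(nn.Module):
    """Split/bottleneck/concatenate block (optionally with MLCA).

    A 1x1 conv expands to two hidden halves; one half runs through ``n``
    bottlenecks whose outputs are all retained; when attention is attached it
    is applied to the last bottleneck output before the 1x1 fusion conv.
    Setting ``attn = None`` recovers the plain block with identical weights.
    """

    def __init__(self, c_in: int, c_out: int, n: int = 1,
                 attn: nn.Module | None = None):
        super().__init__()
        self.c_in = c_in
        self.c_h = c_out // 2
        self.cv1 = nn.ConvBnAct(c_in, 2 * self.c_h, 1)
        self.blocks = [Bottleneck(self.c_h) for _ in range(n)]
        self.cv2 = nn.ConvBnAct((2 + n) * self.c_h, c_out, 1)
        self.attn = attn

    def forward(self, x):
        if x.shape[1] != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {x.shape[1]}")
        y = self.cv1(x)
        a = y[:, :self.c_h]
        b = y[:, self.c_h:]
        outs = [a, b]
        for m in self.blocks:
            b = m(b)
            outs.append(b)
        if self.attn is not None:
            outs[-1] = self.attn(outs[-1])
        return self.cv2(ad.concat(outs, axis=1))


def c3k2_mlca(c_in: int, c_out: int, n: int = 1, k: int = 5,
              ks: int | None = None) -> C3k2:
    """Factory for the C3k2 block hosting MLCA on its last bottleneck."""
    return C3k2(c_in, c_out, n, attn=MLCA(c_out // 2, k=k, ks=ks))
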