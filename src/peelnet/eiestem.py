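"""EIEStem: edge-information-enhanced input stem.

Replaces the first two stride-2 convolutions of the backbone.  After an
initial stride-2 conv the features split into (a) a SobelConv branch — a
frozen per-channel (grouped) convolution with the fixed Sobel stencils Gx and
Gy, both directional responses kept as channels — and (b) a pooling branch
(zero-padded 3x3 max pooling, stride 1).  The branches are concatenated along
channels, downsampled by a second stride-2 conv, and adjusted by a final 1x1
conv.  Output resolution is input/4.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

SOBEL_GX = np.array([[-1.0, 0.0, 1.0],
                     [-2.0, 0.0, 2.0],
                     [-1.0, 0.0, 1.0]])
SOBEL_GY = SOBEL_GX.T.copy()


class SobelConv(nn.Module):
    """Fixed (non-learnable) grouped convolution with Gx and Gy stencils.

    Each input channel produces two output channels (its Gx and Gy response),
    so C channels become 2C.  The kernels live in the buffer dict and receive
    no gradient updates.
    """

    def __init__(self, channels: int):
        super().__init__()
        self.channels = channels
        w = np.stack([SOBEL_GX, SOBEL_GY])[:, None]          # (2,1,3,3)
        w = np.tile(w, (channels, 1, 1, 1))                  # (2C,1,3,3)
        self._buffers = {"weight": w}

    def forward(self, x):
        if x.shape[2] < 3 or x.shape[3] < 3:
            raise ValueError("Sobel convolution needs spatial size >= 3")
        # replicate padding: a constant image has zero response at the border too
        return ad.conv2d(ad.pad2d_edge1(x), Tensor(self._buffers["weight"]),
                         None, stride=1, padding=0, groups=self.channels)


class EIEStem(nn.Module):
    def __init__(self, c_out: int):
        super().__init__()
        c_mid = max(c_out // 2, 4)
        self.conv1 = nn.ConvBnAct(3, c_mid, 3, stride=2)
        self.sobel = SobelConv(c_mid)
        self.sobel_bn = nn.BatchNorm2d(2 * c_mid)
        self.conv2 = nn.ConvBnAct(3 * c_mid, c_out, 3, stride=2)
        self.conv3 = nn.ConvBnAct(c_out, c_out, 1)

    def forward(self, x):
        _, _, h, w = x.shape
        if h % 4 or w % 4:
            raise ValueError(f"stem needs spatial size divisible by 4, got {(h, w)}")
        y = self.conv1(x)
        edge = ad.silu(self.sobel_bn(self.sobel(y)))   # scale-matched to conv blocks
        pooled = ad.maxpool2d(y, 3, stride=1, padding=1)
        return self.conv3(self.conv2(ad.concat([edge, pooled], axis=1)))


class PlainStem(nn.Module):
    """Two plain stride-2 conv blocks; the stock drop-in for the ablation."""

    def __init__(self, c_out: int):
        super().__init__()
        c_mid = max(c_out // 2, 4)
        self.conv1 = nn.ConvBnAct(3, c_mid, 3, stride=2)
        self.conv2 = nn.ConvBnAct(c_mid, c_out, 3, stride=2)

    def forward(self, x):
        _, _, h, w = x.shape
        if h % 4 or w % 4:
            raise ValueError(f"stem needs spatial size divisible by 4, got {(h, w)}")
        return self.conv2(self.conv1(x))
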