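"""Full detector assembly: stem -> backbone -> neck -> decoupled head.

The enhanced configuration composes EIEStem, C3k2-MLCA backbone blocks, the
Re-Calibration FPN neck and the AFPN head; toggling each field back to its
stock counterpart reconstructs the baseline and every intermediate ablation
configuration.  Channel widths default to a compact scale so the whole
model trains on a single CPU at desk-scale image sizes.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from . import nn
from .afpn import AFPN, PlainHead, decode
from .eiestem import EIEStem, PlainStem
from .mlca import C3k2, MLCA
from .sba import PANFPN, ReCalibrationFPN

STRIDES = (8, 16, 32)


@dataclasses.dataclass
class ModelConfig:
    stem: str = "eiestem"               # eiestem | plain
    neck: str = "recalibration_fpn"     # recalibration_fpn | pan_fpn
    head: str = "afpn"                  # afpn | plain
    mlca: bool = True
    channels: tuple = (12, 24, 40, 56)  # stem width, P3, P4, P5
    num_classes: int = 1
    image_size: int = 128
    mlca_k: int = 5
    mlca_ks: int | None = None
    head_iterations: int = 2

    def validate(self):
        if self.image_size % 32:
            raise ValueError("image size must be divisible by 32")
        if any(c <= 0 for c in self.channels) or len(self.channels) != 4:
            raise ValueError("channels must be four positive widths")
        if self.stem not in ("eiestem", "plain"):
            raise ValueError(f"unknown stem {self.stem!r}")
        if self.neck not in ("recalibration_fpn", "pan_fpn"):
            raise ValueError(f"unknown neck {self.neck!r}")
        if self.head not in ("afpn", "plain"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.head_iterations < 1:
            raise ValueError("head_iterations must be >= 1")
        return self

    @classmethod
    def ablation(cls, level: int, **kw) -> "ModelConfig":
        """The five-step ablation lattice: 0 = baseline ... 4 = full model.

        Modules accumulate in the order MLCA, Re-Calibration FPN, EIEStem,
        AFPN head.
        """
        return cls(
            mlca=level >= 1,
            neck="recalibration_fpn" if level >= 2 else "pan_fpn",
            stem="eiestem" if level >= 3 else "plain",
            head="afpn" if level >= 4 else "plain",
            **kw,
        ).validate()


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): cascaded 5x5 max pools, concatenated."""

    def __init__(self, c: int):
        super().__init__()
        ch = c // 2
        self.cv1 = nn.ConvBnAct(c, ch, 1)
        self.cv2 = nn.ConvBnAct(4 * ch, c, 1)

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(ad.maxpool2d(y[-1], 5, stride=1, padding=2))
        return self.cv2(ad.concat(y, axis=1))


class PSABlock(nn.Module):
    """Position-sensitive attention block over the deepest backbone stage:
    a 1x1 projection, a sigmoid spatial-channel gate and a residual 3x3 mix.
    """

    def __init__(self, c: int):
        super().__init__()
        self.proj = nn.ConvBnAct(c, c, 1)
        self.gate = nn.Conv2d(c, c, 1)
        self.mix = nn.ConvBnAct(c, c, 3)

    def forward(self, x):
        h = self.proj(x)
        return x + self.mix(h * ad.sigmoid(self.gate(h)))


class Detector(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        cs, c3, c4, c5 = cfg.channels

        def attn(c, stride):
            if not cfg.mlca:
                return None
            # the local grid cannot exceed the level's spatial size
            k = min(cfg.mlca_k, cfg.image_size // stride)
            return MLCA(c, k, cfg.mlca_ks)

        self.stem = EIEStem(cs) if cfg.stem == "eiestem" else PlainStem(cs)
        self.down3 = nn.ConvBnAct(cs, c3, 3, stride=2)
        self.c3k2_3 = C3k2(c3, c3, n=1, attn=attn(c3 // 2, 8))
        self.down4 = nn.ConvBnAct(c3, c4, 3, stride=2)
        self.c3k2_4 = C3k2(c4, c4, n=1, attn=attn(c4 // 2, 16))
        self.down5 = nn.ConvBnAct(c4, c5, 3, stride=2)
        self.c3k2_5 = C3k2(c5, c5, n=1, attn=attn(c5 // 2, 32))
        self.sppf = SPPF(c5)
        self.psa = PSABlock(c5)

        neck_cls = ReCalibrationFPN if cfg.neck == "recalibration_fpn" else PANFPN
        self.neck = neck_cls((c3, c4, c5))
        head_cls = AFPN if cfg.head == "afpn" else PlainHead
        self.head = head_cls((c3, c4, c5), cfg.head_iterations)

        self.cls_branch = [nn.Sequential(nn.ConvBnAct(c, c, 3),
                                         nn.Conv2d(c, cfg.num_classes, 1))
                           for c in (c3, c4, c5)]
        self.reg_branch = [nn.Sequential(nn.ConvBnAct(c, c, 3),
                                         nn.Conv2d(c, 4, 1))
                           for c in (c3, c4, c5)]

    def forward(self, x):
        """(N,3,H,W) image -> list over levels of (cls_logits, reg) Tensors."""
        x = ad.as_tensor(x)
        _, _, h, w = x.shape
        if h != self.cfg.image_size or w != self.cfg.image_size:
            raise ValueError(f"expected {self.cfg.image_size}-pixel square input, "
                             f"got {(h, w)}")
        y = self.stem(x)
        p3 = self.c3k2_3(self.down3(y))
        p4 = self.c3k2_4(self.down4(p3))
        p5 = self.psa(self.sppf(self.c3k2_5(self.down5(p4))))
        levels = self.head(self.neck([p3, p4, p5]))
        return [(cb(f), rb(f)) for cb, rb, f in
                zip(self.cls_branch, self.reg_branch, levels)]

    def predict(self, images: np.ndarray, conf_thr: float = 0.25,
                nms_iou: float = 0.45):
        """Run eval-mode inference on (N,3,H,W) images -> per-image detections."""
        was_training = self.training
        self.eval()
        preds = self.forward(np.asarray(images, dtype=np.float64))
        out = []
        n = preds[0][0].shape[0]
        for i in range(n):
            per_level = [(c.data[i], r.data[i]) for c, r in preds]
            out.append(decode(per_level, STRIDES, conf_thr, nms_iou, image_id=i))
        if was_training:
            self.train()
        return out


def build_model(cfg: ModelConfig, seed: int = 0) -> Detector:
    """Construct a detector with reproducible parameter initialization."""
    nn.seed_all(seed)
    return Detector(cfg)


def count_parameters(model: nn.Module) -> int:
    return int(sum(p.size for p in model.parameters()))
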