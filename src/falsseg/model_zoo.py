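"""Model variants and structural profiling (parameters, GFLOPs).

Four builds of the same detection+segmentation graph (n-scale widths:
16/32/64/128/256, C2f depths 1/2/2/1 in the backbone):

* ``baseline``        — YOLOv8n-Seg: stride-2 Conv downsamplers, standard head
* ``flrdown``         — backbone downsamplers (post-stem) replaced by FLRDown
* ``flrdown_lscshn``  — + the lightweight shared-convolution head
* ``fals_yolo``       — + AdaSimAM after each neck output (adds no parameters)

Parameter counts are reported in the deploy-time convention (BatchNorm folded
into conv biases, the fixed DFL projection included), which is what YOLO
tooling prints.  GFLOPs sums 2*Hout*Wout*(Cin/g)*Cout*Kh*Kw over every
convolution (including the transposed convolution in the prototype module,
counted over output elements with its full kernel); pooling, normalisation,
activations, resampling and the FFT are excluded from the count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from . import nn_primitives as nnp
from .adasimam import AdaSimAM, AdaSimAMConfig
from .autograd import Tensor
from .flrdown import FLRDown
from .lscshn import LSCSHN, HeadConfig, SegmentHead
from .nn_primitives import C2f, Conv, Module, SPPF

VARIANTS = ("baseline", "flrdown", "flrdown_lscshn", "fals_yolo")


@dataclass
class ModelProfile:
    variant: str
    total_params: int
    gflops: float
    input_size: int
    num_classes: int


class FalsModel(Module):
    """Backbone + PAN neck + segmentation head as one module."""

    def __init__(self, variant: str = "fals_yolo", num_classes: int = 3, seed: int = 0):
        super().__init__()
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; valid: {VARIANTS}")
        rng = np.random.default_rng(seed)
        self.variant = variant
        self.num_classes = num_classes
        use_flr = variant != "baseline"
        use_lsc = variant in ("flrdown_lscshn", "fals_yolo")
        self.use_attn = variant == "fals_yolo"

        def down(cin, cout):
            return FLRDown(cin, cout, rng=rng) if use_flr else Conv(cin, cout, 3, 2, rng=rng)

        # backbone
        self.stem = Conv(3, 16, 3, 2, rng=rng)
        self.d1 = down(16, 32)
        self.c2f_1 = C2f(32, 32, 1, True, rng=rng)
        self.d2 = down(32, 64)
        self.c2f_2 = C2f(64, 64, 2, True, rng=rng)
        self.d3 = down(64, 128)
        self.c2f_3 = C2f(128, 128, 2, True, rng=rng)
        self.d4 = down(128, 256)
        self.c2f_4 = C2f(256, 256, 1, True, rng=rng)
        self.sppf = SPPF(256, 256, 5, rng=rng)
        # neck (PAN)
        self.n1 = C2f(256 + 128, 128, 1, False, rng=rng)
        self.n2 = C2f(128 + 64, 64, 1, False, rng=rng)
        self.n3_down = Conv(64, 64, 3, 2, rng=rng)
        self.n3 = C2f(128 + 64, 128, 1, False, rng=rng)
        self.n4_down = Conv(128, 128, 3, 2, rng=rng)
        self.n4 = C2f(256 + 128, 256, 1, False, rng=rng)
        self.attn = [AdaSimAM(AdaSimAMConfig()) for _ in range(3)] if self.use_attn else []
        # head
        if use_lsc:
            self.head = LSCSHN((64, 128, 256), HeadConfig(num_classes=num_classes), rng=rng)
        else:
            self.head = SegmentHead(
                (64, 128, 256),
                HeadConfig(num_classes=num_classes, num_mask_coeffs=32),
                rng=rng,
            )
        self.strides = (8, 16, 32)

    def features(self, x: Tensor) -> list[Tensor]:
        y = self.stem(x)
        y = self.c2f_1(self.d1(y))
        p3 = self.c2f_2(self.d2(y))
        p4 = self.c2f_3(self.d3(p3))
        p5 = self.sppf(self.c2f_4(self.d4(p4)))
        # top-down
        t4 = self.n1(ag.concat([ag.upsample_nearest2x(p5), p4], axis=1))
        t3 = self.n2(ag.concat([ag.upsample_nearest2x(t4), p3], axis=1))
        # bottom-up
        b4 = self.n3(ag.concat([self.n3_down(t3), t4], axis=1))
        b5 = self.n4(ag.concat([self.n4_down(b4), p5], axis=1))
        feats = [t3, b4, b5]
        if self.use_attn:
            feats = [a(f) for a, f in zip(self.attn, feats)]
        return feats

    def __call__(self, x: Tensor) -> dict:
        return self.head(self.features(x))


def build_model(variant: str, num_classes: int = 3, seed: int = 0) -> FalsModel:
    return FalsModel(variant, num_classes, seed)


def count_parameters(model: FalsModel) -> int:
    """Deploy-time (fused) parameter count — the published convention."""
    return model.fused_param_count()


def count_parameters_raw(model: FalsModel) -> int:
    """Raw trainable element count (norm affine terms unfused)."""
    return model.num_parameters()


def estimate_gflops(model: FalsModel, input_size: int = 640) -> float:
    if input_size % 32:
        raise ValueError("input_size must be divisible by 32")
    log: list = []
    nnp.set_profile_log(log)
    try:
        model.eval()
        with ag.no_grad():
            model(Tensor(np.zeros((1, 3, input_size, input_size), np.float32)))
    finally:
        nnp.set_profile_log(None)
        model.train()
    macs = sum(cin * cout * kh * kw * h * w for cin, cout, kh, kw, h, w in log)
    # the DFL projection applied at decode time: one 16->1 conv per box side
    anchors = sum((input_size // s) ** 2 for s in model.strides)
    macs += anchors * 4 * model.head.dfl.reg_max
    return 2.0 * macs / 1e9


def profile_model(variant: str, num_classes: int = 3, input_size: int = 640) -> ModelProfile:
    model = build_model(variant, num_classes)
    return ModelProfile(
        variant=variant,
        total_params=count_parameters(model),
        gflops=estimate_gflops(model, input_size),
        input_size=input_size,
        num_classes=num_classes,
    )
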