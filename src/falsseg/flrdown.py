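"""FLRDown: a half-resolution downsampling block that pairs a low-rank
(1x3 then 3x1) separable convolution with a Fourier low-pass branch.

The input is split channel-wise into two halves.  The spatial half goes
through the factorised convolution (the 3x1 stage carries stride 2 in both
dimensions plus the norm/activation); the frequency half is low-pass filtered
in the DFT domain (top-left quadrant crop), aligned to the spatial branch's
output grid by bilinear interpolation, and refined by a 1x1 convolution.
Both branches emit C2/2 channels and are concatenated, so the block maps
(H, W, C1) -> (ceil(H/2), ceil(W/2), C2) and is a drop-in replacement for a
3x3 stride-2 downsampling convolution with strictly fewer parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn_primitives import Conv, Conv2d, Module, ShapeError


@dataclass
class FLRDownConfig:
    in_channels: int
    out_channels: int
    # width of the tensor between the 1x3 and 3x1 convs; the default (C2/2,
    # i.e. the branch output width) is what reproduces the published size
    mid_channels: int | None = None
    freq_kernel: int = 1

    def __post_init__(self):
        if self.in_channels % 2 or self.out_channels % 2:
            raise ValueError("FLRDown requires even in/out channel counts")
        if self.mid_channels is None:
            self.mid_channels = self.out_channels // 2

    @property
    def branch_in(self) -> int:
        return self.in_channels // 2

    @property
    def branch_out(self) -> int:
        return self.out_channels // 2


def split_channels(x: Tensor) -> tuple[Tensor, Tensor]:
    """First half of the channels feeds the spatial branch, second half the
    frequency branch; concatenating the two restores the input."""
    if x.shape[1] % 2:
        raise ShapeError(f"cannot split odd channel count {x.shape[1]}")
    return tuple(ag.chunk(x, 2, axis=1))


def spectral_lowpass(x: Tensor) -> Tensor:
    """Low-frequency crop in the DFT domain; see `autograd.spectral_lowpass`."""
    if x.shape[2] < 2 or x.shape[3] < 2:
        raise ShapeError("spectral_lowpass needs H, W >= 2")
    return ag.spectral_lowpass(x)


class LowRankBranch(Module):
    """1x3 conv (stride 1, bare) then 3x1 conv (stride 2, norm+SiLU).

    With norms disabled and the two kernels set to the rank-1 factors of a
    separable 3x3 kernel, the cascade equals the full 3x3 convolution.
    """

    def __init__(self, cfg: FLRDownConfig, norm: bool = True, rng=None):
        super().__init__()
        self.cv_h = Conv2d(cfg.branch_in, cfg.mid_channels, (1, 3), 1, bias=False, rng=rng)
        if norm:
            self.cv_v = Conv(cfg.mid_channels, cfg.branch_out, (3, 1), (2, 2), rng=rng)
        else:
            self.cv_v = Conv2d(cfg.mid_channels, cfg.branch_out, (3, 1), (2, 2), bias=False, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[2] < 2 or x.shape[3] < 2:
            raise ShapeError("low-rank branch needs H, W >= 2")
        return self.cv_v(self.cv_h(x))


class FreqBranch(Module):
    """spectral low-pass -> bilinear align to (H', W') -> 1x1 refine conv."""

    def __init__(self, cfg: FLRDownConfig, rng=None):
        super().__init__()
        self.cv_freq = Conv2d(cfg.branch_in, cfg.branch_out, cfg.freq_kernel, 1,
                              bias=False, rng=rng)

    def __call__(self, x: Tensor, out_hw: tuple[int, int]) -> Tensor:
        y = spectral_lowpass(x)
        y = ag.bilinear_resize(y, out_hw)
        return self.cv_freq(y)


class FLRDown(Module):
    def __init__(self, cin: int, cout: int, cfg: FLRDownConfig | None = None, rng=None):
        super().__init__()
        self.cfg = cfg or FLRDownConfig(cin, cout)
        if (self.cfg.in_channels, self.cfg.out_channels) != (cin, cout):
            raise ValueError("config channel mismatch")
        self.lowrank = LowRankBranch(self.cfg, rng=rng)
        self.freq = FreqBranch(self.cfg, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        xs, xf = split_channels(x)
        ys = self.lowrank(xs)
        yf = self.freq(xf, (ys.shape[2], ys.shape[3]))
        assert yf.shape[2:] == ys.shape[2:], "branch outputs must align"
        return ag.concat([ys, yf], axis=1)


def lowrank_branch(x: Tensor, cfg: FLRDownConfig, norm: bool = True, rng=None) -> Tensor:
    return LowRankBranch(cfg, norm=norm, rng=rng)(x)


def freq_branch(x: Tensor, cfg: FLRDownConfig, out_hw=None, rng=None) -> Tensor:
    if out_hw is None:
        out_hw = ((x.shape[2] + 1) // 2, (x.shape[3] + 1) // 2)
    return FreqBranch(cfg, rng=rng)(x, out_hw)


def flrdown_forward(x: Tensor, cfg: FLRDownConfig, rng=None) -> Tensor:
    return FLRDown(cfg.in_channels, cfg.out_channels, cfg, rng=rng)(x)


def spectral_lowpass_oracle(x: np.ndarray) -> np.ndarray:
    """Literal O(N^4) summation implementation of the DFT / crop / inverse-DFT
    chain, kept deliberately loop-based and independent of the FFT path.

    Same conventions as the fast path: unshifted top-left quadrant crop with
    exclusive bounds, inverse evaluated on the cropped grid with a 1/(H*W)
    scale so the DC component is preserved, real part returned.
    """
    h, w = x.shape[-2:]
    hc, wc = (h + 1) // 2, (w + 1) // 2
    spec = np.zeros((hc, wc), dtype=complex)
    for u in range(hc):
        for v in range(wc):
            acc = 0.0 + 0.0j
            for m in range(h):
                for n in range(w):
                    acc += x[m, n] * np.exp(-2j * np.pi * (u * m / h + v * n / w))
            spec[u, v] = acc
    out = np.zeros((hc, wc), dtype=complex)
    for m in range(hc):
        for n in range(wc):
            acc = 0.0 + 0.0j
            for u in range(hc):
                for v in range(wc):
                    acc += spec[u, v] * np.exp(2j * np.pi * (u * m / hc + v * n / wc))
            out[m, n] = acc / (h * w)
    return out.real
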