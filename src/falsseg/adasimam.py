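"""AdaSimAM: adaptive, parameter-free 3-D attention.

SimAM scores every activation by an energy function built from its squared
deviation from the channel mean; the gate is sigmoid(inverse energy).  This
variant makes three substitutions aimed at noisy grayscale medical imagery:

1. the statistics are computed on a smoothed copy of the feature map
   (stride-1 average pooling) so single-pixel noise does not dominate;
2. the global channel mean is replaced by a local windowed mean (falling back
   to the global mean when the window would cover the whole map);
3. the regulariser lambda is not a fixed constant but scales with the
   per-channel spatial standard deviation of the input
   (lambda_c = max(sigma_c * alpha, lambda_floor)).

The block has zero trainable parameters; the original (unsmoothed) input is
what gets gated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn_primitives import Module


@dataclass
class AdaSimAMConfig:
    smooth_kernel_size: int = 3
    local_window_size: int = 7
    alpha: float = 0.01
    lambda_floor: float = 1e-4

    def __post_init__(self):
        if self.smooth_kernel_size % 2 == 0 or self.smooth_kernel_size < 1:
            raise ValueError("smooth_kernel_size must be odd and >= 1")
        if self.local_window_size % 2 == 0 or self.local_window_size < 1:
            raise ValueError("local_window_size must be odd and >= 1")
        if self.alpha <= 0 or self.lambda_floor <= 0:
            raise ValueError("alpha and lambda_floor must be positive")


def smooth(x: Tensor, k: int) -> Tensor:
    """Stride-1 average pooling with k//2 zero padding (same spatial size)."""
    if k % 2 == 0:
        raise ValueError("smoothing kernel must be odd")
    if k == 1:
        return x
    return ag.avg_pool2d_s1(x, k)


def local_mean(x: Tensor, w: int) -> Tensor:
    """Per-position windowed mean; degenerates to the global channel mean map
    when the window covers the whole map (w >= min(H, W))."""
    if w % 2 == 0:
        raise ValueError("local window must be odd")
    h, wd = x.shape[2], x.shape[3]
    if w >= min(h, wd):
        return x.mean(axis=(2, 3), keepdims=True) * Tensor(np.ones((1, 1, h, wd), np.float32))
    if w == 1:
        return x
    return ag.avg_pool2d_s1(x, w)


def adaptive_lambda(x: Tensor, cfg: AdaSimAMConfig) -> Tensor:
    """lambda_c = max(sigma_c * alpha, lambda_floor), per sample and channel.

    sigma_c is the (population) spatial standard deviation of the raw input.
    Treated as a constant of the energy term (no gradient through lambda).
    """
    d = x.data
    sigma = d.std(axis=(2, 3), dtype=np.float64).astype(np.float32)
    lam = np.maximum(sigma * cfg.alpha, cfg.lambda_floor)
    return Tensor(lam[:, :, None, None])


class AdaSimAM(Module):
    """Zero-parameter attention gate: y = x * sigmoid(E_inv)."""

    def __init__(self, cfg: AdaSimAMConfig | None = None):
        super().__init__()
        self.cfg = cfg or AdaSimAMConfig()

    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        n, c, h, w = x.shape
        xs = smooth(x, cfg.smooth_kernel_size)
        mu = local_mean(xs, cfg.local_window_size)
        d2 = (xs - mu) ** 2
        # channel variance of the smoothed map with the SimAM n-1 divisor
        nm1 = max(h * w - 1, 1)
        var = ((xs - xs.mean(axis=(2, 3), keepdims=True)) ** 2).sum(
            axis=(2, 3), keepdims=True
        ) * (1.0 / nm1)
        lam = adaptive_lambda(x, cfg)
        e_inv = d2 / ((var + lam) * 4.0) + 0.5
        return x * e_inv.sigmoid()


def adasimam_forward(x: Tensor, cfg: AdaSimAMConfig | None = None) -> Tensor:
    return AdaSimAM(cfg)(x)


def simam_reference(x: np.ndarray, e_lambda: float = 1e-4) -> np.ndarray:
    """Plain SimAM (inference form) coded directly from its published energy
    expression, as an independent oracle: per channel,
    w = sigmoid( (t-mu)^2 / (4*(sigma^2 + lambda)) + 0.5 ), y = x * w,
    with sigma^2 the spatial variance using the n = H*W - 1 divisor."""
    n, c, h, w = x.shape
    mu = x.mean(axis=(2, 3), keepdims=True)
    d2 = (x - mu) ** 2
    var = d2.sum(axis=(2, 3), keepdims=True) / max(h * w - 1, 1)
    e_inv = d2 / (4.0 * (var + e_lambda)) + 0.5
    return x / (1.0 + np.exp(-e_inv))
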