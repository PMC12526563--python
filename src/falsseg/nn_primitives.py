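"""Reusable network blocks: conv-norm-activation, C2f, SPPF, group-normalised
conv, the learnable regression Scale, and the DFL distribution decoder.

Conventions (inherited from the YOLOv8-n lineage these models descend from):

* convolutions followed by a norm layer carry no bias;
* activation is SiLU wherever a norm+activation conv is used;
* BatchNorm eps 1e-3, momentum 0.03; GroupNorm eps 1e-5, 16 groups;
* parameter *reporting* uses the deploy-time (fused) convention — BatchNorm
  affine terms fold into a conv bias, GroupNorm cannot be folded and keeps its
  2·C affine parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor


@dataclass
class ConvSpec:
    """Declarative description of a convolution layer."""

    in_channels: int
    out_channels: int
    kernel: tuple[int, int] = (3, 3)
    stride: tuple[int, int] = (1, 1)
    padding: tuple[int, int] | None = None  # None -> "same" (k//2)
    has_norm: bool = True
    norm_kind: str = "batch"  # {"batch", "group"}
    has_activation: bool = True

    def __post_init__(self):
        if isinstance(self.kernel, int):
            self.kernel = (self.kernel, self.kernel)
        if isinstance(self.stride, int):
            self.stride = (self.stride, self.stride)
        if self.padding is None:
            self.padding = (self.kernel[0] // 2, self.kernel[1] // 2)
        elif isinstance(self.padding, int):
            self.padding = (self.padding, self.padding)
        for v in (self.in_channels, self.out_channels, *self.kernel):
            if v < 1:
                raise ValueError("channels and kernel dims must be >= 1")

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        (kh, kw), (sh, sw), (ph, pw) = self.kernel, self.stride, self.padding
        return (h + 2 * ph - kh) // sh + 1, (w + 2 * pw - kw) // sw + 1


class ShapeError(ValueError):
    pass


class Module:
    """Tiny module base: parameter registry + profiling hooks."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_children", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for cn, child in self._children.items():
            out.extend(child.named_parameters(prefix + cn + "."))
        return out

    def modules(self):
        yield self
        for child in self._children.values():
            yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self) -> int:
        """Raw trainable parameter count (norm affine terms unfused)."""
        return sum(p.size for p in self.parameters())

    def fused_param_count(self) -> int:
        """Deploy-time parameter count (Conv+BatchNorm folded).

        Layers override `_own_fused_count`; the default sums children.
        """
        total = self._own_fused_count()
        for child in self._children.values():
            total += child.fused_param_count()
        return total

    def _own_fused_count(self) -> int:
        return sum(p.size for p in self._params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {n: p.data.copy() for n, p in self.named_parameters()}
        for m_i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                out[f"__bnstat{m_i}.mean"] = m.running_mean.copy()
                out[f"__bnstat{m_i}.var"] = m.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for n, p in self.named_parameters():
            p.data[...] = state[n]
        for m_i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean[...] = state[f"__bnstat{m_i}.mean"]
                m.running_var[...] = state[f"__bnstat{m_i}.var"]


# profiling record: every conv-like layer appends
# (cin_per_group, cout, kh, kw, hout, wout) to model._flop_log when profiling
_PROFILE_LOG: list[tuple[int, int, int, int, int, int]] | None = None


def profile_log():
    return _PROFILE_LOG


def set_profile_log(log):
    global _PROFILE_LOG
    _PROFILE_LOG = log


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.weight = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training and ag.is_grad_enabled():
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mean.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.data.ravel() - self.running_var)
        else:
            mean = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mean) / ((var + self.eps) ** 0.5)
        return xhat * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)

    def _own_fused_count(self) -> int:
        return 0  # folded into the preceding conv


class GroupNorm(Module):
    def __init__(self, groups: int, c: int, eps: float = 1e-5):
        super().__init__()
        if c % groups:
            raise ValueError(f"channels {c} not divisible by groups {groups}")
        self.groups = groups
        self.c = c
        self.eps = eps
        self.weight = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(c, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, c // g, h, w)
        mean = xg.mean(axis=(2, 3, 4), keepdims=True)
        var = ((xg - mean) ** 2).mean(axis=(2, 3, 4), keepdims=True)
        xhat = ((xg - mean) / ((var + self.eps) ** 0.5)).reshape(n, c, h, w)
        return xhat * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)
    # GroupNorm cannot be folded: default count (2C) applies


class Conv2d(Module):
    """Plain convolution (optionally biased); records itself when profiling."""

    def __init__(self, cin, cout, k=1, s=1, p=None, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if isinstance(k, int):
            k = (k, k)
        if p is None:
            p = (k[0] // 2, k[1] // 2)
        elif isinstance(p, int):
            p = (p, p)
        self.cin, self.cout, self.k, self.s, self.p = cin, cout, k, (s, s) if isinstance(s, int) else s, p
        w = _kaiming(rng, (cout, cin, *k), cin * k[0] * k[1])
        self.weight = Tensor(w, requires_grad=True)
        self.weight.decay = True
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cin:
            raise ShapeError(f"expected {self.cin} input channels, got {x.shape[1]}")
        out = ag.conv2d(x, self.weight, self.bias, self.s, self.p)
        if _PROFILE_LOG is not None:
            _PROFILE_LOG.append((self.cin, self.cout, *self.k, out.shape[2], out.shape[3]))
        return out


class ConvTranspose2d(Module):
    def __init__(self, cin, cout, k=2, s=2, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        self.weight = Tensor(_kaiming(rng, (cin, cout, k, k), cin), requires_grad=True)
        self.weight.decay = True
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = ag.conv_transpose2d(x, self.weight, self.bias, self.k)
        if _PROFILE_LOG is not None:
            # counted over output elements with the full k*k kernel, the
            # convention mainstream YOLO profilers use for this layer
            _PROFILE_LOG.append((self.cin, self.cout, self.k, self.k, out.shape[2], out.shape[3]))
        return out


class Conv(Module):
    """Conv2d + BatchNorm2d + SiLU (the standard styled conv)."""

    def __init__(self, cin, cout, k=1, s=1, p=None, act=True, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, s, p, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = act

    def __call__(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        return y.silu() if self.act else y

    def fused_param_count(self) -> int:
        # conv weight + the bias the folded BN leaves behind
        return self.conv.weight.size + self.conv.cout


class ConvGN(Module):
    """Conv2d + GroupNorm + SiLU — batch-size-robust head conv."""

    def __init__(self, cin, cout, k=1, s=1, groups=16, act=True, rng=None):
        super().__init__()
        if cout % groups:
            raise ValueError(f"Conv_GN width {cout} not divisible by {groups} groups")
        self.conv = Conv2d(cin, cout, k, s, bias=False, rng=rng)
        self.gn = GroupNorm(groups, cout)
        self.act = act

    def __call__(self, x: Tensor) -> Tensor:
        y = self.gn(self.conv(x))
        return y.silu() if self.act else y


class Bottleneck(Module):
    def __init__(self, cin, cout, shortcut=True, e=1.0, rng=None):
        super().__init__()
        ch = int(cout * e)
        self.cv1 = Conv(cin, ch, 3, 1, rng=rng)
        self.cv2 = Conv(ch, cout, 3, 1, rng=rng)
        self.add = shortcut and cin == cout
        if self.add:
            # residual branch starts at zero (identity block): speeds and
            # stabilises from-scratch training without changing any count
            self.cv2.bn.weight.data[...] = 0.0

    def __call__(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(Module):
    """Cross-stage partial block: split, n bottlenecks, concat, fuse."""

    def __init__(self, cin, cout, n=1, shortcut=False, rng=None):
        super().__init__()
        if cout % 2:
            raise ValueError("C2f output channels must be even")
        self.c = cout // 2
        self.cv1 = Conv(cin, 2 * self.c, 1, 1, rng=rng)
        self.cv2 = Conv((2 + n) * self.c, cout, 1, 1, rng=rng)
        self.m = [Bottleneck(self.c, self.c, shortcut, e=1.0, rng=rng) for _ in range(n)]

    def __call__(self, x: Tensor) -> Tensor:
        y = ag.chunk(self.cv1(x), 2, axis=1)
        for b in self.m:
            y.append(b(y[-1]))
        return self.cv2(ag.concat(y, axis=1))


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained 5x5 stride-1 max pools."""

    def __init__(self, cin, cout, k=5, rng=None):
        super().__init__()
        ch = cin // 2
        self.cv1 = Conv(cin, ch, 1, 1, rng=rng)
        self.cv2 = Conv(ch * 4, cout, 1, 1, rng=rng)
        self.k = k

    def __call__(self, x: Tensor) -> Tensor:
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(ag.max_pool2d(y[-1], self.k, 1))
        return self.cv2(ag.concat(y, axis=1))


class Scale(Module):
    """Learnable scalar multiplier for regression logits, initialised to 1."""

    def __init__(self, init: float = 1.0):
        super().__init__()
        self.theta = Tensor(np.float32(init), requires_grad=True)

    def __call__(self, t: Tensor) -> Tensor:
        return t * self.theta


class DFL(Module):
    """Distribution-focal decoder: expectation over reg_max discrete bins.

    Holds the fixed (non-trainable) projection 0..reg_max-1; counted in the
    deploy parameter tally like mainstream profilers do.
    """

    def __init__(self, reg_max: int = 16):
        super().__init__()
        if reg_max < 2:
            raise ValueError("reg_max must be >= 2")
        self.reg_max = reg_max
        self.proj = np.arange(reg_max, dtype=np.float32)

    def __call__(self, logits: Tensor) -> Tensor:
        """logits (..., 4, reg_max, A) -> distances (..., 4, A)."""
        p = logits.softmax(axis=-2)
        return (p * Tensor(self.proj.reshape(1, 1, -1, 1))).sum(axis=-2)

    def decode_np(self, logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        return (p * self.proj).sum(axis=-1)

    def _own_fused_count(self) -> int:
        return self.reg_max

    def num_parameters(self) -> int:  # not trainable
        return 0


def conv_bn_act(x: Tensor, spec: ConvSpec, rng=None) -> Tensor:
    """One-off functional conv-norm-act per a ConvSpec (mainly for tests)."""
    layer = make_conv(spec, rng=rng)
    return layer(x)


def make_conv(spec: ConvSpec, rng=None) -> Module:
    if spec.has_norm and spec.norm_kind == "batch":
        m = Conv(spec.in_channels, spec.out_channels, spec.kernel, spec.stride,
                 spec.padding, act=spec.has_activation, rng=rng)
    elif spec.has_norm:
        m = ConvGN(spec.in_channels, spec.out_channels, spec.kernel[0],
                   spec.stride[0], act=spec.has_activation, rng=rng)
    else:
        m = Conv2d(spec.in_channels, spec.out_channels, spec.kernel, spec.stride,
                   spec.padding, bias=False, rng=rng)
    return m
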