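"""Building blocks of the ghost-attention segmentation network.

The backbone's downsampling stages are ghost bottlenecks: residual blocks
whose convolutions are *ghost modules* — a reduced primary 1x1 convolution
producing c2/r channels, a cheap depthwise "ghost" operation generating the
remaining c2*(r-1)/r channels from it, and a channel concatenation.  This
yields the same output width as a dense convolution at a fraction of the
parameters.  The neck carries global attention modules (GAM): sequential
channel attention (global average pooling, two projections, sigmoid) and
spatial attention (two wide convolutions, sigmoid), each multiplied into
the feature map.  Conv/C2f/SPPF follow the standard YOLOv8 designs.

Every convolution is followed by batch normalisation and SiLU, except the
final projections inside SE/GAM attention branches (which end in a sigmoid
and carry a bias instead of a norm) and the residual shortcut's pointwise
convolution (normalisation only).  Normalisation uses eps 1e-3 and
momentum 0.03 on the running statistics.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Param, Tensor

BN_EPS = 1e-3
BN_MOMENTUM = 0.03

_ACTS = {
    "silu": ad.silu,
    "relu": ad.relu,
    "sigmoid": ad.sigmoid,
    None: lambda t: t,
}


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = float(np.sqrt(1.0 / max(fan_in, 1)))
    return rng.uniform(-bound, bound, size=shape).astype(ad.DTYPE)


class Module:
    """Minimal container with recursive parameter / buffer discovery."""

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Param):
                yield (f"{prefix}{name}", value)
        for cname, child in self._children():
            yield from child.named_parameters(f"{prefix}{cname}.")

    def parameters(self) -> list[Param]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray) and name.startswith("running_"):
                yield (f"{prefix}{name}", value)
        for cname, child in self._children():
            yield from child.named_buffers(f"{prefix}{cname}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: p.data for name, p in self.named_parameters()}
        d.update({name: buf for name, buf in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(d[name], dtype=ad.DTYPE).reshape(p.data.shape)
        for name, buf in self.named_buffers():
            buf[...] = np.asarray(d[name], dtype=buf.dtype).reshape(buf.shape)

    def conv_weight_count(self) -> int:
        """Number of convolution-kernel weights (excludes norms and biases)."""
        return int(sum(p.data.size for name, p in self.named_parameters()
                       if name.rsplit(".", 1)[-1] == "weight"))

    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return self.forward(x, training)


class Identity(Module):
    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        return x


class BatchNorm2d(Module):
    def __init__(self, channels: int):
        self.gamma = Param(np.ones(channels), name="bn.gamma", decay=False)
        self.beta = Param(np.zeros(channels), name="bn.beta", decay=False)
        self.running_mean = np.zeros(channels, dtype=ad.DTYPE)
        self.running_var = np.ones(channels, dtype=ad.DTYPE)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        return ad.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, training, BN_MOMENTUM, BN_EPS)


class Conv(Module):
    """Convolution + optional BatchNorm + activation (SiLU by default)."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, p: int | None = None,
                 act: str | None = "silu", bn: bool = True, bias: bool | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        if p is None:
            p = k // 2
        self.c1, self.c2, self.k, self.s, self.p = c1, c2, k, s, p
        self.act = act
        fan_in = c1 * k * k
        self.weight = Param(_kaiming_uniform(rng, (c2, c1, k, k), fan_in), name="conv.weight")
        use_bias = (not bn) if bias is None else bias
        self.bias = Param(np.zeros(c2), name="conv.bias", decay=False) if use_bias else None
        self.bn = BatchNorm2d(c2) if bn else None

    def named_parameters(self, prefix: str = ""):
        yield (f"{prefix}weight", self.weight)
        if self.bias is not None:
            yield (f"{prefix}bias", self.bias)
        if self.bn is not None:
            yield from self.bn.named_parameters(f"{prefix}bn.")

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        y = ad.conv2d(x, self.weight, self.bias, stride=self.s, padding=self.p)
        if self.bn is not None:
            y = self.bn(y, training)
        return _ACTS[self.act](y)


class DWConv(Module):
    """Depthwise convolution (+BN, optional activation, channel multiplier)."""

    def __init__(self, c: int, k: int = 3, s: int = 1, act: str | None = None,
                 multiplier: int = 1, bn: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c, self.k, self.s, self.mult = c, k, s, multiplier
        self.p = k // 2
        self.act = act
        self.weight = Param(_kaiming_uniform(rng, (c * multiplier, 1, k, k), k * k),
                            name="dwconv.weight")
        self.bn = BatchNorm2d(c * multiplier) if bn else None

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        y = ad.depthwise_conv2d(x, self.weight, None, stride=self.s, padding=self.p,
                                multiplier=self.mult)
        if self.bn is not None:
            y = self.bn(y, training)
        return _ACTS[self.act](y)


class GhostModule(Module):
    """Primary 1x1 convolution to c2/r channels, cheap depthwise ghost
    features for the remaining c2(r-1)/r, concatenated to c2 channels."""

    def __init__(self, c1: int, c2: int, r: int = 2, dw_kernel: int = 3,
                 act: str | None = "silu", rng: np.random.Generator | None = None):
        if c2 % r:
            raise ValueError(f"output channels {c2} not divisible by ratio {r}")
        rng = rng or np.random.default_rng(0)
        self.c1, self.c2, self.r = c1, c2, r
        cp = c2 // r
        self.primary = Conv(c1, cp, 1, 1, act=act, rng=rng)
        self.cheap = DWConv(cp, dw_kernel, 1, act=act, multiplier=r - 1, rng=rng)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        x1 = self.primary(x, training)
        x2 = self.cheap(x1, training)
        return ad.concat([x1, x2], axis=1)


class SELayer(Module):
    """Squeeze-and-excitation: GAP -> FC/ReLU -> FC/sigmoid -> channel scale."""

    def __init__(self, c: int, reduction: int = 4, rng: np.random.Generator | None = None):
        if c % reduction:
            raise ValueError(f"channels {c} not divisible by reduction {reduction}")
        rng = rng or np.random.default_rng(0)
        cr = c // reduction
        self.fc1 = Conv(c, cr, 1, act="relu", bn=False, bias=True, rng=rng)
        self.fc2 = Conv(cr, c, 1, act="sigmoid", bn=False, bias=True, rng=rng)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        s = self.fc2(self.fc1(ad.global_avg_pool(x), training), training)
        return ad.mul(x, s)


class GhostBottleneck(Module):
    """Residual block: ghost module -> (stride-2 depthwise) -> (SE) -> ghost
    module, summed with an identity or depthwise+pointwise shortcut."""

    def __init__(self, c1: int, c2: int, k: int = 3, s: int = 1, use_se: bool = False,
                 r: int = 2, se_reduction: int = 4, rng: np.random.Generator | None = None):
        if s not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {s}")
        rng = rng or np.random.default_rng(0)
        self.c1, self.c2, self.s = c1, c2, s
        mid = c2 // 2
        self.ghost1 = GhostModule(c1, mid, r=r, act="silu", rng=rng)
        self.down = DWConv(mid, k, 2, act=None, rng=rng) if s == 2 else None
        self.se = SELayer(mid, se_reduction, rng=rng) if use_se else None
        self.ghost2 = GhostModule(mid, c2, r=r, act=None, rng=rng)
        if s == 1 and c1 == c2:
            self.short_dw = None
            self.short_pw = None
        else:
            self.short_dw = DWConv(c1, k, s, act=None, rng=rng)
            self.short_pw = Conv(c1, c2, 1, act=None, rng=rng)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        y = self.ghost1(x, training)
        if self.down is not None:
            y = self.down(y, training)
        if self.se is not None:
            y = self.se(y, training)
        y = self.ghost2(y, training)
        if self.short_dw is None:
            shortcut = x
        else:
            shortcut = self.short_pw(self.short_dw(x, training), training)
        return ad.add(y, shortcut)


class GAM(Module):
    """Global attention: channel gate then spatial gate.

    Channel branch: sigmoid(W2 . silu(W1 . GAP(x))), broadcast over space.
    Spatial branch: sigmoid(conv(silu(bn(conv(xc))))), two k x k
    convolutions with channel reduction then restoration, broadcast over
    channels of the channel-attended map.
    """

    def __init__(self, c: int, reduction: int = 4, spatial_kernel: int = 7,
                 rng: np.random.Generator | None = None):
        if c % reduction:
            raise ValueError(f"channels {c} not divisible by reduction {reduction}")
        if spatial_kernel % 2 == 0:
            raise ValueError("spatial kernel must be odd")
        rng = rng or np.random.default_rng(0)
        cr = c // reduction
        self.ch_fc1 = Conv(c, cr, 1, act="silu", bn=False, bias=True, rng=rng)
        self.ch_fc2 = Conv(cr, c, 1, act="sigmoid", bn=False, bias=True, rng=rng)
        self.sp_conv1 = Conv(c, cr, spatial_kernel, act="silu", rng=rng)
        self.sp_conv2 = Conv(cr, c, spatial_kernel, act="sigmoid", bn=False, bias=True,
                             rng=rng)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        ac = self.ch_fc2(self.ch_fc1(ad.global_avg_pool(x), training), training)
        xc = ad.mul(x, ac)
        asp = self.sp_conv2(self.sp_conv1(xc, training), training)
        return ad.mul(xc, asp)


class Bottleneck(Module):
    """Two 3x3 convolutions with optional residual add (C2f inner block)."""

    def __init__(self, c1: int, c2: int, shortcut: bool = True, e: float = 1.0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        ch = int(c2 * e)
        self.cv1 = Conv(c1, ch, 3, 1, rng=rng)
        self.cv2 = Conv(ch, c2, 3, 1, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        y = self.cv2(self.cv1(x, training), training)
        return ad.add(x, y) if self.add else y


class C2f(Module):
    """Cross-stage-partial block: split, chained bottlenecks, concat, fuse."""

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c = c2 // 2
        self.n = n
        self.cv1 = Conv(c1, 2 * self.c, 1, 1, rng=rng)
        self.bottlenecks = [Bottleneck(self.c, self.c, shortcut, rng=rng)
                            for _ in range(n)]
        self.cv2 = Conv((2 + n) * self.c, c2, 1, 1, rng=rng)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        y = self.cv1(x, training)
        parts = [y[:, : self.c], y[:, self.c:]]
        for b in self.bottlenecks:
            parts.append(b(parts[-1], training))
        return self.cv2(ad.concat(parts, axis=1), training)


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained equal max-pools."""

    def __init__(self, c1: int, c2: int, k: int = 5,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        c_ = c1 // 2
        self.k = k
        self.cv1 = Conv(c1, c_, 1, 1, rng=rng)
        self.cv2 = Conv(c_ * 4, c2, 1, 1, rng=rng)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        y = self.cv1(x, training)
        p = self.k // 2
        y1 = ad.maxpool2d(y, self.k, 1, p)
        y2 = ad.maxpool2d(y1, self.k, 1, p)
        y3 = ad.maxpool2d(y2, self.k, 1, p)
        return self.cv2(ad.concat([y, y1, y2, y3], axis=1), training)


def ghost_vs_dense_weight_counts(c1: int, c2: int, k: int = 3, r: int = 2) -> tuple[int, int]:
    """Convolution-weight counts of a ghost module versus a dense k x k
    convolution with the same channel map (the efficiency argument)."""
    cp = c2 // r
    ghost = c1 * cp + cp * (r - 1) * k * k  # primary 1x1 + cheap depthwise
    dense = c1 * c2 * k * k
    return ghost, dense
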