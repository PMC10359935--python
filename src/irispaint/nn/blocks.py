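"""Network building blocks: conv modules, the deepened residual block, and
the squeeze-and-excitation / spatial-attention primitives used by the
attention-gated skip connections of the fine repair network.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Tiny layer base class: parameter traversal and train/eval mode."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield prefix + name, v
        for name, child in self._children():
            yield from child.named_parameters(f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(f"{prefix}{name}.")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def he_normal(rng: np.random.Generator, shape, fan_in: int, dtype) -> Tensor:
    """He (fan-in scaled Gaussian) initialization for rectifier networks."""
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(dtype), requires_grad=True)


class Conv2d(Module):
    """Same-padded convolution (pad = kernel//2), odd kernels, NCHW."""

    def __init__(self, in_ch, out_ch, kernel, rng, stride=1, bias=True,
                 dtype=np.float32):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("odd kernel sizes only")
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        self.weight = he_normal(
            rng, (out_ch, in_ch, kernel, kernel), in_ch * kernel * kernel, dtype
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, stride=self.stride)


class Linear(Module):
    def __init__(self, in_f, out_f, rng, bias=True, dtype=np.float32):
        super().__init__()
        self.weight = he_normal(rng, (in_f, out_f), in_f, dtype)
        self.bias = Tensor(np.zeros(out_f, dtype=dtype), requires_grad=True) if bias else None

    def forward(self, x):
        out = T.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1)
        return out


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel.

    Training mode uses batch statistics and updates exponential running
    estimates; eval mode uses the running estimates as constants.
    """

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, ch, momentum=0.1, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.gamma = Tensor(np.ones(ch, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(ch, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)

    def forward(self, x):
        if self.training:
            mu = T.mean(x, axis=(0, 2, 3), keepdims=True)
            var = T.mean((x - mu) ** 2, axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu.data.ravel()).astype(
                self.running_mean.dtype
            )
            self.running_var = ((1 - m) * self.running_var + m * var.data.ravel()).astype(
                self.running_var.dtype
            )
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) / T.sqrt(var + self.eps)
        return self.gamma.reshape(1, -1, 1, 1) * xhat + self.beta.reshape(1, -1, 1, 1)


class ConvModule(Module):
    """Conv-BN-activation unit: the ``Conv3×3-BN-LReLU`` style building brick."""

    def __init__(self, in_ch, out_ch, rng, kernel=3, stride=1, use_bn=True,
                 act="lrelu", slope=0.2, dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, rng, stride=stride,
                           bias=not use_bn, dtype=dtype)
        self.bn = BatchNorm2d(out_ch, dtype=dtype) if use_bn else None
        self.act, self.slope = act, slope

    def forward(self, x):
        x = self.conv(x)
        if self.bn is not None:
            x = self.bn(x)
        if self.act == "lrelu":
            x = T.leaky_relu(x, self.slope)
        elif self.act == "sigmoid":
            x = T.sigmoid(x)
        elif self.act != "none":
            raise ValueError(f"unknown activation {self.act!r}")
        return x


class MRB(Module):
    """Deepened residual block with internal feature reuse.

    Two Conv1×1-BN-LReLU / Conv3×3-BN-LReLU module pairs in sequence; the
    output of the first pair (y1) both feeds the second pair (y2) and is
    concatenated with it, and the concatenation is added to an identity
    branch.  y1 and y2 each carry ``out_ch // 2`` channels so the Concat
    matches the identity branch; a bias-free 1×1 projection is inserted on
    the identity branch whenever in_ch != out_ch.
    """

    def __init__(self, in_ch, out_ch, rng, slope=0.2, dtype=np.float32):
        super().__init__()
        if out_ch % 2:
            raise ValueError("MRB out_ch must be even")
        mid = out_ch // 2
        kw = dict(slope=slope, dtype=dtype)
        self.m1 = ConvModule(in_ch, mid, rng, kernel=1, **kw)
        self.m2 = ConvModule(mid, mid, rng, kernel=3, **kw)
        self.m3 = ConvModule(mid, mid, rng, kernel=1, **kw)
        self.m4 = ConvModule(mid, mid, rng, kernel=3, **kw)
        self.proj = (
            Conv2d(in_ch, out_ch, 1, rng, bias=False, dtype=dtype)
            if in_ch != out_ch
            else None
        )

    def forward(self, x):
        y1 = self.m2(self.m1(x))
        y2 = self.m4(self.m3(y1))
        identity = self.proj(x) if self.proj is not None else x
        return T.concat([y1, y2], axis=1) + identity


class SqueezeExcite(Module):
    """Channel attention: sigmoid(LReLU(GAP(x) W1) W2), one gain per channel.

    GAP is the spatial global average; W1/W2 are bias-free fully connected
    layers with reduction ratio ``r``.
    """

    def __init__(self, ch, rng, r=16, slope=0.2, dtype=np.float32):
        super().__init__()
        hidden = max(1, ch // r)
        self.w1 = he_normal(rng, (ch, hidden), ch, dtype)
        self.w2 = he_normal(rng, (hidden, ch), hidden, dtype)
        self.slope = slope

    def forward(self, x):
        n, c = x.shape[0], x.shape[1]
        gap = T.mean(x, axis=(2, 3))  # (N, C)
        gains = T.sigmoid(T.matmul(T.leaky_relu(T.matmul(gap, self.w1), self.slope), self.w2))
        return gains.reshape(n, c, 1, 1)


class SpatialAttention(Module):
    """Spatial attention: sigmoid(Conv7×7(Concat(channel-mean, channel-max))).

    Returns one gain per spatial location, in (0, 1); the gains are not
    pre-multiplied into the input.
    """

    def __init__(self, rng, kernel=7, dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel, rng, bias=True, dtype=dtype)

    def forward(self, x):
        avg = T.mean(x, axis=1, keepdims=True)
        mx = T.max_(x, axis=1, keepdims=True)
        return T.sigmoid(self.conv(T.concat([avg, mx], axis=1)))


class DACC(Module):
    """Dual-attention skip connection between encoder and decoder features.

    Output = Concat( LReLU(BN1(x_de * SA(x_en))),  SE(x_en) * sigmoid(BN2(x_de)) )
    so C-channel inputs produce a 2C-channel output.  ``use_se=False`` forces
    the channel gains to 1 (the spatial-attention-only ablation).
    """

    def __init__(self, ch, rng, r=16, slope=0.2, use_se=True, dtype=np.float32):
        super().__init__()
        self.sa = SpatialAttention(rng, dtype=dtype)
        self.se = SqueezeExcite(ch, rng, r=r, slope=slope, dtype=dtype) if use_se else None
        self.bn1 = BatchNorm2d(ch, dtype=dtype)
        self.bn2 = BatchNorm2d(ch, dtype=dtype)
        self.slope = slope

    def forward(self, x_en, x_de):
        if x_en.shape[2:] != x_de.shape[2:]:
            raise ValueError(
                f"DACC spatial mismatch: encoder {x_en.shape}, decoder {x_de.shape}"
            )
        sa = self.sa(x_en)  # (N,1,H,W)
        b1 = T.leaky_relu(self.bn1(x_de * sa), self.slope)
        gate = T.sigmoid(self.bn2(x_de))
        b2 = self.se(x_en) * gate if self.se is not None else gate
        return T.concat([b1, b2], axis=1)
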