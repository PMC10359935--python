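"""The coarse repair network, fine repair network and critic.

All three are built from the blocks in :mod:`irispaint.nn.blocks` with He
initialization driven by a single integer seed, and can be checkpointed to
HDF5 with a bit-exact round trip.

Architecture summary (default widths, 256×256 input):

* Coarse net — U-Net: 4 encoder layers of two Conv3×3-BN-LReLU modules plus
  2×2 max pooling (bottleneck 16×16), a two-module transition, 4 decoder
  layers of nearest-neighbour ×2 upsampling + plain skip concat + two conv
  modules, and a final 1×1 conv + sigmoid back to the input channel count.
* Fine net — encoder layer 1 is a conv module + pool; layers 2–5 are a
  modified residual block (MRB) + pool (bottleneck 8×8); decoder layers are
  Conv1×1 + nearest-neighbour upsampling, an attention-gated skip merge
  (DACC by default; plain concat and SA-only are the ablation wirings), and
  one Conv3×3-BN-LReLU module; final 1×1 conv + sigmoid.
* Critic — six Conv5×5 stride-2 + LReLU layers (no batch norm, as required
  for a gradient-penalty critic), then Conv3×3 + LReLU + global average
  pooling and a linear layer to one unbounded score per image.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from . import tensor as T
from .blocks import (
    MRB,
    BatchNorm2d,
    Conv2d,
    ConvModule,
    DACC,
    Linear,
    Module,
    Sequential,
)
from .tensor import Tensor

COARSE_WIDTHS = (64, 128, 256, 512)
FINE_WIDTHS = (64, 128, 256, 512, 512)
DISC_WIDTHS = (64, 128, 256, 256, 512, 512)

SKIP_MODES = ("dacc", "concat", "sa_only")


def _check_divisible(x, factor, name):
    h, w = x.shape[2], x.shape[3]
    if h % factor or w % factor:
        raise ValueError(f"{name} needs spatial size divisible by {factor}, got {h}x{w}")


class CoarseNet(Module):
    """Stage-1 generator: contour and rough-texture repair, trained with L1."""

    def __init__(self, in_ch=1, widths=COARSE_WIDTHS, seed=0, slope=0.2,
                 dtype=np.float32):
        super().__init__()
        self.hyper = dict(arch="coarse", in_ch=in_ch, widths=tuple(widths),
                          seed=seed, slope=slope)
        rng = np.random.default_rng(seed)
        kw = dict(slope=slope, dtype=dtype)
        self.enc = []
        prev = in_ch
        for w in widths:
            self.enc.append(Sequential(ConvModule(prev, w, rng, **kw),
                                       ConvModule(w, w, rng, **kw)))
            prev = w
        self.trans = Sequential(ConvModule(prev, prev, rng, **kw),
                                ConvModule(prev, prev, rng, **kw))
        self.dec = []
        for w in reversed(widths):
            self.dec.append(Sequential(ConvModule(prev + w, w, rng, **kw),
                                       ConvModule(w, w, rng, **kw)))
            prev = w
        self.out_conv = Conv2d(prev, in_ch, 1, rng, dtype=dtype)

    def forward(self, x):
        _check_divisible(x, 2 ** len(self.enc), "coarse network")
        feats = []
        for block in self.enc:
            f = block(x)
            feats.append(f)
            x = T.maxpool2(f)
        x = self.trans(x)
        for block, f in zip(self.dec, reversed(feats)):
            x = T.upsample2(x)
            x = block(T.concat([x, f], axis=1))
        return T.sigmoid(self.out_conv(x))


class FineNet(Module):
    """Stage-2 generator: texture refinement with attention-gated skips."""

    def __init__(self, in_ch=1, widths=FINE_WIDTHS, seed=0, skip_mode="dacc",
                 se_ratio=16, slope=0.2, dtype=np.float32):
        super().__init__()
        if skip_mode not in SKIP_MODES:
            raise ValueError(f"skip_mode must be one of {SKIP_MODES}, got {skip_mode!r}")
        self.hyper = dict(arch="fine", in_ch=in_ch, widths=tuple(widths), seed=seed,
                          skip_mode=skip_mode, se_ratio=se_ratio, slope=slope)
        self.skip_mode = skip_mode
        rng = np.random.default_rng(seed)
        kw = dict(slope=slope, dtype=dtype)
        self.enc = [ConvModule(in_ch, widths[0], rng, **kw)]
        for cin, cout in zip(widths, widths[1:]):
            self.enc.append(MRB(cin, cout, rng, slope=slope, dtype=dtype))
        prev = widths[-1]
        self.trans = Sequential(ConvModule(prev, prev, rng, **kw),
                                ConvModule(prev, prev, rng, **kw))
        self.up_convs, self.skips, self.dec = [], [], []
        rev = list(reversed(widths))
        outs = rev[1:] + [widths[0]]
        for w, wout in zip(rev, outs):
            self.up_convs.append(Conv2d(prev, w, 1, rng, dtype=dtype))
            if skip_mode == "dacc":
                self.skips.append(DACC(w, rng, r=se_ratio, slope=slope, dtype=dtype))
            elif skip_mode == "sa_only":
                self.skips.append(DACC(w, rng, r=se_ratio, slope=slope,
                                       use_se=False, dtype=dtype))
            else:
                self.skips.append(None)
            self.dec.append(ConvModule(2 * w, wout, rng, **kw))
            prev = wout
        self.out_conv = Conv2d(prev, in_ch, 1, rng, dtype=dtype)

    def forward(self, x):
        _check_divisible(x, 2 ** len(self.enc), "fine network")
        feats = []
        for block in self.enc:
            f = block(x)
            feats.append(f)
            x = T.maxpool2(f)
        x = self.trans(x)
        for up, skip, block, f in zip(self.up_convs, self.skips, self.dec,
                                      reversed(feats)):
            x = T.upsample2(up(x))
            merged = T.concat([x, f], axis=1) if skip is None else skip(f, x)
            x = block(merged)
        return T.sigmoid(self.out_conv(x))


class Discriminator(Module):
    """WGAN-GP critic: one unbounded realness score per image, no batch norm."""

    def __init__(self, in_ch=1, widths=DISC_WIDTHS, seed=0, slope=0.2,
                 dtype=np.float32):
        super().__init__()
        self.hyper = dict(arch="discriminator", in_ch=in_ch, widths=tuple(widths),
                          seed=seed, slope=slope)
        self.slope = slope
        rng = np.random.default_rng(seed)
        self.convs = []
        prev = in_ch
        for w in widths:
            self.convs.append(Conv2d(prev, w, 5, rng, stride=2, dtype=dtype))
            prev = w
        self.last_conv = Conv2d(prev, prev, 3, rng, stride=1, dtype=dtype)
        self.fc = Linear(prev, 1, rng, dtype=dtype)

    def forward(self, x):
        _check_divisible(x, 2 ** len(self.convs), "discriminator")
        for conv in self.convs:
            x = T.leaky_relu(conv(x), self.slope)
        x = T.leaky_relu(self.last_conv(x), self.slope)
        x = T.mean(x, axis=(2, 3))  # global average pool -> (N, C)
        return self.fc(x).reshape(-1)

    def features(self, x):
        """Pre-pooling feature map (exposed for shape diagnostics)."""
        for conv in self.convs:
            x = T.leaky_relu(conv(x), self.slope)
        return T.leaky_relu(self.last_conv(x), self.slope)


_ARCHS = {"coarse": CoarseNet, "fine": FineNet, "discriminator": Discriminator}

_DEFAULT_WIDTHS = {"coarse": COARSE_WIDTHS, "fine": FINE_WIDTHS,
                   "discriminator": DISC_WIDTHS}


def init_params(arch: str, widths=None, seed: int = 0, **kwargs) -> Module:
    """Build a seeded, He-initialized network of the given architecture.

    ``arch`` is one of ``coarse`` / ``fine`` / ``discriminator``; the same
    (arch, widths, seed) always yields bit-identical parameters.
    """
    if arch not in _ARCHS:
        raise ValueError(f"unknown architecture {arch!r}")
    widths = tuple(widths) if widths is not None else _DEFAULT_WIDTHS[arch]
    return _ARCHS[arch](widths=widths, seed=seed, **kwargs)


def scaled_widths(arch: str, factor: int):
    """Default widths divided by an integer factor (miniature configurations)."""
    return tuple(max(2, w // factor) for w in _DEFAULT_WIDTHS[arch])


def save_checkpoint(path, nets: dict):
    """Write named networks to HDF5: parameter/buffer arrays + JSON header."""
    with h5py.File(path, "w") as f:
        for name, net in nets.items():
            grp = f.create_group(name)
            grp.attrs["hyper"] = json.dumps(net.hyper)
            for pname, p in net.named_parameters():
                grp.create_dataset("param/" + pname, data=p.data)
            for bname, b in net.named_buffers():
                grp.create_dataset("buffer/" + bname, data=b)


def load_checkpoint(path) -> dict:
    """Reconstruct networks saved by :func:`save_checkpoint`, bit-exactly."""
    nets = {}
    with h5py.File(path, "r") as f:
        for name, grp in f.items():
            hyper = json.loads(grp.attrs["hyper"])
            arch = hyper.pop("arch")
            net = _ARCHS[arch](**hyper)
            params = dict(net.named_parameters())
            for pname, p in params.items():
                p.data = np.asarray(grp["param"][pname])
            buffers = dict(net.named_buffers())
            _set_buffers(net, {bname: np.asarray(grp["buffer"][bname])
                               for bname in buffers})
            nets[name] = net
    return nets


def _set_buffers(net: Module, values: dict, prefix: str = ""):
    for name in getattr(net, "_buffer_names", ()):
        full = prefix + name
        if full in values:
            setattr(net, name, values[full])
    for name, child in net._children():
        _set_buffers(child, values, f"{prefix}{name}.")
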