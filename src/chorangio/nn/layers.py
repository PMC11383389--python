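"""Network modules: compact U-Net segmentors and the 5-layer output-space
discriminator (EDD).

The default backbone is deliberately small (depth 3, base width 16) so that
CPU-only training on phantom data finishes in minutes; larger backbones plug in
behind the same forward contract (logit maps at input resolution).
"""

from __future__ import annotations

import numpy as np

from .ops import conv2d, maxpool2x2, upsample2x_nearest
from .tensor import Tensor, concat


class Module:
    """Tiny module base: parameter discovery + state (de)serialization."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor):
                        params.append(item)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def freeze(self):
        for p in self.parameters():
            p.requires_grad = False

    def unfreeze(self):
        for p in self.parameters():
            p.requires_grad = True

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"state mismatch: {len(arrays)} arrays vs {len(params)} params")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float32).copy()


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 init_std: float | None = None):
        # default: He fan-in (ReLU nets); discriminators pass the DCGAN 0.02
        std = np.sqrt(2.0 / (in_ch * kernel * kernel)) if init_std is None else init_std
        self.weight = Tensor(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DoubleConv(Module):
    def __init__(self, in_ch, out_ch, rng):
        self.c1 = Conv2d(in_ch, out_ch, 3, rng, padding=1)
        self.c2 = Conv2d(out_ch, out_ch, 3, rng, padding=1)

    def __call__(self, x):
        return self.c2(self.c1(x).relu()).relu()


class UNetTrunk(Module):
    """Encoder-decoder trunk; returns a `base`-channel feature map at input size.

    Input spatial dims must be divisible by 2**depth (callers pad beforehand).
    """

    def __init__(self, in_ch: int, rng: np.random.Generator, base: int = 16, depth: int = 3):
        self.depth = depth
        self.base = base
        widths = [base * (2 ** d) for d in range(depth + 1)]
        self.encoders = []
        ch = in_ch
        for w in widths[:-1]:
            self.encoders.append(DoubleConv(ch, w, rng))
            ch = w
        self.bottleneck = DoubleConv(ch, widths[-1], rng)
        self.decoders = []
        up = widths[-1]
        for w in reversed(widths[:-1]):
            self.decoders.append(DoubleConv(up + w, w, rng))
            up = w

    def __call__(self, x: Tensor) -> Tensor:
        skips = []
        h = x
        for enc in self.encoders:
            h = enc(h)
            skips.append(h)
            h = maxpool2x2(h)
        h = self.bottleneck(h)
        for dec, skip in zip(self.decoders, reversed(skips)):
            h = dec(concat([upsample2x_nearest(h), skip], axis=1))
        return h


class SingleTaskSegmentor(Module):
    """U-Net trunk + one 1x1-conv logit head (vessel: 2ch, sublayer: 3ch)."""

    def __init__(self, in_ch: int, n_classes: int, rng, base: int = 16, depth: int = 3):
        self.trunk = UNetTrunk(in_ch, rng, base=base, depth=depth)
        self.head = Conv2d(base, n_classes, 1, rng)
        self.n_classes = n_classes
        self.depth = depth

    def __call__(self, x: Tensor) -> Tensor:
        return self.head(self.trunk(x))


class MultiTaskSegmentor(Module):
    """Shared trunk emitting both subtask heads in one forward pass."""

    def __init__(self, in_ch: int, rng, base: int = 16, depth: int = 3):
        self.trunk = UNetTrunk(in_ch, rng, base=base, depth=depth)
        self.head_layer = Conv2d(base, 3, 1, rng)
        self.head_vessel = Conv2d(base, 2, 1, rng)
        self.depth = depth

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        f = self.trunk(x)
        return self.head_layer(f), self.head_vessel(f)


#: discriminator architecture: (channels, stride) per layer; kernel 4, padding 1
EDD_CHANNELS = (64, 128, 256, 512, 1)
EDD_STRIDES = (2, 2, 1, 1, 1)
EDD_KERNEL = 4
EDD_PADDING = 1


class EDD(Module):
    """Output-space domain discriminator.

    Five 4x4 convolutions, channels (64, 128, 256, 512, 1), strides
    (2, 2, 1, 1, 1), paddings all 1, leaky-ReLU (slope 0.2) between layers, a
    single-channel logit map out.  Sigmoid of the logits is the domain score S,
    with S -> 0 read as source-like.
    """

    MIN_INPUT = 16

    def __init__(self, in_ch: int, rng: np.random.Generator):
        self.in_ch = in_ch
        self.convs = []
        ch = in_ch
        for out_ch, stride in zip(EDD_CHANNELS, EDD_STRIDES):
            # DCGAN-style N(0, 0.02) init keeps the early adversarial game gentle
            self.convs.append(Conv2d(ch, out_ch, EDD_KERNEL, rng,
                                     stride=stride, padding=EDD_PADDING,
                                     init_std=0.02))
            ch = out_ch

    def __call__(self, x: Tensor) -> Tensor:
        h, w = x.data.shape[2], x.data.shape[3]
        if min(h, w) < self.MIN_INPUT:
            raise ValueError(f"EDD input {h}x{w} below minimum {self.MIN_INPUT}")
        out = x
        for i, conv in enumerate(self.convs):
            out = conv(out)
            if i < len(self.convs) - 1:
                out = out.leaky_relu(0.2)
        return out
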