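"""Network architectures: U-net, context encoder, calibration decoder, backbone.

All are small configurable CNNs.  The U-net follows the pix2pix generator
shape (channel doubling per level with a cap, skip connections, 50% dropout
before the output layer, sigmoid output); the calibration encoder/decoder
mirror its halves.  Sizes are configurable so that desk-scale experiments can
use 64 px inputs and a handful of channels.
"""

from __future__ import annotations

import numpy as np

from .core import (BatchNorm2d, Conv2d, ConvTranspose2d, Dropout, GlobalAvgPool,
                   Layer, Linear, MaxPool2d, Param, ReLU, Sigmoid)

__all__ = ["Network", "ConvBlock", "UNet", "ContextEncoder", "CalibDecoder",
           "GlobalBackbone", "ReferenceDetectorNet", "logit"]


def logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


#: sigmoid(FINAL_BIAS) ~ 0.1 — biases output maps toward background at init,
#: which keeps the additive fusion of two heads inside (0, 1) at the start.
FINAL_BIAS = logit(0.1)


class ConvBlock(Layer):
    """(conv3x3 -> [BN] -> ReLU) x 2."""

    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator, bn: bool = True):
        seq: list[Layer] = [Conv2d(cin, cout, 3, rng=rng)]
        if bn:
            seq.append(BatchNorm2d(cout))
        seq.append(ReLU())
        seq.append(Conv2d(cout, cout, 3, rng=rng))
        if bn:
            seq.append(BatchNorm2d(cout))
        seq.append(ReLU())
        self.seq = seq

    def sublayers(self):
        return list(enumerate(self.seq))

    def params(self) -> list[Param]:
        return [p for l in self.seq for p in l.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for l in self.seq:
            x = l.forward(x, train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for l in reversed(self.seq):
            gy = l.backward(gy)
        return gy


class Network:
    """Base class: named-layer registry, (de)serialization, freezing."""

    def __init__(self) -> None:
        self._named: list[tuple[str, Layer]] = []

    def _reg(self, name: str, layer: Layer) -> Layer:
        self._named.append((name, layer))
        return layer

    def _flat(self) -> list[tuple[str, Layer]]:
        out = []
        stack = list(self._named)
        while stack:
            name, layer = stack.pop(0)
            subs = getattr(layer, "sublayers", None)
            if subs is not None and subs():
                stack = [(f"{name}.{i}", l) for i, l in subs()] + stack
            else:
                out.append((name, layer))
        return out

    def params(self) -> list[Param]:
        return [p for _, l in self._flat() for p in l.params()]

    def state_dict(self) -> dict[str, np.ndarray]:
        st: dict[str, np.ndarray] = {}
        for name, layer in self._flat():
            for i, p in enumerate(layer.params()):
                st[f"{name}.p{i}"] = p.data.copy()
            extra = getattr(layer, "extra_state", None)
            if extra is not None:
                for k, v in extra().items():
                    st[f"{name}.{k}"] = v.copy()
        return st

    def load_state_dict(self, st: dict[str, np.ndarray]) -> None:
        for name, layer in self._flat():
            for i, p in enumerate(layer.params()):
                p.data[...] = st[f"{name}.p{i}"]
            load = getattr(layer, "load_extra_state", None)
            if load is not None:
                load({k: st[f"{name}.{k}"] for k in ("running_mean", "running_var")})

    def freeze(self) -> None:
        for p in self.params():
            p.frozen = True


class UNet(Network):
    """Encoder (conv + max-pool) / decoder (up-conv) with skip connections.

    Input: normalized images in [-1, 1], shape (N, S, S, in_channels) with S
    divisible by 2**depth.  Output: per-pixel confidences in [0, 1].
    """

    def __init__(self, *, input_size: int = 256, depth: int = 4, base_channels: int = 16,
                 in_channels: int = 1, batch_norm: bool = True, seed: int = 0):
        super().__init__()
        if input_size % (2 ** depth) != 0:
            raise ValueError(f"input_size {input_size} not divisible by 2^{depth}")
        self.config = dict(input_size=input_size, depth=depth, base_channels=base_channels,
                           in_channels=in_channels, batch_norm=batch_norm, seed=seed)
        rng = np.random.default_rng(seed)
        cap = 8 * base_channels
        ch = [min(base_channels * 2 ** i, cap) for i in range(depth + 1)]
        self.depth = depth
        self.input_size = input_size
        self.enc = [self._reg(f"enc{i}", ConvBlock(in_channels if i == 0 else ch[i - 1],
                                                   ch[i], rng=rng, bn=batch_norm))
                    for i in range(depth)]
        self.pools = [self._reg(f"pool{i}", MaxPool2d(2)) for i in range(depth)]
        self.bott = self._reg("bott", ConvBlock(ch[depth - 1], ch[depth], rng=rng, bn=batch_norm))
        self.ups, self.dec = [], []
        prev = ch[depth]
        for i in reversed(range(depth)):
            self.ups.append(self._reg(f"up{i}", ConvTranspose2d(prev, ch[i], 2, rng=rng)))
            self.dec.append(self._reg(f"dec{i}", ConvBlock(2 * ch[i], ch[i], rng=rng, bn=batch_norm)))
            prev = ch[i]
        self.dropout = self._reg("drop", Dropout(0.5, np.random.default_rng(seed + 1)))
        self.head = self._reg("head", Conv2d(prev, 1, 1, rng=rng, bias_init=FINAL_BIAS))
        self.act = self._reg("act", Sigmoid())
        self._skip_ch = [c for c in ch[:depth]]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        skips = []
        h = x
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h)
        h = self.bott.forward(h, train)
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([skip, h], axis=3)
            h = blk.forward(h, train)
        h = self.dropout.forward(h, train)
        return self.act.forward(self.head.forward(h))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.head.backward(self.act.backward(gy))
        g = self.dropout.backward(g)
        # decoder runs shallow -> deep in backward
        skip_grads: list[np.ndarray] = [None] * self.depth  # type: ignore[list-item]
        for j in range(self.depth - 1, -1, -1):
            level = self.depth - 1 - j  # encoder level this decoder stage joined
            g = self.dec[j].backward(g)
            c = self._skip_ch[level]
            skip_grads[level] = g[..., :c]
            g = self.ups[j].backward(np.ascontiguousarray(g[..., c:]))
        g = self.bott.backward(g)
        for i in range(self.depth - 1, -1, -1):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc[i].backward(g)
        return g


class ContextEncoder(Network):
    """Embeds the six cropped context frames (stacked as channels).

    Input (N, S, S, 6); output (N, S/2**depth, S/2**depth, out_channels).
    """

    def __init__(self, *, input_size: int = 256, depth: int = 4, base_channels: int = 16,
                 out_channels: int = 32, in_channels: int = 6, batch_norm: bool = True,
                 seed: int = 0):
        super().__init__()
        if input_size % (2 ** depth) != 0:
            raise ValueError(f"input_size {input_size} not divisible by 2^{depth}")
        self.config = dict(input_size=input_size, depth=depth, base_channels=base_channels,
                           out_channels=out_channels, in_channels=in_channels,
                           batch_norm=batch_norm, seed=seed)
        rng = np.random.default_rng(seed)
        cap = 8 * base_channels
        ch = [min(base_channels * 2 ** i, cap) for i in range(depth)]
        ch[-1] = out_channels
        self.depth = depth
        self.out_channels = out_channels
        self.bottleneck_size = input_size // 2 ** depth
        self.blocks = [self._reg(f"blk{i}", ConvBlock(in_channels if i == 0 else ch[i - 1],
                                                      ch[i], rng=rng, bn=batch_norm))
                       for i in range(depth)]
        self.pools = [self._reg(f"pool{i}", MaxPool2d(2)) for i in range(depth)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for blk, pool in zip(self.blocks, self.pools):
            x = pool.forward(blk.forward(x, train))
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for blk, pool in zip(reversed(self.blocks), reversed(self.pools)):
            gy = blk.backward(pool.backward(gy))
        return gy


class CalibDecoder(Network):
    """Decodes (context embedding || tiled global vector) to calibration maps.

    ``out_channels=1`` is the calibration decoder D; ``out_channels=6`` is the
    reconstruction decoder used during context-autoencoder training.  With
    ``glob_dim=0`` the global branch is absent.
    """

    def __init__(self, *, ctx_channels: int = 32, glob_dim: int = 2048,
                 mix_channels: int = 32, depth: int = 4, out_channels: int = 1,
                 batch_norm: bool = True, head_bias: float = FINAL_BIAS, seed: int = 0):
        super().__init__()
        self.config = dict(ctx_channels=ctx_channels, glob_dim=glob_dim,
                           mix_channels=mix_channels, depth=depth,
                           out_channels=out_channels, batch_norm=batch_norm,
                           head_bias=head_bias, seed=seed)
        rng = np.random.default_rng(seed)
        self.glob_dim = glob_dim
        self.depth = depth
        self.mix = self._reg("mix", Conv2d(ctx_channels + glob_dim, mix_channels, 1, rng=rng))
        self.mix_act = self._reg("mix_act", ReLU())
        self.ups, self.blocks = [], []
        prev = mix_channels
        for i in range(depth):
            nxt = max(prev // 2, 8)
            self.ups.append(self._reg(f"up{i}", ConvTranspose2d(prev, nxt, 2, rng=rng)))
            self.blocks.append(self._reg(f"blk{i}", ConvBlock(nxt, nxt, rng=rng, bn=batch_norm)))
            prev = nxt
        self.head = self._reg("head", Conv2d(prev, out_channels, 1, rng=rng,
                                             bias_init=head_bias))
        self.act = self._reg("act", Sigmoid())

    def forward(self, ctx: np.ndarray, glob: np.ndarray | None = None,
                train: bool = False) -> np.ndarray:
        n, h, w, _ = ctx.shape
        if self.glob_dim:
            if glob is None or glob.shape != (n, self.glob_dim):
                raise ValueError(f"expected global vector of shape ({n}, {self.glob_dim})")
            tiled = np.broadcast_to(glob[:, None, None, :], (n, h, w, self.glob_dim))
            x = np.concatenate([ctx, tiled], axis=3)
        else:
            x = ctx
        self._ctx_ch = ctx.shape[-1]
        x = self.mix_act.forward(self.mix.forward(x), train)
        for up, blk in zip(self.ups, self.blocks):
            x = blk.forward(up.forward(x), train)
        return self.act.forward(self.head.forward(x))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        """Returns the gradient with respect to the context embedding."""
        g = self.head.backward(self.act.backward(gy))
        for up, blk in zip(reversed(self.ups), reversed(self.blocks)):
            g = up.backward(blk.backward(g))
        g = self.mix.backward(self.mix_act.backward(g))
        return np.ascontiguousarray(g[..., :self._ctx_ch])


class GlobalBackbone(Network):
    """Frozen image-embedding network: full frame -> 2048-vector.

    The default is a small randomly-initialized CNN whose parameters are
    frozen after construction; a pretrained VGG-16 can be plugged in through
    the same interface when weights are available on disk.  Input frames are
    resized to ``input_size`` (224 px) and a grayscale channel is replicated
    to three channels.
    """

    OUT_DIM = 2048

    def __init__(self, *, input_size: int = 224, seed: int = 0, frozen: bool = True):
        super().__init__()
        self.config = dict(input_size=input_size, seed=seed, frozen=frozen)
        if input_size % 32 != 0:
            raise ValueError("backbone input_size must be divisible by 32")
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        s = input_size // 32
        self.seq: list[Layer] = [
            self._reg("c0", Conv2d(3, 8, 3, rng=rng)), self._reg("r0", ReLU()),
            self._reg("p0", MaxPool2d(4)),
            self._reg("c1", Conv2d(8, 16, 3, rng=rng)), self._reg("r1", ReLU()),
            self._reg("p1", MaxPool2d(4)),
            self._reg("c2", Conv2d(16, 32, 3, rng=rng)), self._reg("r2", ReLU()),
            self._reg("p2", MaxPool2d(2)),
        ]
        self.fc = self._reg("fc", Linear(32 * s * s, self.OUT_DIM, rng=rng))
        if frozen:
            self.freeze()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for l in self.seq:
            x = l.forward(x, train)
        return self.fc.forward(x.reshape(x.shape[0], -1))


class ReferenceDetectorNet(Network):
    """Single-box regressor: image -> (tx, ty, tw, th, objectness) logits."""

    def __init__(self, *, input_size: int = 64, seed: int = 0):
        super().__init__()
        self.config = dict(input_size=input_size, seed=seed)
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.seq: list[Layer] = [
            self._reg("c0", Conv2d(1, 8, 3, rng=rng)), self._reg("r0", ReLU()),
            self._reg("p0", MaxPool2d(2)),
            self._reg("c1", Conv2d(8, 16, 3, rng=rng)), self._reg("r1", ReLU()),
            self._reg("p1", MaxPool2d(2)),
            self._reg("c2", Conv2d(16, 32, 3, rng=rng)), self._reg("r2", ReLU()),
            self._reg("p2", MaxPool2d(2)),
            self._reg("c3", Conv2d(32, 32, 3, rng=rng)), self._reg("r3", ReLU()),
            self._reg("gap", GlobalAvgPool()),
        ]
        self.fc1 = self._reg("fc1", Linear(32, 64, rng=rng))
        self.fc1_act = self._reg("fc1_act", ReLU())
        self.fc2 = self._reg("fc2", Linear(64, 5, rng=rng))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for l in self.seq:
            x = l.forward(x, train)
        return self.fc2.forward(self.fc1_act.forward(self.fc1.forward(x), train))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.fc1.backward(self.fc1_act.backward(self.fc2.backward(gy)))
        for l in reversed(self.seq):
            g = l.backward(g)
        return g
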