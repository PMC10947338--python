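"""A compact CPU implementation of the 3D dense dilated U-Net.

Layers are plain numpy with hand-written backpropagation: 'same'-padded 3D
convolutions via im2col, dense blocks (each layer sees the concatenation of
the block input and all previous features), 2x average-pool / nearest-
neighbour upsample for the encoder-decoder levels, dilated convolutions in
the bottleneck, and a softplus output head so predicted dose is non-negative
by construction.  Optimization is Adam.

The engine operates on single samples shaped ``(C, Z, Y, X)`` in float32;
patch batching is done by gradient accumulation in the training loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NetworkConfig", "DenseDilatedUNet", "Adam"]

F32 = np.float32


def im2col(x: np.ndarray, k: int, dilation: int = 1) -> np.ndarray:
    """Unfold a (C, Z, Y, X) volume into (C*k^3, Z*Y*X) columns ('same' pad).

    Column index is offset-major within each channel: ((c*k + a)*k + b)*k + d
    for kernel offset (a, b, d), matching the weight layout of :class:`Conv3d`.
    """
    c, z, y, w = x.shape
    p = dilation * (k // 2)
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    col = np.empty((c, k, k, k, z * y * w), dtype=F32)
    for a in range(k):
        za = a * dilation
        for b in range(k):
            yb = b * dilation
            for d in range(k):
                xd = d * dilation
                col[:, a, b, d] = xp[:, za : za + z, yb : yb + y, xd : xd + w].reshape(c, -1)
    return col.reshape(c * k**3, z * y * w)


def col2im(gcol: np.ndarray, shape: tuple[int, int, int, int], k: int, dilation: int = 1) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add column gradients back."""
    c, z, y, w = shape
    p = dilation * (k // 2)
    g = gcol.reshape(c, k, k, k, z, y, w)
    gx = np.zeros((c, z + 2 * p, y + 2 * p, w + 2 * p), dtype=F32)
    for a in range(k):
        for b in range(k):
            for d in range(k):
                gx[:, a * dilation : a * dilation + z,
                   b * dilation : b * dilation + y,
                   d * dilation : d * dilation + w] += g[:, a, b, d]
    return gx[:, p : p + z, p : p + y, p : p + w]


class Conv3d:
    """'Same'-padded 3D convolution with optional dilation (He init)."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.dilation = c_in, c_out, k, dilation
        scale = np.sqrt(2.0 / (c_in * k**3))
        self.W = rng.normal(0.0, scale, (c_in * k**3, c_out)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._col: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, store: bool = True) -> np.ndarray:
        c, z, y, w = x.shape
        col = im2col(x, self.k, self.dilation)
        out = self.W.T @ col + self.b[:, None]
        if store:
            self._col, self._shape = col, x.shape
        return out.reshape(self.c_out, z, y, w)

    def backward(self, g: np.ndarray) -> np.ndarray:
        gmat = g.reshape(self.c_out, -1).astype(F32)
        self.gW += self._col @ gmat.T
        self.gb += gmat.sum(axis=1)
        gcol = self.W @ gmat
        gx = col2im(gcol, self._shape, self.k, self.dilation)
        self._col = None
        return gx

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class ReLU:
    def forward(self, x: np.ndarray, store: bool = True) -> np.ndarray:
        out = np.maximum(x, 0)
        if store:
            self._mask = x > 0
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class Softplus:
    """Numerically stable softplus; keeps the output strictly non-negative."""

    def forward(self, x: np.ndarray, store: bool = True) -> np.ndarray:
        out = np.where(x > 20, x, np.log1p(np.exp(np.minimum(x, 20)))).astype(F32)
        if store:
            self._x = x
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        sig = 1.0 / (1.0 + np.exp(-np.clip(self._x, -60, 60)))
        return (g * sig).astype(F32)


class AvgPool2:
    """2x average pooling along each spatial axis (dims must be even)."""

    def forward(self, x: np.ndarray, store: bool = True) -> np.ndarray:
        c, z, y, w = x.shape
        if z % 2 or y % 2 or w % 2:
            raise ValueError(f"spatial dims must be even to pool, got {x.shape}")
        v = x.reshape(c, z // 2, 2, y // 2, 2, w // 2, 2)
        if store:
            self._shape = x.shape
        return v.mean(axis=(2, 4, 6))

    def backward(self, g: np.ndarray) -> np.ndarray:
        c, z, y, w = self._shape
        g8 = (g / 8.0).astype(F32)
        out = np.broadcast_to(
            g8[:, :, None, :, None, :, None], (c, z // 2, 2, y // 2, 2, w // 2, 2)
        )
        return out.reshape(c, z, y, w).copy()


class UpNearest2:
    """2x nearest-neighbour upsampling along each spatial axis."""

    def forward(self, x: np.ndarray, store: bool = True) -> np.ndarray:
        if store:
            self._shape = x.shape
        return np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        c, z, y, w = self._shape
        v = g.reshape(c, z, 2, y, 2, w, 2)
        return v.sum(axis=(2, 4, 6)).astype(F32)


class DenseBlock:
    """Dense block: layer ``i`` convolves concat(input, f_1..f_{i-1}).

    The block output is the concatenation of its input and every layer's
    features, so output channels = ``c_in + n_layers * growth``.
    """

    def __init__(self, c_in: int, n_layers: int, growth: int,
                 dilations: tuple[int, ...] | None = None,
                 rng: np.random.Generator | None = None):
        dil = dilations or (1,) * n_layers
        if len(dil) != n_layers:
            dil = tuple(dil[i % len(dil)] for i in range(n_layers))
        self.convs = [
            Conv3d(c_in + i * growth, growth, k=3, dilation=dil[i], rng=rng)
            for i in range(n_layers)
        ]
        self.relus = [ReLU() for _ in range(n_layers)]
        self.c_in = c_in
        self.c_out = c_in + n_layers * growth
        self.growth = growth

    def forward(self, x: np.ndarray, store: bool = True) -> np.ndarray:
        feats = [x]
        for conv, relu in zip(self.convs, self.relus):
            inp = np.concatenate(feats, axis=0)
            feats.append(relu.forward(conv.forward(inp, store=store), store=store))
        return np.concatenate(feats, axis=0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        sizes = [self.c_in] + [self.growth] * len(self.convs)
        bounds = np.cumsum(sizes)
        grads = list(np.split(g, bounds[:-1], axis=0))
        for i in reversed(range(len(self.convs))):
            gf = grads[i + 1]
            gin = self.convs[i].backward(self.relus[i].backward(gf))
            in_bounds = np.cumsum(sizes[: i + 1])
            for j, piece in enumerate(np.split(gin, in_bounds[:-1], axis=0)):
                grads[j] = grads[j] + piece
        return grads[0]

    def layers(self):
        return self.convs


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of the dense dilated U-Net.

    ``levels`` encoder/decoder resolution levels (0 = single resolution),
    ``block_layers`` convolutions per dense block, ``growth`` feature maps
    added per dense layer, ``dilations`` the bottleneck dilation rates.
    The output head is a 1x1x1 convolution followed by softplus (one channel,
    dose in Gy, non-negative by construction).
    """

    in_channels: int = 16
    levels: int = 3
    block_layers: int = 4
    growth: int = 16
    dilations: tuple[int, ...] = (1, 2, 4)

    def __post_init__(self) -> None:
        if self.levels < 0 or self.block_layers < 1 or self.growth < 1:
            raise ValueError("invalid network configuration")
        if any(d < 1 for d in self.dilations):
            raise ValueError("dilation rates must be >= 1")


class DenseDilatedUNet:
    """Encoder-decoder with dense blocks per level and a dilated bottleneck."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.in_channels
        self.enc: list[DenseBlock] = []
        self.pools = [AvgPool2() for _ in range(config.levels)]
        skip_channels = []
        for _ in range(config.levels):
            blk = DenseBlock(c, config.block_layers, config.growth, rng=rng)
            self.enc.append(blk)
            skip_channels.append(blk.c_out)
            c = blk.c_out
        self.bottleneck = DenseBlock(
            c, len(config.dilations), config.growth, dilations=config.dilations, rng=rng
        )
        c = self.bottleneck.c_out
        self.ups = [UpNearest2() for _ in range(config.levels)]
        self.dec: list[DenseBlock] = []
        for lvl in reversed(range(config.levels)):
            blk = DenseBlock(c + skip_channels[lvl], config.block_layers, config.growth, rng=rng)
            self.dec.append(blk)
            c = blk.c_out
        self.head = Conv3d(c, 1, k=1, rng=rng)
        self.out_act = Softplus()
        self._skip_channels = skip_channels
        self.receptive_field = self._receptive_field()

    def _receptive_field(self) -> int:
        """Receptive field (voxels at input resolution) of the full network."""
        rf, scale = 1, 1
        for _ in range(self.config.levels):
            rf += 2 * self.config.block_layers * scale
            scale *= 2  # pooling
            rf += scale - 1
        for d in self.config.dilations:
            rf += 2 * d * scale
        for _ in range(self.config.levels):
            scale //= 2
            rf += 2 * self.config.block_layers * scale
        return rf

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray, store: bool = True) -> np.ndarray:
        """Predict a (1, Z, Y, X) dose volume from a (C, Z, Y, X) input stack."""
        if x.shape[0] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, got {x.shape[0]}"
            )
        mult = 2**self.config.levels
        if any(s % mult for s in x.shape[1:]):
            raise ValueError(f"spatial dims must be divisible by {mult}, got {x.shape[1:]}")
        cur = np.asarray(x, dtype=F32)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            cur = blk.forward(cur, store=store)
            skips.append(cur)
            cur = pool.forward(cur, store=store)
        cur = self.bottleneck.forward(cur, store=store)
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            cur = up.forward(cur, store=store)
            cur = np.concatenate([skip, cur], axis=0)
            cur = blk.forward(cur, store=store)
        if store:
            self._dec_in_channels = [s.shape[0] for s in skips]
        return self.out_act.forward(self.head.forward(cur, store=store), store=store)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference without gradient caches; returns a (Z, Y, X) dose array."""
        return self.forward(x, store=False)[0]

    __call__ = predict

    def backward(self, g: np.ndarray) -> None:
        cur = self.head.backward(self.out_act.backward(g))
        skip_grads: list[np.ndarray | None] = [None] * self.config.levels
        for i, (up, blk) in enumerate(zip(self.ups, self.dec)):
            lvl = self.config.levels - 1 - i
            cur = blk.backward(cur)
            n_skip = self._dec_in_channels[lvl]
            skip_grads[lvl] = cur[:n_skip]
            cur = up.backward(cur[n_skip:])
        cur = self.bottleneck.backward(cur)
        for lvl in reversed(range(self.config.levels)):
            cur = self.pools[lvl].backward(cur)
            cur = cur + skip_grads[lvl]
            cur = self.enc[lvl].backward(cur)

    # ------------------------------------------------------------------
    def _convs(self) -> list[Conv3d]:
        convs: list[Conv3d] = []
        for blk in self.enc:
            convs.extend(blk.layers())
        convs.extend(self.bottleneck.layers())
        for blk in self.dec:
            convs.extend(blk.layers())
        convs.append(self.head)
        return convs

    def params(self):
        out = []
        for conv in self._convs():
            out.extend(conv.params())
        return out

    def zero_grad(self) -> None:
        for conv in self._convs():
            conv.gW[:] = 0
            conv.gb[:] = 0

    @property
    def n_params(self) -> int:
        return sum(c.n_params for c in self._convs())

    def get_weights(self) -> list[np.ndarray]:
        return [c.W.copy() for c in self._convs()] + [c.b.copy() for c in self._convs()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        convs = self._convs()
        n = len(convs)
        for c, w in zip(convs, weights[:n]):
            c.W[:] = w
        for c, b in zip(convs, weights[n:]):
            c.b[:] = b


class Adam:
    """Adam optimizer over a network's (param, grad) pairs."""

    def __init__(self, net: DenseDilatedUNet, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.net = net
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in net.params()]
        self.v = [np.zeros_like(p) for p, _ in net.params()]

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (p, g), m, v in zip(self.net.params(), self.m, self.v):
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p -= lr * mh / (np.sqrt(vh) + self.eps)
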