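"""A compact encoder–decoder segmentation network in pure numpy.

Layers implement explicit forward/backward passes (im2col convolutions,
2×2 max-pooling, nearest-neighbour upsampling, channel concatenation,
spatial dropout, logistic output). Arrays are NHWC float32. The network is
small by design: it targets desk-scale experiments on 32–128 px images,
where a handful of convolution stages is enough to segment a darker lesion
against a skin-toned background.

Weight initialisation is He-normal from a seeded generator, so two networks
built from the same spec are bitwise identical.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CompactSegNet"]


class Conv2d:
    """Same-padded k×k convolution with optional dilation, stride 1."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, dilation: int = 1):
        self.cin, self.cout, self.k, self.dilation = cin, cout, k, dilation
        fan_in = k * k * cin
        std = np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, std, size=(fan_in, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _offsets(self):
        k, d = self.k, self.dilation
        return [(i, j) for i in range(k) for j in range(k)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        k, d = self.k, self.dilation
        pad = d * (k // 2)
        if pad:
            xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        else:
            xp = x
        cols = np.empty((n, h, w, k * k, c), dtype=np.float32)
        for idx, (i, j) in enumerate(self._offsets()):
            cols[:, :, :, idx, :] = xp[:, i * d : i * d + h, j * d : j * d + w, :]
        cols = cols.reshape(n, h, w, k * k * c)
        self._cols = cols
        self._in_shape = x.shape
        return cols @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        k, d = self.k, self.dilation
        pad = d * (k // 2)
        cols2d = self._cols.reshape(-1, self.W.shape[0])
        dy2d = dy.reshape(-1, self.cout)
        self.dW += cols2d.T @ dy2d
        self.db += dy2d.sum(axis=0)
        dcols = (dy2d @ self.W.T).reshape(n, h, w, k * k, c)
        dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=np.float32)
        for idx, (i, j) in enumerate(self._offsets()):
            dxp[:, i * d : i * d + h, j * d : j * d + w, :] += dcols[:, :, :, idx, :]
        self._cols = None
        if pad:
            return dxp[:, pad : pad + h, pad : pad + w, :]
        return dxp


class InstanceNorm:
    """Per-sample, per-channel normalization with learned gain and bias.

    Behaves identically in train and eval mode (no running statistics), so
    it keeps evaluation deterministic while making small from-scratch
    networks far less sensitive to weight initialisation.
    """

    EPS = 1e-5

    def __init__(self, channels: int):
        self.g = np.ones(channels, dtype=np.float32)
        self.b = np.zeros(channels, dtype=np.float32)
        self.dg = np.zeros_like(self.g)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.g, self.dg), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.EPS)
        self._xhat = (x - mu) * self._inv
        return self.g * self._xhat + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n = dy.shape[1] * dy.shape[2]
        self.dg += (dy * self._xhat).sum(axis=(0, 1, 2))
        self.db += dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.g
        mean_d = dxhat.mean(axis=(1, 2), keepdims=True)
        mean_dx = (dxhat * self._xhat).mean(axis=(1, 2), keepdims=True)
        return (dxhat - mean_d - self._xhat * mean_dx) * self._inv


class ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """2×2 max pooling; backward routes gradient to the argmax position."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        flat = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        dflat = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(dflat, self._argmax[..., None], dy[..., None], axis=-1)
        dxr = dflat.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dxr.reshape(n, h, w, c)


class Upsample2:
    """Nearest-neighbour 2× upsampling."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class SpatialDropout:
    """Drops whole channels in training mode, scaled by 1/(1-p)."""

    def __init__(self, p: float):
        self.p = p
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        mask = (rng.random((x.shape[0], 1, 1, x.shape[3])) < keep) / keep
        self._mask = mask.astype(np.float32)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class CompactSegNet:
    """Encoder–decoder with optional multi-rate dilated context block.

    Channel widths double per stage, capped at 8× the base width. Skip
    connections concatenate encoder features into the decoder. A single
    spatial-dropout layer before the 1×1 classifier provides the model
    noise used during student training.
    """

    def __init__(
        self,
        depth: int,
        base_channels: int,
        use_aspp: bool,
        skip_connections: bool,
        dropout_p: float,
        seed: int,
    ):
        self.depth = depth
        self.base_channels = base_channels
        self.use_aspp = use_aspp
        self.skip_connections = skip_connections
        self.dropout_p = dropout_p
        self.seed = seed

        rng = np.random.default_rng(seed)
        ch = [min(base_channels * 2**s, base_channels * 8) for s in range(depth)]
        self.channels = ch

        self.enc_convs: list[Conv2d] = []
        self.enc_norms: list[InstanceNorm] = []
        self.enc_relus: list[ReLU] = []
        self.pools: list[MaxPool2] = []
        cin = 3
        for s in range(depth):
            self.enc_convs.append(Conv2d(cin, ch[s], 3, rng))
            self.enc_norms.append(InstanceNorm(ch[s]))
            self.enc_relus.append(ReLU())
            self.pools.append(MaxPool2())
            cin = ch[s]

        cb = ch[-1]
        if use_aspp:
            # parallel dilated branches (rates 1, 2, 4) summed, DeepLab-style
            self.aspp = [Conv2d(cin, cb, 3, rng, dilation=r) for r in (1, 2, 4)]
            self.bottleneck = None
        else:
            self.aspp = None
            self.bottleneck = Conv2d(cin, cb, 3, rng)
        self.bott_norm = InstanceNorm(cb)
        self.bott_relu = ReLU()

        self.ups: list[Upsample2] = []
        self.dec_convs: list[Conv2d] = []
        self.dec_norms: list[InstanceNorm] = []
        self.dec_relus: list[ReLU] = []
        cin = cb
        for s in reversed(range(depth)):
            self.ups.append(Upsample2())
            dec_in = cin + (ch[s] if skip_connections else 0)
            self.dec_convs.append(Conv2d(dec_in, ch[s], 3, rng))
            self.dec_norms.append(InstanceNorm(ch[s]))
            self.dec_relus.append(ReLU())
            cin = ch[s]

        self.dropout = SpatialDropout(dropout_p)
        self.head = Conv2d(cin, 1, 1, rng)

    # -- parameter access ---------------------------------------------------

    def _conv_layers(self) -> list:
        layers: list = []
        for conv, norm in zip(self.enc_convs, self.enc_norms):
            layers += [conv, norm]
        layers += self.aspp if self.aspp is not None else [self.bottleneck]
        layers.append(self.bott_norm)
        for conv, norm in zip(self.dec_convs, self.dec_norms):
            layers += [conv, norm]
        layers.append(self.head)
        return layers

    def params(self):
        out = []
        for layer in self._conv_layers():
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(int(w.size) for w, _ in self.params())

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for w, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(weights) != len(own):
            raise ValueError("weight list length mismatch")
        for (w, _), new in zip(own, weights):
            if w.shape != new.shape:
                raise ValueError(f"weight shape mismatch {w.shape} vs {new.shape}")
            w[...] = new.astype(np.float32)

    # -- forward / backward -------------------------------------------------

    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Map an NHWC image batch to per-pixel foreground probabilities."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[3] != 3:
            raise ValueError(f"expected NHWC RGB batch, got shape {x.shape}")
        if x.shape[1] % 2**self.depth or x.shape[2] % 2**self.depth:
            raise ValueError(
                f"spatial size {x.shape[1]}x{x.shape[2]} not divisible by 2^{self.depth}"
            )
        skips = []
        for conv, norm, relu, pool in zip(
            self.enc_convs, self.enc_norms, self.enc_relus, self.pools
        ):
            x = relu.forward(norm.forward(conv.forward(x, train), train), train)
            skips.append(x)
            x = pool.forward(x, train)
        if self.aspp is not None:
            x = sum(branch.forward(x, train) for branch in self.aspp)
        else:
            x = self.bottleneck.forward(x, train)
        x = self.bott_relu.forward(self.bott_norm.forward(x, train), train)
        self._skip_channels = []
        for up, conv, norm, relu, skip in zip(
            self.ups, self.dec_convs, self.dec_norms, self.dec_relus, reversed(skips)
        ):
            x = up.forward(x, train)
            if self.skip_connections:
                self._skip_channels.append(x.shape[3])
                x = np.concatenate([x, skip], axis=3)
            x = relu.forward(norm.forward(conv.forward(x, train), train), train)
        x = self.dropout.forward(x, train, rng)
        z = self.head.forward(x, train)[..., 0]
        self._prob = 1.0 / (1.0 + np.exp(-z))
        return self._prob

    def backward(self, dprob: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dProbability."""
        p = self._prob
        dz = (dprob * p * (1.0 - p)).astype(np.float32)[..., None]
        dx = self.head.backward(dz)
        dx = self.dropout.backward(dx)
        dskips = [None] * self.depth
        for i, (up, conv, norm, relu) in enumerate(
            zip(
                reversed(self.ups),
                reversed(self.dec_convs),
                reversed(self.dec_norms),
                reversed(self.dec_relus),
            )
        ):
            dx = conv.backward(norm.backward(relu.backward(dx)))
            if self.skip_connections:
                ncore = self._skip_channels[len(self.ups) - 1 - i]
                stage = self.depth - 1 - (len(self.ups) - 1 - i)
                dskips[stage] = dx[..., ncore:]
                dx = dx[..., :ncore]
            dx = up.backward(dx)
        dx = self.bott_norm.backward(self.bott_relu.backward(dx))
        if self.aspp is not None:
            dx = sum(branch.backward(dx) for branch in self.aspp)
        else:
            dx = self.bottleneck.backward(dx)
        for s in reversed(range(self.depth)):
            dx = self.pools[s].backward(dx)
            if dskips[s] is not None:
                dx = dx + dskips[s]
            dx = self.enc_convs[s].backward(
                self.enc_norms[s].backward(self.enc_relus[s].backward(dx))
            )

    # -- inference helpers --------------------------------------------------

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode probabilities for an NHWC batch (deterministic)."""
        return self.forward(x, train=False)
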