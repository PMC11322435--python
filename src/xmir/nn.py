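"""Minimal numpy convolutional network with manual backpropagation.

Implements exactly what the contrastive representation stage needs: 3x3/1x1
convolutions (channels-last im2col feeding a single GEMM per layer), ReLU,
2x2 average pooling, nearest-neighbour upsampling, a small U-Net with skip
connections and a bounded (tanh) output head, and Adam.  Everything is
float32 and fully deterministic given a seed.

The public tensor layout is (B, C, H, W); internally activations are kept
channels-last (B, H, W, C) so the im2col buffers reshape into contiguous
matrix products.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "UNetSmall", "Adam"]


class Conv2d:
    """Same-padded k x k convolution (k = 1 or 3) on (B, H, W, C) tensors."""

    def __init__(self, c_in: int, c_out: int, k: int, rng) -> None:
        if k not in (1, 3):
            raise ValueError("kernel size must be 1 or 3")
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        scale = np.sqrt(2.0 / (c_in * k * k))  # He initialization
        self.W = (rng.standard_normal((k * k * c_in, c_out)) * scale).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._col = None
        self._shape = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        col = np.empty((b, h, w, 9, c), dtype=np.float32)
        for t in range(9):
            dy, dx = divmod(t, 3)
            col[:, :, :, t, :] = xp[:, dy : dy + h, dx : dx + w, :]
        return col

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, c = x.shape
        self._shape = (b, h, w, c)
        if self.k == 1:
            col = x
        else:
            col = self._im2col(x)
        flat = col.reshape(b * h * w, -1)
        self._col = flat if train else None
        out = flat @ self.W + self.b
        return out.reshape(b, h, w, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._col is None:
            raise RuntimeError("forward(train=True) must precede backward()")
        b, h, w, c = self._shape
        dflat = dout.reshape(b * h * w, self.c_out)
        self.dW[:] = self._col.T @ dflat
        self.db[:] = dflat.sum(axis=0)
        dcol = dflat @ self.W.T
        self._col = None
        if self.k == 1:
            return dcol.reshape(b, h, w, c)
        dcol = dcol.reshape(b, h, w, 9, c)
        dxp = np.zeros((b, h + 2, w + 2, c), dtype=np.float32)
        for t in range(9):
            dy, dx = divmod(t, 3)
            dxp[:, dy : dy + h, dx : dx + w, :] += dcol[:, :, :, t, :]
        return dxp[:, 1:-1, 1:-1, :]


class InstanceNorm:
    """Per-sample, per-channel spatial standardization (no affine terms).

    Makes the downstream contrastive loss invariant to representation
    scale, which removes the constant-output collapse mode of MSE-critic
    InfoNCE training.
    """

    EPS = 1e-5

    def __init__(self) -> None:
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        s = np.sqrt(var + self.EPS)
        y = (x - mu) / s
        self._cache = (y, s) if train else None
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("forward(train=True) must precede backward()")
        y, s = self._cache
        self._cache = None
        m1 = dout.mean(axis=(1, 2), keepdims=True)
        m2 = (dout * y).mean(axis=(1, 2), keepdims=True)
        return (dout - m1 - y * m2) / s


def _avgpool2(x):
    b, h, w, c = x.shape
    return x.reshape(b, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))


def _avgpool2_backward(dout):
    return np.repeat(np.repeat(dout, 2, axis=1), 2, axis=2) * np.float32(0.25)


def _upsample2(x):
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _upsample2_backward(dout):
    b, h, w, c = dout.shape
    return dout.reshape(b, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class UNetSmall:
    """Three-level U-Net-style encoder-decoder producing a 1-channel map.

    One 3x3 conv + instance norm + ReLU per level on the way down and up,
    nearest-neighbour upsampling, channel-concatenated skip connections,
    and a 1x1 + tanh output head, so representation values are bounded in
    (-1, 1) for any weights.  Input spatial dims must be multiples of 4
    (``apply`` pads and crops arbitrary sizes).
    """

    def __init__(self, c_in: int = 1, base_channels: int = 8, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        c = base_channels
        self.c_in = c_in
        self.base_channels = c
        self.enc1 = Conv2d(c_in, c, 3, rng)
        self.enc2 = Conv2d(c, 2 * c, 3, rng)
        self.bott = Conv2d(2 * c, 4 * c, 3, rng)
        self.dec2 = Conv2d(6 * c, 2 * c, 3, rng)
        self.dec1 = Conv2d(3 * c, c, 3, rng)
        self.head = Conv2d(c, 1, 1, rng)
        self.layers = [self.enc1, self.enc2, self.bott, self.dec2, self.dec1, self.head]
        self.norms = [InstanceNorm() for _ in range(5)]
        self._cache = None

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x is (B, C, H, W); returns (B, 1, H, W)."""
        x = np.ascontiguousarray(
            np.transpose(np.asarray(x, dtype=np.float32), (0, 2, 3, 1))
        )
        n1, n2, n3, n4, n5 = self.norms
        e1 = np.maximum(n1.forward(self.enc1.forward(x, train), train), 0.0)
        p1 = _avgpool2(e1)
        e2 = np.maximum(n2.forward(self.enc2.forward(p1, train), train), 0.0)
        p2 = _avgpool2(e2)
        bo = np.maximum(n3.forward(self.bott.forward(p2, train), train), 0.0)
        u2 = _upsample2(bo)
        d2 = np.maximum(
            n4.forward(self.dec2.forward(np.concatenate([u2, e2], axis=3), train), train),
            0.0,
        )
        u1 = _upsample2(d2)
        d1 = np.maximum(
            n5.forward(self.dec1.forward(np.concatenate([u1, e1], axis=3), train), train),
            0.0,
        )
        out = np.tanh(self.head.forward(d1, train))
        self._cache = (e1, e2, bo, d2, d1, out) if train else None
        return np.transpose(out, (0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> None:
        """dout is (B, 1, H, W), the gradient w.r.t. forward()'s output."""
        if self._cache is None:
            raise RuntimeError("forward(train=True) must precede backward()")
        e1, e2, bo, d2, d1, out = self._cache
        c = self.base_channels
        n1, n2, n3, n4, n5 = self.norms
        g = np.ascontiguousarray(
            np.transpose(np.asarray(dout, dtype=np.float32), (0, 2, 3, 1))
        )
        g = g * (1.0 - out * out)  # tanh
        g = self.head.backward(g)
        g = g * (d1 > 0)
        g = self.dec1.backward(n5.backward(g))
        gu1, ge1_skip = g[..., : 2 * c], g[..., 2 * c :]
        g = _upsample2_backward(gu1)
        g = g * (d2 > 0)
        g = self.dec2.backward(n4.backward(g))
        gu2, ge2_skip = g[..., : 4 * c], g[..., 4 * c :]
        g = _upsample2_backward(gu2)
        g = g * (bo > 0)
        g = self.bott.backward(n3.backward(g))
        g = _avgpool2_backward(g)
        g = (g + ge2_skip) * (e2 > 0)
        g = self.enc2.backward(n2.backward(g))
        g = _avgpool2_backward(g)
        g = (g + ge1_skip) * (e1 > 0)
        self.enc1.backward(n1.backward(g))
        self._cache = None

    def apply(self, image: np.ndarray) -> np.ndarray:
        """Run on a single 2-D image of arbitrary size (pad to /4, crop back)."""
        h, w = image.shape
        ph = (-h) % 4
        pw = (-w) % 4
        x = np.pad(image, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else image
        out = self.forward(x[None, None], train=False)[0, 0]
        return out[:h, :w]

    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers):
            state[f"W{i}"] = layer.W
            state[f"b{i}"] = layer.b
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            layer.W = np.asarray(state[f"W{i}"], dtype=np.float32)
            layer.b = np.asarray(state[f"b{i}"], dtype=np.float32)
            layer.dW = np.zeros_like(layer.W)
            layer.db = np.zeros_like(layer.b)


class Adam:
    """Adaptive-moment optimizer over a list of (param, grad) pairs."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
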