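"""A compact NumPy convolutional encoder-decoder with hand-written backprop.

The denoiser used inside the unrolled reconstruction is a small U-Net-style
network: three average-pooling stages, a base width of 32 features doubling
per stage, 3x3 convolutions with leaky-ReLU activations, transposed-
convolution upsampling, skip connections, no dropout and no normalisation
layers, plus a global residual connection.  It operates on 2D slices whose
channels are the real and imaginary parts of the spectral components
(2r channels for r complex components).

Everything is implemented directly in NumPy (forward, backward, Adam), so
inference and training are fully deterministic given a seed.
"""

from __future__ import annotations

import json

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNet2d", "Adam", "l1_loss", "save_weights", "load_weights"]


class Conv2d:
    """3x3 (or 1x1) same-padding convolution on (C, H, W) arrays."""

    def __init__(self, cin, cout, kernel=3, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * kernel * kernel))
        self.w = rng.normal(scale=scale, size=(cout, cin, kernel, kernel))
        self.b = np.zeros(cout)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.kernel = kernel
        self._cache = None

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x):
        c, h, w = x.shape
        k = self.kernel
        p = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        cols = sliding_window_view(xp, (k, k), axis=(1, 2))  # (C, H, W, k, k)
        cols = cols.transpose(1, 2, 0, 3, 4).reshape(h * w, c * k * k)
        wmat = self.w.reshape(self.w.shape[0], -1)
        y = cols @ wmat.T + self.b
        self._cache = (cols, x.shape)
        return y.T.reshape(-1, h, w)

    def backward(self, gy):
        cols, (c, h, w) = self._cache
        k = self.kernel
        p = (k - 1) // 2
        o = gy.shape[0]
        gy2 = gy.reshape(o, h * w).T  # (HW, O)
        wmat = self.w.reshape(o, -1)
        self.gw += (gy2.T @ cols).reshape(self.w.shape)
        self.gb += gy2.sum(axis=0)
        gcols = (gy2 @ wmat).reshape(h, w, c, k, k)
        gxp = np.zeros((c, h + 2 * p, w + 2 * p))
        for dy in range(k):
            for dx in range(k):
                gxp[:, dy : dy + h, dx : dx + w] += gcols[:, :, :, dy, dx].transpose(
                    2, 0, 1
                )
        return gxp[:, p : p + h, p : p + w] if p else gxp


class ConvTranspose2d:
    """2x2 stride-2 transposed convolution (learned upsampling)."""

    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * 4))
        self.w = rng.normal(scale=scale, size=(cin, cout, 2, 2))
        self.b = np.zeros(cout)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x):
        cin, h, w = x.shape
        cout = self.w.shape[1]
        y = np.zeros((cout, 2 * h, 2 * w))
        for dy in range(2):
            for dx in range(2):
                y[:, dy::2, dx::2] = np.tensordot(self.w[:, :, dy, dx], x, axes=(0, 0))
        y += self.b[:, None, None]
        self._cache = x
        return y

    def backward(self, gy):
        x = self._cache
        gx = np.zeros_like(x)
        for dy in range(2):
            for dx in range(2):
                g = gy[:, dy::2, dx::2]  # (cout, h, w)
                self.gw[:, :, dy, dx] += np.tensordot(x, g, axes=((1, 2), (1, 2)))
                gx += np.tensordot(self.w[:, :, dy, dx], g, axes=(1, 0))
        self.gb += gy.sum(axis=(1, 2))
        return gx


class LeakyReLU:
    def __init__(self, alpha=0.01):
        self.alpha = alpha
        self._mask = None

    def params(self):
        return []

    def forward(self, x):
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, gy):
        return np.where(self._mask, gy, self.alpha * gy)


class AvgPool2d:
    def params(self):
        return []

    def forward(self, x):
        c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))

    def backward(self, gy):
        c, h, w = self._shape
        g = np.repeat(np.repeat(gy, 2, axis=1), 2, axis=2) / 4.0
        return g


class _Block:
    """conv-relu-conv-relu."""

    def __init__(self, cin, cout, rng):
        self.c1 = Conv2d(cin, cout, rng=rng)
        self.r1 = LeakyReLU()
        self.c2 = Conv2d(cout, cout, rng=rng)
        self.r2 = LeakyReLU()

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, g):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(g))))


class UNet2d:
    """Encoder-decoder on (C, H, W) slices with a global residual connection.

    Parameters
    ----------
    in_channels:
        Input (= output) channel count, ``2r`` for r complex components.
    base_features:
        Width of the first stage; doubles at each of the ``n_pools`` stages.
    n_pools:
        Number of average-pooling downsamplings (default 3).
    """

    def __init__(self, in_channels, base_features=32, n_pools=3, seed=0):
        self.arch = dict(
            in_channels=int(in_channels),
            base_features=int(base_features),
            n_pools=int(n_pools),
        )
        rng = np.random.default_rng(seed)
        widths = [base_features * 2**i for i in range(n_pools + 1)]
        self.enc = []
        cin = in_channels
        for wdt in widths[:-1]:
            self.enc.append(_Block(cin, wdt, rng))
            cin = wdt
        self.pools = [AvgPool2d() for _ in range(n_pools)]
        self.bottleneck = _Block(widths[-2], widths[-1], rng)
        self.ups = []
        self.dec = []
        for i in range(n_pools - 1, -1, -1):
            self.ups.append(ConvTranspose2d(widths[i + 1], widths[i], rng=rng))
            self.dec.append(_Block(2 * widths[i], widths[i], rng))
        self.out_conv = Conv2d(widths[0], in_channels, kernel=1, rng=rng)

    # -- parameter plumbing ----------------------------------------------

    def _modules(self):
        mods = list(self.enc) + [self.bottleneck] + list(self.ups) + list(self.dec)
        mods.append(self.out_conv)
        return mods

    def params(self):
        out = []
        for m in self._modules():
            out.extend(m.params())
        return out

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0

    def n_parameters(self):
        return sum(v.size for v, _ in self.params())

    # -- forward / backward ----------------------------------------------

    def _pad(self, x):
        mult = 2 ** self.arch["n_pools"]
        c, h, w = x.shape
        ph = (-h) % mult
        pw = (-w) % mult
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw)), mode="edge")
        return x, (h, w)

    def forward(self, x):
        if x.shape[0] != self.arch["in_channels"]:
            raise ValueError("channel count mismatch")
        xp, (h, w) = self._pad(np.asarray(x, float))
        self._hw = (h, w)
        self._x_in = xp
        skips = []
        t = xp
        for blk, pool in zip(self.enc, self.pools):
            t = blk.forward(t)
            skips.append(t)
            t = pool.forward(t)
        t = self.bottleneck.forward(t)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            t = up.forward(t)
            t = dec.forward(np.concatenate([t, skip], axis=0))
        t = self.out_conv.forward(t)
        y = xp + t  # global residual
        return y[:, :h, :w]

    def backward(self, gy):
        h, w = self._hw
        xp = self._x_in
        g = np.zeros_like(xp)
        g[:, :h, :w] = gy
        g_res = g  # gradient through the residual path
        t = self.out_conv.backward(g)
        g_skips = []
        for dec, up in zip(reversed(self.dec), reversed(self.ups)):
            g = dec.backward(t)
            n_up = up.w.shape[1]
            g_up, g_skip = g[:n_up], g[n_up:]
            g_skips.append(g_skip)
            t = up.backward(g_up)
        t = self.bottleneck.backward(t)
        g_skips = list(reversed(g_skips))  # now ordered deepest stage first
        for blk, pool, gs in zip(reversed(self.enc), reversed(self.pools), g_skips):
            t = pool.backward(t)
            t = blk.backward(t + gs)
        return (t + g_res)[:, :h, :w]

    # -- complex packing ---------------------------------------------------

    @staticmethod
    def pack(x_complex):
        """(r, H, W) complex -> (2r, H, W) real channels."""
        return np.concatenate([x_complex.real, x_complex.imag], axis=0)

    @staticmethod
    def unpack(x_real):
        r = x_real.shape[0] // 2
        return x_real[:r] + 1j * x_real[r:]


class Adam:
    """Adam optimizer over the network's (value, grad) parameter list."""

    def __init__(self, net, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(v) for v, _ in net.params()]
        self.v = [np.zeros_like(v) for v, _ in net.params()]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (val, grad), m, v in zip(self.net.params(), self.m, self.v):
            m[...] = b1 * m + (1 - b1) * grad
            v[...] = b2 * v + (1 - b2) * grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            val -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def l1_loss(pred, target):
    """Mean absolute error and its gradient with respect to ``pred``."""
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


def save_weights(path, net, lambdas=None, metadata=None):
    """Single-file checkpoint: architecture + arrays + lambda schedule."""
    arrays = {}
    for i, (val, _) in enumerate(net.params()):
        arrays[f"p{i}"] = val
    meta = dict(metadata or {})
    np.savez(
        path,
        __arch__=json.dumps(net.arch),
        __meta__=json.dumps(meta),
        __lambdas__=np.asarray(lambdas if lambdas is not None else []),
        **arrays,
    )


def load_weights(path):
    """Load a checkpoint; returns (net, lambdas, metadata)."""
    with np.load(path, allow_pickle=False) as f:
        arch = json.loads(str(f["__arch__"]))
        meta = json.loads(str(f["__meta__"]))
        lambdas = f["__lambdas__"]
        net = UNet2d(**arch)
        for i, (val, _) in enumerate(net.params()):
            val[...] = f[f"p{i}"]
    return net, (lambdas if lambdas.size else None), meta
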