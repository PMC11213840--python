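"""Minimal deterministic CPU conv-net toolkit (float32, numpy only).

Implements exactly what the projection-inpainting network needs: 3x3/1x1
convolutions via im2col, ReLU, 2x2 average pooling, nearest-neighbour
upsampling, channel concatenation, and an Adam optimiser.  Everything is
seeded and free of hidden global state, so training is bit-reproducible
run to run on the same machine.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*k*k) patch matrix, stride 1, same padding."""
    B, C, H, W = x.shape
    if k == 1:
        return x.transpose(0, 2, 3, 1).reshape(B * H * W, C)
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B, C, H, W, k, k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * H * W, C * k * k
    )


def conv_forward(x, W, b):
    """x (B,Cin,H,W), W (Cout,Cin,k,k) -> out (B,Cout,H,W) and the patch matrix."""
    B, C, H, Wd = x.shape
    cout, cin, k, _ = W.shape
    cols = _im2col(x, k)
    out = cols @ W.reshape(cout, cin * k * k).T
    if b is not None:
        out += b
    return out.reshape(B, H, Wd, cout).transpose(0, 3, 1, 2), cols


class Conv:
    """3x3 or 1x1 convolution with bias, stride 1, same padding."""

    def __init__(self, cin, cout, k, rng, w_scale=None):
        std = w_scale if w_scale is not None else np.sqrt(2.0 / (cin * k * k))
        self.W = rng.normal(0.0, std, (cout, cin, k, k)).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.k = k
        self._cols = None
        self._in_shape = None

    def forward(self, x):
        out, self._cols = conv_forward(x, self.W, self.b)
        self._in_shape = x.shape
        return out

    def backward(self, dy):
        B, cout, H, Wd = dy.shape
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(B * H * Wd, cout)
        self.dW = (dy_mat.T @ self._cols).reshape(self.W.shape)
        self.db = dy_mat.sum(axis=0)
        # dx = convolution of dy with the flipped, channel-swapped kernels
        Wflip = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        dx, _ = conv_forward(dy, np.ascontiguousarray(Wflip), None)
        self._cols = None
        return dx

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]


def relu_forward(x):
    return np.maximum(x, 0.0), x > 0


def relu_backward(dy, mask):
    return dy * mask


def avgpool2_forward(x):
    B, C, H, W = x.shape
    return x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))


def avgpool2_backward(dy):
    return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) * F32(0.25)


def upsample2_forward(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def upsample2_backward(dy):
    B, C, H, W = dy.shape
    return dy.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for lay in layers for _, p in lay.params()]
        self.v = [np.zeros_like(p) for lay in layers for _, p in lay.params()]

    def step(self):
        self.t += 1
        i = 0
        for lay in self.layers:
            for (name, p), g in zip(lay.params(), lay.grads()):
                self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
                self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
                mhat = self.m[i] / (1 - self.b1**self.t)
                vhat = self.v[i] / (1 - self.b2**self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
                i += 1


class UNet:
    """Encoder-decoder with skip connections mapping a C-channel image to a
    C-channel image (the projection stack is treated as channels).

    Three resolution levels; input height/width must be divisible by 4.
    The final 1x1 convolution is initialised near zero so the network starts
    as (approximately) the identity on whatever baseline it is added to.
    """

    def __init__(self, channels: int, base: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.channels = channels
        self.base = base
        self.seed = seed
        b = base
        self.enc1a = Conv(channels, b, 3, rng)
        self.enc1b = Conv(b, b, 3, rng)
        self.enc2a = Conv(b, 2 * b, 3, rng)
        self.enc2b = Conv(2 * b, 2 * b, 3, rng)
        self.bot_a = Conv(2 * b, 4 * b, 3, rng)
        self.bot_b = Conv(4 * b, 4 * b, 3, rng)
        self.dec2a = Conv(6 * b, 2 * b, 3, rng)
        self.dec2b = Conv(2 * b, 2 * b, 3, rng)
        self.dec1a = Conv(3 * b, b, 3, rng)
        self.dec1b = Conv(b, b, 3, rng)
        self.head = Conv(b, channels, 1, rng, w_scale=1e-3)
        self.layers = [
            self.enc1a, self.enc1b, self.enc2a, self.enc2b, self.bot_a,
            self.bot_b, self.dec2a, self.dec2b, self.dec1a, self.dec1b, self.head,
        ]

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=F32)
        c = {}
        e1, c["r1a"] = relu_forward(self.enc1a.forward(x))
        e1, c["r1b"] = relu_forward(self.enc1b.forward(e1))
        p1 = avgpool2_forward(e1)
        e2, c["r2a"] = relu_forward(self.enc2a.forward(p1))
        e2, c["r2b"] = relu_forward(self.enc2b.forward(e2))
        p2 = avgpool2_forward(e2)
        bt, c["rba"] = relu_forward(self.bot_a.forward(p2))
        bt, c["rbb"] = relu_forward(self.bot_b.forward(bt))
        u2 = np.concatenate([e2, upsample2_forward(bt)], axis=1)
        d2, c["rd2a"] = relu_forward(self.dec2a.forward(u2))
        d2, c["rd2b"] = relu_forward(self.dec2b.forward(d2))
        u1 = np.concatenate([e1, upsample2_forward(d2)], axis=1)
        d1, c["rd1a"] = relu_forward(self.dec1a.forward(u1))
        d1, c["rd1b"] = relu_forward(self.dec1b.forward(d1))
        out = self.head.forward(d1)
        if train:
            self._cache = c
        return out

    def backward(self, dout):
        c = self._cache
        b = self.base
        dd1 = self.head.backward(np.ascontiguousarray(dout, dtype=F32))
        dd1 = self.dec1b.backward(relu_backward(dd1, c["rd1b"]))
        du1 = self.dec1a.backward(relu_backward(dd1, c["rd1a"]))
        de1_skip, dd2_up = du1[:, :b], du1[:, b:]
        dd2 = upsample2_backward(dd2_up)
        dd2 = self.dec2b.backward(relu_backward(dd2, c["rd2b"]))
        du2 = self.dec2a.backward(relu_backward(dd2, c["rd2a"]))
        de2_skip, dbt_up = du2[:, : 2 * b], du2[:, 2 * b :]
        dbt = upsample2_backward(dbt_up)
        dbt = self.bot_b.backward(relu_backward(dbt, c["rbb"]))
        dp2 = self.bot_a.backward(relu_backward(dbt, c["rba"]))
        de2 = avgpool2_backward(dp2) + de2_skip
        de2 = self.enc2b.backward(relu_backward(de2, c["r2b"]))
        dp1 = self.enc2a.backward(relu_backward(de2, c["r2a"]))
        de1 = avgpool2_backward(dp1) + de1_skip
        de1 = self.enc1b.backward(relu_backward(de1, c["r1b"]))
        self.enc1a.backward(relu_backward(de1, c["r1a"]))
        self._cache = None

    def state_dict(self):
        d = {"channels": self.channels, "base": self.base, "seed": self.seed}
        arrs = {}
        for i, lay in enumerate(self.layers):
            arrs[f"W{i}"] = lay.W
            arrs[f"b{i}"] = lay.b
        return d, arrs

    @classmethod
    def from_state(cls, meta, arrs):
        net = cls(meta["channels"], meta["base"], meta.get("seed", 0))
        for i, lay in enumerate(net.layers):
            lay.W = arrs[f"W{i}"].astype(F32)
            lay.b = arrs[f"b{i}"].astype(F32)
        return net
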