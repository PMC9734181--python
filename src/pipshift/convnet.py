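"""A compact convolutional binary classifier in pure numpy.

Architecture: a configurable stack of (3x3 conv, ReLU, 2x2 max-pool) blocks,
global average pooling, and a sigmoid linear head, trained with mini-batch
SGD (optional momentum) on the binary cross-entropy.  Everything is seeded
and deterministic: initialization, shuffling, and updates are pure functions
of the seed, so two runs with identical configuration produce identical
weights.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SmallConvNet", "DivergenceError"]


class DivergenceError(RuntimeError):
    """Training loss became non-finite (try a lower learning rate)."""


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patches of the 1-padded input."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))       # (N, C, H, W, 3, 3)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)


class SmallConvNet:
    """Seeded small CNN for 2-D grayscale inputs in [-1, 1].

    ``input_shape`` must be divisible by ``2 ** len(channels)`` so the
    pooling stack is exact.  Weights use He-normal initialization.
    """

    def __init__(self, input_shape=(64, 64), channels=(8, 16, 32), seed: int = 0):
        h, w = input_shape
        stride = 2 ** len(channels)
        if h % stride or w % stride:
            raise ValueError(f"input {input_shape} not divisible by 2^{len(channels)}")
        self.input_shape = tuple(input_shape)
        self.channels = tuple(channels)
        rng = np.random.default_rng(seed)
        self.conv_w, self.conv_b = [], []
        c_in = 1
        for c_out in channels:
            fan_in = c_in * 9
            self.conv_w.append(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                          size=(fan_in, c_out)).astype(np.float32))
            self.conv_b.append(np.zeros(c_out, dtype=np.float32))
            c_in = c_out
        self.head_w = rng.normal(0.0, np.sqrt(1.0 / c_in), size=c_in).astype(np.float32)
        self.head_b = np.float32(0.0)
        self._velocity = None

    # -- forward ----------------------------------------------------------

    def _forward(self, x: np.ndarray, keep_cache: bool):
        n = x.shape[0]
        a = x.reshape(n, 1, *self.input_shape).astype(np.float32)
        cache = []
        for wmat, b in zip(self.conv_w, self.conv_b):
            _, c, h, w = a.shape
            cols = _im2col(a)
            z = cols @ wmat + b                                # (N*h*w, c_out)
            c_out = wmat.shape[1]
            z = z.reshape(n, h, w, c_out).transpose(0, 3, 1, 2)
            r = np.maximum(z, 0.0)
            h2, w2 = h // 2, w // 2
            r4 = (r.reshape(n, c_out, h2, 2, w2, 2)
                   .transpose(0, 1, 2, 4, 3, 5)
                   .reshape(n, c_out, h2, w2, 4))
            idx = r4.argmax(axis=-1)
            pooled = np.take_along_axis(r4, idx[..., None], axis=-1)[..., 0]
            if keep_cache:
                cache.append((cols, z, idx, (h, w, c)))
            a = pooled
        gap = a.mean(axis=(2, 3))                              # (N, C_last)
        logits = gap @ self.head_w + self.head_b
        p = _sigmoid(logits)
        if keep_cache:
            return p, (cache, gap, a.shape)
        return p

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Positive-class probability for a stack of images (N, H, W)."""
        out = [self._forward(x[i:i + batch_size], False)
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out)

    # -- backward ---------------------------------------------------------

    def _grads(self, x: np.ndarray, y: np.ndarray):
        n = x.shape[0]
        p, (cache, gap, last_shape) = self._forward(x, True)
        eps = 1e-7
        pc = np.clip(p, eps, 1 - eps)
        loss = float(-(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean())

        dlogits = (p - y).astype(np.float32) / n
        g_head_w = gap.T @ dlogits
        g_head_b = dlogits.sum()
        dgap = np.outer(dlogits, self.head_w)                  # (N, C_last)
        _, c_last, hL, wL = last_shape
        da = np.broadcast_to(dgap[:, :, None, None] / (hL * wL),
                             last_shape).astype(np.float32)

        g_conv_w = [None] * len(self.conv_w)
        g_conv_b = [None] * len(self.conv_w)
        for li in range(len(self.conv_w) - 1, -1, -1):
            cols, z, idx, (h, w, c_in) = cache[li]
            c_out = self.conv_w[li].shape[1]
            h2, w2 = h // 2, w // 2
            # un-pool: route gradient to each window's argmax
            g4 = np.zeros((n, c_out, h2, w2, 4), dtype=np.float32)
            np.put_along_axis(g4, idx[..., None], da[..., None], axis=-1)
            dr = (g4.reshape(n, c_out, h2, w2, 2, 2)
                    .transpose(0, 1, 2, 4, 3, 5)
                    .reshape(n, c_out, h, w))
            dz = dr * (z > 0)
            dzf = dz.transpose(0, 2, 3, 1).reshape(n * h * w, c_out)
            g_conv_w[li] = cols.T @ dzf
            g_conv_b[li] = dzf.sum(axis=0)
            if li > 0:
                dcols = (dzf @ self.conv_w[li].T) \
                    .reshape(n, h, w, c_in, 3, 3).transpose(0, 3, 1, 2, 4, 5)
                dxp = np.zeros((n, c_in, h + 2, w + 2), dtype=np.float32)
                for di in range(3):
                    for dj in range(3):
                        dxp[:, :, di:di + h, dj:dj + w] += dcols[..., di, dj]
                da = dxp[:, :, 1:h + 1, 1:w + 1]
        return loss, (g_conv_w, g_conv_b, g_head_w, g_head_b)

    # -- optimization -----------------------------------------------------

    def _params_and_grads(self, grads):
        g_cw, g_cb, g_hw, g_hb = grads
        pairs = list(zip(self.conv_w, g_cw)) + list(zip(self.conv_b, g_cb))
        pairs.append((self.head_w, g_hw))
        return pairs, g_hb

    def sgd_step(self, x: np.ndarray, y: np.ndarray, lr: float,
                 momentum: float = 0.0) -> float:
        """One mini-batch update; returns the batch loss."""
        loss, grads = self._grads(x, y)
        if not np.isfinite(loss):
            raise DivergenceError("non-finite training loss; lower the learning rate")
        pairs, g_hb = self._params_and_grads(grads)
        if self._velocity is None:
            self._velocity = [np.zeros_like(p) for p, _ in pairs] + [np.float32(0.0)]
        for k, (param, grad) in enumerate(pairs):
            self._velocity[k] = momentum * self._velocity[k] - lr * grad
            param += self._velocity[k]
        self._velocity[-1] = momentum * self._velocity[-1] - lr * g_hb
        self.head_b += self._velocity[-1]
        return loss

    def state(self) -> list:
        """Flat copy of all weights (for determinism checks)."""
        return ([w.copy() for w in self.conv_w] + [b.copy() for b in self.conv_b]
                + [self.head_w.copy(), np.float32(self.head_b)])
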