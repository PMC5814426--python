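"""Minimal NumPy CNN engine: layers, backprop, Adamax.

Implements exactly what the sex-classification network needs — 2-D
convolution with Keras-style "same" padding, max-pooling with truncating
windows, inverted dropout, dense softmax head, categorical cross-entropy
and the Adamax optimizer — in float32.  Activations are stored
channels-last, (batch, height, width, features), so that im2col
convolution reduces every forward and backward pass to one large BLAS
matrix product with no transposition; for EEG epochs the height axis
carries the electrodes and the width axis carries time.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "MaxPool2D", "MeanPool2D", "Dropout", "Flatten",
           "Dense", "Adamax", "softmax", "softmax_xent", "glorot_uniform"]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int,
                   fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _same_pad(k: int) -> tuple[int, int]:
    # Keras convention: total = k-1, 'before' gets the smaller half
    before = (k - 1) // 2
    return before, k - 1 - before


class Layer:
    trainable = False

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple[int, int, int]) -> tuple[int, int, int]:
        """(height, width, features) shape arithmetic."""
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded stride-1 convolution with optional fused ReLU.

    Weights are stored as a (kh*kw*c_in, c_out) matrix whose row order
    matches the im2col patch layout (kernel row, kernel column, input
    feature)."""

    trainable = True

    def __init__(self, c_in: int, c_out: int, kh: int, kw: int,
                 activation: str | None = "relu",
                 rng: np.random.Generator | None = None):
        if activation not in (None, "relu", "linear"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.c_in, self.c_out, self.kh, self.kw = c_in, c_out, kh, kw
        self.activation = activation if activation != "linear" else None
        k = c_in * kh * kw
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W = glorot_uniform(rng, (k, c_out), fan_in=k,
                                fan_out=c_out * kh * kw)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def kernel(self) -> np.ndarray:
        """Weights as (kh, kw, c_in, c_out)."""
        return self.W.reshape(self.kh, self.kw, self.c_in, self.c_out)

    def _pads(self):
        return _same_pad(self.kh), _same_pad(self.kw)

    def forward(self, x, train=False, rng=None):
        b, h, w, c = x.shape
        (pt, pb), (pl, pr) = self._pads()
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        cols = np.empty((b, h, w, self.kh * self.kw * self.c_in),
                        dtype=np.float32)
        for i in range(self.kh):
            for j in range(self.kw):
                s = (i * self.kw + j) * self.c_in
                cols[..., s:s + self.c_in] = xp[:, i:i + h, j:j + w, :]
        cols2 = cols.reshape(-1, cols.shape[-1])
        out = cols2 @ self.W
        out += self.b
        if self.activation == "relu":
            mask = out > 0
            out *= mask
        else:
            mask = None
        self._cache = (cols2, mask, (b, h, w))
        return out.reshape(b, h, w, self.c_out)

    def backward(self, dy):
        cols2, mask, (b, h, w) = self._cache
        dyf = dy.reshape(-1, self.c_out)
        if mask is not None:
            dyf = dyf * mask
        self.db[:] = dyf.sum(axis=0)
        self.dW[:] = cols2.T @ dyf
        dcols = dyf @ self.W.T
        dcols = dcols.reshape(b, h, w, self.kh * self.kw * self.c_in)
        (pt, pb), (pl, pr) = self._pads()
        dxp = np.zeros((b, h + pt + pb, w + pl + pr, self.c_in),
                       dtype=np.float32)
        for i in range(self.kh):
            for j in range(self.kw):
                s = (i * self.kw + j) * self.c_in
                dxp[:, i:i + h, j:j + w, :] += dcols[..., s:s + self.c_in]
        self._cache = None
        return dxp[:, pt:pt + h, pl:pl + w, :]

    def out_shape(self, in_shape):
        h, w, c = in_shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input features, got {c}")
        return (h, w, self.c_out)


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/columns that do not fill
    a window are dropped."""

    def __init__(self, ph: int, pw: int):
        self.ph, self.pw = ph, pw
        self._cache = None

    def _crop(self, x):
        b, h, w, c = x.shape
        ho, wo = h // self.ph, w // self.pw
        return x[:, :ho * self.ph, :wo * self.pw, :], ho, wo

    def forward(self, x, train=False, rng=None):
        xc, ho, wo = self._crop(x)
        # pairwise maxima over strided views: cheap, no transposition
        m = xc[:, 0::self.ph].copy()
        for k in range(1, self.ph):
            np.maximum(m, xc[:, k::self.ph], out=m)
        out = m[:, :, 0::self.pw].copy()
        for k in range(1, self.pw):
            np.maximum(out, m[:, :, k::self.pw], out=out)
        self._cache = (x, out)
        return out

    def backward(self, dy):
        # Route the gradient to every window position equal to the max.
        # After a ReLU the only realistic ties are exact zeros, whose
        # gradient the preceding activation mask kills anyway.
        x, out = self._cache
        xc, ho, wo = self._crop(x)
        b, h, w, c = x.shape
        xr = xc.reshape(b, ho, self.ph, wo, self.pw, c)
        mask = xr == out[:, :, None, :, None, :]
        dxr = mask * dy[:, :, None, :, None, :]
        dx = np.zeros_like(x)
        dx[:, :ho * self.ph, :wo * self.pw, :] = dxr.reshape(
            b, ho * self.ph, wo * self.pw, c)
        self._cache = None
        return dx

    def out_shape(self, in_shape):
        h, w, c = in_shape
        return (h // self.ph, w // self.pw, c)


class MeanPool2D(MaxPool2D):
    """Mean pooling variant (same window/truncation semantics)."""

    def forward(self, x, train=False, rng=None):
        xc, ho, wo = self._crop(x)
        b, _, _, c = x.shape
        out = xc.reshape(b, ho, self.ph, wo, self.pw, c).mean(axis=(2, 4))
        self._cache = x.shape
        return np.asarray(out, dtype=np.float32)

    def backward(self, dy):
        b, h, w, c = self._cache
        ho, wo = h // self.ph, w // self.pw
        dx = np.zeros((b, h, w, c), dtype=np.float32)
        up = np.repeat(np.repeat(dy, self.ph, axis=1), self.pw, axis=2)
        dx[:, :ho * self.ph, :wo * self.pw, :] = up / (self.ph * self.pw)
        self._cache = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - self.rate
        u = rng.random(x.shape, dtype=np.float32)
        self._mask = (u < keep).astype(np.float32) / np.float32(keep)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        out = dy * self._mask
        self._mask = None
        return out

    def out_shape(self, in_shape):
        return in_shape


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def out_shape(self, in_shape):
        h, w, c = in_shape
        return (1, 1, h * w * c)


class Dense(Layer):
    """Affine layer; the softmax (if any) is applied by the loss/predict
    path, so ``forward`` returns logits."""

    trainable = True

    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.n_in, self.n_out = n_in, n_out
        self.W = glorot_uniform(rng, (n_in, n_out), fan_in=n_in, fan_out=n_out)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        dy = np.asarray(dy, dtype=np.float32)
        self.dW[:] = self._x.T @ dy
        self.db[:] = dy.sum(axis=0)
        self._x = None
        return dy @ self.W.T

    def out_shape(self, in_shape):
        return (1, 1, self.n_out)


def softmax_xent(logits: np.ndarray, onehot: np.ndarray):
    """Mean categorical cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.mean(np.sum(onehot * np.log(np.maximum(p, 1e-12)), axis=1))
    grad = ((p - onehot) / n).astype(np.float32)
    return loss, grad, p


class Adamax:
    """Adamax: Adam with an infinity-norm second moment.

    m <- b1*m + (1-b1)*g ;  u <- max(b2*u, |g|)
    p <- p - lr/(1-b1^t) * m / (u + eps)
    """

    def __init__(self, lr: float = 0.002, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._u: dict[int, np.ndarray] = {}

    def step(self, params) -> None:
        """Update every (param, grad) pair in-place."""
        self.t += 1
        bias = 1.0 - self.beta1 ** self.t
        for i, (p, g) in enumerate(params):
            if i not in self._m:
                self._m[i] = np.zeros_like(p)
                self._u[i] = np.zeros_like(p)
            m, u = self._m[i], self._u[i]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            np.maximum(self.beta2 * u, np.abs(g), out=u)
            p -= (self.lr / bias) * m / (u + self.eps)
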