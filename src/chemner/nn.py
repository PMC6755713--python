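"""A compact NumPy engine for recurrent sequence taggers.

Implements exactly the layer set the taggers need — embedding lookup,
same-padded 1-D convolution, (bidirectional) LSTM with input and recurrent
dropout, time-distributed dense heads, global max pooling — together with
RMSProp and fused softmax/sigmoid cross-entropy gradients, all with manual
backpropagation.  Mini-batches contain equal-length sequences only, so no
masking or padding machinery is needed anywhere.

Conventions
-----------
* All activations are ``float32`` by default (``dtype`` is a constructor
  argument; gradient-check tests use ``float64``).
* ``forward(..., train=True)`` caches what backward needs; ``backward``
  consumes the caches of the most recent forward.
* Dense heads with softmax/sigmoid activations are trained with fused
  cross-entropy: their ``backward`` expects the gradient with respect to the
  *pre-activation* logits, i.e. ``(probs - targets) / normaliser``.
* Dropout follows the recurrent-network convention of one mask per sequence,
  shared across timesteps.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Param",
    "RMSProp",
    "Embedding",
    "Conv1DSame",
    "Dropout",
    "LSTM",
    "BiLSTM",
    "TimeDense",
    "Dense",
    "GlobalMaxPool",
    "softmax_xent",
    "sigmoid_bce",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def orthogonal(rng: np.random.Generator, rows: int, cols: int, dtype) -> np.ndarray:
    """Orthogonal init for recurrent kernels, built in square blocks."""
    blocks = []
    remaining = cols
    while remaining > 0:
        a = rng.standard_normal((rows, rows))
        q, r = np.linalg.qr(a)
        q *= np.sign(np.diag(r))  # deterministic sign convention
        blocks.append(q[:, : min(rows, remaining)])
        remaining -= rows
    return np.concatenate(blocks, axis=1)[:, :cols].astype(dtype)


class RMSProp:
    """Root-mean-square propagation with Keras-style defaults."""

    def __init__(self, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-7) -> None:
        self.lr, self.rho, self.eps = lr, rho, eps
        self._cache: dict[int, np.ndarray] = {}

    def step(self, params: Sequence[Param]) -> None:
        for p in params:
            c = self._cache.get(id(p))
            if c is None:
                c = np.zeros_like(p.value)
                self._cache[id(p)] = c
            g = p.grad
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            p.value -= self.lr * g / (np.sqrt(c) + self.eps)
            g[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []


class Embedding(Layer):
    """Integer ids (B, T) -> vectors (B, T, D)."""

    def __init__(
        self,
        num_embeddings: int,
        dim: int,
        rng: np.random.Generator,
        init: np.ndarray | None = None,
        trainable: bool = True,
        dtype=np.float32,
    ) -> None:
        if init is not None:
            w = np.asarray(init, dtype=dtype).copy()
            if w.shape != (num_embeddings, dim):
                raise ValueError(f"init shape {w.shape} != {(num_embeddings, dim)}")
        else:
            w = (rng.uniform(-0.05, 0.05, size=(num_embeddings, dim))).astype(dtype)
        self.W = Param(w, "embedding")
        self.trainable = trainable
        self._ids: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W] if self.trainable else []

    def forward(self, ids: np.ndarray, train: bool = False) -> np.ndarray:
        self._ids = ids
        return self.W.value[ids]

    def backward(self, d_out: np.ndarray) -> None:
        if self.trainable:
            np.add.at(self.W.grad, self._ids, d_out)


class Conv1DSame(Layer):
    """Width-w 1-D convolution over the time axis, 'same' zero padding, relu."""

    def __init__(
        self,
        in_dim: int,
        filters: int,
        width: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ) -> None:
        if width % 2 != 1:
            raise ValueError("width must be odd for same padding")
        self.in_dim, self.filters, self.width = in_dim, filters, width
        self.W = Param(glorot_uniform(rng, (width * in_dim, filters), dtype), "conv_W")
        self.b = Param(np.zeros(filters, dtype=dtype), "conv_b")
        self.dtype = dtype

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _windows(self, x: np.ndarray) -> np.ndarray:
        B, T, D = x.shape
        half = self.width // 2
        xp = np.zeros((B, T + 2 * half, D), dtype=x.dtype)
        xp[:, half : half + T] = x
        return np.concatenate(
            [xp[:, k : k + T] for k in range(self.width)], axis=2
        )  # (B, T, width*D)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        win = self._windows(x)
        z = win @ self.W.value + self.b.value
        a = np.maximum(z, 0.0)
        self._cache = (x.shape, win, z > 0)
        return a

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        (B, T, D), win, pos = self._cache
        dz = d_out * pos
        dz2 = dz.reshape(-1, self.filters)
        self.W.grad += win.reshape(-1, self.width * self.in_dim).T @ dz2
        self.b.grad += dz2.sum(axis=0)
        dwin = dz @ self.W.value.T  # (B, T, width*D)
        half = self.width // 2
        dxp = np.zeros((B, T + 2 * half, D), dtype=d_out.dtype)
        for k in range(self.width):
            dxp[:, k : k + T] += dwin[:, :, k * D : (k + 1) * D]
        return dxp[:, half : half + T]


class Dropout(Layer):
    """Inverted dropout with one mask per sequence shared over timesteps."""

    def __init__(self, rate: float) -> None:
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (rng.random((x.shape[0], x.shape[-1])) < keep).astype(x.dtype) / keep
        self._mask = mask
        return x * mask[:, None, :] if x.ndim == 3 else x * mask

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return d_out
        m = self._mask
        return d_out * m[:, None, :] if d_out.ndim == 3 else d_out * m


class LSTM(Layer):
    """A single-direction LSTM returning the full hidden sequence.

    ``reverse=True`` runs over the sequence back-to-front (output re-aligned
    to input order).  ``dropout`` masks the inputs and ``recurrent_dropout``
    the recurrent state, each with one mask per sequence.  Gate order is
    i, f, g, o with forget-gate bias initialised to 1.
    """

    def __init__(
        self,
        in_dim: int,
        units: int,
        rng: np.random.Generator,
        reverse: bool = False,
        dropout: float = 0.0,
        recurrent_dropout: float = 0.0,
        dtype=np.float32,
    ) -> None:
        self.in_dim, self.units, self.reverse = in_dim, units, reverse
        self.dropout, self.recurrent_dropout = dropout, recurrent_dropout
        self.Wx = Param(glorot_uniform(rng, (in_dim, 4 * units), dtype), "lstm_Wx")
        self.Wh = Param(orthogonal(rng, units, 4 * units, dtype), "lstm_Wh")
        b = np.zeros(4 * units, dtype=dtype)
        b[units : 2 * units] = 1.0  # forget-gate bias
        self.b = Param(b, "lstm_b")
        self.dtype = dtype

    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]

    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        if self.reverse:
            x = x[:, ::-1]
        B, T, _ = x.shape
        u = self.units
        dt = x.dtype

        mask_x = None
        if train and self.dropout > 0.0:
            keep = 1.0 - self.dropout
            mask_x = (rng.random((B, self.in_dim)) < keep).astype(dt) / keep
            x = x * mask_x[:, None, :]
        mask_h = None
        if train and self.recurrent_dropout > 0.0:
            keep = 1.0 - self.recurrent_dropout
            mask_h = (rng.random((B, u)) < keep).astype(dt) / keep

        xw = x.reshape(B * T, self.in_dim) @ self.Wx.value
        xw = xw.reshape(B, T, 4 * u) + self.b.value

        I = np.empty((B, T, u), dtype=dt)
        F = np.empty_like(I)
        G = np.empty_like(I)
        O = np.empty_like(I)
        C = np.empty_like(I)
        TC = np.empty_like(I)
        H = np.empty_like(I)
        h = np.zeros((B, u), dtype=dt)
        c = np.zeros((B, u), dtype=dt)
        Wh = self.Wh.value
        for t in range(T):
            hd = h * mask_h if mask_h is not None else h
            z = xw[:, t] + hd @ Wh
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            I[:, t], F[:, t], G[:, t], O[:, t], C[:, t], TC[:, t], H[:, t] = (
                i, f, g, o, c, tc, h,
            )
        self._cache = (x, mask_x, mask_h, I, F, G, O, C, TC, H)
        return H[:, ::-1] if self.reverse else H

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        x, mask_x, mask_h, I, F, G, O, C, TC, H = self._cache
        if self.reverse:
            d_out = d_out[:, ::-1]
        B, T, u = I.shape
        dt = x.dtype
        Wh = self.Wh.value
        dZ = np.empty((B, T, 4 * u), dtype=dt)
        dh_next = np.zeros((B, u), dtype=dt)
        dc_next = np.zeros((B, u), dtype=dt)
        for t in range(T - 1, -1, -1):
            i, f, g, o, tc = I[:, t], F[:, t], G[:, t], O[:, t], TC[:, t]
            dh = d_out[:, t] + dh_next
            dc = dh * o * (1.0 - tc * tc) + dc_next
            c_prev = C[:, t - 1] if t > 0 else 0.0
            dz = dZ[:, t]
            dz[:, :u] = dc * g * i * (1.0 - i)
            dz[:, u : 2 * u] = dc * c_prev * f * (1.0 - f)
            dz[:, 2 * u : 3 * u] = dc * i * (1.0 - g * g)
            dz[:, 3 * u :] = dh * tc * o * (1.0 - o)
            dc_next = dc * f
            dh_next = dz @ Wh.T
            if mask_h is not None:
                dh_next = dh_next * mask_h
        # recurrent kernel gradient: Hprev[t] = H[t-1] (zeros at t=0)
        Hprev = np.concatenate([np.zeros((B, 1, u), dtype=dt), H[:, :-1]], axis=1)
        if mask_h is not None:
            Hprev = Hprev * mask_h[:, None, :]
        dZ2 = dZ.reshape(B * T, 4 * u)
        self.Wh.grad += Hprev.reshape(B * T, u).T @ dZ2
        self.Wx.grad += x.reshape(B * T, self.in_dim).T @ dZ2
        self.b.grad += dZ2.sum(axis=0)
        dx = (dZ2 @ self.Wx.value.T).reshape(B, T, self.in_dim)
        if mask_x is not None:
            dx = dx * mask_x[:, None, :]
        return dx[:, ::-1] if self.reverse else dx


class BiLSTM(Layer):
    """Forward + backward LSTM with concatenated outputs (2*units wide)."""

    def __init__(
        self,
        in_dim: int,
        units: int,
        rng: np.random.Generator,
        dropout: float = 0.0,
        recurrent_dropout: float = 0.0,
        dtype=np.float32,
    ) -> None:
        self.units = units
        self.fw = LSTM(in_dim, units, rng, False, dropout, recurrent_dropout, dtype)
        self.bw = LSTM(in_dim, units, rng, True, dropout, recurrent_dropout, dtype)

    def params(self) -> list[Param]:
        return self.fw.params() + self.bw.params()

    def forward(self, x, train=False, rng=None):
        return np.concatenate(
            [self.fw.forward(x, train, rng), self.bw.forward(x, train, rng)], axis=2
        )

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        u = self.units
        return self.fw.backward(d_out[:, :, :u]) + self.bw.backward(d_out[:, :, u:])


class TimeDense(Layer):
    """Per-position dense layer (B, T, in) -> (B, T, out).

    For ``softmax``/``sigmoid`` activations, ``backward`` expects the
    gradient with respect to the logits (fused cross-entropy convention);
    for ``linear`` it is the plain upstream gradient.
    """

    def __init__(
        self, in_dim: int, out_dim: int, rng: np.random.Generator,
        activation: str = "linear", dtype=np.float32,
    ) -> None:
        if activation not in ("linear", "softmax", "sigmoid"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.in_dim, self.out_dim, self.activation = in_dim, out_dim, activation
        self.W = Param(glorot_uniform(rng, (in_dim, out_dim), dtype), "dense_W")
        self.b = Param(np.zeros(out_dim, dtype=dtype), "dense_b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        z = x @ self.W.value + self.b.value
        if self.activation == "softmax":
            z = z - z.max(axis=-1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=-1, keepdims=True)
        if self.activation == "sigmoid":
            return _sigmoid(z)
        return z

    def backward(self, d_logits: np.ndarray) -> np.ndarray:
        x = self._x
        flat_x = x.reshape(-1, self.in_dim)
        flat_d = d_logits.reshape(-1, self.out_dim)
        self.W.grad += flat_x.T @ flat_d
        self.b.grad += flat_d.sum(axis=0)
        return (flat_d @ self.W.value.T).reshape(x.shape)


class Dense(TimeDense):
    """Alias for a dense layer on (B, in) inputs; same fused convention."""


class GlobalMaxPool(Layer):
    """(B, T, D) -> (B, D) max over time."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._arg = x.argmax(axis=1)  # (B, D)
        self._shape = x.shape
        return np.take_along_axis(x, self._arg[:, None, :], axis=1)[:, 0, :]

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape, dtype=d_out.dtype)
        np.put_along_axis(dx, self._arg[:, None, :], d_out[:, None, :], axis=1)
        return dx


def softmax_xent(
    probs: np.ndarray, onehot: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and the fused logit gradient.

    ``mask`` (matching ``probs`` minus the class axis) excludes positions
    from both the loss and the gradient; the mean is over unmasked
    positions.
    """
    eps = 1e-9
    if mask is None:
        n = max(int(np.prod(probs.shape[:-1])), 1)
        loss = -(onehot * np.log(probs + eps)).sum() / n
        return float(loss), (probs - onehot) / n
    n = max(float(mask.sum()), 1.0)
    m = mask[..., None]
    loss = -(m * onehot * np.log(probs + eps)).sum() / n
    return float(loss), (probs - onehot) * m / n


def sigmoid_bce(probs: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy over all bits and the fused logit gradient."""
    eps = 1e-9
    n = max(int(np.prod(probs.shape)), 1)
    loss = -(
        targets * np.log(probs + eps) + (1 - targets) * np.log(1 - probs + eps)
    ).sum() / n
    return float(loss), (probs - targets) / n
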