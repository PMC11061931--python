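"""A small sequence-network engine in numpy.

Implements exactly the layer set explored for repurposing prediction —
SimpleRNN, GRU, LSTM, their bidirectional variants, 1-D convolution,
max-pooling and dropout — with full backpropagation(-through-time), Adam,
binary cross-entropy on logits, and early stopping with best-weight
restoration.  Gate conventions and parameter counts follow the common
deep-learning-framework defaults (GRU uses separate input/recurrent
biases, i.e. 3·(d·u + u² + 2u) parameters; LSTM 4·(d·u + u² + u) with a
unit forget-gate bias at init).

Inputs are batch-first arrays of shape (batch, time, features); a
recurrent layer returns its full sequence only when a later layer
consumes one, otherwise just its last state.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Dense",
    "Conv1D",
    "MaxPool1D",
    "Dropout",
    "Flatten",
    "SimpleRNN",
    "GRU",
    "LSTM",
    "Bidirectional",
    "Network",
    "Adam",
    "bce_with_logits",
    "train_network",
    "TrainingHistory",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, int], dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _orthogonal_block(rng: np.random.Generator, n: int, cols: int, dtype) -> np.ndarray:
    """(n, cols) recurrent kernel built from per-gate orthogonal blocks."""
    blocks = []
    for _ in range(cols // n):
        a = rng.standard_normal((n, n))
        q, r = np.linalg.qr(a)
        blocks.append(q * np.sign(np.diag(r)))
    return np.concatenate(blocks, axis=1).astype(dtype)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]
    consumes_sequence = False  # does this layer need (T, F) input?

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def build(self, input_shape: tuple[int, ...], rng: np.random.Generator, dtype) -> tuple[int, ...]:
        raise NotImplementedError

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class Dense(Layer):
    def __init__(self, units: int) -> None:
        super().__init__()
        if units < 1:
            raise ValueError("units must be >= 1")
        self.units = units

    def build(self, input_shape, rng, dtype):
        if len(input_shape) != 1:
            raise ValueError(f"Dense expects flat input, got shape {input_shape}")
        (f,) = input_shape
        self.W = _glorot(rng, (f, self.units), dtype)
        self.b = np.zeros(self.units, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        return (self.units,)

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0] += self._x.T @ dout
        self.grads[1] += dout.sum(axis=0)
        return dout @ self.W.T


class Flatten(Layer):
    def build(self, input_shape, rng, dtype):
        self._shape = input_shape
        return (int(np.prod(input_shape)),)

    def forward(self, x, training):
        self._batch = x.shape[0]
        return x.reshape(self._batch, -1)

    def backward(self, dout):
        return dout.reshape(self._batch, *self._shape)


class Conv1D(Layer):
    consumes_sequence = True

    def __init__(self, filters: int, kernel_size: int = 3) -> None:
        super().__init__()
        if filters < 1 or kernel_size < 1:
            raise ValueError("filters and kernel_size must be >= 1")
        self.filters = filters
        self.kernel_size = kernel_size

    def build(self, input_shape, rng, dtype):
        t, d = input_shape
        if t < self.kernel_size:
            raise ValueError(f"sequence length {t} shorter than kernel {self.kernel_size}")
        k = self.kernel_size
        limit = np.sqrt(6.0 / (k * d + k * self.filters))
        self.W = rng.uniform(-limit, limit, size=(k, d, self.filters)).astype(dtype)
        self.b = np.zeros(self.filters, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        return (t - k + 1, self.filters)

    def forward(self, x, training):
        k = self.kernel_size
        # (B, L, k, D) windows over time
        win = sliding_window_view(x, k, axis=1).transpose(0, 1, 3, 2)
        z = np.tensordot(win, self.W, axes=((2, 3), (0, 1))) + self.b
        self._win = win
        self._mask = z > 0
        return np.where(self._mask, z, 0.0)  # ReLU

    def backward(self, dout):
        dz = np.where(self._mask, dout, 0.0)
        self.grads[0] += np.tensordot(self._win, dz, axes=((0, 1), (0, 1)))
        self.grads[1] += dz.sum(axis=(0, 1))
        dwin = np.tensordot(dz, self.W, axes=(2, 2))  # (B, L, k, D)
        b, l, k, d = dwin.shape
        dx = np.zeros((b, l + k - 1, d), dtype=dwin.dtype)
        for i in range(k):
            dx[:, i : i + l, :] += dwin[:, :, i, :]
        return dx


class MaxPool1D(Layer):
    consumes_sequence = True

    def __init__(self, pool_size: int) -> None:
        super().__init__()
        if pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        self.pool_size = pool_size

    def build(self, input_shape, rng, dtype):
        t, f = input_shape
        if t < self.pool_size:
            raise ValueError(f"sequence length {t} shorter than pool size {self.pool_size}")
        return (t // self.pool_size, f)

    def forward(self, x, training):
        p = self.pool_size
        b, t, f = x.shape
        l = t // p
        self._in_shape = x.shape
        blocks = x[:, : l * p].reshape(b, l, p, f)
        self._arg = blocks.argmax(axis=2)
        return np.take_along_axis(blocks, self._arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dout):
        b, t, f = self._in_shape
        p = self.pool_size
        l = t // p
        dblocks = np.zeros((b, l, p, f), dtype=dout.dtype)
        np.put_along_axis(dblocks, self._arg[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, : l * p] = dblocks.reshape(b, l * p, f)
        return dx


class Dropout(Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        if not (0.0 < rate < 1.0):
            raise ValueError("dropout rate must be in (0, 1)")
        self.rate = rate

    def build(self, input_shape, rng, dtype):
        self._rng = rng
        return input_shape

    def forward(self, x, training):
        if not training:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class _Recurrent(Layer):
    consumes_sequence = True
    n_gates = 1

    def __init__(self, units: int, return_sequences: bool = False) -> None:
        super().__init__()
        if units < 1:
            raise ValueError("units must be >= 1")
        self.units = units
        self.return_sequences = return_sequences

    def build(self, input_shape, rng, dtype):
        t, d = input_shape
        self._t, self._d = t, d
        self._build_kernels(d, rng, dtype)
        return (t, self.units) if self.return_sequences else (self.units,)


class SimpleRNN(_Recurrent):
    def _build_kernels(self, d, rng, dtype):
        u = self.units
        self.W = _glorot(rng, (d, u), dtype)
        self.U = _orthogonal_block(rng, u, u, dtype)
        self.b = np.zeros(u, dtype=dtype)
        self.params = [self.W, self.U, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training):
        b, t, _ = x.shape
        u = self.units
        h = np.zeros((b, u), dtype=x.dtype)
        self._x = x
        self._hs = [h]
        outs = np.empty((b, t, u), dtype=x.dtype)
        for i in range(t):
            h = np.tanh(x[:, i] @ self.W + h @ self.U + self.b)
            self._hs.append(h)
            outs[:, i] = h
        self._outs = outs
        return outs if self.return_sequences else outs[:, -1]

    def backward(self, dout):
        x, hs = self._x, self._hs
        b, t, _ = x.shape
        dW, dU, db = self.grads
        dx = np.zeros_like(x)
        dh_next = np.zeros((b, self.units), dtype=x.dtype)
        for i in reversed(range(t)):
            dh = dh_next + (dout[:, i] if self.return_sequences else 0)
            if not self.return_sequences and i == t - 1:
                dh = dh + dout
            h = hs[i + 1]
            da = dh * (1.0 - h * h)
            dW += x[:, i].T @ da
            dU += hs[i].T @ da
            db += da.sum(axis=0)
            dx[:, i] = da @ self.W.T
            dh_next = da @ self.U.T
        return dx


class GRU(_Recurrent):
    """Gated recurrent unit with separate input and recurrent biases."""

    def _build_kernels(self, d, rng, dtype):
        u = self.units
        self.W = _glorot(rng, (d, 3 * u), dtype)
        self.U = _orthogonal_block(rng, u, 3 * u, dtype)
        self.b_in = np.zeros(3 * u, dtype=dtype)
        self.b_rec = np.zeros(3 * u, dtype=dtype)
        self.params = [self.W, self.U, self.b_in, self.b_rec]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training):
        b, t, _ = x.shape
        u = self.units
        h = np.zeros((b, u), dtype=x.dtype)
        self._x = x
        self._cache = []
        outs = np.empty((b, t, u), dtype=x.dtype)
        for i in range(t):
            xp = x[:, i] @ self.W + self.b_in
            hp = h @ self.U + self.b_rec
            z = _sigmoid(xp[:, :u] + hp[:, :u])
            r = _sigmoid(xp[:, u : 2 * u] + hp[:, u : 2 * u])
            s = hp[:, 2 * u :]
            cand = np.tanh(xp[:, 2 * u :] + r * s)
            h_new = z * h + (1.0 - z) * cand
            self._cache.append((h, z, r, s, cand))
            h = h_new
            outs[:, i] = h
        return outs if self.return_sequences else outs[:, -1]

    def backward(self, dout):
        x = self._x
        b, t, _ = x.shape
        u = self.units
        dW, dU, db_in, db_rec = self.grads
        dx = np.zeros_like(x)
        dh_next = np.zeros((b, u), dtype=x.dtype)
        for i in reversed(range(t)):
            dh = dh_next + (dout[:, i] if self.return_sequences else 0)
            if not self.return_sequences and i == t - 1:
                dh = dh + dout
            h_prev, z, r, s, cand = self._cache[i]
            dz = dh * (h_prev - cand)
            dcand = dh * (1.0 - z)
            dh_prev = dh * z
            da = dcand * (1.0 - cand * cand)
            dr = da * s
            ds = da * r
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            gx = np.concatenate([daz, dar, da], axis=1)
            gh = np.concatenate([daz, dar, ds], axis=1)
            dW += x[:, i].T @ gx
            db_in += gx.sum(axis=0)
            dU += h_prev.T @ gh
            db_rec += gh.sum(axis=0)
            dx[:, i] = gx @ self.W.T
            dh_next = dh_prev + gh @ self.U.T
        return dx


class LSTM(_Recurrent):
    def _build_kernels(self, d, rng, dtype):
        u = self.units
        self.W = _glorot(rng, (d, 4 * u), dtype)
        self.U = _orthogonal_block(rng, u, 4 * u, dtype)
        self.b = np.zeros(4 * u, dtype=dtype)
        self.b[u : 2 * u] = 1.0  # forget-gate bias
        self.params = [self.W, self.U, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training):
        b, t, _ = x.shape
        u = self.units
        h = np.zeros((b, u), dtype=x.dtype)
        c = np.zeros((b, u), dtype=x.dtype)
        self._x = x
        self._cache = []
        outs = np.empty((b, t, u), dtype=x.dtype)
        for idx in range(t):
            zcat = x[:, idx] @ self.W + h @ self.U + self.b
            i = _sigmoid(zcat[:, :u])
            f = _sigmoid(zcat[:, u : 2 * u])
            g = np.tanh(zcat[:, 2 * u : 3 * u])
            o = _sigmoid(zcat[:, 3 * u :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            self._cache.append((h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
            outs[:, idx] = h
        return outs if self.return_sequences else outs[:, -1]

    def backward(self, dout):
        x = self._x
        b, t, _ = x.shape
        u = self.units
        dW, dU, db = self.grads
        dx = np.zeros_like(x)
        dh_next = np.zeros((b, u), dtype=x.dtype)
        dc_next = np.zeros((b, u), dtype=x.dtype)
        for idx in reversed(range(t)):
            dh = dh_next + (dout[:, idx] if self.return_sequences else 0)
            if not self.return_sequences and idx == t - 1:
                dh = dh + dout
            h_prev, c_prev, i, f, g, o, c = self._cache[idx]
            tc = np.tanh(c)
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            gz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)], axis=1
            )
            dW += x[:, idx].T @ gz
            dU += h_prev.T @ gz
            db += gz.sum(axis=0)
            dx[:, idx] = gz @ self.W.T
            dh_next = gz @ self.U.T
        return dx


class Bidirectional(Layer):
    """Run a recurrent layer forwards and backwards in time; concatenate."""

    consumes_sequence = True

    def __init__(self, layer_cls, units: int, return_sequences: bool = False) -> None:
        super().__init__()
        self.fwd = layer_cls(units, return_sequences=return_sequences)
        self.bwd = layer_cls(units, return_sequences=return_sequences)
        self.return_sequences = return_sequences
        self.units = units

    def build(self, input_shape, rng, dtype):
        shape_f = self.fwd.build(input_shape, rng, dtype)
        self.bwd.build(input_shape, rng, dtype)
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads
        if self.return_sequences:
            return (shape_f[0], 2 * self.units)
        return (2 * self.units,)

    def forward(self, x, training):
        out_f = self.fwd.forward(x, training)
        out_b = self.bwd.forward(x[:, ::-1], training)
        if self.return_sequences:
            return np.concatenate([out_f, out_b[:, ::-1]], axis=-1)
        return np.concatenate([out_f, out_b], axis=-1)

    def backward(self, dout):
        u = self.units
        if self.return_sequences:
            dx_f = self.fwd.backward(dout[:, :, :u])
            dx_b = self.bwd.backward(dout[:, ::-1, u:])
        else:
            dx_f = self.fwd.backward(dout[:, :u])
            dx_b = self.bwd.backward(dout[:, u:])
        return dx_f + dx_b[:, ::-1]


class Network:
    """A sequential stack ending in a single-logit head."""

    def __init__(self, layers: list[Layer], input_shape: tuple[int, int], seed: int = 0,
                 dtype=np.float32) -> None:
        self.layers = layers
        self.input_shape = input_shape
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        shape: tuple[int, ...] = input_shape
        for layer in layers:
            shape = layer.build(shape, rng, dtype)
        if shape != (1,):
            raise ValueError(f"network must end in a single output unit, got shape {shape}")
        self.params = [p for layer in layers for p in layer.params]
        self.grads = [g for layer in layers for g in layer.grads]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            out = layer.forward(out, training)
        return out[:, 0]  # logits

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits[:, None].astype(self.dtype)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        probs = []
        for lo in range(0, len(x), batch_size):
            probs.append(_sigmoid(self.forward(x[lo : lo + batch_size], training=False)))
        return np.concatenate(probs) if probs else np.zeros(0)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.m is None:
            self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
            self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g.astype(np.float64) ** 2)
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z = logits.astype(np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    grad = (_sigmoid(z) - y) / len(z)
    return loss, grad


class TrainingHistory:
    """Per-epoch train/validation losses plus the early-stopping outcome."""

    def __init__(self) -> None:
        self.train_loss: list[float] = []
        self.val_loss: list[float] = []
        self.best_epoch: int = -1
        self.stopped_early: bool = False

    def __len__(self) -> int:
        return len(self.val_loss)


def train_network(
    net: Network,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    batch_size: int = 64,
    max_epochs: int = 100,
    patience: int = 10,
    learning_rate: float = 1e-3,
    seed: int = 0,
) -> TrainingHistory:
    """Mini-batch Adam with early stopping on validation loss.

    Stops after ``patience`` epochs without improvement (or at
    ``max_epochs``) and restores the weights of the best validation epoch.
    """
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("training and validation sets must be non-empty")
    opt = Adam(lr=learning_rate)
    rng = np.random.default_rng(seed)
    history = TrainingHistory()
    best_val = np.inf
    best_weights = net.get_weights()
    since_best = 0
    y_train = np.asarray(y_train, dtype=np.float64)
    y_val = np.asarray(y_val, dtype=np.float64)
    for epoch in range(max_epochs):
        order = rng.permutation(len(X_train))
        epoch_loss = 0.0
        for lo in range(0, len(order), batch_size):
            sel = order[lo : lo + batch_size]
            logits = net.forward(X_train[sel], training=True)
            loss, grad = bce_with_logits(logits, y_train[sel])
            net.zero_grads()
            net.backward(grad)
            opt.step(net.params, net.grads)
            epoch_loss += loss * len(sel)
        history.train_loss.append(epoch_loss / len(order))

        val_logits = []
        for lo in range(0, len(X_val), 256):
            val_logits.append(net.forward(X_val[lo : lo + 256], training=False))
        vloss, _ = bce_with_logits(np.concatenate(val_logits), y_val)
        history.val_loss.append(vloss)
        if vloss < best_val:
            best_val = vloss
            best_weights = net.get_weights()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                history.stopped_early = True
                break
    net.set_weights(best_weights)
    return history
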