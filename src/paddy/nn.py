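"""Minimal convolutional-network framework for 5x5 patch regression.

Implements exactly what the autoencoder-like yield models need — 2D/3D
convolutions (stride 1, TensorFlow-style "same"/"valid" padding), dense
layers, ReLU, mean-squared-error loss, Adam, and an epoch loop that
checkpoints the weights with the best validation loss.  Everything runs on
float32 numpy; convolutions are evaluated as one GEMM per kernel offset,
which is efficient at these tiny spatial extents.

Channel-last layout throughout: 2D tensors are (N, H, W, C); 3D tensors are
(N, H, W, D, C) with D the date axis.
"""

from __future__ import annotations

import itertools
import numpy as np

__all__ = ["Conv2D", "Conv3D", "Dense", "Flatten", "Reshape", "Sequential", "Adam", "fit"]

DTYPE = np.float32


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def _same_padding(k: int) -> tuple[int, int]:
    # TF convention at stride 1: total = k-1, split begin = floor(total/2)
    total = k - 1
    begin = total // 2
    return begin, total - begin


class Layer:
    """Base layer: forward caches what backward needs; params/grads exposed."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class _Activated(Layer):
    """Mixin handling the fused relu/linear activation."""

    def __init__(self, activation: str) -> None:
        super().__init__()
        if activation not in ("relu", "linear"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.activation = activation
        self._relu_mask: np.ndarray | None = None

    def _activate(self, z: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            self._relu_mask = z > 0
            np.multiply(z, self._relu_mask, out=z)
        return z

    def _deactivate(self, dy: np.ndarray) -> np.ndarray:
        # dy is a transient upstream buffer; in-place masking is safe
        if self.activation == "relu":
            dy = np.multiply(dy, self._relu_mask, out=np.ascontiguousarray(dy))
        return dy


class _ConvND(_Activated):
    """N-dimensional stride-1 convolution via one GEMM per kernel offset."""

    def __init__(
        self,
        in_channels: int,
        filters: int,
        kernel_size: tuple[int, ...],
        padding: str = "same",
        activation: str = "relu",
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__(activation)
        if padding not in ("same", "valid"):
            raise ValueError(f"unsupported padding {padding!r}")
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.filters = filters
        self.kernel_size = tuple(kernel_size)
        self.padding = padding
        k_prod = int(np.prod(self.kernel_size))
        fan_in = k_prod * in_channels
        fan_out = k_prod * filters
        # weights stored as (n_offsets * Cin, F): a single GEMM operand
        self.w = _glorot_uniform(rng, (k_prod * in_channels, filters), fan_in, fan_out)
        self.b = np.zeros(filters, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._offsets = list(itertools.product(*(range(k) for k in self.kernel_size)))

    def _pads(self) -> list[tuple[int, int]]:
        if self.padding == "same":
            return [_same_padding(k) for k in self.kernel_size]
        return [(0, 0)] * len(self.kernel_size)

    def _padded(self, x: np.ndarray) -> np.ndarray:
        pads = self._pads()
        if all(b == 0 and e == 0 for b, e in pads):
            return np.ascontiguousarray(x, dtype=DTYPE)
        shape = (
            (x.shape[0],)
            + tuple(s + b + e for s, (b, e) in zip(x.shape[1:-1], pads))
            + (x.shape[-1],)
        )
        xp = np.zeros(shape, dtype=DTYPE)
        core = (slice(None),) + tuple(
            slice(b, b + s) for s, (b, e) in zip(x.shape[1:-1], pads)
        ) + (slice(None),)
        xp[core] = x
        return xp

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = self._padded(x)
        in_spatial = xp.shape[1:-1]
        out_spatial = tuple(
            s - k + 1 for s, k in zip(in_spatial, self.kernel_size)
        )
        self._xp_shape = xp.shape
        self._out_spatial = out_spatial
        n = x.shape[0]
        flat = int(np.prod(out_spatial))
        c = self.in_channels
        cols = np.empty((n * flat, len(self._offsets) * c), dtype=DTYPE)
        for idx, off in enumerate(self._offsets):
            sl = (slice(None),) + tuple(
                slice(o, o + s) for o, s in zip(off, out_spatial)
            )
            cols[:, idx * c : (idx + 1) * c] = xp[sl].reshape(n * flat, c)
        self._cols = cols
        z = (cols @ self.w + self.b).reshape((n,) + out_spatial + (self.filters,))
        return self._activate(z)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self._deactivate(dy)
        n = dy.shape[0]
        flat = int(np.prod(self._out_spatial))
        dy2 = dy.reshape(n * flat, self.filters).astype(DTYPE, copy=False)
        self.grads[1][...] = dy2.sum(axis=0)
        np.matmul(self._cols.T, dy2, out=self.grads[0])
        dcols = dy2 @ self.w.T
        dxp = np.zeros(self._xp_shape, dtype=DTYPE)
        c = self.in_channels
        for idx, off in enumerate(self._offsets):
            sl = (slice(None),) + tuple(
                slice(o, o + s) for o, s in zip(off, self._out_spatial)
            )
            dxp[sl] += dcols[:, idx * c : (idx + 1) * c].reshape(
                (n,) + self._out_spatial + (c,)
            )
        pads = self._pads()
        sl = (slice(None),) + tuple(
            slice(b, dim - e if e else None)
            for (b, e), dim in zip(pads, dxp.shape[1:-1])
        )
        return dxp[sl]


class Conv2D(_ConvND):
    def __init__(self, in_channels, filters, kernel_size, padding="same",
                 activation="relu", rng=None):
        if len(kernel_size) != 2:
            raise ValueError("Conv2D kernel must be 2-D")
        super().__init__(in_channels, filters, kernel_size, padding, activation, rng)


class Conv3D(_ConvND):
    def __init__(self, in_channels, filters, kernel_size, padding="same",
                 activation="relu", rng=None):
        if len(kernel_size) != 3:
            raise ValueError("Conv3D kernel must be 3-D")
        super().__init__(in_channels, filters, kernel_size, padding, activation, rng)


class Dense(_Activated):
    def __init__(self, in_features, units, activation="relu", rng=None):
        super().__init__(activation)
        rng = rng or np.random.default_rng(0)
        self.w = _glorot_uniform(rng, (in_features, units), in_features, units)
        self.b = np.zeros(units, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return self._activate(x @ self.w + self.b)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self._deactivate(dy).astype(DTYPE, copy=False)
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.w.T


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, target_shape: tuple[int, ...]) -> None:
        super().__init__()
        self.target_shape = tuple(target_shape)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.target_shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Sequential:
    """A layer pipeline with all parameters consolidated into one flat
    float32 buffer (layers hold reshaped views), so the optimizer updates a
    single contiguous array."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers
        total = sum(p.size for layer in layers for p in layer.params)
        self.flat_params = np.empty(total, dtype=DTYPE)
        self.flat_grads = np.zeros(total, dtype=DTYPE)
        offset = 0
        for layer in layers:
            views, gviews = [], []
            for p in layer.params:
                view = self.flat_params[offset : offset + p.size].reshape(p.shape)
                view[...] = p
                gviews.append(
                    self.flat_grads[offset : offset + p.size].reshape(p.shape)
                )
                views.append(view)
                offset += p.size
            layer.params = views
            layer.grads = gviews
            if hasattr(layer, "w"):
                layer.w, layer.b = views

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_params(self) -> int:
        return int(self.flat_params.size)

    def get_weights(self) -> np.ndarray:
        return self.flat_params.copy()

    def set_weights(self, weights: np.ndarray) -> None:
        self.flat_params[...] = weights

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        outs = [
            self.forward(x[i : i + batch_size])
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)


try:  # fused single-pass update; the update is memory-bound in pure numpy
    import numba

    @numba.njit(cache=True, fastmath=True)
    def _adam_update(p, g, m, v, lr, beta1, beta2, eps, b1t, b2t):
        one = np.float32(1.0)
        lr = np.float32(lr)
        c1 = one - np.float32(beta1)
        c2 = one - np.float32(beta2)
        eps = np.float32(eps)
        ib1t = one / np.float32(b1t)
        ib2t = one / np.float32(b2t)
        # parameters with zero gradient (e.g. behind dead ReLU units) have
        # exponentially decaying moments; flush them to zero before they
        # reach the float32 denormal range, where CPU arithmetic is orders
        # of magnitude slower
        tiny = np.float32(1e-30)
        zero = np.float32(0.0)
        for i in range(p.size):
            gi = g[i]
            mi = m[i] + c1 * (gi - m[i])
            if -tiny < mi < tiny:
                mi = zero
            vi = v[i] + c2 * (gi * gi - v[i])
            if vi < tiny:
                vi = zero
            m[i] = mi
            v[i] = vi
            p[i] -= lr * (mi * ib1t) / (np.sqrt(vi * ib2t) + eps)

except ImportError:  # pragma: no cover - numba is a hard dependency in practice

    def _adam_update(p, g, m, v, lr, beta1, beta2, eps, b1t, b2t):
        m += (1.0 - beta1) * (g - m)
        v += (1.0 - beta2) * (g * g - v)
        tiny = 1e-30
        m[np.abs(m) < tiny] = 0.0
        v[v < tiny] = 0.0
        p -= lr * (m / b1t) / (np.sqrt(v / b2t) + eps)


class Adam:
    """Adaptive-moment gradient descent (Keras-default hyperparameters).

    Operates on a single flat parameter/gradient array with a fused
    elementwise update.
    """

    def __init__(self, params: np.ndarray, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = np.zeros_like(params)
        self.v = np.zeros_like(params)
        self.t = 0

    def step(self, grads: np.ndarray) -> None:
        self.t += 1
        _adam_update(
            self.params,
            grads,
            self.m,
            self.v,
            self.lr,
            self.beta1,
            self.beta2,
            self.eps,
            1.0 - self.beta1**self.t,
            1.0 - self.beta2**self.t,
        )


def mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


def fit(
    model: Sequential,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    epochs: int = 50,
    batch_size: int = 32,
    lr: float = 1e-3,
    rng: np.random.Generator | None = None,
) -> dict:
    """Mini-batch MSE training with per-epoch best-validation checkpointing.

    Returns a history dict with per-epoch ``train_loss``/``val_loss`` and
    ``best_epoch`` (0-based); the model is left holding the checkpointed
    (best-validation) weights.  Raises ``FloatingPointError`` on NaN loss.
    """
    rng = rng or np.random.default_rng(0)
    x_train = np.ascontiguousarray(x_train, dtype=DTYPE)
    y_train = np.ascontiguousarray(y_train, dtype=DTYPE)
    x_val = np.ascontiguousarray(x_val, dtype=DTYPE)
    y_val = np.ascontiguousarray(y_val, dtype=DTYPE)
    opt = Adam(model.flat_params, lr=lr)
    n = len(x_train)
    history: dict = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = model.get_weights()
    best_epoch = -1

    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = x_train[idx], y_train[idx]
            pred = model.forward(xb)
            yb = yb.reshape(pred.shape)
            batch_loss = mse(pred, yb)
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {batch_loss}"
                )
            epoch_loss += batch_loss * len(xb)
            model.backward((2.0 / pred.size) * (pred - yb))
            opt.step(model.flat_grads)
        val_pred = model.predict(x_val)
        val_loss = mse(val_pred, y_val.reshape(val_pred.shape))
        if not np.isfinite(val_loss):
            raise FloatingPointError(
                f"non-finite validation loss at epoch {epoch}"
            )
        history["train_loss"].append(epoch_loss / n)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch

    model.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_val
    return history
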