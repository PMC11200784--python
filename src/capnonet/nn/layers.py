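"""Layer implementations with explicit forward/backward passes.

Every layer exposes ``forward(x, train)`` and ``backward(dout)``;
trainable arrays live in ``layer.params`` with matching gradient buffers in
``layer.grads`` (filled by ``backward``).  Shapes follow the NCHW
convention and all arithmetic is float32.  The implementation is
allocation-conscious: convolutions go through a single BLAS matmul on an
im2col patch matrix, the first convolution of a network can skip its input
gradient, and consecutive 2×2/s2 max pools may be fused into one
2^s-window pool (max is associative, so the result is identical).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _f32(x: np.ndarray) -> np.ndarray:
    return x if x.dtype == np.float32 else x.astype(np.float32)


class Layer:
    """Base class: stateless pass-through with no parameters."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        return sum(int(p.size) for p in self.params.values())


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) → (B·H·W, C·k²) patch matrix for a stride-1 'same' conv."""
    pad = k // 2
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # B, C, H, W, k, k
    b, c, h, w = win.shape[:4]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        b * h * w, c * k * k
    )


def conv2d_same(x: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Stride-1 zero-padded convolution (cross-correlation), bias-free."""
    cout, cin, k, _ = weight.shape
    b, _, h, w = x.shape
    cols = _im2col(x, k)
    out = cols @ weight.reshape(cout, cin * k * k).T
    return np.ascontiguousarray(out.reshape(b, h, w, cout).transpose(0, 3, 1, 2))


class Conv2d(Layer):
    """Stride-1 'same' convolution without bias (BN follows every conv).

    ``input_grad=False`` skips the input-gradient convolution — used for a
    network's first layer, whose input needs no gradient.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int,
        rng: np.random.Generator,
        input_grad: bool = True,
    ):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.input_grad = input_grad
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.params = {"weight": w.astype(np.float32)}
        self.grads = {"weight": np.zeros_like(self.params["weight"])}
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, _, h, w = x.shape
        self._cols = _im2col(_f32(x), self.k) if train else None
        cols = self._cols if train else _im2col(_f32(x), self.k)
        out = cols @ self.params["weight"].reshape(self.cout, -1).T
        return np.ascontiguousarray(out.reshape(b, h, w, self.cout).transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, _, h, w = dout.shape
        dout = _f32(dout)
        dcols = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(
            b * h * w, self.cout
        )
        self.grads["weight"] = (dcols.T @ self._cols).reshape(
            self.params["weight"].shape
        )
        self._cols = None
        if not self.input_grad:
            return dout  # placeholder; first layer's input gradient is unused
        # dx = 'same' convolution of dout with the flipped, channel-swapped kernel
        w_flip = self.params["weight"][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        return conv2d_same(dout, np.ascontiguousarray(w_flip))


class BatchNorm2d(Layer):
    """Per-channel batch normalization with affine parameters.

    Training uses batch statistics over (B, H, W) and maintains running
    estimates (momentum 0.1) used at evaluation time.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {
            "gamma": np.ones(c, dtype=np.float32),
            "beta": np.zeros(c, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = _f32(x)
        if train:
            mean = x.mean(axis=(0, 2, 3), dtype=np.float32)
            var = x.var(axis=(0, 2, 3), dtype=np.float32)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            inv_std = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
            self._cache = (x, mean, inv_std)  # x kept by reference, no copy
        else:
            mean, inv_std = self.running_mean, 1.0 / np.sqrt(
                self.running_var + self.eps
            )
        scale = self.params["gamma"] * inv_std
        shift = self.params["beta"] - mean * scale
        out = x * scale[None, :, None, None].astype(np.float32)
        out += shift[None, :, None, None].astype(np.float32)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, mean, inv_std = self._cache
        self._cache = None
        dout = _f32(dout)
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dbeta = np.einsum("bchw->c", dout, dtype=np.float32)
        # dgamma = Σ dout·x̂ with x̂ = (x − mean)·inv_std, without forming x̂
        dxx = np.einsum("bchw,bchw->c", dout, x, dtype=np.float32)
        dgamma = inv_std * (dxx - mean * dbeta)
        self.grads["gamma"] = dgamma
        self.grads["beta"] = dbeta
        # dx = A·dout + B·x + C per channel (algebraic collapse of the
        # standard batch-norm backward)
        a = self.params["gamma"] * inv_std
        b = -a * dgamma * inv_std / n
        c = -a * dbeta / n - b * mean
        dx = dout * a[None, :, None, None]
        dx += x * b[None, :, None, None]
        dx += c[None, :, None, None]
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.maximum(x, 0, out=x)  # safe: upstream layers emit fresh arrays

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout *= self._mask  # safe: upstream backward emits fresh arrays
        self._mask = None
        return dout


class MaxPool2x2(Layer):
    """Max pooling over a 2^s × 2^s window with matching stride.

    ``stages`` consecutive 2×2/s2 pools are computed as one fused pool —
    max is associative, so the output (and the subgradient routed to the
    maximal element) is identical to applying them one by one.
    """

    def __init__(self, stages: int = 1):
        super().__init__()
        self.w = 2**stages

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, wd = x.shape
        w = self.w
        if h % w or wd % w:
            raise ValueError(f"{w}x{w}/s{w} pooling needs divisible sides, got {h}x{wd}")
        win = x.reshape(b, c, h // w, w, wd // w, w).transpose(0, 1, 2, 4, 3, 5)
        win = np.ascontiguousarray(win).reshape(b, c, h // w, wd // w, w * w)
        self._arg = win.argmax(axis=-1)
        self._inshape = x.shape
        return win.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h2, w2 = dout.shape
        w = self.w
        dwin = np.zeros((b, c, h2, w2, w * w), dtype=np.float32)
        np.put_along_axis(dwin, self._arg[..., None], _f32(dout)[..., None], axis=-1)
        self._arg = None
        dx = dwin.reshape(b, c, h2, w2, w, w).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx).reshape(self._inshape)


class GlobalAvgPool(Layer):
    """(B, C, H, W) → (B, C) spatial mean."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._inshape = x.shape
        return x.mean(axis=(2, 3), dtype=np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._inshape
        return np.broadcast_to(
            _f32(dout)[:, :, None, None] / np.float32(h * w), self._inshape
        )


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / np.float32(
            keep
        )
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cout, cin))
        self.params = {
            "weight": w.astype(np.float32),
            "bias": np.zeros(cout, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = _f32(x)
        return self._x @ self.params["weight"].T + self.params["bias"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = _f32(dout)
        self.grads["weight"] = dout.T @ self._x
        self.grads["bias"] = dout.sum(axis=0)
        return dout @ self.params["weight"]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def param_layers(self) -> list[Layer]:
        out = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                out.extend(layer.param_layers())
            elif layer.params:
                out.append(layer)
        return out

    def param_count(self) -> int:
        return sum(l.param_count() for l in self.layers)
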