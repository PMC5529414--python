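"""Small patch-classification CNN: architecture, training, inference.

The network maps a 33x33 grayscale patch (intensities on the 0-255 normalized
scale) to a two-class probability (non-cone, cone). The layer stack is::

    conv 5x5x1 -> 32   (pad 2, stride 1)        33 x 33 x 32
    batch-norm                                  33 x 33 x 32
    max-pool 3x3 stride 2                       16 x 16 x 32
    ReLU
    conv 5x5x32 -> 32  (pad 2)                  16 x 16 x 32
    batch-norm, ReLU
    avg-pool 3x3 stride 2 (pad 1 bottom/right)   8 x  8 x 32
    conv 5x5x32 -> 64  (pad 2)                   8 x  8 x 64
    batch-norm, ReLU
    avg-pool 3x3 stride 2 (pad 1 bottom/right)   4 x  4 x 64
    fully connected 4x4x64 -> 64
    batch-norm, ReLU
    fully connected 64 -> 2
    soft-max

Pooling uses a 3x3 window with stride 2; the asymmetric zero padding on the
average-pooling layers produces the 16 -> 8 -> 4 spatial sizes, while
33 -> 16 needs none. Forward, backward, and SGD (momentum, weight decay,
learning-rate drops) are implemented here in NumPy so that training is
exactly reproducible on a single thread.

Activations are kept channels-last (N, H, W, C): per-pixel detection
classifies tens of thousands of overlapping patches per image, and in this
layout every convolution reduces to a handful of BLAS matrix products, which
is what makes CPU-only sliding-window inference practical.

Class ordering is fixed: index 0 = non-cone, index 1 = cone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.linalg import get_blas_funcs

__all__ = [
    "TrainingConfig",
    "ConeCNN",
    "build_network",
    "train_network",
    "predict_proba",
    "parameter_shapes",
    "DivergenceError",
    "PATCH_SIZE",
    "CLASS_NONCONE",
    "CLASS_CONE",
]

PATCH_SIZE = 33
CLASS_NONCONE, CLASS_CONE = 0, 1


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def _gemm_accum(out2: np.ndarray, X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """``out2 += X @ W`` through BLAS gemm with beta=1 (no temporaries).

    ``out2`` (m, o) and ``X`` (m, k) must be C-contiguous; computed as
    ``out2.T = W.T @ X.T + out2.T`` on the F-contiguous transposed views.
    """
    gemm = get_blas_funcs("gemm", (out2, X, W))
    gemm(1.0, W.T, X.T, beta=1.0, c=out2.T, overwrite_c=True)
    return out2


@dataclass
class TrainingConfig:
    """SGD hyper-parameters.

    Defaults are the full-scale published schedule: mini-batches of 100,
    45 epochs, weight learning rate 1e-3 (1e-4 for the final fully-connected
    layer), bias learning rate 0.1 (0.01 for the final layer), both dropped
    by a factor of 10 entering epochs 31 and 41, and weight decay 1e-4.
    Momentum 0.9 is the toolbox-default reading; set it to 0 for plain SGD.
    """

    minibatch_size: int = 100
    epochs: int = 45
    lr_weights: float = 1e-3
    lr_biases: float = 0.1
    final_fc_lr_weights: float = 1e-4
    final_fc_lr_biases: float = 1e-2
    lr_drop_factor: float = 10.0
    lr_drop_epochs: tuple[int, ...] = (31, 41)
    weight_decay: float = 1e-4
    momentum: float = 0.9
    init_std: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.lr_drop_epochs = tuple(self.lr_drop_epochs)
        for name in ("lr_weights", "lr_biases", "final_fc_lr_weights", "final_fc_lr_biases"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.epochs < 1 or self.minibatch_size < 1:
            raise ValueError("epochs and minibatch_size must be >= 1")
        if any(not 1 <= e < self.epochs for e in self.lr_drop_epochs):
            raise ValueError("lr_drop_epochs must lie in [1, epochs)")

    def lr_factor(self, epoch: int) -> float:
        """Schedule multiplier for a 1-based epoch number."""
        drops = sum(1 for e in self.lr_drop_epochs if epoch >= e)
        return self.lr_drop_factor ** -drops

    def scaled(self, epochs: int) -> "TrainingConfig":
        """A reduced-epoch config with drops at the same relative positions
        (31/45 and 41/45) as the full schedule."""
        drops = tuple(sorted({
            max(2, min(epochs - 1, round(e * epochs / self.epochs)))
            for e in self.lr_drop_epochs
        })) if epochs >= 3 else ()
        d = self.to_dict()
        d["epochs"] = epochs
        d["lr_drop_epochs"] = drops
        return TrainingConfig.from_dict(d)

    def to_dict(self) -> dict:
        return {
            "minibatch_size": self.minibatch_size,
            "epochs": self.epochs,
            "lr_weights": self.lr_weights,
            "lr_biases": self.lr_biases,
            "final_fc_lr_weights": self.final_fc_lr_weights,
            "final_fc_lr_biases": self.final_fc_lr_biases,
            "lr_drop_factor": self.lr_drop_factor,
            "lr_drop_epochs": list(self.lr_drop_epochs),
            "weight_decay": self.weight_decay,
            "momentum": self.momentum,
            "init_std": self.init_std,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        d = dict(d)
        d["lr_drop_epochs"] = tuple(d.get("lr_drop_epochs", ()))
        return cls(**d)


# ---------------------------------------------------------------------------
# Parameters and layers
# ---------------------------------------------------------------------------

class Param:
    """A learnable array with its gradient and SGD metadata."""

    __slots__ = ("name", "value", "grad", "kind", "decay", "momentum_buf")

    def __init__(self, name: str, value: np.ndarray, kind: str, decay: bool):
        self.name = name
        self.value = value
        self.grad: np.ndarray | None = None
        self.kind = kind  # "weight"/"bias"/"final_weight"/"final_bias"
        self.decay = decay
        self.momentum_buf: np.ndarray | None = None


class Layer:
    name = "layer"
    params: list[Param] = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """'Same' convolution (pad k//2, stride 1), channels-last.

    Multi-channel input uses one GEMM per kernel tap accumulated into the
    output ("shift-and-multiply"); single-channel input builds a (k*k, n)
    column matrix with contiguous writes and uses a single GEMM. Both paths
    are mathematically the plain zero-padded convolution.
    """

    def __init__(self, name: str, in_ch: int, out_ch: int, ksize: int,
                 rng: np.random.Generator, init_std: float, dtype):
        self.name = name
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, ksize
        self.pad = ksize // 2
        W = rng.normal(0.0, init_std, size=(ksize, ksize, in_ch, out_ch)).astype(dtype)
        self.W = Param(f"{name}.W", W, "weight", decay=True)
        self.b = Param(f"{name}.b", np.zeros(out_ch, dtype=dtype), "bias", decay=False)
        self.params = [self.W, self.b]
        self._cache = None
        self._tmp = None  # reused shift buffer (inference hot path)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        k, p, o = self.k, self.pad, self.out_ch
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        Wv = self.W.value
        if c == 1:
            cols_t = np.empty((k * k, n * h * w), dtype=x.dtype)
            for i in range(k):
                for j in range(k):
                    cols_t[i * k + j] = xp[:, i:i + h, j:j + w, 0].ravel()
            out2 = cols_t.T @ Wv.reshape(k * k, o)
            if train:
                self._cache = (cols_t, (n, h, w, c))
        else:
            out2 = np.zeros((n * h * w, o), dtype=x.dtype)
            if self._tmp is None or self._tmp.shape != (n, h, w, c) or self._tmp.dtype != x.dtype:
                self._tmp = np.empty((n, h, w, c), dtype=x.dtype)
            tmp = self._tmp
            for i in range(k):
                for j in range(k):
                    np.copyto(tmp, xp[:, i:i + h, j:j + w, :])
                    _gemm_accum(out2, tmp.reshape(-1, c), Wv[i, j])
            if train:
                self._cache = (xp, (n, h, w, c))
        out2 += self.b.value
        return out2.reshape(n, h, w, o)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cached, (n, h, w, c) = self._cache
        self._cache = None
        k, p, o = self.k, self.pad, self.out_ch
        dm = dout.reshape(-1, o)
        self.b.grad = dm.sum(axis=0)
        dW = np.empty_like(self.W.value)
        if c == 1:
            cols_t = cached
            dW[:] = (cols_t @ dm).reshape(k, k, 1, o)
            dcols = dm @ self.W.value.reshape(k * k, o).T  # (nhw, k*k)
            dxp = np.zeros((n, h + 2 * p, w + 2 * p, 1), dtype=dout.dtype)
            for i in range(k):
                for j in range(k):
                    dxp[:, i:i + h, j:j + w, 0] += dcols[:, i * k + j].reshape(n, h, w)
        else:
            xp = cached
            dxp = np.zeros_like(xp)
            Wv = self.W.value
            for i in range(k):
                for j in range(k):
                    xs = np.ascontiguousarray(xp[:, i:i + h, j:j + w, :]).reshape(-1, c)
                    dW[i, j] = xs.T @ dm
                    dxp[:, i:i + h, j:j + w, :] += (dm @ Wv[i, j].T).reshape(n, h, w, c)
        self.W.grad = dW
        return dxp[:, p:p + h, p:p + w, :] if p else dxp


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial) dimensions."""

    def __init__(self, name: str, ch: int, dtype, eps: float = 1e-5, bn_momentum: float = 0.1):
        self.name = name
        self.eps = eps
        self.bn_momentum = bn_momentum
        self.gamma = Param(f"{name}.gamma", np.ones(ch, dtype=dtype), "weight", decay=False)
        self.beta = Param(f"{name}.beta", np.zeros(ch, dtype=dtype), "bias", decay=False)
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.params = [self.gamma, self.beta]
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.bn_momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * ivar
        out = self.gamma.value * xhat + self.beta.value
        if train:
            self._cache = (xhat, ivar, axes)
        return out.astype(x.dtype, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivar, axes = self._cache
        self._cache = None
        m = float(np.prod([dout.shape[a] for a in axes]))
        self.gamma.grad = (dout * xhat).sum(axis=axes)
        self.beta.grad = dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        s1 = dxhat.sum(axis=axes) / m
        s2 = (dxhat * xhat).sum(axis=axes) / m
        dx = (dxhat - s1 - xhat * s2) * ivar
        return dx.astype(dout.dtype, copy=False)


class ReLU(Layer):
    def __init__(self, name: str):
        self.name = name
        self.params = []
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


def _pool_out_size(size: int, k: int, s: int, pad: int) -> int:
    return (size + pad - k) // s + 1


class MaxPool(Layer):
    """3x3 max pooling, stride 2, no padding (33 -> 16)."""

    def __init__(self, name: str, ksize: int = 3, stride: int = 2):
        self.name = name
        self.k, self.s = ksize, stride
        self.params = []
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, s = self.k, self.s
        n, h, w, c = x.shape
        oh, ow = _pool_out_size(h, k, s, 0), _pool_out_size(w, k, s, 0)
        if train:
            win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::s, ::s]  # (n,oh,ow,c,k,k)
            flat = win.reshape(n, oh, ow, c, k * k)
            arg = flat.argmax(axis=4)
            out = np.take_along_axis(flat, arg[..., None], axis=4)[..., 0]
            self._cache = (arg, x.shape)
            return np.ascontiguousarray(out)
        # separable max (rows then columns) halves the memory traffic
        rows = np.full((n, oh, w, c), -np.inf, dtype=x.dtype)
        for i in range(k):
            np.maximum(rows, x[:, i:i + (oh - 1) * s + 1:s, :, :], out=rows)
        out = np.full((n, oh, ow, c), -np.inf, dtype=x.dtype)
        for j in range(k):
            np.maximum(out, rows[:, :, j:j + (ow - 1) * s + 1:s, :], out=out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        arg, in_shape = self._cache
        self._cache = None
        n, oh, ow, c = dout.shape
        k, s = self.k, self.s
        dx = np.zeros(in_shape, dtype=dout.dtype)
        ns, ohs, ows, cs = np.ix_(np.arange(n), np.arange(oh), np.arange(ow), np.arange(c))
        np.add.at(dx, (ns, ohs * s + arg // k, ows * s + arg % k, cs), dout)
        return dx


class AvgPool(Layer):
    """3x3 average pooling, stride 2, asymmetric zero pad bottom/right.

    The divisor is the full window size (9) including padded zeros; with
    pad 1 this maps 16 -> 8 and 8 -> 4.
    """

    def __init__(self, name: str, ksize: int = 3, stride: int = 2, pad_br: int = 1):
        self.name = name
        self.k, self.s, self.pad_br = ksize, stride, pad_br
        self.params = []
        self._in_shape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, s, p = self.k, self.s, self.pad_br
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (0, p), (0, p), (0, 0))) if p else x
        oh, ow = _pool_out_size(h, k, s, p), _pool_out_size(w, k, s, p)
        out = np.zeros((n, oh, ow, c), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                out += xp[:, i:i + (oh - 1) * s + 1:s, j:j + (ow - 1) * s + 1:s, :]
        out /= k * k
        if train:
            self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        self._in_shape = None
        k, s, p = self.k, self.s, self.pad_br
        oh, ow = dout.shape[1], dout.shape[2]
        dxp = np.zeros((n, h + p, w + p, c), dtype=dout.dtype)
        g = dout / (k * k)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + (oh - 1) * s + 1:s, j:j + (ow - 1) * s + 1:s, :] += g
        return dxp[:, :h, :w, :] if p else dxp


class Flatten(Layer):
    def __init__(self, name: str):
        self.name = name
        self.params = []
        self._shape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        shape = self._shape
        self._shape = None
        return dout.reshape(shape)


class Dense(Layer):
    def __init__(self, name: str, in_f: int, out_f: int, rng: np.random.Generator,
                 init_std: float, dtype, final: bool = False):
        self.name = name
        W = rng.normal(0.0, init_std, size=(out_f, in_f)).astype(dtype)
        kinds = ("final_weight", "final_bias") if final else ("weight", "bias")
        self.W = Param(f"{name}.W", W, kinds[0], decay=True)
        self.b = Param(f"{name}.b", np.zeros(out_f, dtype=dtype), kinds[1], decay=False)
        self.params = [self.W, self.b]
        self._x = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        self._x = None
        self.W.grad = dout.T @ x
        self.b.grad = dout.sum(axis=0)
        return dout @ self.W.value


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

class ConeCNN:
    """The 17-layer cone / non-cone patch classifier."""

    def __init__(self, seed: int = 0, init_std: float = 0.01, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.dtype = dtype
        self.seed = seed
        self.layers: list[Layer] = [
            Conv2D("conv1", 1, 32, 5, rng, init_std, dtype),
            BatchNorm("bn1", 32, dtype),
            MaxPool("pool1"),
            ReLU("relu1"),
            Conv2D("conv2", 32, 32, 5, rng, init_std, dtype),
            BatchNorm("bn2", 32, dtype),
            ReLU("relu2"),
            AvgPool("pool2"),
            Conv2D("conv3", 32, 64, 5, rng, init_std, dtype),
            BatchNorm("bn3", 64, dtype),
            ReLU("relu3"),
            AvgPool("pool3"),
            Flatten("flatten"),
            Dense("fc1", 4 * 4 * 64, 64, rng, init_std, dtype),
            BatchNorm("bn4", 64, dtype),
            ReLU("relu4"),
            Dense("fc2", 64, 2, rng, init_std, dtype, final=True),
        ]
        self._check_shapes()

    # -- structure ---------------------------------------------------------

    #: the (height, width, channels) contract after each named layer
    SHAPE_CONTRACT = {
        "conv1": (33, 33, 32),
        "pool1": (16, 16, 32),
        "conv2": (16, 16, 32),
        "pool2": (8, 8, 32),
        "conv3": (8, 8, 64),
        "pool3": (4, 4, 64),
        "fc1": (64,),
        "fc2": (2,),
    }

    def _check_shapes(self) -> None:
        for name, shape in self.activation_shapes().items():
            want = self.SHAPE_CONTRACT.get(name)
            if want is not None and shape != want:
                raise ValueError(f"layer {name}: activation shape {shape} != contract {want}")

    def activation_shapes(self, patch_size: int = PATCH_SIZE) -> dict[str, tuple[int, ...]]:
        """Output shape after each layer for a single patch, as
        (height, width, channels) tuples (vectors as (features,))."""
        x = np.zeros((1, patch_size, patch_size, 1), dtype=self.dtype)
        shapes: dict[str, tuple[int, ...]] = {}
        for layer in self.layers:
            x = layer.forward(x, train=False)
            shapes[layer.name] = tuple(x.shape[1:])
        return shapes

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def parameter_count(self) -> int:
        return sum(p.value.size for p in self.params)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits (n, 2) for a batch of patches (n, 33, 33, 1)."""
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    # -- fast inference -----------------------------------------------------
    #
    # At detection time the classifier is applied to every pixel of an image
    # (tens of thousands of overlapping patches), so inference goes through a
    # fused plan: each batch-norm layer, being affine with frozen running
    # statistics, is folded into the convolution / fully-connected layer that
    # precedes it (W' = W * gamma/sqrt(var+eps), with the matching bias shift).
    # This is exact linear algebra, not an approximation; it only removes
    # full-image temporaries.

    def _layer(self, name: str) -> Layer:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(name)

    def _inference_plan(self) -> dict:
        def fold(lin: Layer, bn: BatchNorm, conv: bool):
            scale = bn.gamma.value / np.sqrt(bn.running_var + bn.eps)
            shift = bn.beta.value - bn.running_mean * scale
            if conv:
                Wf = np.ascontiguousarray(lin.W.value * scale)  # scale last (out) axis
            else:
                Wf = np.ascontiguousarray(lin.W.value * scale[:, None])
            bf = lin.b.value * scale + shift
            return Wf.astype(self.dtype), bf.astype(self.dtype)

        return {
            "conv1": fold(self._layer("conv1"), self._layer("bn1"), conv=True),
            "conv2": fold(self._layer("conv2"), self._layer("bn2"), conv=True),
            "conv3": fold(self._layer("conv3"), self._layer("bn3"), conv=True),
            "fc1": fold(self._layer("fc1"), self._layer("bn4"), conv=False),
            "fc2": (self._layer("fc2").W.value, self._layer("fc2").b.value),
        }

    def _conv_eval(self, x: np.ndarray, W: np.ndarray, b: np.ndarray,
                   bufs: dict) -> np.ndarray:
        n, h, w, c = x.shape
        k = W.shape[0]
        o = W.shape[3]
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        if c == 1:
            key = ("cols", n, h, w, k)
            if key not in bufs:
                bufs[key] = np.empty((k * k, n * h * w), dtype=self.dtype)
            cols_t = bufs[key]
            for i in range(k):
                for j in range(k):
                    cols_t[i * k + j] = xp[:, i:i + h, j:j + w, 0].ravel()
            out2 = cols_t.T @ W.reshape(k * k, o)
        else:
            key = ("tmp", n, h, w, c)
            if key not in bufs:
                bufs[key] = np.empty((n, h, w, c), dtype=self.dtype)
            tmp = bufs[key]
            out2 = np.zeros((n * h * w, o), dtype=self.dtype)
            for i in range(k):
                for j in range(k):
                    np.copyto(tmp, xp[:, i:i + h, j:j + w, :])
                    _gemm_accum(out2, tmp.reshape(-1, c), W[i, j])
        out2 += b
        return out2.reshape(n, h, w, o)

    def _forward_fused(self, x: np.ndarray, plan: dict, bufs: dict) -> np.ndarray:
        x = self._conv_eval(x, *plan["conv1"], bufs)
        x = self._layer("pool1").forward(x, train=False)
        np.maximum(x, 0, out=x)
        x = self._conv_eval(x, *plan["conv2"], bufs)
        np.maximum(x, 0, out=x)
        x = self._layer("pool2").forward(x, train=False)
        x = self._conv_eval(x, *plan["conv3"], bufs)
        np.maximum(x, 0, out=x)
        x = self._layer("pool3").forward(x, train=False)
        x = x.reshape(x.shape[0], -1)
        Wf, bf = plan["fc1"]
        x = x @ Wf.T + bf
        np.maximum(x, 0, out=x)
        Wl, bl = plan["fc2"]
        return x @ Wl.T + bl

    def predict_proba(self, patches: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Cone probability for each 33x33 patch.

        Accepts (33, 33), (n, 33, 33) or (n, 33, 33, 1); returns (n,) floats
        in [0, 1] (p(cone) + p(non-cone) = 1 by soft-max). Batched evaluation
        equals one-at-a-time evaluation: the network has no cross-patch state
        at inference (batch-norm uses frozen running statistics).
        """
        patches = np.asarray(patches)
        if patches.ndim == 2:
            patches = patches[None]
        if patches.ndim == 3:
            patches = patches[..., None]
        if patches.shape[1:] != (PATCH_SIZE, PATCH_SIZE, 1):
            raise ValueError(
                f"patches must be {PATCH_SIZE}x{PATCH_SIZE}, got {patches.shape[1:]}")
        plan = self._inference_plan()
        bufs: dict = {}
        out = np.empty(len(patches), dtype=np.float64)
        for lo in range(0, len(patches), batch_size):
            chunk = np.ascontiguousarray(
                patches[lo:lo + batch_size].astype(self.dtype, copy=False))
            logits = self._forward_fused(chunk, plan, bufs)
            out[lo:lo + batch_size] = softmax(logits.astype(np.float64))[:, CLASS_CONE]
        return out

    # -- (de)serialization ---------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {p.name: p.value.copy() for p in self.params}
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                arrays[f"{layer.name}.running_mean"] = layer.running_mean.copy()
                arrays[f"{layer.name}.running_var"] = layer.running_var.copy()
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for p in self.params:
            v = np.asarray(arrays[p.name], dtype=self.dtype)
            if v.shape != p.value.shape:
                raise ValueError(f"{p.name}: shape {v.shape} != {p.value.shape}")
            p.value = v.copy()
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(
                    arrays[f"{layer.name}.running_mean"], dtype=self.dtype).copy()
                layer.running_var = np.asarray(
                    arrays[f"{layer.name}.running_var"], dtype=self.dtype).copy()


def parameter_shapes() -> dict[str, tuple[int, ...]]:
    """Canonical array shapes of a serialized model (used to validate bundles)."""
    return {k: tuple(v.shape) for k, v in ConeCNN(seed=0).state_arrays().items()}


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_network(seed: int = 0, init_std: float = 0.01, dtype=np.float32) -> ConeCNN:
    """A freshly initialized network (Gaussian weights, std ``init_std``; zero biases)."""
    return ConeCNN(seed=seed, init_std=init_std, dtype=dtype)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _loss_and_grad(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, int]:
    """Mean cross-entropy, gradient w.r.t. logits, and #correct predictions."""
    n = len(labels)
    p = softmax(logits.astype(np.float64))
    loss = -np.log(p[np.arange(n), labels] + 1e-12).mean()
    grad = p
    grad[np.arange(n), labels] -= 1.0
    grad /= n
    correct = int((logits.argmax(axis=1) == labels).sum())
    return float(loss), grad.astype(logits.dtype), correct


def train_network(
    net: ConeCNN,
    patches: np.ndarray,
    labels: np.ndarray,
    config: TrainingConfig,
    log: Callable[[dict], None] | None = None,
) -> list[dict]:
    """Train ``net`` in place by mini-batch SGD; returns the per-epoch log.

    ``patches``: (n, 33, 33) floats on the 0-255 normalized scale;
    ``labels``: (n,) ints in {0 = non-cone, 1 = cone}; both classes must be
    present. Mini-batches are drawn by a fresh shuffle each epoch from the
    config seed, so a run is bit-reproducible single-threaded.
    """
    patches = np.asarray(patches)
    labels = np.asarray(labels, dtype=np.int64)
    if patches.ndim == 3:
        patches = patches[..., None]
    if patches.shape[1:] != (PATCH_SIZE, PATCH_SIZE, 1):
        raise ValueError(f"patches must be n x {PATCH_SIZE} x {PATCH_SIZE}")
    if len(patches) != len(labels):
        raise ValueError("patches and labels differ in length")
    classes = np.unique(labels)
    if not np.array_equal(classes, [CLASS_NONCONE, CLASS_CONE]):
        raise ValueError(f"training set must contain both classes, got labels {classes}")

    x_all = patches.astype(net.dtype, copy=False)
    rng = np.random.default_rng(config.seed)
    lr_of_kind = {
        "weight": config.lr_weights,
        "bias": config.lr_biases,
        "final_weight": config.final_fc_lr_weights,
        "final_bias": config.final_fc_lr_biases,
    }
    history: list[dict] = []
    n = len(labels)
    bs = config.minibatch_size
    for epoch in range(1, config.epochs + 1):
        factor = config.lr_factor(epoch)
        perm = rng.permutation(n)
        losses, correct = [], 0
        for lo in range(0, n, bs):
            idx = perm[lo:lo + bs]
            logits = net.forward(x_all[idx], train=True)
            loss, dlogits, c = _loss_and_grad(logits, labels[idx])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}, batch {lo // bs}")
            losses.append(loss)
            correct += c
            net.backward(dlogits)
            for p in net.params:
                lr = factor * lr_of_kind[p.kind]
                g = p.grad
                if p.decay and config.weight_decay:
                    g = g + config.weight_decay * p.value
                if config.momentum:
                    if p.momentum_buf is None:
                        p.momentum_buf = np.zeros_like(p.value)
                    p.momentum_buf = config.momentum * p.momentum_buf - lr * g
                    p.value = p.value + p.momentum_buf
                else:
                    p.value = p.value - lr * g
                p.grad = None
        rec = {
            "epoch": epoch,
            "mean_loss": float(np.mean(losses)),
            "train_accuracy": correct / n,
            "lr_factor": factor,
        }
        history.append(rec)
        if log is not None:
            log(rec)
    return history


def predict_proba(net: ConeCNN, patches: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`ConeCNN.predict_proba`."""
    return net.predict_proba(patches)
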