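"""Small NumPy neural-net substrate: layers, SGD-momentum, checkpoints.

Layers operate on batches shaped ``(N, C, H, W)`` and compute in the
input's dtype (training uses float32 for speed; attribution and numerical
tests can pass float64).  Convolutions and pools use TF-style "same"
padding resolved per input shape (total padding
``max((ceil(in/s)-1)*s + k - in, 0)``, split before/after with the extra
sample after), which is what reproduces the published activation-shape
chain exactly.  Every layer caches what its backward pass and the
relevance-propagation rules need, so the same objects serve training,
inference, and attribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# Training repeatedly allocates and frees multi-hundred-MB im2col buffers.
# Keep them on the main heap (no per-buffer mmap/munmap churn, so pages are
# faulted in once and reused) while still trimming the heap beyond a 64 MB
# slack so memory is bounded over long sessions.
try:  # glibc only; harmless elsewhere
    import ctypes

    _libc = ctypes.CDLL("libc.so.6", use_errno=True)
    _libc.mallopt(-4, 0)                  # M_MMAP_MAX = 0
    _libc.mallopt(-1, 64 * 1024 * 1024)   # M_TRIM_THRESHOLD = 64 MB
except Exception:  # pragma: no cover
    pass


def same_pad(size: int, kernel: int, stride: int) -> tuple[int, int]:
    out = -(-size // stride)  # ceil division
    total = max((out - 1) * stride + kernel - size, 0)
    return total // 2, total - total // 2


def _out_hw(shape: tuple, stride: tuple[int, int]) -> tuple[int, int]:
    return -(-shape[2] // stride[0]), -(-shape[3] // stride[1])


def _windows(xp: np.ndarray, kernel: tuple[int, int], stride: tuple[int, int],
             oh: int, ow: int) -> np.ndarray:
    """(N, C, oh, ow, kh, kw) strided view of the padded input."""
    v = sliding_window_view(xp, kernel, axis=(2, 3))
    return v[:, :, :: stride[0], :: stride[1]][:, :, :oh, :ow]


class Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_trainable(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv2d(Layer):
    """Same-padded 2-D convolution, weight (O, C, kh, kw)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int],
                 stride: tuple[int, int], rng: np.random.Generator) -> None:
        super().__init__()
        kh, kw = kernel
        fan_in = in_ch * kh * kw
        bound = 1.0 / np.sqrt(fan_in)
        self.params["w"] = rng.uniform(-bound, bound, size=(out_ch, in_ch, kh, kw))
        self.params["b"] = rng.uniform(-bound, bound, size=out_ch)
        self.kernel = kernel
        self.stride = stride

    def _geometry(self, shape: tuple) -> tuple:
        ph = same_pad(shape[2], self.kernel[0], self.stride[0])
        pw = same_pad(shape[3], self.kernel[1], self.stride[1])
        oh, ow = _out_hw(shape, self.stride)
        return ph, pw, oh, ow

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(C*kh*kw, N*oh*ow) contiguous patch matrix (one gather per pass)."""
        ph, pw, oh, ow = self._geometry(x.shape)
        xp = np.pad(x, ((0, 0), (0, 0), ph, pw))
        v = _windows(xp, self.kernel, self.stride, oh, ow)  # (N,C,oh,ow,kh,kw)
        cols = np.ascontiguousarray(v.transpose(1, 4, 5, 0, 2, 3))
        return cols.reshape(-1, x.shape[0] * oh * ow)

    def _col2im(self, gcols_t: np.ndarray, x_shape: tuple) -> np.ndarray:
        """Scatter a (N*oh*ow, C*kh*kw) patch-gradient matrix back to input."""
        (kh, kw), (sh, sw) = self.kernel, self.stride
        ph, pw, oh, ow = self._geometry(x_shape)
        n, in_ch = x_shape[0], x_shape[1]
        g = gcols_t.reshape(n, oh, ow, in_ch, kh, kw)
        g = np.ascontiguousarray(g.transpose(0, 3, 4, 5, 1, 2))  # (N,C,kh,kw,oh,ow)
        gxp = np.zeros(
            (n, in_ch, x_shape[2] + sum(ph), x_shape[3] + sum(pw)), dtype=gcols_t.dtype
        )
        for p in range(kh):
            for q in range(kw):
                gxp[:, :, p : p + sh * oh : sh, q : q + sw * ow : sw] += g[:, :, p, q]
        return gxp[:, :, ph[0] : ph[0] + x_shape[2], pw[0] : pw[0] + x_shape[3]]

    def conv(self, x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
             cols: np.ndarray | None = None) -> np.ndarray:
        """Convolve with explicit parameters (batch-norm folding, LRP)."""
        n = x.shape[0]
        _, _, oh, ow = self._geometry(x.shape)
        if cols is None:
            cols = self._im2col(x)
        w2 = w.reshape(w.shape[0], -1).astype(x.dtype, copy=False)
        out = (w2 @ cols).reshape(w.shape[0], n, oh, ow)
        out = np.ascontiguousarray(out.transpose(1, 0, 2, 3))
        if b is not None:
            out += b.astype(x.dtype, copy=False)[None, :, None, None]
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._cols = self._im2col(x)
        out = self.conv(x, self.params["w"], self.params["b"], cols=self._cols)
        self.last_input = x
        self.last_output = out
        return out

    def input_grad(self, grad: np.ndarray, x_ref: np.ndarray,
                   w: np.ndarray | None = None) -> np.ndarray:
        """Transpose-convolution of ``grad`` back to input coordinates."""
        if w is None:
            w = self.params["w"]
        w2 = w.reshape(w.shape[0], -1).astype(grad.dtype, copy=False)
        n = x_ref.shape[0]
        _, _, oh, ow = self._geometry(x_ref.shape)
        g_t = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, grad.shape[1])
        return self._col2im(g_t @ w2, x_ref.shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self.last_input
        n = x.shape[0]
        _, _, oh, ow = self._geometry(x.shape)
        g2 = np.ascontiguousarray(grad.transpose(1, 0, 2, 3)).reshape(
            grad.shape[1], n * oh * ow
        )
        self.grads["w"] = (g2 @ self._cols.T).reshape(self.params["w"].shape)
        self.grads["b"] = grad.sum(axis=(0, 2, 3))
        self._cols = None  # release the patch buffer before the next big alloc
        return self.input_grad(grad, x)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._collect: list | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3), dtype=np.float64)
            var = x.var(axis=(0, 2, 3), dtype=np.float64)
            if self._collect is not None:
                n = x.shape[0] * x.shape[2] * x.shape[3]
                self._collect.append((n, mean, var))
            else:
                self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
                self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(x.dtype)
        mean = mean.astype(x.dtype)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std)
        gamma = self.params["gamma"].astype(x.dtype)
        beta = self.params["beta"].astype(x.dtype)
        out = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
        self.last_input = x
        self.last_output = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        gamma = self.params["gamma"].astype(grad.dtype)
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.grads["gamma"] = np.einsum("ncij,ncij->c", grad, xhat)
        self.grads["beta"] = grad.sum(axis=(0, 2, 3))
        gxhat = grad * gamma[None, :, None, None]
        gx = (
            gxhat
            - gxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (np.einsum("ncij,ncij->c", gxhat, xhat) / n)[None, :, None, None].astype(grad.dtype)
        ) / std[None, :, None, None]
        return gx

    # population-statistics finalization (post-training full-data pass)
    def finalize_begin(self) -> None:
        self._collect = []

    def finalize_end(self) -> None:
        assert self._collect is not None
        total = sum(n for n, _, _ in self._collect)
        mean = sum(n * m for n, m, _ in self._collect) / total
        # pooled population variance: E[x^2] - E[x]^2
        ex2 = sum(n * (v + m**2) for n, m, v in self._collect) / total
        self.running_mean = mean
        self.running_var = np.maximum(ex2 - mean**2, 0.0)
        self._collect = None

    def inference_affine(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-channel (scale, shift) of the frozen inference transform."""
        scale = self.params["gamma"] / np.sqrt(self.running_var + self.eps)
        shift = self.params["beta"] - scale * self.running_mean
        return scale, shift


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        self.last_input = x
        self.last_output = x * self._mask
        return self.last_output

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2d(Layer):
    """Same-padded max pool; remembers the argmax for backward/winner-take-all."""

    def __init__(self, kernel: tuple[int, int], stride: tuple[int, int]) -> None:
        super().__init__()
        self.kernel = kernel
        self.stride = stride

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        (kh, kw), (sh, sw) = self.kernel, self.stride
        ph = same_pad(x.shape[2], kh, sh)
        pw = same_pad(x.shape[3], kw, sw)
        fill = np.finfo(x.dtype).min if np.issubdtype(x.dtype, np.floating) else np.iinfo(x.dtype).min
        xp = np.pad(x, ((0, 0), (0, 0), ph, pw), constant_values=fill)
        oh, ow = _out_hw(x.shape, self.stride)
        v = _windows(xp, self.kernel, self.stride, oh, ow).reshape(
            x.shape[0], x.shape[1], oh, ow, kh * kw
        )
        arg = v.argmax(axis=-1)
        out = np.take_along_axis(v, arg[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, xp.shape, ph, pw, arg, oh, ow)
        self.last_input = x
        self.last_output = out
        return out

    def scatter(self, grad: np.ndarray) -> np.ndarray:
        """Route each output's value to its argmax input position."""
        (kh, kw), (sh, sw) = self.kernel, self.stride
        x_shape, xp_shape, ph, pw, arg, oh, ow = self._cache
        gxp = np.zeros(xp_shape, dtype=grad.dtype)
        for p in range(kh):
            for q in range(kw):
                sel = (arg == p * kw + q) * grad
                gxp[:, :, p : p + sh * oh : sh, q : q + sw * ow : sw] += sel
        return gxp[:, :, ph[0] : ph[0] + x_shape[2], pw[0] : pw[0] + x_shape[3]]

    backward = scatter


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        self.last_input = x
        self.last_output = x.reshape(x.shape[0], -1)
        return self.last_output

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.params["w"] = rng.uniform(-bound, bound, size=(out_features, in_features))
        self.params["b"] = rng.uniform(-bound, bound, size=out_features)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        w = self.params["w"].astype(x.dtype, copy=False)
        b = self.params["b"].astype(x.dtype, copy=False)
        self.last_input = x
        self.last_output = x @ w.T + b
        return self.last_output

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["w"] = grad.T @ self.last_input
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["w"].astype(grad.dtype, copy=False)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on the softmax output and its logit gradient."""
    p = softmax(logits)
    n = len(targets)
    loss = -np.mean(np.log(p[np.arange(n), targets] + 1e-12))
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return float(loss), grad / n


@dataclass
class SGDMomentum:
    """SGD with classical momentum and L2 weight decay added to the gradient."""

    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4

    def __post_init__(self) -> None:
        self._velocity: dict[int, dict[str, np.ndarray]] = {}

    def step(self, layers: list[Layer]) -> None:
        for li, layer in enumerate(layers):
            if not layer.params:
                continue
            vel = self._velocity.setdefault(
                li, {k: np.zeros_like(v) for k, v in layer.params.items()}
            )
            for k, p in layer.params.items():
                g = layer.grads[k].astype(np.float64) + self.weight_decay * p
                vel[k] = self.momentum * vel[k] - self.lr * g
                p += vel[k]
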