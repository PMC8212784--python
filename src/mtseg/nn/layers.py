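"""Minimal 3D CNN building blocks on numpy with explicit backpropagation.

Everything the segmentation network needs — 3D convolution, transposed
convolution, batch normalization, ReLU — implemented channel-first
(N, C, D, H, W) in float32.  Convolutions are lowered to matrix products
(im2col) so the heavy lifting is a BLAS GEMM; two layouts cover the
cases the architecture uses:

* stride 1 with symmetric zero padding (3×3×3 body convolutions and
  1×1×1 heads), where the input gradient is itself a correlation with
  the flipped, channel-transposed kernel;
* stride equal to the kernel extent with no padding (2×2×2 down- and
  up-sampling), where windows do not overlap and im2col degenerates to a
  reshape, making the backward pass an exact inverse reshape.

Each layer owns ``params`` and ``grads`` dicts; ``forward`` caches what
``backward`` needs.  Layers are seeded through a numpy Generator passed
at construction (He-style weight initialization).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Layer", "Conv3d", "ConvTranspose3d", "BatchNorm3d", "InstanceNorm3d", "ReLU", "ConvUnit", "softmax", "sigmoid"]


class Layer:
    """Base class: parameter/gradient registry plus train/eval mode."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def named_params(self, prefix: str = "") -> dict[str, np.ndarray]:
        return {prefix + k: v for k, v in self.params.items()}


def _check_channels(x: np.ndarray, expected: int, who: str) -> None:
    if x.ndim != 5 or x.shape[1] != expected:
        raise ValueError(f"{who}: expected (N, {expected}, D, H, W) input, got shape {x.shape}")


class Conv3d(Layer):
    """3D convolution; supports (stride=1, any pad) and (stride=kernel, pad=0)."""

    def __init__(self, cin: int, cout: int, kernel: int = 3, stride: int = 1, padding: int | None = None, rng: np.random.Generator | None = None, bias: bool = True):
        super().__init__()
        if stride != 1 and stride != kernel:
            raise ValueError("supported: stride 1, or stride == kernel (patch downsampling)")
        self.cin, self.cout, self.k, self.stride = cin, cout, kernel, stride
        self.padding = (kernel // 2 if stride == 1 else 0) if padding is None else padding
        if stride != 1 and self.padding != 0:
            raise ValueError("strided convolution requires padding 0")
        rng = rng or np.random.default_rng()
        fan_in = cin * kernel**3
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, kernel, kernel, kernel)).astype(np.float32)
        if bias:
            self.params["b"] = np.zeros(cout, dtype=np.float32)
        self._cache: tuple | None = None

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int, int]]:
        k, p = self.k, self.padding
        n, c = x.shape[:2]
        if self.stride == 1:
            if p:
                x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
            win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
            out_sp = win.shape[2:5]
            cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(-1, c * k**3)
        else:
            d, h, w = x.shape[2:]
            if d % k or h % k or w % k:
                raise ValueError(f"spatial shape {x.shape[2:]} not divisible by stride {k}")
            out_sp = (d // k, h // k, w // k)
            xr = x.reshape(n, c, out_sp[0], k, out_sp[1], k, out_sp[2], k)
            cols = np.ascontiguousarray(xr.transpose(0, 2, 4, 6, 1, 3, 5, 7)).reshape(-1, c * k**3)
        return cols, out_sp

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        _check_channels(x, self.cin, type(self).__name__)
        x = np.ascontiguousarray(x)
        cols, out_sp = self._im2col(x)
        wm = self.params["W"].reshape(self.cout, -1)
        y = cols @ wm.T
        if "b" in self.params:
            y += self.params["b"]
        n = x.shape[0]
        y = y.reshape(n, *out_sp, self.cout).transpose(0, 4, 1, 2, 3)
        if training:
            self._cache = (cols, x.shape, out_sp)
        return np.ascontiguousarray(y)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, x_shape, out_sp = self._cache
        n = x_shape[0]
        k = self.k
        gm = np.ascontiguousarray(gy.transpose(0, 2, 3, 4, 1)).reshape(-1, self.cout)
        self.grads["W"] = (gm.T @ cols).reshape(self.params["W"].shape)
        if "b" in self.params:
            self.grads["b"] = gm.sum(axis=0)
        if self.stride == 1:
            # gradient w.r.t. input = correlation of gy with flipped kernels,
            # channels transposed, at complementary padding
            w_flip = self.params["W"][:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            pb = k - 1 - self.padding
            g = gy
            if pb:
                g = np.pad(gy, ((0, 0), (0, 0), (pb, pb), (pb, pb), (pb, pb)))
            elif pb < 0:
                raise AssertionError("padding exceeds kernel-1")
            win = sliding_window_view(g, (k, k, k), axis=(2, 3, 4))
            gcols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(-1, self.cout * k**3)
            gx = gcols @ w_flip.reshape(self.cin, -1).T
            gx = gx.reshape(n, *x_shape[2:], self.cin).transpose(0, 4, 1, 2, 3)
        else:
            dcols = gm @ self.params["W"].reshape(self.cout, -1)
            dcols = dcols.reshape(n, *out_sp, self.cin, k, k, k)
            gx = dcols.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(x_shape)
        return np.ascontiguousarray(gx)


class ConvTranspose3d(Layer):
    """Transposed convolution with kernel == stride (exact 2× upsampling)."""

    def __init__(self, cin: int, cout: int, kernel: int = 2, rng: np.random.Generator | None = None):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, kernel
        rng = rng or np.random.default_rng()
        fan_in = cin
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cin, cout, kernel, kernel, kernel)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        _check_channels(x, self.cin, type(self).__name__)
        x = np.ascontiguousarray(x)
        n, _, d, h, w = x.shape
        k = self.k
        xm = np.ascontiguousarray(x.transpose(0, 2, 3, 4, 1)).reshape(-1, self.cin)
        ym = xm @ self.params["W"].reshape(self.cin, -1)  # (N*P, cout*k^3)
        y = ym.reshape(n, d, h, w, self.cout, k, k, k)
        y = y.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(n, self.cout, d * k, h * k, w * k)
        y = y + self.params["b"][None, :, None, None, None]
        if training:
            self._cache = (xm, x.shape)
        return np.ascontiguousarray(y)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xm, x_shape = self._cache
        n, _, d, h, w = x_shape
        k = self.k
        gr = gy.reshape(n, self.cout, d, k, h, k, w, k)
        gcols = np.ascontiguousarray(gr.transpose(0, 2, 4, 6, 1, 3, 5, 7)).reshape(-1, self.cout * k**3)
        self.grads["W"] = (xm.T @ gcols).reshape(self.params["W"].shape)
        self.grads["b"] = gy.sum(axis=(0, 2, 3, 4))
        gx = gcols @ self.params["W"].reshape(self.cin, -1).T
        gx = gx.reshape(n, d, h, w, self.cin).transpose(0, 4, 1, 2, 3)
        return np.ascontiguousarray(gx)


class BatchNorm3d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.c, self.eps, self.momentum = channels, eps, momentum
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        _check_channels(x, self.c, type(self).__name__)
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * invstd[None, :, None, None, None]
        y = self.params["gamma"][None, :, None, None, None] * xhat + self.params["beta"][None, :, None, None, None]
        if training:
            self._cache = (xhat, invstd)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        axes = (0, 2, 3, 4)
        m = gy.size / self.c
        dgamma = (gy * xhat).sum(axis=axes)
        dbeta = gy.sum(axis=axes)
        self.grads["gamma"] = dgamma
        self.grads["beta"] = dbeta
        g = self.params["gamma"][None, :, None, None, None] * invstd[None, :, None, None, None]
        return g * (gy - dbeta[None, :, None, None, None] / m - xhat * dgamma[None, :, None, None, None] / m)


class InstanceNorm3d(Layer):
    """Per-sample, per-channel normalization over the spatial axes.

    No running statistics: training and evaluation behave identically,
    which avoids the train/eval distribution mismatch batch norm suffers
    with batch size 1 and non-i.i.d. patch sampling.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.c, self.eps = channels, eps
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        _check_channels(x, self.c, type(self).__name__)
        axes = (2, 3, 4)
        mean = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        y = self.params["gamma"][None, :, None, None, None] * xhat + self.params["beta"][None, :, None, None, None]
        if training:
            self._cache = (xhat, invstd)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        axes = (2, 3, 4)
        m = float(np.prod(gy.shape[2:]))
        self.grads["gamma"] = (gy * xhat).sum(axis=(0, 2, 3, 4))
        self.grads["beta"] = gy.sum(axis=(0, 2, 3, 4))
        g = self.params["gamma"][None, :, None, None, None] * invstd
        return g * (
            gy
            - gy.mean(axis=axes, keepdims=True)
            - xhat * (gy * xhat).mean(axis=axes, keepdims=True)
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class ConvUnit(Layer):
    """Conv → optional normalization → optional ReLU, the network's basic unit.

    ``norm`` may be "batch", "instance", or falsy for none (True means
    batch norm).
    """

    def __init__(self, cin: int, cout: int, kernel: int = 3, stride: int = 1, norm: bool | str | None = True, relu: bool = True, rng: np.random.Generator | None = None, transpose: bool = False):
        super().__init__()
        self.conv: Layer = (
            ConvTranspose3d(cin, cout, kernel=kernel, rng=rng)
            if transpose
            else Conv3d(cin, cout, kernel=kernel, stride=stride, rng=rng)
        )
        if norm is True or norm == "batch":
            self.bn: Layer | None = BatchNorm3d(cout)
        elif norm == "instance":
            self.bn = InstanceNorm3d(cout)
        elif not norm:
            self.bn = None
        else:
            raise ValueError(f"unknown normalization {norm!r}")
        self.act = ReLU() if relu else None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        y = self.conv.forward(x, training)
        if self.bn is not None:
            y = self.bn.forward(y, training)
        if self.act is not None:
            y = self.act.forward(y, training)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self.act is not None:
            gy = self.act.backward(gy)
        if self.bn is not None:
            gy = self.bn.backward(gy)
        return self.conv.backward(gy)

    def named_params(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = self.conv.named_params(prefix + "conv.")
        if self.bn is not None:
            out |= self.bn.named_params(prefix + "bn.")
        return out

    def named_grads(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + "conv." + k: v for k, v in self.conv.grads.items()}
        if self.bn is not None:
            out |= {prefix + "bn." + k: v for k, v in self.bn.grads.items()}
        return out


def softmax(x: np.ndarray, axis: int = 1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
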