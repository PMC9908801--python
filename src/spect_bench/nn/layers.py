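"""3D convolution, pooling, dense and activation layers with backprop.

Arrays are float32 in channels-last layout ``(batch, x, y, z, channel)``.
Convolutions use a shift-and-matmul scheme: for every kernel offset the
(padded, strided) input slice is flattened to a ``(voxels, C_in)`` matrix
and multiplied with that offset's ``(C_in, C_out)`` weight slab.  This keeps
every BLAS call dense and skips the large im2col gather, which dominates
run time for small channel counts.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    """Base: parameter dict + matching gradient dict."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


class Conv3d(Layer):
    """3D convolution, zero padding, arbitrary stride.

    Defaults give a "same" 3x3x3 stride-1 convolution; the discriminator
    uses 4x4x4 stride-2 pad-1 (exact halving for even sizes).  Weights are
    stored as ``(k, k, k, C_in, C_out)``.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 3,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
        init_scale: float = 1.0,
    ):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.k, self.s = kernel, stride
        self.pad = (kernel - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel**3
        self.params["W"] = init_scale * he_init(
            rng, (kernel, kernel, kernel, c_in, c_out), fan_in
        )
        self.params["b"] = np.zeros(c_out, dtype=F32)

    def _slices(self, out_sp: tuple[int, int, int], a: int, b: int, c: int):
        s = self.s
        return (
            slice(a, a + s * out_sp[0], s),
            slice(b, b + s * out_sp[1], s),
            slice(c, c + s * out_sp[2], s),
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.s, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0))) if p else x
        self._xp = xp
        bsz = x.shape[0]
        out_sp = tuple((xp.shape[i + 1] - k) // s + 1 for i in range(3))
        self._out_sp = out_sp
        W = self.params["W"]
        yf = np.zeros((bsz * out_sp[0] * out_sp[1] * out_sp[2], self.c_out), dtype=F32)
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    sa, sb, sc = self._slices(out_sp, a, b, c)
                    xs = xp[:, sa, sb, sc, :].reshape(-1, self.c_in)
                    yf += xs @ W[a, b, c]
        yf += self.params["b"]
        return yf.reshape(bsz, *out_sp, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.pad
        xp = self._xp
        out_sp = self._out_sp
        dyf = dy.reshape(-1, self.c_out)
        W = self.params["W"]
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    sa, sb, sc = self._slices(out_sp, a, b, c)
                    xs = xp[:, sa, sb, sc, :].reshape(-1, self.c_in)
                    dW[a, b, c] = xs.T @ dyf
                    dxp[:, sa, sb, sc, :] += (dyf @ W[a, b, c].T).reshape(
                        dy.shape[0], *out_sp, self.c_in
                    )
        self.grads["W"] = dW
        self.grads["b"] = dyf.sum(axis=0).astype(F32)
        self._xp = None
        if p == 0:
            return dxp
        return dxp[:, p:-p, p:-p, p:-p, :]


class ConvTranspose3d(Layer):
    """Transposed convolution with kernel 2, stride 2 (exact x2 upsampling).
    Weights are ``(2, 2, 2, C_in, C_out)``."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        rng = rng or np.random.default_rng(0)
        self.params["W"] = he_init(rng, (2, 2, 2, c_in, c_out), c_in * 8)
        self.params["b"] = np.zeros(c_out, dtype=F32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        bsz, d, h, w, _ = x.shape
        xf = x.reshape(-1, self.c_in)
        y = np.empty((bsz, 2 * d, 2 * h, 2 * w, self.c_out), dtype=F32)
        W = self.params["W"]
        for a in range(2):
            for b in range(2):
                for c in range(2):
                    y[:, a::2, b::2, c::2, :] = (xf @ W[a, b, c]).reshape(
                        bsz, d, h, w, self.c_out
                    )
        return y + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        bsz, d, h, w, _ = x.shape
        xf = x.reshape(-1, self.c_in)
        W = self.params["W"]
        dW = np.empty_like(W)
        dxf = np.zeros_like(xf)
        for a in range(2):
            for b in range(2):
                for c in range(2):
                    dyf = dy[:, a::2, b::2, c::2, :].reshape(-1, self.c_out)
                    dW[a, b, c] = xf.T @ dyf
                    dxf += dyf @ W[a, b, c].T
        self.grads["W"] = dW
        self.grads["b"] = dy.sum(axis=(0, 1, 2, 3)).astype(F32)
        self._x = None
        return dxf.reshape(bsz, d, h, w, self.c_in)


class MaxPool3d(Layer):
    """2x2x2 max pooling (even input sizes only)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        bsz, d, h, w, ch = x.shape
        r = x.reshape(bsz, d // 2, 2, h // 2, 2, w // 2, 2, ch)
        r = r.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(
            bsz, d // 2, h // 2, w // 2, ch, 8
        )
        self._arg = r.argmax(axis=-1)
        self._in_shape = x.shape
        return np.ascontiguousarray(r.max(axis=-1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        bsz, d, h, w, ch = self._in_shape
        scat = np.zeros(dy.shape + (8,), dtype=F32)
        np.put_along_axis(scat, self._arg[..., None], dy[..., None], axis=-1)
        scat = scat.reshape(bsz, d // 2, h // 2, w // 2, ch, 2, 2, 2)
        return np.ascontiguousarray(
            scat.transpose(0, 1, 5, 2, 6, 3, 7, 4)
        ).reshape(bsz, d, h, w, ch)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = he_init(rng, (n_out, n_in), n_in)
        self.params["b"] = np.zeros(n_out, dtype=F32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._xf = np.ascontiguousarray(x.reshape(x.shape[0], -1))
        return self._xf @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = (dy.T @ self._xf).astype(F32)
        self.grads["b"] = dy.sum(axis=0).astype(F32)
        dx = dy @ self.params["W"]
        self._xf = None
        return dx.reshape(self._shape).astype(F32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0).astype(F32)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy).astype(F32)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred.astype(np.float64) - target
    loss = float(np.mean(diff**2))
    return loss, (2.0 * diff / diff.size).astype(F32)


def bce_with_logits(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy on logits; gradient w.r.t.
    the logits."""
    z = logits.astype(np.float64)
    y = labels.astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(z) - y) / z.size).astype(F32)
    return loss, grad
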