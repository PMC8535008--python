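"""Minimal 3-D convolutional network with explicit gradients.

Implements exactly the pieces the patch classifier needs: 3-D convolution
with stride/dilation/zero-padding, ReLU, a fully connected head, Kaiming
initialization, class-weighted softmax cross-entropy and SGD with weight
decay.  Everything is plain numpy; each convolution is evaluated as one
im2col gather plus a single BLAS matmul, which is efficient for the small
kernels (≤3 per axis) and small spatial extents (5×5) used here.  Layers
compute in float32 by default (a ``dtype`` argument selects float64, e.g.
for finite-difference gradient verification).

Array layout is ``(batch, channels, depth, height, width)`` with the
spectral axis mapped to depth, so "spectral" 1-D convolutions are 3-D
kernels of spatial extent 1.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3d",
    "ReLU",
    "Flatten",
    "Linear",
    "Network",
    "weighted_cross_entropy",
    "SGD",
]

Triple = tuple[int, int, int]


def _triple(x) -> Triple:
    if isinstance(x, int):
        return (x, x, x)
    t = tuple(int(v) for v in x)
    if len(t) != 3:
        raise ValueError("expected an int or a length-3 tuple")
    return t  # type: ignore[return-value]


class Conv3d:
    """3-D convolution (cross-correlation) with stride, dilation, padding."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel,
        stride=1,
        dilation=1,
        padding=0,
        dtype=np.float32,
    ) -> None:
        self.c_in, self.c_out = c_in, c_out
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.dilation = _triple(dilation)
        self.padding = _triple(padding)
        self.dtype = np.dtype(dtype)
        self.w = np.zeros((c_out, c_in, *self.kernel), dtype=self.dtype)
        self.b = np.zeros(c_out, dtype=self.dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache: tuple | None = None

    # -- parameter plumbing -------------------------------------------------
    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def n_weights(self) -> int:
        return self.w.size + self.b.size

    def init_kaiming(self, rng: np.random.Generator) -> None:
        fan_in = self.c_in * int(np.prod(self.kernel))
        self.w[...] = rng.normal(0.0, np.sqrt(2.0 / fan_in), self.w.shape).astype(self.dtype)
        self.b[...] = 0.0

    def out_shape(self, in_shape: Triple) -> Triple:
        out = []
        for i in range(3):
            eff = self.dilation[i] * (self.kernel[i] - 1) + 1
            n = (in_shape[i] + 2 * self.padding[i] - eff) // self.stride[i] + 1
            if n < 1:
                raise ValueError(
                    f"kernel {self.kernel} does not fit input extent {in_shape}"
                )
            out.append(n)
        return tuple(out)  # type: ignore[return-value]

    # -- forward / backward -------------------------------------------------
    # The convolution is evaluated as one im2col + matmul: a strided view
    # gathers every receptive field into a (B·Do·Ho·Wo, C·kd·kh·kw) matrix,
    # which keeps the arithmetic in a single BLAS call per layer.

    def _offset_slice(self, i: int, k: tuple[int, int, int], out_sp: Triple):
        d, s = self.dilation[i], self.stride[i]
        start = k[i] * d
        return slice(start, start + (out_sp[i] - 1) * s + 1, s)

    def _im2col(self, xp: np.ndarray, out_sp: Triple) -> np.ndarray:
        B, C = xp.shape[:2]
        kd, kh, kw = self.kernel
        sB, sC, sD, sH, sW = xp.strides
        shape = (B, *out_sp, C, kd, kh, kw)
        strides = (
            sB,
            sD * self.stride[0],
            sH * self.stride[1],
            sW * self.stride[2],
            sC,
            sD * self.dilation[0],
            sH * self.dilation[1],
            sW * self.dilation[2],
        )
        view = np.lib.stride_tricks.as_strided(xp, shape=shape, strides=strides)
        rows = B * int(np.prod(out_sp))
        return view.reshape(rows, C * kd * kh * kw)  # materializes one copy

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        B = x.shape[0]
        pd, ph, pw = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        out_sp = self.out_shape(x.shape[2:])
        col = self._im2col(xp, out_sp)
        w2 = self.w.reshape(self.c_out, -1)
        out = col @ w2.T + self.b
        if train:
            self._cache = (col, xp.shape, x.shape, out_sp)
        return np.moveaxis(out.reshape(B, *out_sp, self.c_out), -1, 1)

    def backward(self, gout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        assert self._cache is not None, "forward(train=True) must precede backward"
        col, xp_shape, x_shape, out_sp = self._cache
        B = gout.shape[0]
        g2 = np.ascontiguousarray(np.moveaxis(gout, 1, -1), dtype=self.dtype).reshape(
            -1, self.c_out
        )
        self.gw += (g2.T @ col).reshape(self.w.shape)
        self.gb += g2.sum(axis=0)
        if not need_input_grad:
            self._cache = None
            return None
        gcol = g2 @ self.w.reshape(self.c_out, -1)
        kd, kh, kw = self.kernel
        gview = gcol.reshape(B, *out_sp, self.c_in, kd, kh, kw)
        gxp = np.zeros(xp_shape, dtype=gout.dtype)
        for a in range(kd):
            for b in range(kh):
                for c in range(kw):
                    k = (a, b, c)
                    gxp[
                        :,
                        :,
                        self._offset_slice(0, k, out_sp),
                        self._offset_slice(1, k, out_sp),
                        self._offset_slice(2, k, out_sp),
                    ] += np.moveaxis(gview[..., a, b, c], -1, 1)
        pd, ph, pw = self.padding
        _, _, D, H, W = x_shape
        self._cache = None
        return gxp[:, :, pd : pd + D, ph : ph + H, pw : pw + W]


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def params(self):
        return []

    def n_weights(self) -> int:
        return 0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if gout.flags.writeable:
            gout *= self._mask
            return gout
        return gout * self._mask


class Flatten:
    def __init__(self) -> None:
        self._shape: tuple | None = None

    def params(self):
        return []

    def n_weights(self) -> int:
        return 0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout.reshape(self._shape)


class Linear:
    def __init__(self, n_in: int, n_out: int, dtype=np.float32) -> None:
        self.n_in, self.n_out = n_in, n_out
        self.dtype = np.dtype(dtype)
        self.w = np.zeros((n_out, n_in), dtype=self.dtype)
        self.b = np.zeros(n_out, dtype=self.dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def n_weights(self) -> int:
        return self.w.size + self.b.size

    def init_kaiming(self, rng: np.random.Generator) -> None:
        self.w[...] = rng.normal(0.0, np.sqrt(2.0 / self.n_in), self.w.shape).astype(self.dtype)
        self.b[...] = 0.0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if train:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, gout: np.ndarray) -> np.ndarray:
        gout = np.asarray(gout, dtype=self.dtype)
        self.gw += gout.T @ self._x
        self.gb += gout.sum(axis=0)
        return gout @ self.w


class Network:
    """A plain sequential stack of the layers above."""

    def __init__(self, layers: list) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gout: np.ndarray) -> None:
        for i, layer in enumerate(reversed(self.layers)):
            last = i == len(self.layers) - 1
            if last and isinstance(layer, Conv3d):
                layer.backward(gout, need_input_grad=False)
            else:
                gout = layer.backward(gout)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    def n_weights(self) -> int:
        return sum(layer.n_weights() for layer in self.layers)

    def init_kaiming(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if hasattr(layer, "init_kaiming"):
                layer.init_kaiming(rng)

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for (p, _), saved in zip(self.params(), state):
            p[...] = saved


def weighted_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy and its gradient w.r.t. logits.

    The loss is the weighted mean ``sum_i w[y_i] * ce_i / sum_i w[y_i]``
    (the convention of the usual deep-learning frameworks).
    """
    logits = np.asarray(logits, dtype=np.float64)
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = logits.shape[0]
    w = class_weights[labels]
    loss = float(-(w * logp[np.arange(n), labels]).sum() / w.sum())
    p = np.exp(logp)
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (w / w.sum())[:, None]
    return loss, grad


class SGD:
    """Vanilla stochastic gradient descent with decoupled-style L2 decay
    folded into the gradient (the classic ``grad + wd*w`` formulation)."""

    def __init__(self, network: Network, lr: float, weight_decay: float = 0.0) -> None:
        self.network = network
        self.lr = lr
        self.weight_decay = weight_decay

    def step(self) -> None:
        for p, g in self.network.params():
            p -= self.lr * (g + self.weight_decay * p)
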