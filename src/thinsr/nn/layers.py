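"""Convolution, dense and activation primitives with explicit backprop.

Convolutions run through numba-compiled direct kernels (see ``_kernels``):
on this workload a direct convolution with a contiguous inner loop is
several times faster than im2col + GEMM, whose gather traffic is
memory-bound.  The input gradient is computed as a transposed convolution
(zero-stuffed output gradient convolved with the spatially flipped,
channel-transposed kernel), reusing the forward kernel.  Everything works
for 2D and 3D isotropic kernels and arbitrary stride/zero-padding, which
is all the networks here require.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np

from ._kernels import conv_fwd_2d, conv_fwd_3d, conv_gradw_2d, conv_gradw_3d

__all__ = [
    "Conv",
    "Linear",
    "relu",
    "relu_grad",
    "leaky_relu",
    "leaky_relu_grad",
    "sigmoid",
]


def _pad(x: np.ndarray, pad: int, ndim: int) -> np.ndarray:
    if pad == 0:
        return np.ascontiguousarray(x)
    width = ((0, 0), (0, 0)) + ((pad, pad),) * ndim
    return np.pad(x, width)


def _dilate(gy: np.ndarray, stride: int) -> np.ndarray:
    if stride == 1:
        return gy
    sp = gy.shape[2:]
    new = tuple((d - 1) * stride + 1 for d in sp)
    z = np.zeros(gy.shape[:2] + new, dtype=gy.dtype)
    z[(slice(None), slice(None)) + tuple(slice(None, None, stride) for _ in sp)] = gy
    return z


class Conv:
    """N-dimensional convolution layer (isotropic kernel, zero padding).

    Weights use He-normal initialization unless ``zero_init`` is set, in
    which case both kernel and bias start at exactly zero (used by the
    generator's exit branches so an untrained network is the identity).
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel_size: int = 3,
        ndim: int = 3,
        stride: int = 1,
        padding: int = 0,
        rng: Optional[np.random.Generator] = None,
        zero_init: bool = False,
        dtype=np.float32,
    ) -> None:
        if ndim not in (2, 3):
            raise ValueError("only 2D and 3D convolutions are supported")
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.k = int(kernel_size)
        self.ndim = int(ndim)
        self.stride = int(stride)
        self.pad = int(padding)
        kshape = (out_ch, in_ch) + (self.k,) * self.ndim
        if zero_init:
            self.w = np.zeros(kshape, dtype=dtype)
        else:
            if rng is None:
                rng = np.random.default_rng()
            fan_in = in_ch * self.k**self.ndim
            self.w = (
                rng.standard_normal(kshape) * math.sqrt(2.0 / fan_in)
            ).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._xp: Optional[np.ndarray] = None
        self._in_sp: Optional[Tuple[int, ...]] = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]

    def zero_grad(self) -> None:
        self.gw[...] = 0
        self.gb[...] = 0

    def _fwd(self, xp: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int):
        if self.ndim == 3:
            return conv_fwd_3d(xp, w, b, stride)
        return conv_fwd_2d(xp, w, b, stride)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != self.ndim + 2 or x.shape[1] != self.in_ch:
            raise ValueError(
                f"expected (N, {self.in_ch}, *spatial^{self.ndim}), got {x.shape}"
            )
        x = np.ascontiguousarray(x, dtype=self.w.dtype)
        self._in_sp = x.shape[2:]
        self._xp = _pad(x, self.pad, self.ndim)
        return self._fwd(self._xp, self.w, self.b, self.stride)

    def backward(self, gy: np.ndarray, need_input_grad: bool = True):
        assert self._xp is not None, "backward before forward"
        gy = np.ascontiguousarray(gy, dtype=self.w.dtype)
        if self.ndim == 3:
            self.gw += conv_gradw_3d(self._xp, gy, self.k, self.stride)
        else:
            self.gw += conv_gradw_2d(self._xp, gy, self.k, self.stride)
        self.gb += gy.sum(axis=(0,) + tuple(range(2, gy.ndim)))
        if not need_input_grad:
            return None
        # transposed convolution with the flipped, channel-transposed kernel
        wft = np.ascontiguousarray(
            np.flip(self.w, axis=tuple(range(2, 2 + self.ndim))).transpose(
                1, 0, *range(2, 2 + self.ndim)
            )
        )
        gyp = _pad(_dilate(gy, self.stride), self.k - 1, self.ndim)
        full = self._fwd(gyp, wft, np.zeros(self.in_ch, dtype=self.w.dtype), 1)
        gx = np.zeros((gy.shape[0], self.in_ch) + self._in_sp, dtype=self.w.dtype)
        # positions beyond the last window receive zero gradient
        avail = tuple(
            min(self._in_sp[i], full.shape[2 + i] - self.pad)
            for i in range(self.ndim)
        )
        dst = (Ellipsis,) + tuple(slice(0, a) for a in avail)
        src = (Ellipsis,) + tuple(slice(self.pad, self.pad + a) for a in avail)
        gx[dst] = full[src]
        return gx


class Linear:
    """Dense layer ``y = x @ w.T + b``."""

    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: Optional[np.random.Generator] = None,
        dtype=np.float32,
    ) -> None:
        if rng is None:
            rng = np.random.default_rng()
        self.w = (
            rng.standard_normal((out_features, in_features))
            * math.sqrt(2.0 / in_features)
        ).astype(dtype)
        self.b = np.zeros(out_features, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x: Optional[np.ndarray] = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]

    def zero_grad(self) -> None:
        self.gw[...] = 0
        self.gb[...] = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.gw += gy.T @ self._x
        self.gb += gy.sum(axis=0)
        return gy @ self.w


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


def relu_grad(x: np.ndarray, gy: np.ndarray) -> np.ndarray:
    return gy * (x > 0)


def leaky_relu(x: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def leaky_relu_grad(x: np.ndarray, gy: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return gy * np.where(x > 0, 1.0, slope).astype(gy.dtype)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out.astype(x.dtype)
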