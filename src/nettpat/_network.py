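"""Minimal convolutional-network engine with exact hand-written backprop.

Implements the residual U-Net used as the learnable part of the NETT
regularizer: 3x3 same-padding convolutions (im2col + GEMM), ReLU, 2x2 average
pooling, nearest-neighbour upsampling, concatenating skip connections, a
final 1x1 correction added to the input, and the Adam optimizer.  Backward
passes propagate gradients both to the parameters (for training) and to the
network input (the vector-Jacobian product needed for the regularizer
gradient); both are exact derivatives of the forward pass and are checked
against finite differences in the test suite.

Arrays are laid out ``(batch, channels, height, width)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNet", "Adam"]


# ---------------------------------------------------------------------------
# primitive layers (forward returns (out, cache); backward returns grads)

def _conv2d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padding stride-1 cross-correlation. W: (Cout, Cin, kh, kw)."""
    B, Cin, H, Wd = x.shape
    Cout, _, kh, kw = W.shape
    ph, pw = kh // 2, kw // 2
    if kh == 1 and kw == 1:
        out = np.tensordot(x, W[:, :, 0, 0], axes=([1], [1])).transpose(0, 3, 1, 2)
        out += b[None, :, None, None]
        return out, x
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))       # (B,Cin,H,W,kh,kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B, H * Wd, Cin * kh * kw)
    out = cols @ W.reshape(Cout, -1).T                          # (B, HW, Cout)
    out = out.transpose(0, 2, 1).reshape(B, Cout, H, Wd) + b[None, :, None, None]
    return out, cols


def _conv2d_backward(dout: np.ndarray, cache, x_shape, W: np.ndarray):
    """Gradients of the same-padding convolution w.r.t. (x, W, b)."""
    B, Cin, H, Wd = x_shape
    Cout, _, kh, kw = W.shape
    if kh == 1 and kw == 1:
        x = cache
        dW = np.tensordot(dout, x, axes=([0, 2, 3], [0, 2, 3]))[:, :, None, None]
        db = dout.sum(axis=(0, 2, 3))
        dx = np.tensordot(dout, W[:, :, 0, 0], axes=([1], [0])).transpose(0, 3, 1, 2)
        return dx, dW, db
    cols = cache                                                # (B, HW, Cin*kh*kw)
    dflat = dout.reshape(B, Cout, H * Wd)
    dW = np.einsum("bof,bfk->ok", dflat, cols, optimize=True).reshape(W.shape)
    db = dout.sum(axis=(0, 2, 3))
    # grad wrt input = convolution of dout with spatially flipped, transposed W
    Wt = np.ascontiguousarray(W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    dx, _ = _conv2d_forward(dout, Wt, np.zeros(Cin, dtype=W.dtype))
    return dx, dW, db


def _relu_forward(x):
    mask = x > 0
    return x * mask, mask


def _relu_backward(dout, mask):
    return dout * mask


def _avgpool2_forward(x):
    B, C, H, W = x.shape
    out = x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))
    return out, x.shape


def _avgpool2_backward(dout, x_shape):
    B, C, H, W = x_shape
    g = dout[:, :, :, None, :, None] / 4.0
    return np.broadcast_to(g, (B, C, H // 2, 2, W // 2, 2)).reshape(B, C, H, W)


def _upsample2_forward(x):
    return x.repeat(2, axis=2).repeat(2, axis=3), x.shape


def _upsample2_backward(dout, x_shape):
    B, C, H, W = x_shape
    return dout.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------------------

class UNet:
    """Residual U-Net ``Phi(x) = x + correction(x)``.

    Parameters
    ----------
    depth
        Number of down-/upsampling stages (the ``m`` of ``Phi^(m)``); the
        input side length must be divisible by ``2**depth``.
    base_channels
        Channels at the finest scale; doubled at each coarser scale.
    kernel_size
        Spatial kernel size of all hidden convolutions (odd).
    residual
        If False the final 1x1 output is returned without adding the input.
    seed
        Seed of the He-normal parameter initialization.
    dtype
        Parameter/computation dtype (float64 by default for exact-gradient
        work; float32 roughly halves the training cost).
    """

    def __init__(self, depth: int = 1, base_channels: int = 32,
                 kernel_size: int = 3, residual: bool = True,
                 seed: int = 0, dtype=np.float64):
        if depth < 1:
            raise ValueError(f"depth must be >= 1, got {depth}")
        if kernel_size % 2 != 1:
            raise ValueError(f"kernel size must be odd, got {kernel_size}")
        self.depth = depth
        self.base_channels = base_channels
        self.kernel_size = kernel_size
        self.residual = residual
        self.dtype = np.dtype(dtype)
        self.params: dict[str, np.ndarray] = {}
        self._init_params(seed)

    # -- construction ------------------------------------------------------

    def _add_conv(self, rng, name: str, cin: int, cout: int, k: int) -> None:
        std = np.sqrt(2.0 / (cin * k * k))
        self.params[name + ".W"] = (std * rng.standard_normal((cout, cin, k, k))
                                    ).astype(self.dtype)
        self.params[name + ".b"] = np.zeros(cout, dtype=self.dtype)

    def _init_params(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        k, C = self.kernel_size, self.base_channels
        cin = 1
        for level in range(self.depth):
            c = C * 2**level
            self._add_conv(rng, f"enc{level}.conv1", cin, c, k)
            self._add_conv(rng, f"enc{level}.conv2", c, c, k)
            cin = c
        cb = C * 2**self.depth
        self._add_conv(rng, "bottleneck.conv1", cin, cb, k)
        self._add_conv(rng, "bottleneck.conv2", cb, cb, k)
        for level in reversed(range(self.depth)):
            c = C * 2**level
            self._add_conv(rng, f"dec{level}.up", 2 * c, c, k)
            self._add_conv(rng, f"dec{level}.conv1", 2 * c, c, k)
            self._add_conv(rng, f"dec{level}.conv2", c, c, k)
        self._add_conv(rng, "out", C, 1, 1)

    # -- forward / backward ------------------------------------------------

    def _conv_relu(self, x, name, cache):
        out, c1 = _conv2d_forward(x, self.params[name + ".W"], self.params[name + ".b"])
        out, c2 = _relu_forward(out)
        cache.append((name, x.shape, c1, c2))
        return out

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Apply the network to a batch ``(B, 1, N, N)``."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected input of shape (B, 1, N, N), got {x.shape}")
        N = x.shape[-1]
        if x.shape[-2] != N or N % 2**self.depth:
            raise ValueError(
                f"input side {x.shape[-2]}x{N} must be square and divisible "
                f"by 2**depth = {2**self.depth}")
        cache: list = []
        h = x
        skips = []
        for level in range(self.depth):
            h = self._conv_relu(h, f"enc{level}.conv1", cache)
            h = self._conv_relu(h, f"enc{level}.conv2", cache)
            skips.append(h)
            h, pc = _avgpool2_forward(h)
            cache.append(("pool", pc))
        h = self._conv_relu(h, "bottleneck.conv1", cache)
        h = self._conv_relu(h, "bottleneck.conv2", cache)
        for level in reversed(range(self.depth)):
            h, uc = _upsample2_forward(h)
            cache.append(("up", uc))
            h = self._conv_relu(h, f"dec{level}.up", cache)
            h = np.concatenate([skips[level], h], axis=1)
            cache.append(("concat", skips[level].shape[1]))
            h = self._conv_relu(h, f"dec{level}.conv1", cache)
            h = self._conv_relu(h, f"dec{level}.conv2", cache)
        out, oc = _conv2d_forward(h, self.params["out.W"], self.params["out.b"])
        cache.append(("out", h.shape, oc))
        if self.residual:
            out = out + x
        return (out, cache) if want_cache else out

    def backward(self, dout: np.ndarray, cache) -> tuple[np.ndarray, dict]:
        """Propagate ``dout`` back through a cached forward pass.

        Returns ``(dx, grads)``: the gradient w.r.t. the network input (the
        VJP ``J_Phi(x)^T dout``) and the parameter-gradient dict.
        """
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dout = np.asarray(dout, dtype=self.dtype)
        cache = list(cache)
        tag = cache.pop()
        assert tag[0] == "out"
        _, h_shape, oc = tag
        g, dW, db = _conv2d_backward(dout, oc, h_shape, self.params["out.W"])
        grads["out.W"] += dW
        grads["out.b"] += db

        def back_conv_relu(g):
            name, x_shape, c1, c2 = cache.pop()
            g = _relu_backward(g, c2)
            g, dW, db = _conv2d_backward(g, c1, x_shape, self.params[name + ".W"])
            grads[name + ".W"] += dW
            grads[name + ".b"] += db
            return g

        dskips = [None] * self.depth
        for level in range(self.depth):
            g = back_conv_relu(g)
            g = back_conv_relu(g)
            tag, nskip = cache.pop()
            assert tag == "concat"
            dskips[level] = g[:, :nskip]
            g = g[:, nskip:]
            g = back_conv_relu(g)
            tag, uc = cache.pop()
            assert tag == "up"
            g = _upsample2_backward(g, uc)
        g = back_conv_relu(g)
        g = back_conv_relu(g)
        for level in reversed(range(self.depth)):
            tag, pc = cache.pop()
            assert tag == "pool"
            g = _avgpool2_backward(g, pc)
            g = g + dskips[level]
            g = back_conv_relu(g)
            g = back_conv_relu(g)
        assert not cache
        if self.residual:
            g = g + dout
        return g, grads

    # -- parameter plumbing ------------------------------------------------

    def get_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        if set(params) != set(self.params):
            raise ValueError("parameter-name mismatch when loading network weights")
        for k, v in params.items():
            if v.shape != self.params[k].shape:
                raise ValueError(f"shape mismatch for {k}: {v.shape} vs "
                                 f"{self.params[k].shape}")
            self.params[k] = np.asarray(v, dtype=self.dtype)

    def zero_correction(self) -> None:
        """Zero the final 1x1 layer so that ``Phi`` is the identity."""
        self.params["out.W"][:] = 0.0
        self.params["out.b"][:] = 0.0


class Adam:
    """Adam optimizer over a parameter dict (standard bias-corrected form)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError(f"learning rate must be > 0, got {lr}")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)
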