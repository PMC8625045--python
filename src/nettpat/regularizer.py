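"""Learned NETT regularizer ``R(x) = ||x - Phi(x)||^2 + beta * ||grad x||_{1,eps}``.

``Phi`` is a residual U-Net trained so that clean phantoms are (near) fixed
points while basic pseudoinverse reconstructions are mapped back towards the
clean image; the squared distance to the network output therefore scores how
"plausible" a candidate reconstruction is.  The second term is a smoothed
isotropic total variation that keeps the functional differentiable.  Both
the value and the exact gradient (including the vector-Jacobian product
through the network) are exposed for use inside the variational solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._network import Adam, UNet
from .phantoms import Dataset

__all__ = [
    "NetworkSpec",
    "LearnedRegularizer",
    "TrainConfig",
    "TrainingDivergenceError",
    "smoothed_tv",
    "smoothed_tv_gradient",
    "network_apply",
    "regularizer_value",
    "regularizer_gradient",
    "train_regularizer",
]


class TrainingDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the residual U-Net ``Phi^(m)``.

    ``depth`` is the number of down-/upsampling stages ``m``; the image side
    must be divisible by ``2**depth``.  ``base_channels`` doubles per scale.
    """

    depth: int = 1
    base_channels: int = 32
    kernel_size: int = 3
    residual: bool = True
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"network depth must be >= 1, got {self.depth}")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")

    def build(self, seed: int = 0) -> UNet:
        return UNet(depth=self.depth, base_channels=self.base_channels,
                    kernel_size=self.kernel_size, residual=self.residual,
                    seed=seed, dtype=np.dtype(self.dtype))


@dataclass
class LearnedRegularizer:
    """Trained network plus the TV weight ``beta`` and smoothing ``eps``.

    Defaults ``beta=15`` (the weight used throughout the reconstruction
    study) and ``eps=1e-3`` relative to the unit dynamic range.
    """

    net: UNet | None
    beta: float = 15.0
    eps: float = 1e-3

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.eps < 0:
            raise ValueError(f"eps must be >= 0, got {self.eps}")

    @classmethod
    def untrained(cls, spec: NetworkSpec, beta: float = 15.0, eps: float = 1e-3,
                  seed: int = 0) -> "LearnedRegularizer":
        return cls(net=spec.build(seed=seed), beta=beta, eps=eps)

    @classmethod
    def identity(cls, spec: NetworkSpec, beta: float = 0.0, eps: float = 1e-3,
                 seed: int = 0) -> "LearnedRegularizer":
        """Regularizer whose network is exactly the identity (zero correction)."""
        net = spec.build(seed=seed)
        net.zero_correction()
        return cls(net=net, beta=beta, eps=eps)

    @classmethod
    def quadratic(cls, beta: float = 0.0, eps: float = 1e-3) -> "LearnedRegularizer":
        """Network-free regularizer with ``Phi == 0``: ``R(x) = ||x||^2 + beta*TV``.

        Works on coefficient vectors of any length (no image reshaping when
        ``beta == 0``); used for convex-case solver verification.
        """
        return cls(net=None, beta=beta, eps=eps)


def _as_image(x: np.ndarray) -> np.ndarray:
    """Reshape a flat coefficient vector (or square image) to (N, N)."""
    x = np.asarray(x)
    if x.ndim == 1:
        N = int(round(np.sqrt(x.size)))
        if N * N != x.size:
            raise ValueError(f"vector of length {x.size} is not a square image")
        return x.reshape(N, N)
    if x.ndim == 2 and x.shape[0] == x.shape[1]:
        return x
    raise ValueError(f"expected flat vector or square image, got shape {x.shape}")


def smoothed_tv(x: np.ndarray, eps: float) -> float:
    """Smoothed isotropic total variation.

    ``sum_{i1,i2} sqrt((D1 x)^2 + (D2 x)^2 + eps^2)`` with forward differences
    and replicate boundary (differences past the last row/column are zero).
    A constant image gives exactly ``N^2 * eps``.
    """
    if eps < 0:
        raise ValueError(f"eps must be >= 0, got {eps}")
    img = _as_image(x).astype(np.float64)
    d1 = np.zeros_like(img)
    d2 = np.zeros_like(img)
    d1[:-1, :] = img[1:, :] - img[:-1, :]
    d2[:, :-1] = img[:, 1:] - img[:, :-1]
    return float(np.sum(np.sqrt(d1**2 + d2**2 + eps**2)))


def smoothed_tv_gradient(x: np.ndarray, eps: float) -> np.ndarray:
    """Exact gradient of :func:`smoothed_tv`; requires ``eps > 0``."""
    if eps <= 0:
        raise ValueError("smoothed-TV gradient requires eps > 0")
    img = _as_image(x).astype(np.float64)
    d1 = np.zeros_like(img)
    d2 = np.zeros_like(img)
    d1[:-1, :] = img[1:, :] - img[:-1, :]
    d2[:, :-1] = img[:, 1:] - img[:, :-1]
    q = np.sqrt(d1**2 + d2**2 + eps**2)
    g = -(d1 + d2) / q
    g[1:, :] += (d1 / q)[:-1, :]
    g[:, 1:] += (d2 / q)[:, :-1]
    return g.reshape(np.asarray(x).shape)


def network_apply(reg: LearnedRegularizer, x: np.ndarray) -> np.ndarray:
    """Apply ``Phi`` to one image; output has the shape of the input.

    A network-free regularizer (``net=None``, i.e. ``Phi == 0``) returns the
    zero array."""
    shape = np.asarray(x).shape
    if reg.net is None:
        return np.zeros(shape)
    img = _as_image(x)
    out = reg.net.forward(img[None, None].astype(reg.net.dtype))
    return np.asarray(out[0, 0], dtype=np.float64).reshape(shape)


def regularizer_value(reg: LearnedRegularizer, x: np.ndarray) -> float:
    """``||x - Phi(x)||_2^2 + beta * ||grad x||_{1,eps}``; always >= 0."""
    x = np.asarray(x, dtype=np.float64)
    r = x - network_apply(reg, x)
    val = float(np.sum(r**2))
    if reg.beta > 0:
        val += reg.beta * smoothed_tv(x, reg.eps)
    return val


def regularizer_gradient(reg: LearnedRegularizer, x: np.ndarray) -> np.ndarray:
    """Exact gradient of :func:`regularizer_value` w.r.t. ``x``.

    ``grad = 2 (I - J_Phi(x))^T (x - Phi(x)) + beta * grad TV_eps(x)``; the
    Jacobian-transpose product is evaluated by backpropagation through the
    network's forward pass.
    """
    x = np.asarray(x, dtype=np.float64)
    if reg.net is None:
        grad = 2.0 * x
        if reg.beta > 0:
            grad = grad + reg.beta * smoothed_tv_gradient(x, reg.eps)
        return grad
    img = _as_image(x)
    out, cache = reg.net.forward(img[None, None].astype(reg.net.dtype),
                                 want_cache=True)
    r = img - np.asarray(out[0, 0], dtype=np.float64)
    dx, _ = reg.net.backward(np.asarray(r, dtype=reg.net.dtype)[None, None], cache)
    grad = 2.0 * (r - np.asarray(dx[0, 0], dtype=np.float64))
    if reg.beta > 0:
        grad = grad + reg.beta * smoothed_tv_gradient(img, reg.eps)
    return grad.reshape(x.shape)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters.

    ``lr=0.01`` and ``gamma=0.1`` (the weight of the clean-image fidelity
    term) follow the published training recipe; epochs and batch size are
    implementation defaults.
    """

    lr: float = 0.01
    gamma: float = 0.1
    epochs: int = 50
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError(f"learning rate must be > 0, got {self.lr}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


def _epoch_loss(net: UNet, x: np.ndarray, h: np.ndarray, gamma: float) -> float:
    """Mean per-sample loss ``||Phi(h)-x||_1 + gamma ||Phi(x)-x||_1``."""
    total = 0.0
    for a in range(x.shape[0]):
        xa = x[a][None, None]
        ph = net.forward(h[a][None, None])
        total += float(np.abs(ph - xa).sum())
        if gamma > 0:
            px = net.forward(xa)
            total += gamma * float(np.abs(px - xa).sum())
    return total / x.shape[0]


def train_regularizer(data: Dataset, spec: NetworkSpec, cfg: TrainConfig,
                      beta: float = 15.0, eps: float = 1e-3,
                      verbose: bool = False) -> tuple[LearnedRegularizer, list[float]]:
    """Train ``Phi`` on pairs ``(x_a, h_a)`` with the two-term L1 loss.

    Minimizes ``sum_a ||Phi(h_a) - x_a||_1 + gamma ||Phi(x_a) - x_a||_1``
    over minibatches with Adam.  Returns the regularizer carrying the
    parameters of the epoch with the lowest loss, together with the per-epoch
    training curve (epoch-mean loss evaluated online during the sweep).
    """
    if len(data) == 0:
        raise ValueError("training dataset is empty")
    net = spec.build(seed=cfg.seed)
    dt = net.dtype
    N = int(round(np.sqrt(data.x.shape[1])))
    x = np.ascontiguousarray(data.x.reshape(-1, N, N), dtype=dt)
    h = np.ascontiguousarray(data.h.reshape(-1, N, N), dtype=dt)
    opt = Adam(net.params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    n = x.shape[0]
    curve: list[float] = []
    best_loss, best_params = np.inf, net.get_params()
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = x[idx][:, None]
            hb = h[idx][:, None]
            out_h, cache_h = net.forward(hb, want_cache=True)
            res_h = out_h - xb
            loss = float(np.abs(res_h).sum())
            _, grads = net.backward(np.sign(res_h), cache_h)
            if cfg.gamma > 0:
                out_x, cache_x = net.forward(xb, want_cache=True)
                res_x = out_x - xb
                loss += cfg.gamma * float(np.abs(res_x).sum())
                _, grads_x = net.backward(cfg.gamma * np.sign(res_x), cache_x)
                for k in grads:
                    grads[k] += grads_x[k]
            if not np.isfinite(loss):
                raise TrainingDivergenceError(
                    f"non-finite training loss at epoch {epoch}")
            for k in grads:
                grads[k] /= len(idx)
            opt.step(net.params, grads)
            epoch_total += loss
        epoch_loss = epoch_total / n
        curve.append(epoch_loss)
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs}: loss {epoch_loss:.5f}")
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best_params = net.get_params()
    net.set_params(best_params)
    return LearnedRegularizer(net=net, beta=beta, eps=eps), curve
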