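"""Forward-backward minimization of the NETT functional.

The reconstruction minimizes ``T(x) = ||A x - y||^2 / 2 + alpha * R(x)`` by
splitting: an explicit (forward) gradient step on the learned regularizer
followed by an implicit (backward/proximal) step on the quadratic data term,

    ``x_{k+1} = (s A^T A + I)^{-1} (s A^T y + x_k - s * alpha * grad R(x_k))``.

Because the step size is constant, the linear solve is realized once through
the operator's SVD factors and reused for every iteration and every data set:
``(s A^T A + I)^{-1} z = z + V diag(1/(s sigma_i^2 + 1) - 1) V^T z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import TruncatedOperator, forward_apply, pinv_apply
from .regularizer import LearnedRegularizer, network_apply, regularizer_gradient, \
    regularizer_value

__all__ = [
    "SolverConfig",
    "ReconResult",
    "SolverDivergenceError",
    "nett_objective",
    "forward_backward_solve",
    "post_process",
    "bregman_distance",
    "default_alpha",
    "stable_tv_eps",
]

#: regularization weights of the reconstruction study, per relative noise level
ALPHA_BY_NOISE = {0.0: 0.015, 0.01: 0.016, 0.1: 0.02}


def default_alpha(sigma: float) -> float:
    """Study default for ``alpha`` given the relative noise level."""
    return ALPHA_BY_NOISE.get(float(sigma), 0.016)


class SolverDivergenceError(RuntimeError):
    """Raised when an iterate becomes non-finite."""


def stable_tv_eps(alpha: float, beta: float, s: float, margin: float = 2.0) -> float:
    """Smallest TV smoothing that keeps the explicit regularizer step stable.

    The smoothed-TV Hessian is bounded by ``8/eps`` (each pixel couples to
    four difference terms, each of curvature at most ``2/eps``), so the
    explicit gradient step of size ``s * alpha * beta`` on the TV part stays
    non-expansive when ``s * alpha * beta * 8/eps <= 2``, i.e.
    ``eps >= 4 * s * alpha * beta``.  ``margin`` multiplies that bound
    (default 2, giving ``eps = 8 * s * alpha * beta``).
    """
    return margin * 4.0 * s * alpha * beta


@dataclass(frozen=True)
class SolverConfig:
    """NETT solver settings: ``alpha`` the regularization weight, ``s`` the
    step size, ``Niter`` the iteration count, and the initialization rule
    (``"network-pinv"`` = Phi(A^+ y), ``"network-adjoint"`` = Phi(A^T y),
    ``"pinv"``, or ``"zero"``)."""

    alpha: float = 0.016
    s: float = 0.25
    Niter: int = 15
    init: str = "network-pinv"
    reuse_inverse: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.s <= 0:
            raise ValueError(f"step size s must be > 0, got {self.s}")
        if self.Niter < 0:
            raise ValueError(f"Niter must be >= 0, got {self.Niter}")
        if self.init not in ("network-pinv", "network-adjoint", "pinv", "zero"):
            raise ValueError(f"unknown init rule {self.init!r}")


@dataclass(frozen=True)
class ReconResult:
    """NETT minimizer with its objective trace and final decomposition."""

    x: np.ndarray
    objective_trace: np.ndarray     # length Niter + 1
    data_fidelity: float
    regularizer: float
    config: SolverConfig

    def __post_init__(self) -> None:
        if self.objective_trace.shape != (self.config.Niter + 1,):
            raise ValueError("objective trace must have length Niter + 1")
        if not (np.all(np.isfinite(self.objective_trace))
                and np.all(np.isfinite(self.x))):
            raise ValueError("non-finite values in reconstruction result")


def nett_objective(op: TruncatedOperator, reg: LearnedRegularizer,
                   x: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """``||A x - y||^2 / 2 + alpha * R(x)``."""
    r = forward_apply(op, x) - np.asarray(y, dtype=np.float64)
    val = 0.5 * float(r @ r)
    if alpha != 0:
        val += alpha * regularizer_value(reg, x)
    return val


def _initial_iterate(op: TruncatedOperator, reg: LearnedRegularizer,
                     y: np.ndarray, init: str) -> np.ndarray:
    if init == "zero":
        return np.zeros(op.n_coef)
    if init == "pinv":
        return pinv_apply(op, y)
    if init == "network-adjoint":
        return network_apply(reg, op.Vt.T @ (op.s * (op.U.T @ y)))
    return network_apply(reg, pinv_apply(op, y))


def forward_backward_solve(op: TruncatedOperator, reg: LearnedRegularizer,
                           y: np.ndarray, cfg: SolverConfig) -> ReconResult:
    """Run the forward-backward iteration on data ``y``.

    With ``reuse_inverse=True`` (default) the implicit step uses the
    spectral closed form of ``(s A^T A + I)^{-1}`` precomputed once from the
    operator's SVD factors; otherwise the dense system is factorized and
    solved each iteration (identical result, kept for verification).
    """
    y = np.asarray(y, dtype=np.float64)
    if y.shape != (op.n_data,):
        raise ValueError(f"data shape {y.shape} != ({op.n_data},)")
    x = _initial_iterate(op, reg, y, cfg.init)
    Aty = op.Vt.T @ (op.s * (op.U.T @ y))

    if cfg.reuse_inverse:
        shrink = 1.0 / (cfg.s * op.s**2 + 1.0) - 1.0     # per retained mode

        def implicit_step(z):
            return z + op.Vt.T @ (shrink * (op.Vt @ z))
    else:
        import scipy.linalg
        M = cfg.s * op.normal_matrix() + np.eye(op.n_coef)
        lu = scipy.linalg.lu_factor(M)

        def implicit_step(z):
            return scipy.linalg.lu_solve(lu, z)

    trace = np.empty(cfg.Niter + 1)
    trace[0] = nett_objective(op, reg, x, y, cfg.alpha)
    for k in range(cfg.Niter):
        z = x + cfg.s * Aty
        if cfg.alpha != 0:
            z = z - cfg.s * cfg.alpha * regularizer_gradient(reg, x)
        x = implicit_step(z)
        if not np.all(np.isfinite(x)):
            raise SolverDivergenceError(f"non-finite iterate at iteration {k + 1}")
        trace[k + 1] = nett_objective(op, reg, x, y, cfg.alpha)
    data_fid = trace[-1] - cfg.alpha * regularizer_value(reg, x) if cfg.alpha else trace[-1]
    return ReconResult(x=x, objective_trace=trace,
                       data_fidelity=float(data_fid),
                       regularizer=float(regularizer_value(reg, x)),
                       config=cfg)


def post_process(op: TruncatedOperator, reg: LearnedRegularizer,
                 y: np.ndarray) -> np.ndarray:
    """Post-processing baseline: one network pass over the basic
    reconstruction, ``Phi(A^+ y)``."""
    return network_apply(reg, pinv_apply(op, y))


def bregman_distance(R_value, R_grad, x: np.ndarray, x_star: np.ndarray) -> float:
    """Absolute Bregman distance ``|R(x) - R(x*) - <R'(x*), x - x*>|``.

    ``R_value`` and ``R_grad`` are callables evaluating the functional and
    its gradient; works for non-convex ``R`` (hence the absolute value).
    """
    x = np.asarray(x, dtype=np.float64)
    x_star = np.asarray(x_star, dtype=np.float64)
    diff = (x - x_star).ravel()
    g = np.asarray(R_grad(x_star), dtype=np.float64).ravel()
    return float(abs(R_value(x) - R_value(x_star) - g @ diff))
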