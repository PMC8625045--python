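"""Photoacoustic forward operator built from Kaiser-Bessel (KB) basis atoms.

The initial pressure is expanded in translates of a radially symmetric,
compactly supported generalized Kaiser-Bessel function.  Because the 3D wave
equation with a radial initial condition has a closed-form solution
(Poisson-Kirchhoff), each system-matrix entry — the pressure trace of one
atom at one sensor and time — is evaluated analytically ("pseudo-3D"
modelling of a 2D circular-detection geometry).

The masked operator ``W @ diag(mask)`` is stabilized by a truncated SVD:
singular values below a threshold ``sigma_star`` are set to zero, which makes
both the forward matrix ``A = U S* V^T`` and its Moore-Penrose pseudoinverse
``A^+ = V S*^+ U^T`` explicit and cheap to apply.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import scipy.linalg
from scipy.special import iv

from .geometry import GridSpec, SensorGeometry

__all__ = [
    "KBParams",
    "SystemMatrix",
    "TruncatedOperator",
    "kb_profile",
    "kb_pressure",
    "assemble_system_matrix",
    "truncate_operator",
    "forward_apply",
    "pinv_apply",
    "simulate_noisy_data",
]

#: refuse dense system matrices above this grid size unless overridden
DEFAULT_GRID_CAP = 192


@dataclass(frozen=True)
class KBParams:
    """Generalized Kaiser-Bessel profile parameters.

    ``m`` is the smoothness order (``m >= 1`` makes the profile vanish
    continuously at the support boundary), ``gamma`` the window taper, and
    ``R`` the support radius in the same length units as the grid (the
    detection circle has radius 1).
    """

    m: int = 2
    gamma: float = 3.0
    R: float = 0.05

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"KB order m must be >= 1, got {self.m}")
        if self.gamma <= 0:
            raise ValueError(f"KB taper gamma must be > 0, got {self.gamma}")
        if self.R <= 0:
            raise ValueError(f"KB support radius R must be > 0, got {self.R}")

    @classmethod
    def for_grid(cls, grid: GridSpec, m: int = 2, gamma: float = 3.0,
                 radius_in_pixels: float = 2.0) -> "KBParams":
        """Default atom sized relative to the pixel spacing."""
        return cls(m=m, gamma=gamma, R=radius_in_pixels * grid.spacing)


def kb_profile(rho, kb: KBParams):
    """Radial KB profile ``psi(rho)``.

    ``psi(rho) = (1 - rho^2/R^2)^(m/2) * I_m(gamma*sqrt(1 - rho^2/R^2)) / I_m(gamma)``
    for ``rho <= R`` and 0 beyond the support.  ``I_m`` is the modified Bessel
    function of the first kind.  Accepts scalars or arrays; ``rho >= 0``.
    """
    rho = np.asarray(rho, dtype=np.float64)
    if np.any(rho < 0):
        raise ValueError("radial distance rho must be >= 0")
    u2 = np.clip(1.0 - (rho / kb.R) ** 2, 0.0, None)
    root = np.sqrt(u2)
    val = u2 ** (kb.m / 2.0) * iv(kb.m, kb.gamma * root) / iv(kb.m, kb.gamma)
    return np.where(rho <= kb.R, val, 0.0)[()]


def kb_pressure(d, t, kb: KBParams):
    """Pressure trace of a KB atom: 3D wave solution at distance ``d``, time ``t``.

    For a radially symmetric initial pressure ``psi`` and zero initial
    velocity, the Poisson-Kirchhoff formula ``p = d/dt (t * spherical mean)``
    reduces to the closed form

        ``p(d, t) = (1/(2d)) * [ g(d+t) - sign(t-d) * g(|d-t|) ]``

    with ``g(rho) = rho * psi(rho)``.  The trace vanishes whenever the sphere
    of radius ``t`` around the sensor misses the support ball
    (``t < d - R`` or ``t > d + R``).  Broadcasts over ``d`` and ``t``.
    """
    d = np.asarray(d, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if np.any(d <= 0):
        raise ValueError("sensor-to-center distance d must be > 0")
    if np.any(d < 1e-9):
        raise ValueError("distance d below 1e-9: atom center coincides with sensor")
    if np.any(t < 0):
        raise ValueError("time t must be >= 0")
    d, t = np.broadcast_arrays(d, t)

    def g(rho):
        return rho * kb_profile(rho, kb)

    p = (g(d + t) - np.sign(t - d) * g(np.abs(d - t))) / (2.0 * d)
    return p[()]


@dataclass(frozen=True)
class SystemMatrix:
    """Dense PAT model matrix ``W`` of shape ``(Nt*Ns, N^2)``.

    Row ``Nt*(k-1) + j`` holds sensor ``k``'s trace at time ``t_j``; column
    ``N*(i1-1) + i2`` corresponds to the atom centered at pixel ``i``.
    """

    W: np.ndarray
    grid: GridSpec
    geom: SensorGeometry
    kb: KBParams

    def __post_init__(self) -> None:
        expected = (self.geom.Nt * self.geom.Ns, self.grid.n_pixels)
        if self.W.shape != expected:
            raise ValueError(f"system matrix shape {self.W.shape} != expected {expected}")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("system matrix contains non-finite entries")


def assemble_system_matrix(grid: GridSpec, geom: SensorGeometry, kb: KBParams,
                           max_grid_size: int = DEFAULT_GRID_CAP) -> SystemMatrix:
    """Evaluate ``W[Nt*(k-1)+j, N*(i1-1)+i2] = p_kb(||s_k - c(i)||, t_j)``.

    Dense assembly; refuses grids above ``max_grid_size`` pixels per axis to
    avoid accidental huge allocations (raise the cap explicitly to override).
    """
    if grid.N > max_grid_size:
        raise MemoryError(
            f"grid N={grid.N} exceeds the dense-matrix cap {max_grid_size}; "
            "pass max_grid_size explicitly to override")
    centers = grid.pixel_centers()              # (N^2, 2)
    sensors = geom.sensor_locations()           # (Ns, 2)
    times = geom.time_samples()                 # (Nt,)
    n_pix = grid.n_pixels
    W = np.empty((geom.Nt * geom.Ns, n_pix))
    for k in range(geom.Ns):
        d = np.linalg.norm(centers - sensors[k], axis=1)    # (N^2,)
        W[k * geom.Nt:(k + 1) * geom.Nt] = kb_pressure(d[None, :], times[:, None], kb)
    return SystemMatrix(W=W, grid=grid, geom=geom, kb=kb)


@dataclass(frozen=True)
class TruncatedOperator:
    """Truncated SVD of the masked system matrix ``W @ diag(mask)``.

    Stores the retained factors ``U_r, s_r, Vt_r`` (singular values strictly
    above ``sigma_star``, non-increasing), giving the forward matrix
    ``A = U_r diag(s_r) Vt_r`` and pseudoinverse ``A^+ = Vt_r^T diag(1/s_r) U_r^T``.
    """

    U: np.ndarray          # (n_data, r)
    s: np.ndarray          # (r,) retained singular values
    Vt: np.ndarray         # (r, n_coef)
    sigma_star: float
    maskvec: np.ndarray    # (n_coef,) binary

    def __post_init__(self) -> None:
        if self.s.ndim != 1 or np.any(np.diff(self.s) > 0):
            raise ValueError("retained singular values must be 1-D and non-increasing")
        if np.any(self.s <= self.sigma_star):
            raise ValueError("all retained singular values must exceed sigma_star")

    @property
    def rank(self) -> int:
        return int(self.s.size)

    @property
    def n_data(self) -> int:
        return self.U.shape[0]

    @property
    def n_coef(self) -> int:
        return self.Vt.shape[1]

    @cached_property
    def A(self) -> np.ndarray:
        """Dense forward matrix ``U S* V^T``."""
        return (self.U * self.s) @ self.Vt

    @cached_property
    def A_pinv(self) -> np.ndarray:
        """Dense Moore-Penrose pseudoinverse ``V S*^+ U^T``."""
        return (self.Vt.T / self.s) @ self.U.T

    def normal_matrix(self) -> np.ndarray:
        """Dense ``A^T A`` (Gram matrix on coefficient space)."""
        return (self.Vt.T * self.s**2) @ self.Vt


def truncate_operator(Wm: SystemMatrix | np.ndarray, maskvec: np.ndarray,
                      sigma_star: float = 0.0, *,
                      relative: bool = False) -> TruncatedOperator:
    """SVD of ``W @ diag(maskvec)`` with singular values ``<= sigma_star`` zeroed.

    Parameters
    ----------
    Wm
        System matrix (or raw 2-D array).
    maskvec
        Binary vector of length ``N^2``; masked pixels (0 entries) are
        annihilated by the operator.
    sigma_star
        Truncation threshold, >= 0.  With ``relative=True`` it is interpreted
        as a fraction of the largest singular value.
    """
    W = Wm.W if isinstance(Wm, SystemMatrix) else np.asarray(Wm, dtype=np.float64)
    maskvec = np.asarray(maskvec, dtype=np.float64)
    if maskvec.shape != (W.shape[1],):
        raise ValueError(f"mask length {maskvec.shape} does not match {W.shape[1]} columns")
    if sigma_star < 0:
        raise ValueError(f"sigma_star must be >= 0, got {sigma_star}")
    try:
        U, s, Vt = scipy.linalg.svd(W * maskvec[None, :], full_matrices=False)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - LAPACK failure
        raise scipy.linalg.LinAlgError(
            f"SVD of the masked {W.shape} system matrix did not converge") from exc
    thresh = sigma_star * s[0] if (relative and s.size) else sigma_star
    keep = s > thresh
    return TruncatedOperator(U=U[:, keep], s=s[keep], Vt=Vt[keep],
                             sigma_star=float(thresh), maskvec=maskvec)


def forward_apply(op: TruncatedOperator, x: np.ndarray) -> np.ndarray:
    """Data ``A x`` for a coefficient vector ``x`` of length ``N^2``."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (op.n_coef,):
        raise ValueError(f"coefficient vector shape {x.shape} != ({op.n_coef},)")
    return op.U @ (op.s * (op.Vt @ x))


def pinv_apply(op: TruncatedOperator, y: np.ndarray) -> np.ndarray:
    """Basic reconstruction ``A^+ y`` for a data vector ``y``."""
    y = np.asarray(y, dtype=np.float64)
    if y.shape != (op.n_data,):
        raise ValueError(f"data vector shape {y.shape} != ({op.n_data},)")
    return op.Vt.T @ ((op.U.T @ y) / op.s)


def simulate_noisy_data(op: TruncatedOperator, x: np.ndarray, sigma: float,
                        seed: int) -> np.ndarray:
    """``A x`` plus i.i.d. Gaussian noise of standard deviation ``sigma * ||Ax||_inf``.

    ``sigma`` is the relative noise level (0 gives exact data); ``seed`` makes
    the draw reproducible.
    """
    if sigma < 0:
        raise ValueError(f"noise level sigma must be >= 0, got {sigma}")
    y = forward_apply(op, x)
    if sigma == 0:
        return y
    scale = sigma * np.max(np.abs(y))
    rng = np.random.default_rng(seed)
    return y + scale * rng.standard_normal(y.shape)
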