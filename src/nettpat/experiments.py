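"""Reconstruction study and numerical convergence-rate verification.

Two harnesses:

* :func:`reconstruction_study` reruns the masked-PAT comparison — the
  pseudoinverse baseline ``A^+ y``, the post-processing network
  ``Phi(A^+ y)``, and the full NETT minimization — over a set of test
  phantoms and noise levels, collecting mean squared errors in a tidy table.

* :func:`rates_experiment` checks the convergence-rate theory on a
  controlled toy problem: an ill-conditioned linear operator with a
  quadratic regularizer ``R(x) = ||x||^2`` whose true solution satisfies the
  source condition ``R'(x+) = A^T eta``.  With the parameter choice
  ``alpha ∝ eps`` (``eps`` the noise norm; the theory's noise level is the
  squared norm ``delta = eps^2``) the Bregman distance
  ``B_R(x_alpha, x+) = ||x_alpha - x+||^2`` should decay like ``O(eps)``,
  i.e. log-log slope 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import KBParams, TruncatedOperator, assemble_system_matrix, \
    pinv_apply, simulate_noisy_data
from .geometry import GridSpec, MaskSpec, build_geometry, mask_indicator
from .phantoms import RingPhantomConfig, default_ood_circles, generate_dataset, \
    phantom_seeds, square_ring_phantom
from .regularizer import LearnedRegularizer, NetworkSpec, TrainConfig, \
    train_regularizer
from .solver import SolverConfig, bregman_distance, default_alpha, \
    forward_backward_solve, post_process, stable_tv_eps

__all__ = [
    "RatesConfig",
    "RatesResult",
    "StudyReport",
    "mse",
    "reconstruction_study",
    "ood_comparison",
    "rates_experiment",
    "build_study_operator",
    "masked_pat_study",
]


def mse(x: np.ndarray, x_ref: np.ndarray) -> float:
    """Mean squared error between two equal-shape arrays."""
    x = np.asarray(x, dtype=np.float64)
    x_ref = np.asarray(x_ref, dtype=np.float64)
    if x.shape != x_ref.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_ref.shape}")
    return float(np.mean((x - x_ref) ** 2))


# ---------------------------------------------------------------------------
# reconstruction study

@dataclass(frozen=True)
class StudyReport:
    """Per-item MSE table and method-level aggregates.

    ``table`` has one row per (phantom, noise level, method) with columns
    ``phantom``, ``sigma``, ``method``, ``mse``; ``means`` aggregates over
    phantoms.
    """

    table: pd.DataFrame
    means: pd.DataFrame
    seed: int

    def __post_init__(self) -> None:
        if self.table["mse"].isna().any() or (self.table["mse"] < 0).any():
            raise ValueError("study table contains missing or negative MSE cells")

    def mean_mse(self, method: str, sigma: float | None = None) -> float:
        t = self.table[self.table["method"] == method]
        if sigma is not None:
            t = t[t["sigma"] == sigma]
        if t.empty:
            raise KeyError(f"no rows for method={method!r}, sigma={sigma}")
        return float(t["mse"].mean())


def reconstruction_study(op: TruncatedOperator,
                         regs: dict[str, LearnedRegularizer],
                         phantoms: np.ndarray,
                         noise_levels: list[float],
                         solver_cfgs: dict[float, SolverConfig] | None = None,
                         seed: int = 0,
                         post_reg: str | None = None,
                         stabilize_tv: bool = True) -> StudyReport:
    """MSE comparison of pseudoinverse, post-processing and NETT methods.

    Parameters
    ----------
    regs
        Named learned regularizers; each contributes a ``nett:<name>`` method
        column.  ``post_reg`` selects which network drives the
        post-processing baseline (default: the first).
    phantoms
        Array ``(n_phantoms, N^2)`` of ground-truth images.
    noise_levels
        Relative noise levels ``sigma``; each gets its own simulated data.
    solver_cfgs
        Optional per-noise-level solver settings; defaults to the study
        settings (``Niter=15, s=0.25`` and the per-noise ``alpha``).
    stabilize_tv
        Raise each regularizer's TV smoothing to :func:`stable_tv_eps` for
        the solve, keeping the explicit TV gradient step non-expansive at
        the configured step size (see the solver module).
    """
    import dataclasses
    if len(phantoms) < 1 or len(noise_levels) < 1:
        raise ValueError("need at least one phantom and one noise level")
    if not regs:
        raise ValueError("need at least one regularizer")
    post_reg = post_reg or next(iter(regs))
    noise_seeds = np.random.SeedSequence(seed).generate_state(
        len(phantoms) * len(noise_levels))
    rows = []
    for p_idx, x_true in enumerate(phantoms):
        for s_idx, sigma in enumerate(noise_levels):
            item_seed = int(noise_seeds[p_idx * len(noise_levels) + s_idx])
            y = simulate_noisy_data(op, x_true, sigma, seed=item_seed)
            recons = {"pinv": pinv_apply(op, y),
                      "postproc": post_process(op, regs[post_reg], y)}
            for name, reg in regs.items():
                cfg = (solver_cfgs or {}).get(sigma) or SolverConfig(
                    alpha=default_alpha(sigma))
                if stabilize_tv and reg.beta > 0:
                    eps = max(reg.eps, stable_tv_eps(cfg.alpha, reg.beta, cfg.s))
                    reg = dataclasses.replace(reg, eps=eps)
                res = forward_backward_solve(op, reg, y, cfg)
                recons[f"nett:{name}"] = res.x
            for method, xr in recons.items():
                rows.append({"phantom": p_idx, "sigma": sigma, "method": method,
                             "mse": mse(xr, x_true)})
    table = pd.DataFrame(rows)
    means = (table.groupby(["method", "sigma"], as_index=False)["mse"].mean()
             .rename(columns={"mse": "mean_mse"}))
    return StudyReport(table=table, means=means, seed=seed)


def ood_comparison(op: TruncatedOperator, reg: LearnedRegularizer,
                   phantom: np.ndarray, noise_levels: list[float],
                   seed: int = 0) -> pd.DataFrame:
    """NETT vs post-processing on a single out-of-distribution phantom.

    Runs both methods at every noise level (study solver settings, TV step
    stabilized as in :func:`reconstruction_study`) and returns a table with
    columns ``sigma``, ``mse_nett``, ``mse_postproc``, ``mse_pinv``.
    """
    import dataclasses

    seeds = np.random.SeedSequence(seed).generate_state(len(noise_levels))
    rows = []
    for s_idx, sigma in enumerate(noise_levels):
        y = simulate_noisy_data(op, phantom, sigma, seed=int(seeds[s_idx]))
        cfg = SolverConfig(alpha=default_alpha(sigma))
        solve_reg = reg
        if reg.beta > 0:
            eps = max(reg.eps, stable_tv_eps(cfg.alpha, reg.beta, cfg.s))
            solve_reg = dataclasses.replace(reg, eps=eps)
        res = forward_backward_solve(op, solve_reg, y, cfg)
        rows.append({"sigma": sigma,
                     "mse_nett": mse(res.x, phantom),
                     "mse_postproc": mse(post_process(op, reg, y), phantom),
                     "mse_pinv": mse(pinv_apply(op, y), phantom)})
    return pd.DataFrame(rows)


def build_study_operator(N: int = 64, Ns: int = 75, Nt: int = 64,
                         mask_width: float = 0.34) -> tuple[TruncatedOperator,
                                                            GridSpec]:
    """Masked, truncated PAT operator at the reduced study scale.

    This is the expensive, fully deterministic part of the end-to-end study
    (dense system-matrix assembly plus its SVD); build it once and share it
    across seeds.
    """
    from .forward import truncate_operator

    grid, geom = build_geometry(N=N, Ns=Ns, Nt=Nt)
    kb = KBParams.for_grid(grid)
    W = assemble_system_matrix(grid, geom, kb)
    maskvec = mask_indicator(grid, MaskSpec(width=mask_width))
    op = truncate_operator(W, maskvec, sigma_star=1e-3, relative=True)
    return op, grid


def masked_pat_study(op: TruncatedOperator, grid: GridSpec, seed: int, *,
                     n_train: int = 200, sigma_train: float = 0.01,
                     epochs: int = 5, depth: int = 1, base_channels: int = 16,
                     noise_levels: tuple[float, ...] = (0.0, 0.01, 0.1),
                     n_test: int = 10, test_seed: int = 915148001,
                     ) -> dict:
    """One full pass of the reduced-scale reconstruction study.

    Generates ``n_train`` training pairs at noise ``sigma_train``, trains the
    depth-``depth`` residual U-Net regularizer for ``epochs`` epochs, then
    evaluates pseudoinverse, post-processing and NETT on ``n_test`` held-out
    ring phantoms at every noise level, and on the out-of-distribution
    circles phantom.  The held-out phantoms come from a seed range disjoint
    from the training stream (fixed ``test_seed``).

    Returns a dict with the trained regularizer, the study report, the OOD
    table and the training curve.
    """
    data = generate_dataset(grid, op, n=n_train, sigma=sigma_train, seed=seed)
    spec = NetworkSpec(depth=depth, base_channels=base_channels, dtype="float32")
    reg, curve = train_regularizer(
        data, spec, TrainConfig(epochs=epochs, seed=seed))
    test = np.stack([square_ring_phantom(grid, RingPhantomConfig(), int(s))
                     for s in phantom_seeds(test_seed, n_test)])
    report = reconstruction_study(op, {"R1": reg}, test, list(noise_levels),
                                  seed=seed)
    ood = ood_comparison(op, reg, default_ood_circles(grid),
                         list(noise_levels), seed=seed)
    return {"regularizer": reg, "report": report, "ood": ood,
            "train_curve": curve, "seed": seed}


# ---------------------------------------------------------------------------
# convergence-rates toy problem

@dataclass(frozen=True)
class RatesConfig:
    """Toy-problem setup for the rate experiment.

    The operator is diagonal with geometrically decaying singular values
    ``decay**i`` (``n_modes`` of them); ``n_keep < n_modes`` truncates the
    spectrum, creating a null space.  The true solution is built from a
    source element ``eta`` as ``x+ = A^T eta / 2`` so that the quadratic
    regularizer ``R(x) = ||x||^2`` satisfies ``R'(x+) = A^T eta``; with
    ``source_violation > 0`` a null-space component of that size is added,
    breaking the condition.  ``alpha_rule`` maps the noise norm ``eps`` to
    the regularization weight (default ``alpha_scale * eps``).
    """

    n_modes: int = 12
    decay: float = 0.5
    n_keep: int | None = None
    eps_schedule: tuple[float, ...] = tuple(np.logspace(-1, -4, 7))
    alpha_scale: float = 1.0
    replications: int = 20
    source_violation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        eps = np.asarray(self.eps_schedule)
        if eps.size < 2 or np.any(eps <= 0) or np.any(np.diff(eps) >= 0):
            raise ValueError("eps schedule must be > 0 and strictly decreasing")
        if self.n_modes < 3:
            raise ValueError("toy operator needs at least 3 modes")
        if not (0 < self.decay < 1):
            raise ValueError("decay must be in (0, 1)")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")

    def singular_values(self) -> np.ndarray:
        s = self.decay ** np.arange(self.n_modes)
        if self.n_keep is not None:
            s = np.where(np.arange(self.n_modes) < self.n_keep, s, 0.0)
        return s


@dataclass(frozen=True)
class RatesResult:
    """Measured Bregman distances and the fitted log-log slope."""

    table: pd.DataFrame       # columns: eps, alpha, replication, bregman
    slope: float
    intercept: float
    config: RatesConfig


def _check_schedule(cfg: RatesConfig, s: np.ndarray, x_true: np.ndarray) -> None:
    """Joint parameter-choice sanity: alpha -> 0 and (delta + disc)/alpha -> 0.

    ``delta = eps^2`` is the theory's noise level (squared-norm discrepancy);
    the discretization term uses the truncated operator applied to the
    projected true solution.
    """
    eps = np.asarray(cfg.eps_schedule)
    alpha = cfg.alpha_scale * eps
    if not (np.all(alpha > 0) and np.all(np.diff(alpha) < 0) and alpha[-1] < alpha[0] / 10):
        raise ValueError("parameter schedule must send alpha to 0")
    # discrepancy of the best discrete approximant: ||A z - A x+||^2 with z the
    # projection onto the retained modes; zero here because A annihilates the
    # truncated modes, so the binding check is delta/alpha -> 0.
    ratio = eps**2 / alpha
    if not (np.all(np.diff(ratio) < 0) and ratio[-1] < ratio[0] / 10):
        raise ValueError("schedule violates (delta + discrepancy)/alpha -> 0")


def rates_experiment(cfg: RatesConfig) -> RatesResult:
    """Measure the Bregman-distance decay rate on the quadratic toy problem.

    For each noise norm ``eps`` in the schedule and each replication, draws a
    noise vector of exact norm ``eps``, sets ``alpha = alpha_scale * eps``,
    computes the exact Tikhonov minimizer
    ``x_alpha = (A^T A + 2 alpha I)^{-1} A^T y`` (closed form — no iterative
    solver error), and records ``B_R(x_alpha, x+) = ||x_alpha - x+||^2``.
    Returns the least-squares slope of ``log B`` against ``log eps`` pooled
    over replications.
    """
    s = cfg.singular_values()
    rng = np.random.default_rng(cfg.seed)
    # source element and true solution satisfying R'(x+) = 2 x+ = A^T eta
    eta = rng.standard_normal(cfg.n_modes)
    eta /= np.linalg.norm(eta)
    x_true = s * eta / 2.0
    if cfg.source_violation > 0:
        if cfg.n_keep is None or cfg.n_keep >= cfg.n_modes:
            raise ValueError("source_violation needs a truncated spectrum "
                             "(n_keep < n_modes) to have a null space")
        x_true = x_true.copy()
        x_true[cfg.n_keep:] += cfg.source_violation
    _check_schedule(cfg, s, x_true)
    y_exact = s * x_true
    R = lambda x: float(x @ x)
    Rg = lambda x: 2.0 * x
    rows = []
    for eps in cfg.eps_schedule:
        alpha = cfg.alpha_scale * eps
        for rep in range(cfg.replications):
            noise = rng.standard_normal(cfg.n_modes)
            noise *= eps / np.linalg.norm(noise)
            y = y_exact + noise
            x_alpha = s * y / (s**2 + 2.0 * alpha)
            b = bregman_distance(R, Rg, x_alpha, x_true)
            rows.append({"eps": eps, "alpha": alpha, "replication": rep,
                         "bregman": b})
    table = pd.DataFrame(rows)
    slope, intercept = np.polyfit(np.log(table["eps"]), np.log(table["bregman"]), 1)
    return RatesResult(table=table, slope=float(slope),
                       intercept=float(intercept), config=cfg)
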