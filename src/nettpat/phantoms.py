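"""Synthetic phantoms and training data for the masked PAT problem.

Training images are square-shaped rings (a square annulus) with a random,
smoothly varying intensity profile and a random location inside the unit
disc.  An out-of-distribution phantom made of filled circles probes how the
learned regularizer behaves on structure it never saw during training.
Training pairs couple each clean phantom ``x_a`` with its basic
reconstruction ``h_a = A^+ (A x_a + eta_a)``, the artifact- and noise-
contaminated image the regularizer is trained to push away from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import TruncatedOperator, pinv_apply, simulate_noisy_data
from .geometry import GridSpec

__all__ = [
    "RingPhantomConfig",
    "Dataset",
    "square_ring_phantom",
    "circles_phantom",
    "default_ood_circles",
    "generate_dataset",
    "phantom_seeds",
]

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class RingPhantomConfig:
    """Distribution of the random square-ring phantoms.

    Side length and thickness are in the grid's length units (detection circle
    radius 1).  Centers are drawn uniformly in the disc of radius
    ``1 - margin - side_max * sqrt(2)/2`` so the whole outer square always
    fits strictly inside the unit disc.
    """

    side_range: tuple[float, float] = (0.35, 0.7)
    thickness_range: tuple[float, float] = (0.06, 0.14)
    base_intensity_range: tuple[float, float] = (0.4, 1.0)
    profile_amplitude: float = 0.3
    rings_per_image: int = 1
    margin: float = 0.02

    def __post_init__(self) -> None:
        for name in ("side_range", "thickness_range", "base_intensity_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi, got ({lo}, {hi})")
        if not 1 <= self.rings_per_image <= 3:
            raise ValueError("rings_per_image must be in 1..3")
        if self.max_center_radius() <= 0:
            raise ValueError(
                f"side_range {self.side_range} cannot fit inside the unit disc")

    def max_center_radius(self) -> float:
        # outer-square half-diagonal must stay inside D1
        return 1.0 - self.margin - self.side_range[1] * _SQRT2 / 2.0


def _ring_image(grid: GridSpec, center: np.ndarray, side: float, thickness: float,
                base: float, coeffs: np.ndarray, amplitude: float) -> np.ndarray:
    """One square annulus with a low-order polynomial intensity modulation."""
    centers = grid.pixel_centers()
    rel = centers - center
    cheb = np.max(np.abs(rel), axis=1)                    # sup-norm distance
    half = side / 2.0
    inner = max(half - thickness, 0.0)
    on_ring = (cheb <= half) & (cheb > inner)
    # smooth random profile: base + low-order polynomial in scaled coordinates
    xi = rel / max(half, 1e-12)
    profile = base + amplitude * (
        coeffs[0] * xi[:, 0] + coeffs[1] * xi[:, 1] + coeffs[2] * xi[:, 0] * xi[:, 1])
    img = np.where(on_ring, np.clip(profile, 0.0, 1.0), 0.0)
    return img


def square_ring_phantom(grid: GridSpec, cfg: RingPhantomConfig, seed: int) -> np.ndarray:
    """Random square-ring phantom as a flat coefficient vector in ``[0, 1]``.

    Deterministic for a fixed ``seed``; support lies strictly inside the unit
    disc.  A zero-thickness draw degenerates to the empty image.
    """
    rng = np.random.default_rng(seed)
    img = np.zeros(grid.n_pixels)
    r_max = cfg.max_center_radius()
    for _ in range(cfg.rings_per_image):
        # uniform center in the admissible disc (by radius sqrt-transform)
        radius = r_max * np.sqrt(rng.uniform())
        angle = rng.uniform(0.0, 2.0 * np.pi)
        center = radius * np.array([np.cos(angle), np.sin(angle)])
        side = rng.uniform(*cfg.side_range)
        thickness = rng.uniform(*cfg.thickness_range)
        base = rng.uniform(*cfg.base_intensity_range)
        coeffs = rng.uniform(-1.0, 1.0, size=3)
        ring = _ring_image(grid, center, side, thickness, base, coeffs,
                           cfg.profile_amplitude)
        img = np.maximum(img, ring)
    return np.clip(img, 0.0, 1.0)


def circles_phantom(grid: GridSpec,
                    circles: list[tuple[tuple[float, float], float, float]]) -> np.ndarray:
    """Superposition of filled discs ``(center, radius, intensity)``, clipped to [0,1].

    Every disc must lie inside the unit disc.  An empty list yields the zero
    image; disjoint discs add.
    """
    centers = grid.pixel_centers()
    img = np.zeros(grid.n_pixels)
    for (cx, cy), radius, intensity in circles:
        if radius < 0:
            raise ValueError(f"circle radius must be >= 0, got {radius}")
        if np.hypot(cx, cy) + radius > 1.0:
            raise ValueError(
                f"circle at ({cx}, {cy}) with radius {radius} leaves the unit disc")
        inside = np.hypot(centers[:, 0] - cx, centers[:, 1] - cy) <= radius
        img[inside] += intensity
    return np.clip(img, 0.0, 1.0)


def default_ood_circles(grid: GridSpec) -> np.ndarray:
    """The held-out circles phantom used in the reconstruction study."""
    return circles_phantom(grid, [
        ((-0.35, -0.30), 0.28, 0.9),
        ((0.35, 0.25), 0.18, 0.6),
        ((0.05, 0.42), 0.10, 1.0),
        ((0.30, -0.40), 0.12, 0.75),
    ])


@dataclass(frozen=True)
class Dataset:
    """Paired training corpus: clean phantoms ``x`` and basic reconstructions ``h``.

    ``x`` and ``h`` have shape ``(n, N^2)``; row ``a`` satisfies
    ``h_a = A^+ (A x_a + eta_a)`` at relative noise level ``sigma``.
    """

    x: np.ndarray
    h: np.ndarray
    sigma: float
    seed: int

    def __post_init__(self) -> None:
        if self.x.shape != self.h.shape:
            raise ValueError(f"phantom/reconstruction shape mismatch: "
                             f"{self.x.shape} vs {self.h.shape}")

    def __len__(self) -> int:
        return self.x.shape[0]


def phantom_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-item seeds derived from a master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n)


def generate_dataset(grid: GridSpec, op: TruncatedOperator, n: int, sigma: float,
                     cfg: RingPhantomConfig | None = None, seed: int = 0) -> Dataset:
    """Generate ``n`` training pairs ``(x_a, h_a)``.

    Per-item seeds are derived deterministically from the master ``seed``, so
    regeneration is bit-identical.  The phantom seed stream and the noise seed
    stream are separated to keep phantoms independent of the noise level.
    """
    if n < 1:
        raise ValueError(f"dataset size must be >= 1, got {n}")
    cfg = cfg or RingPhantomConfig()
    seeds = phantom_seeds(master_seed=seed, n=2 * n)
    x = np.empty((n, grid.n_pixels))
    h = np.empty_like(x)
    for a in range(n):
        x[a] = square_ring_phantom(grid, cfg, seed=int(seeds[a]))
        y = simulate_noisy_data(op, x[a], sigma, seed=int(seeds[n + a]))
        h[a] = pinv_apply(op, y)
    return Dataset(x=x, h=h, sigma=sigma, seed=seed)
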