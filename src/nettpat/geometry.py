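"""Discretization geometry for the circular-detection photoacoustic problem.

The image domain is the square ``[-1, 1]^2`` circumscribing the unit disc
``D1`` on whose boundary the sensors sit.  Pixels are indexed by a pair
``i = (i1, i2)`` with ``i1, i2 in {1..N}`` and flattened with the column
convention ``N*(i1-1) + i2`` (1-based); internal arrays are 0-based with the
same ordering.  A "masked" diagonal stripe ``I`` models a region of the object
that generates no acoustic data, turning reconstruction into a combined
wave-inversion and inpainting problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "SensorGeometry",
    "MaskSpec",
    "build_geometry",
    "mask_indicator",
]

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class GridSpec:
    """Uniform ``N x N`` pixel lattice on ``[-1, 1]^2``.

    Pixel centers are ``c(i) = ((2*i1 - N - 1)/N, (2*i2 - N - 1)/N)`` for
    1-based ``(i1, i2)``: a lattice of spacing ``2/N`` that is symmetric under
    ``r -> -r`` and covers the unit disc.
    """

    N: int

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"grid size N must be >= 2, got {self.N}")

    @property
    def spacing(self) -> float:
        return 2.0 / self.N

    @property
    def n_pixels(self) -> int:
        return self.N * self.N

    def pixel_centers(self) -> np.ndarray:
        """All pixel centers, shape ``(N^2, 2)``, in flat-index order."""
        axis = (2.0 * np.arange(1, self.N + 1) - self.N - 1) / self.N
        c1, c2 = np.meshgrid(axis, axis, indexing="ij")
        return np.column_stack([c1.ravel(), c2.ravel()])

    def flat_index(self, i1: int, i2: int) -> int:
        """1-based index pair -> 1-based flat index ``N*(i1-1) + i2``."""
        if not (1 <= i1 <= self.N and 1 <= i2 <= self.N):
            raise ValueError(f"index pair ({i1}, {i2}) outside 1..{self.N}")
        return self.N * (i1 - 1) + i2

    def index_pair(self, flat: int) -> tuple[int, int]:
        """1-based flat index -> 1-based index pair."""
        if not (1 <= flat <= self.n_pixels):
            raise ValueError(f"flat index {flat} outside 1..{self.n_pixels}")
        return (flat - 1) // self.N + 1, (flat - 1) % self.N + 1


@dataclass(frozen=True)
class SensorGeometry:
    """``Ns`` sensors uniformly spaced on the unit circle, ``Nt`` uniform
    measurement times in ``[0, 2]`` (the time a wavefront needs to traverse
    the disc diameter at unit sound speed)."""

    Ns: int
    Nt: int
    angular_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.Ns < 2 or self.Nt < 2:
            raise ValueError("need at least 2 sensors and 2 time samples")

    def sensor_locations(self) -> np.ndarray:
        """Sensor positions on ``S^1``, shape ``(Ns, 2)``."""
        theta = self.angular_offset + 2.0 * np.pi * np.arange(self.Ns) / self.Ns
        return np.column_stack([np.cos(theta), np.sin(theta)])

    def time_samples(self) -> np.ndarray:
        """Strictly increasing times, first 0, last 2, shape ``(Nt,)``."""
        return np.linspace(0.0, 2.0, self.Nt)


@dataclass(frozen=True)
class MaskSpec:
    """Diagonal stripe ``I = { r : |r . u| < width/2 }`` of no-data pixels.

    ``orientation="main"`` puts the stripe along the diagonal ``x1 = x2``
    (``u = (1, -1)/sqrt(2)``); ``"anti"`` along ``x1 = -x2``.
    """

    width: float = 0.34
    orientation: str = "main"

    def __post_init__(self) -> None:
        if self.width < 0:
            raise ValueError(f"stripe width must be >= 0, got {self.width}")
        if self.orientation not in ("main", "anti"):
            raise ValueError(f"orientation must be 'main' or 'anti', got {self.orientation!r}")

    def normal(self) -> np.ndarray:
        """Unit normal of the stripe's center line."""
        if self.orientation == "main":
            return np.array([1.0, -1.0]) / _SQRT2
        return np.array([1.0, 1.0]) / _SQRT2


def build_geometry(N: int, Ns: int, Nt: int) -> tuple[GridSpec, SensorGeometry]:
    """Construct the pixel grid and the sensor/time sampling.

    Parameters
    ----------
    N
        Pixels per image axis.
    Ns
        Number of sensors on the unit circle.
    Nt
        Number of time samples in ``[0, 2]``.
    """
    if N < 2 or Ns < 2 or Nt < 2:
        raise ValueError(f"counts must be >= 2, got N={N}, Ns={Ns}, Nt={Nt}")
    return GridSpec(N=N), SensorGeometry(Ns=Ns, Nt=Nt)


def mask_indicator(grid: GridSpec, mask: MaskSpec) -> np.ndarray:
    """Binary vector of length ``N^2``: 1 where the pixel center lies outside
    the stripe ``I`` (i.e. at perpendicular distance >= width/2 from the
    diagonal line), 0 on masked pixels.  Ordering follows the flat pixel
    convention ``N*(i1-1) + i2``.
    """
    centers = grid.pixel_centers()
    dist = np.abs(centers @ mask.normal())
    return (dist >= mask.width / 2.0).astype(np.float64)
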