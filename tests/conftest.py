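import numpy as np
import pytest

from nettpat.forward import KBParams, assemble_system_matrix, truncate_operator
from nettpat.geometry import GridSpec, MaskSpec, SensorGeometry, build_geometry, \
    mask_indicator


@pytest.fixture(scope="session")
def small_geometry():
    """N=16 grid with a 12-sensor, 16-sample circle: cheap but non-trivial."""
    return build_geometry(N=16, Ns=12, Nt=16)


@pytest.fixture(scope="session")
def small_operator(small_geometry):
    """Masked, truncated operator on the small geometry."""
    grid, geom = small_geometry
    kb = KBParams.for_grid(grid)
    W = assemble_system_matrix(grid, geom, kb)
    mask = mask_indicator(grid, MaskSpec(width=0.34))
    op = truncate_operator(W, mask, sigma_star=1e-3, relative=True)
    return op


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
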