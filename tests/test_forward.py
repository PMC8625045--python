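import math

import numpy as np
import pytest

from nettpat.forward import KBParams, assemble_system_matrix, forward_apply, \
    kb_pressure, kb_profile, pinv_apply, simulate_noisy_data, truncate_operator
from nettpat.geometry import GridSpec, MaskSpec, SensorGeometry, build_geometry, \
    mask_indicator


# ---------------------------------------------------------------------------
# independent oracles

def bessel_iv_series(m: int, z: float, terms: int = 60) -> float:
    """Modified Bessel function I_m(z) by direct power-series summation."""
    total = 0.0
    for k in range(terms):
        total += (z / 2.0) ** (m + 2 * k) / (math.factorial(k) * math.factorial(k + m))
    return total


def kb_profile_series(rho: float, kb: KBParams) -> float:
    if rho > kb.R:
        return 0.0
    u2 = 1.0 - (rho / kb.R) ** 2
    return u2 ** (kb.m / 2) * bessel_iv_series(kb.m, kb.gamma * math.sqrt(u2)) \
        / bessel_iv_series(kb.m, kb.gamma)


def spherical_mean(d: float, t: float, kb: KBParams, nodes: int = 240) -> float:
    """Mean of the radial profile over the sphere of radius t at distance d.

    Gauss-Legendre in the polar angle, restricted to the angular window where
    the sphere intersects the profile's support ball (the integrand vanishes
    outside, and restricting keeps the quadrature spectrally accurate).
    """
    if t <= 0:
        return float(kb_profile(d, kb))
    cos_edge = (d * d + t * t - kb.R**2) / (2 * d * t)
    if cos_edge >= 1.0:
        return 0.0
    theta_max = np.arccos(max(cos_edge, -1.0))
    theta, w = np.polynomial.legendre.leggauss(nodes)
    theta = 0.5 * theta_max * (theta + 1.0)
    w = w * 0.5 * theta_max
    rho = np.sqrt(np.maximum(d * d + t * t - 2 * d * t * np.cos(theta), 0.0))
    vals = np.asarray(kb_profile(rho, kb))
    return float(np.sum(w * vals * np.sin(theta)) / 2.0)


def pressure_quadrature(d: float, t: float, kb: KBParams, dt: float = 1e-5) -> float:
    """Wave solution via d/dt [ t * spherical mean ], central differences."""
    f = lambda tt: tt * spherical_mean(d, tt, kb)
    return (f(t + dt) - f(max(t - dt, 0.0))) / (dt + min(t, dt))


# ---------------------------------------------------------------------------

class TestKBProfile:
    def test_unit_peak_and_zero_boundary(self):
        kb = KBParams(m=2, gamma=3.0, R=0.4)
        assert kb_profile(0.0, kb) == pytest.approx(1.0)
        assert kb_profile(kb.R, kb) == pytest.approx(0.0, abs=1e-14)
        assert kb_profile(kb.R * 1.5, kb) == 0.0

    def test_half_radius_value_matches_bessel_series(self):
        kb = KBParams(m=2, gamma=3.0, R=1.0)
        expected = 0.75 * bessel_iv_series(2, 3.0 * math.sqrt(0.75)) \
            / bessel_iv_series(2, 3.0)
        assert kb_profile(0.5, kb) == pytest.approx(expected, rel=1e-12)

    def test_profile_series_agreement_on_grid(self):
        kb = KBParams(m=3, gamma=2.5, R=0.3)
        for rho in np.linspace(0, 0.3, 13):
            assert kb_profile(rho, kb) == pytest.approx(
                kb_profile_series(rho, kb), rel=1e-10, abs=1e-12)

    def test_negative_rho_rejected(self):
        with pytest.raises(ValueError):
            kb_profile(-0.1, KBParams())


class TestKBPressure:
    def test_zero_before_wave_arrives(self):
        kb = KBParams(m=2, gamma=3.0, R=0.1)
        assert kb_pressure(1.5, 0.1, kb) == 0.0
        assert kb_pressure(1.5, 1.7, kb) == 0.0  # after the wave passed

    def test_initial_condition_is_profile(self):
        kb = KBParams(m=2, gamma=3.0, R=0.3)
        for d in [0.1, 0.25, 0.5]:
            assert kb_pressure(d, 0.0, kb) == pytest.approx(kb_profile(d, kb),
                                                            rel=1e-12)

    def test_closed_form_matches_quadrature_oracle(self):
        # (d, t) = (0.8, 0.85) is the exact wave-departure time t = d + R,
        # where the true value is 0: both routes must agree there too
        kb = KBParams(m=2, gamma=3.0, R=0.05)
        val = kb_pressure(0.8, 0.85, kb)
        oracle = pressure_quadrature(0.8, 0.85, kb)
        assert val == pytest.approx(oracle, rel=1e-4, abs=1e-8)
        # and at an interior point of the arrival window
        val_in = kb_pressure(0.8, 0.79, kb)
        oracle_in = pressure_quadrature(0.8, 0.79, kb)
        assert abs(val_in) > 1e-4
        assert val_in == pytest.approx(oracle_in, rel=1e-4)

    def test_quadrature_agreement_over_dt_plane(self):
        """Closed form vs spherical-mean quadrature + time differentiation."""
        kb = KBParams(m=2, gamma=3.0, R=0.15)
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(25):
            d = rng.uniform(0.2, 2.0)
            t = rng.uniform(0.0, 2.0)
            ref = pressure_quadrature(d, t, kb)
            got = float(kb_pressure(d, t, kb))
            worst = max(worst, abs(got - ref) / max(abs(ref), 1e-3))
        assert worst < 1e-4

    def test_invalid_distance_rejected(self):
        with pytest.raises(ValueError):
            kb_pressure(0.0, 0.5, KBParams())


class TestSystemMatrix:
    def test_shape(self):
        grid, geom = build_geometry(N=4, Ns=3, Nt=5)
        W = assemble_system_matrix(grid, geom, KBParams.for_grid(grid))
        assert W.W.shape == (15, 16)

    def test_columns_reproduce_atom_traces(self):
        grid, geom = build_geometry(N=4, Ns=3, Nt=5)
        kb = KBParams.for_grid(grid)
        W = assemble_system_matrix(grid, geom, kb)
        centers = grid.pixel_centers()
        sensors = geom.sensor_locations()
        times = geom.time_samples()
        i, k = 5, 2
        d = np.linalg.norm(sensors[k] - centers[i])
        col = W.W[k * geom.Nt:(k + 1) * geom.Nt, i]
        assert np.allclose(col, kb_pressure(d, times, kb))

    def test_origin_atom_gives_identical_sensor_blocks(self):
        # odd N so one pixel center sits exactly at the origin
        grid, geom = build_geometry(N=5, Ns=6, Nt=8)
        kb = KBParams.for_grid(grid)
        W = assemble_system_matrix(grid, geom, kb)
        i_origin = grid.flat_index(3, 3) - 1
        blocks = W.W[:, i_origin].reshape(geom.Ns, geom.Nt)
        assert np.allclose(blocks, blocks[0])

    def test_causal_support_window(self):
        """Traces vanish outside the wave-arrival window [d-R, d+R]."""
        grid, geom = build_geometry(N=8, Ns=4, Nt=64)
        kb = KBParams.for_grid(grid)
        W = assemble_system_matrix(grid, geom, kb)
        centers = grid.pixel_centers()
        sensors = geom.sensor_locations()
        times = geom.time_samples()
        for k in (0, 2):
            for i in (0, 20, 63):
                d = np.linalg.norm(sensors[k] - centers[i])
                trace = W.W[k * geom.Nt:(k + 1) * geom.Nt, i]
                outside = (times < d - kb.R) | (times > d + kb.R)
                assert np.all(trace[outside] == 0)

    def test_grid_cap_enforced(self):
        grid, geom = build_geometry(N=16, Ns=4, Nt=8)
        with pytest.raises(MemoryError):
            assemble_system_matrix(grid, geom, KBParams.for_grid(grid),
                                   max_grid_size=8)


class TestTruncatedOperator:
    def test_no_truncation_recovers_matrix(self, rng):
        W = rng.standard_normal((10, 6))
        op = truncate_operator(W, np.ones(6), sigma_star=0.0)
        assert np.allclose(op.A, W)

    def test_diagonal_truncation_rank(self):
        W = np.diag([3.0, 1.0, 0.1])
        op = truncate_operator(W, np.ones(3), sigma_star=0.5)
        assert op.rank == 2
        assert np.allclose(np.sort(op.s)[::-1], [3.0, 1.0])

    def test_moore_penrose_identities(self, rng):
        W = rng.standard_normal((20, 12))
        op = truncate_operator(W, np.ones(12), sigma_star=0.5)
        A, Ap = op.A, op.A_pinv
        assert np.linalg.norm(A @ Ap @ A - A) / np.linalg.norm(A) < 1e-10
        assert np.linalg.norm(Ap @ A @ Ap - Ap) / np.linalg.norm(Ap) < 1e-10

    def test_retained_values_subset_of_masked_spectrum(self, small_operator,
                                                       small_geometry):
        grid, geom = small_geometry
        kb = KBParams.for_grid(grid)
        W = assemble_system_matrix(grid, geom, kb)
        mask = mask_indicator(grid, MaskSpec(width=0.34))
        full = np.linalg.svd(W.W * mask[None, :], compute_uv=False)
        for s in small_operator.s:
            assert np.min(np.abs(full - s)) / s < 1e-10

    def test_masked_pixels_annihilated(self, small_operator, rng):
        x = rng.standard_normal(small_operator.n_coef)
        y_full = forward_apply(small_operator, x)
        y_masked = forward_apply(small_operator, small_operator.maskvec * x)
        assert np.allclose(y_full, y_masked, atol=1e-10)

    def test_pinv_is_projector_on_retained_subspace(self, small_operator, rng):
        op = small_operator
        coeffs = rng.standard_normal(op.rank)
        x = op.Vt.T @ coeffs  # lives in the retained right-singular subspace
        back = pinv_apply(op, forward_apply(op, x))
        assert np.linalg.norm(back - x) / np.linalg.norm(x) < 1e-8

    def test_linearity_and_zero(self, small_operator):
        z = np.zeros(small_operator.n_coef)
        assert np.all(forward_apply(small_operator, z) == 0)
        assert np.all(pinv_apply(small_operator, np.zeros(small_operator.n_data)) == 0)

    def test_shape_mismatch_rejected(self, small_operator):
        with pytest.raises(ValueError):
            forward_apply(small_operator, np.zeros(3))
        with pytest.raises(ValueError):
            pinv_apply(small_operator, np.zeros(3))


class TestNoise:
    def test_zero_sigma_exact(self, small_operator, rng):
        x = rng.uniform(size=small_operator.n_coef)
        assert np.array_equal(simulate_noisy_data(small_operator, x, 0.0, seed=1),
                              forward_apply(small_operator, x))

    def test_seed_reproducibility(self, small_operator, rng):
        x = rng.uniform(size=small_operator.n_coef)
        a = simulate_noisy_data(small_operator, x, 0.05, seed=11)
        b = simulate_noisy_data(small_operator, x, 0.05, seed=11)
        c = simulate_noisy_data(small_operator, x, 0.05, seed=12)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_noise_scale_monte_carlo(self, small_operator, rng):
        """Empirical noise std matches sigma * ||Ax||_inf within 3%."""
        x = rng.uniform(size=small_operator.n_coef)
        y0 = forward_apply(small_operator, x)
        sigma = 0.1
        draws = np.stack([simulate_noisy_data(small_operator, x, sigma, seed=s) - y0
                          for s in range(100)])
        expected = sigma * np.abs(y0).max()
        assert np.std(draws) == pytest.approx(expected, rel=0.03)
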