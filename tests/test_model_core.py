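"""Geometry, kernel and force-field tests for the interaction model."""

import numpy as np
import pytest

from oncostream import (
    CellConfiguration,
    ModelParams,
    guard_singularity,
    minimum_image,
    normalized_distance_sq,
    phi,
    phi_prime,
    project_tangent,
    rhs,
    tension,
)
from oncostream.model import (
    all_forces,
    grad_omega_tension,
    grad_x_tension,
    pair_geometry,
)
from oncostream._kernels import forces_allpairs

from conftest import random_config


class TestParams:
    def test_eccentricity(self):
        p = ModelParams(a=5.5, b=3.0, c=10.0, alpha=40.0, beta=1.0, L=300.0)
        assert p.e == pytest.approx(np.sqrt(1 - 9 / 30.25))
        assert ModelParams(a=4, b=4, c=1, alpha=1, beta=1, L=10).e == 0.0

    @pytest.mark.parametrize(
        "kw",
        [
            dict(a=2.0, b=3.0),  # a < b
            dict(b=0.0),
            dict(c=-1.0),
            dict(L=-5.0),
            dict(d=4),
        ],
    )
    def test_invalid_params_rejected(self, kw):
        base = dict(a=5.5, b=3.0, c=10.0, alpha=40.0, beta=1.0, L=300.0, d=2)
        base.update(kw)
        with pytest.raises(ValueError):
            ModelParams(**base)


class TestMinimumImage:
    @pytest.mark.parametrize(
        "p, q, expected",
        [
            ((0, 0), (1, 0), (1, 0)),
            ((1, 0), (299, 0), (-2, 0)),
            ((5, 5), (5, 5), (0, 0)),
        ],
    )
    def test_examples(self, p, q, expected):
        np.testing.assert_allclose(minimum_image(p, q, 300.0), expected)

    def test_components_bounded(self, rng):
        p = rng.uniform(0, 50, size=(100, 3))
        q = rng.uniform(0, 50, size=(100, 3))
        v = np.array([minimum_image(a, b, 50.0) for a, b in zip(p, q)])
        assert np.all(np.abs(v) <= 25.0 + 1e-12)


class TestPhi:
    def test_compact_support(self):
        assert phi(1.0) == 0.0
        assert phi(2.0) == 0.0
        assert phi_prime(1.5) == 0.0

    def test_closed_form_value(self):
        assert phi(0.5) == pytest.approx(2 * np.exp(-2), rel=1e-12)

    def test_monotone_decreasing_inside(self):
        s = np.linspace(0.05, 0.999, 200)
        assert np.all(np.diff(phi(s)) < 0)
        assert np.all(phi_prime(s) <= 0)

    def test_continuous_at_support_edge(self):
        assert phi(1 - 1e-8) < 1e-10
        assert abs(phi_prime(1 - 1e-4)) < 1e-8

    def test_derivative_matches_finite_difference(self):
        h = 1e-7
        for s in (0.1, 0.3, 0.5, 0.8, 0.95):
            fd = (phi(s + h) - phi(s - h)) / (2 * h)
            assert phi_prime(s) == pytest.approx(fd, rel=1e-6)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            phi(0.0)
        with pytest.raises(ValueError):
            phi_prime(-1.0)

    def test_guard(self):
        assert guard_singularity(0.0) == 1e-6
        assert guard_singularity(0.5) == 0.5


class TestNormalizedDistance:
    def test_circular_reduces_to_scaled_norm(self, rng):
        p = ModelParams(a=4.0, b=4.0, c=1, alpha=1, beta=1, L=100.0)
        for _ in range(20):
            disp = rng.uniform(-3, 3, size=2)
            w = rng.normal(size=2)
            w /= np.linalg.norm(w)
            rsq = normalized_distance_sq(disp, w, p)
            assert rsq == pytest.approx(np.dot(disp, disp) / 16.0, rel=1e-12)

    def test_contact_points(self, params2d):
        w = np.array([1.0, 0.0])
        assert normalized_distance_sq(
            np.array([params2d.a, 0.0]), w, params2d
        ) == pytest.approx(1.0, rel=1e-12)
        assert normalized_distance_sq(
            np.array([0.0, params2d.b]), w, params2d
        ) == pytest.approx(1.0, rel=1e-12)

    def test_explicit_two_axis_form_agrees(self, rng):
        """The body-frame sum |x/a|^2+|y/b|^2 equals the e^2 form, 2D."""
        for _ in range(10_000 // 50):
            a = rng.uniform(1.0, 8.0)
            b = rng.uniform(0.5, 1.0) * a
            p = ModelParams(a=a, b=b, c=1, alpha=1, beta=1, L=100.0)
            disp = rng.uniform(-6, 6, size=(50, 2))
            th = rng.uniform(0, 2 * np.pi, size=50)
            for dv, t in zip(disp, th):
                w = np.array([np.cos(t), np.sin(t)])
                wp = np.array([-np.sin(t), np.cos(t)])
                explicit = (dv @ w / a) ** 2 + (dv @ wp / b) ** 2
                assert normalized_distance_sq(dv, w, p) == pytest.approx(
                    explicit, rel=1e-12, abs=1e-15
                )

    def test_asymmetric_between_frames(self, params2d):
        """r_ij != r_ji when the two headings differ (e > 0)."""
        cfg = CellConfiguration(
            positions=[[10.0, 10.0], [13.0, 10.0]],
            orientations=[[1.0, 0.0], [0.0, 1.0]],
        )
        rij = pair_geometry(0, 1, cfg, params2d).r_sq
        rji = pair_geometry(1, 0, cfg, params2d).r_sq
        assert abs(rij - rji) > 0.1
        # circular cells restore symmetry exactly
        pc = params2d.replace(a=4.0, b=4.0)
        assert pair_geometry(0, 1, cfg, pc).r_sq == pytest.approx(
            pair_geometry(1, 0, cfg, pc).r_sq, rel=1e-15
        )


class TestTension:
    def test_isolated_cell(self, params2d):
        cfg = CellConfiguration(
            positions=[[5.0, 5.0], [30.0, 30.0]],
            orientations=[[1.0, 0.0], [1.0, 0.0]],
        )
        assert tension(0, cfg, params2d) == 0.0
        np.testing.assert_allclose(grad_x_tension(0, cfg, params2d), 0.0)

    def test_single_pair_closed_form(self, params2d):
        # neighbour straight ahead at distance a/sqrt(2) -> r^2 = 1/2
        dist = params2d.a / np.sqrt(2)
        cfg = CellConfiguration(
            positions=[[10.0, 10.0], [10.0 + dist, 10.0]],
            orientations=[[1.0, 0.0], [1.0, 0.0]],
        )
        assert tension(0, cfg, params2d) == pytest.approx(
            2 * np.exp(-2), rel=1e-12
        )

    def test_cutoff_radius_bound(self, params2d, rng):
        """phi(r_ij^2) vanishes whenever the centre distance >= a."""
        for _ in range(200):
            disp = rng.uniform(-1, 1, size=2)
            disp *= (params2d.a + rng.uniform(0, 10)) / np.linalg.norm(disp)
            t = rng.uniform(0, 2 * np.pi)
            w = np.array([np.cos(t), np.sin(t)])
            rsq = normalized_distance_sq(disp, w, params2d)
            assert rsq >= 1.0

    @pytest.mark.parametrize("dim", [2, 3])
    def test_cell_list_matches_all_pairs(self, dim, params2d, params3d):
        p = params2d if dim == 2 else params3d
        cfg = random_config(p, 200, seed=5)
        V, gx, gw = all_forces(cfg, p)
        Vb, gxb, gwb = forces_allpairs(
            cfg.positions, cfg.orientations, p.L, p.a**2, p.b**2, p.e2, 1e-6
        )
        np.testing.assert_allclose(V, Vb, rtol=1e-12, atol=1e-14)
        np.testing.assert_allclose(gx, gxb, rtol=1e-12, atol=1e-14)
        np.testing.assert_allclose(gw, gwb, rtol=1e-12, atol=1e-14)


def _fd_gradient(fun, x0, h=1e-6):
    g = np.zeros_like(x0)
    for k in range(len(x0)):
        xp = x0.copy()
        xp[k] += h
        xm = x0.copy()
        xm[k] -= h
        g[k] = (fun(xp) - fun(xm)) / (2 * h)
    return g


class TestGradients:
    @pytest.mark.parametrize("dim", [2, 3])
    def test_match_finite_differences(self, dim, params2d, params3d):
        p = (params2d if dim == 2 else params3d).replace(L=20.0)
        for seed in range(5):
            cfg = random_config(p, 10, seed=seed)
            for i in range(0, 10, 3):
                gx = grad_x_tension(i, cfg, p)

                def vx(x, i=i):
                    c = cfg.copy()
                    c.positions[i] = x
                    return tension(i, c, p)

                fd = _fd_gradient(vx, cfg.positions[i].copy())
                np.testing.assert_allclose(gx, fd, rtol=1e-5, atol=1e-8)

                gw = grad_omega_tension(i, cfg, p)

                def vw(w, i=i):
                    c = cfg.copy()
                    c.orientations[i] = w
                    return tension(i, c, p)

                fd = _fd_gradient(vw, cfg.orientations[i].copy())
                np.testing.assert_allclose(gw, fd, rtol=1e-5, atol=1e-8)

    def test_circular_cells_never_steer(self, params2d):
        p = params2d.replace(a=3.0, b=3.0)
        cfg = random_config(p, 40, seed=2)
        for i in range(0, 40, 7):
            np.testing.assert_allclose(grad_omega_tension(i, cfg, p), 0.0)
        _, dw = rhs(cfg, p)
        np.testing.assert_allclose(dw, 0.0)

    def test_central_repulsion_at_zero_eccentricity(self):
        p = ModelParams(a=4.0, b=4.0, c=1, alpha=1, beta=1, L=50.0)
        cfg = CellConfiguration(
            positions=[[10.0, 10.0], [12.0, 11.0]],
            orientations=[[1.0, 0.0], [0.0, 1.0]],
        )
        g = grad_x_tension(0, cfg, p)
        d = minimum_image(cfg.positions[0], cfg.positions[1], p.L)
        cross = g[0] * d[1] - g[1] * d[0]
        assert abs(cross) < 1e-12
        assert np.dot(g, d) > 0  # gradient ascent toward the neighbour

    def test_transverse_neighbour_gives_no_torque(self, params2d):
        cfg = CellConfiguration(
            positions=[[10.0, 10.0], [10.0, 12.0]],
            orientations=[[1.0, 0.0], [1.0, 0.0]],
        )
        np.testing.assert_allclose(
            grad_omega_tension(0, cfg, params2d), 0.0, atol=1e-15
        )


class TestProjection:
    def test_examples(self):
        w = np.array([1.0, 0.0])
        np.testing.assert_allclose(project_tangent(w, w), 0.0)
        np.testing.assert_allclose(project_tangent(w, [3.0, 4.0]), [0.0, 4.0])
        v = np.array([0.0, 2.0])
        np.testing.assert_allclose(project_tangent(w, v), v)

    def test_orthogonality(self, rng):
        for _ in range(50):
            w = rng.normal(size=3)
            w /= np.linalg.norm(w)
            v = rng.normal(size=3)
            assert abs(np.dot(project_tangent(w, v), w)) < 1e-12


class TestRhs:
    def test_free_transport(self, params2d):
        cfg = CellConfiguration(
            positions=[[30.0, 30.0]], orientations=[[0.6, 0.8]]
        )
        dx, dw = rhs(cfg, params2d)
        np.testing.assert_allclose(dx[0], params2d.c * np.array([0.6, 0.8]))
        np.testing.assert_allclose(dw[0], 0.0)

    def test_angular_velocity_tangent(self, params2d):
        cfg = random_config(params2d, 60, seed=11)
        _, dw = rhs(cfg, params2d)
        dots = np.sum(dw * cfg.orientations, axis=1)
        np.testing.assert_allclose(dots, 0.0, atol=1e-12)

    def test_singularity_guard_keeps_forces_finite(self, params2d):
        cfg = CellConfiguration(
            positions=[[10.0, 10.0], [10.0, 10.0]],
            orientations=[[1.0, 0.0], [0.0, 1.0]],
        )
        dx, dw = rhs(cfg, params2d)
        assert np.all(np.isfinite(dx)) and np.all(np.isfinite(dw))


class TestSymmetries:
    def test_translation_invariance(self, params2d):
        cfg = random_config(params2d, 50, seed=3)
        V0, gx0, gw0 = all_forces(cfg, params2d)
        from oncostream.model import wrap_positions

        shift = np.array([17.3, -41.9])
        cfg2 = CellConfiguration(
            wrap_positions(cfg.positions + shift, params2d.L),
            cfg.orientations.copy(),
        )
        V1, gx1, gw1 = all_forces(cfg2, params2d)
        np.testing.assert_allclose(V0, V1, rtol=1e-11, atol=1e-12)
        np.testing.assert_allclose(gx0, gx1, rtol=1e-9, atol=1e-11)
        np.testing.assert_allclose(gw0, gw1, rtol=1e-9, atol=1e-11)

    @pytest.mark.parametrize("dim", [2, 3])
    def test_rotational_equivariance(self, dim, params2d, params3d):
        """Rotating the state about the box centre rotates the dynamics.

        The rotation must preserve the periodic lattice, so quarter-turns
        about the centre are used.
        """
        p = params2d if dim == 2 else params3d
        if dim == 2:
            R = np.array([[0.0, -1.0], [1.0, 0.0]])
        else:
            R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        cfg = random_config(p, 40, seed=9)
        dx, dw = rhs(cfg, p)
        from oncostream.model import wrap_positions

        centre = p.L / 2.0
        pos_rot = wrap_positions((cfg.positions - centre) @ R.T + centre, p.L)
        cfg_rot = CellConfiguration(pos_rot, cfg.orientations @ R.T)
        dx_r, dw_r = rhs(cfg_rot, p)
        np.testing.assert_allclose(dx_r, dx @ R.T, rtol=1e-9, atol=1e-10)
        np.testing.assert_allclose(dw_r, dw @ R.T, rtol=1e-9, atol=1e-10)
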