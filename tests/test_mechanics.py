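import math
import random

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rodsphere import (
    GlobalConfig,
    LJParams,
    OverlapError,
    Rod,
    Sphere,
    UnsupportedOperationError,
    finite_rod_potential,
    force_on_rod,
    force_on_sphere,
    infinite_rod_attractive_force,
    infinite_rod_dWdh,
    potential_partials,
    quadrature_torque,
    sphere_point_potential,
    torque_on_rod,
    wrench_global,
)
from rodsphere.mechanics import config_from_xc_h

from conftest import make_config


def _W(xc, h, L, s, rod, p):
    return finite_rod_potential(config_from_xc_h(xc, h, L), s, rod, p).W


def _W_hp(xc, h, L, s, rod, p):
    """Potential for finite differencing: arbitrary-precision evaluation so
    the differenced noise is far below the derivative scale."""
    return finite_rod_potential(config_from_xc_h(xc, h, L), s, rod, p, force_extended=True).W


def _richardson(f, x, d):
    d1 = (f(x + d) - f(x - d)) / (2 * d)
    d2 = (f(x + d / 2) - f(x - d / 2)) / d
    return (4 * d2 - d1) / 3


class TestPartials:
    def test_against_finite_differences(self, lj):
        rng = random.Random(2)
        for _ in range(50):
            c, s, rod = make_config(rng, margin=0.6)
            pp = potential_partials(c, s, rod, lj)
            d = 1e-4 * lj.sigma
            fd_xc = _richardson(lambda x: _W_hp(x, c.h, c.L, s, rod, lj), c.x_c, d)
            fd_h = _richardson(lambda h: _W_hp(c.x_c, h, c.L, s, rod, lj), c.h, d)
            scale = max(abs(fd_xc), abs(fd_h), 1e-12)
            assert abs(pp.dW_dxc - fd_xc) / scale < 1e-6
            assert abs(pp.dW_dh - fd_h) / scale < 1e-6

    def test_polar_partials_against_finite_differences(self, lj):
        """dW/drho and dW/dtheta (chain-rule outputs) vs direct polar FD."""
        rng = random.Random(9)
        for _ in range(20):
            c, s, rod = make_config(rng, margin=0.5)
            pp = potential_partials(c, s, rod, lj)

            def w_pol(rho, theta):
                return _W_hp(rho * math.cos(theta), rho * math.sin(theta), c.L, s, rod, lj)

            d = 1e-5
            fd_rho = _richardson(lambda r: w_pol(r, c.theta), c.rho, d)
            fd_theta = _richardson(lambda t: w_pol(c.rho, t), c.theta, d)
            scale = max(abs(fd_rho), abs(fd_theta), 1e-12)
            assert abs(pp.dW_drho - fd_rho) / scale < 1e-6
            assert abs(pp.dW_dtheta - fd_theta) / scale < 1e-6

    def test_axial_symmetry_over_midpoint(self, lj):
        s, rod = Sphere(a=5.0), Rod(L=8.0)
        c = config_from_xc_h(4.0, 7.0, 8.0)  # above the midpoint
        pp = potential_partials(c, s, rod, lj)
        assert pp.dW_dxc == pytest.approx(0.0, abs=1e-14)

    def test_infinite_rod_derivative(self, lj):
        s = Sphere(a=10.0)
        rod = Rod(L=math.inf)
        c = config_from_xc_h(0.0, 13.0, math.inf)
        pp = potential_partials(c, s, rod, lj)
        assert pp.dW_dxc == 0.0
        assert pp.dW_dh == pytest.approx(infinite_rod_dWdh(13.0, s, 1.0, lj), rel=1e-12)

    def test_infinite_rod_attractive_component(self, lj):
        """At large h the total force is attraction-dominated and matches the
        thin-rod vdW closed form."""
        s = Sphere(a=10.0)
        h = 40.0  # far outside the well: repulsion negligible
        f_att = infinite_rod_attractive_force(h, s, 1.0, lj)
        assert -infinite_rod_dWdh(h, s, 1.0, lj) == pytest.approx(-f_att, rel=1e-6)


class TestForce:
    def test_equals_negative_gradient(self, lj):
        rng = random.Random(6)
        for _ in range(30):
            c, s, rod = make_config(rng, margin=0.6)
            f = force_on_sphere(c, s, rod, lj).force
            d = 1e-4 * lj.sigma
            gx = _richardson(lambda x: _W_hp(x, c.h, c.L, s, rod, lj), c.x_c, d)
            gh = _richardson(lambda h: _W_hp(c.x_c, h, c.L, s, rod, lj), c.h, d)
            scale = max(abs(gx), abs(gh), 1e-12)
            assert abs(f[0] + gx) / scale < 1e-6
            assert abs(f[1] + gh) / scale < 1e-6
            assert f[2] == 0.0

    def test_collinear_force_is_axial(self, lj):
        s, rod = Sphere(a=3.0), Rod(L=4.0)
        c = config_from_xc_h(10.0, 0.0, 4.0)
        f = force_on_sphere(c, s, rod, lj).force
        assert f[1] == pytest.approx(0.0, abs=1e-12)
        assert f[2] == 0.0
        assert f[0] != 0.0

    def test_bisector_force_is_perpendicular(self, lj):
        s, rod = Sphere(a=3.0), Rod(L=6.0)
        c = config_from_xc_h(3.0, 5.0, 6.0)
        f = force_on_sphere(c, s, rod, lj).force
        assert f[0] == pytest.approx(0.0, abs=1e-14)
        assert f[1] != 0.0

    def test_newton_third_law_exact(self, lj):
        rng = random.Random(8)
        c, s, rod = make_config(rng)
        fs = force_on_sphere(c, s, rod, lj).force
        fr = force_on_rod(c, s, rod, lj).force
        assert np.array_equal(fr, -fs)

    def test_force_on_rod_matches_segment_quadrature(self, lj):
        """Integrating the segment force density reproduces the resultant."""
        from scipy.integrate import quad

        rng = random.Random(14)
        for _ in range(10):
            c, s, rod = make_config(rng)
            fr = force_on_rod(c, s, rod, lj).force
            step = 1e-6

            def dusp(rr):
                return (
                    sphere_point_potential(rr + step, s, lj)
                    - sphere_point_potential(rr - step, s, lj)
                ) / (2 * step)

            def fx(x):
                rr = math.hypot(x - c.x_c, c.h)
                return -rod.lambda_lin * dusp(rr) * (x - c.x_c) / rr

            def fh(x):
                rr = math.hypot(x - c.x_c, c.h)
                return -rod.lambda_lin * dusp(rr) * (0.0 - c.h) / rr

            pts = [c.x_c] if 0.0 < c.x_c < c.L else None
            qx, _ = quad(fx, 0.0, c.L, epsabs=0, epsrel=1e-10, limit=400, points=pts)
            qh, _ = quad(fh, 0.0, c.L, epsabs=0, epsrel=1e-10, limit=400, points=pts)
            scale = max(abs(qx), abs(qh), 1e-12)
            assert abs(fr[0] - qx) / scale < 1e-7
            assert abs(fr[1] - qh) / scale < 1e-7


class TestTorque:
    def test_zero_for_collinear(self, lj):
        s, rod = Sphere(a=3.0), Rod(L=4.0)
        for xc in (12.0, -8.0):  # theta = 0 and theta = pi
            c = config_from_xc_h(xc, 0.0, 4.0)
            tau = torque_on_rod(c, s, rod, lj).torque
            assert abs(tau[2]) < 1e-12

    def test_zero_on_perpendicular_bisector(self, lj):
        s, rod = Sphere(a=5.0), Rod(L=20.0)
        c = config_from_xc_h(10.0, 10.0, 20.0)  # rho = L/(2 cos theta)
        tau = torque_on_rod(c, s, rod, lj).torque
        assert abs(tau[2]) < 1e-8

    def test_against_quadrature(self, lj):
        rng = random.Random(12)
        for _ in range(30):
            c, s, rod = make_config(rng)
            for ref in ("rod_center", "rod_end_O"):
                ta = torque_on_rod(c, s, rod, lj, reference_point=ref).torque[2]
                tq = quadrature_torque(c, s, rod, lj, reference_point=ref)
                assert ta == pytest.approx(tq, rel=1e-6, abs=1e-10)

    def test_infinite_rod_rejected(self, lj):
        c = config_from_xc_h(0.0, 13.0, math.inf)
        with pytest.raises(UnsupportedOperationError):
            torque_on_rod(c, Sphere(a=10.0), Rod(L=math.inf), lj)


class TestSegmentIdentity:
    def test_lever_identity_for_central_potentials(self, lj):
        """x (dw/drho + cot(theta)/rho dw/dtheta) = (1/sin theta) dw/dtheta
        whenever w depends on position only through the pair distance."""
        rng = random.Random(21)
        s = Sphere(a=2.0)
        for _ in range(20):
            x = rng.uniform(-5.0, 5.0)
            rho = rng.uniform(6.0, 12.0)
            theta = rng.uniform(0.2, math.pi - 0.2)

            def w(rho_, theta_):
                r = math.sqrt(x * x + rho_ ** 2 - 2 * x * rho_ * math.cos(theta_))
                return sphere_point_potential(r, s, lj)

            d = 1e-6
            dw_drho = (w(rho + d, theta) - w(rho - d, theta)) / (2 * d)
            dw_dtheta = (w(rho, theta + d) - w(rho, theta - d)) / (2 * d)
            lhs = x * (dw_drho + math.cos(theta) / (rho * math.sin(theta)) * dw_dtheta)
            rhs = dw_dtheta / math.sin(theta)
            assert lhs == pytest.approx(rhs, rel=1e-5, abs=1e-12)


class TestGlobalWrench:
    def _random_global(self, rng, c):
        R = Rotation.random(random_state=rng.randint(0, 2 ** 31 - 1)).as_matrix()
        O = np.array([rng.uniform(-5, 5) for _ in range(3)])
        n_x, n_h = R[:, 0], R[:, 1]
        center = O + c.x_c * n_x + c.h * n_h
        return GlobalConfig(center, O, O + c.L * n_x), n_x, n_h

    def test_rotation_equivariance(self, lj):
        from rodsphere import local_config_from_global

        rng = random.Random(31)
        for _ in range(10):
            c, s, rod = make_config(rng)
            g, n_x, n_h = self._random_global(rng, c)
            ws, wr = wrench_global(g, s, rod, lj)
            # exact agreement with the local wrench of the reconstructed frame
            c2, basis = local_config_from_global(g)
            fl2 = force_on_sphere(c2, s, rod, lj).force
            np.testing.assert_allclose(
                ws.force, fl2[0] * basis.n_x + fl2[1] * basis.n_h, rtol=0, atol=1e-12
            )
            tz2 = torque_on_rod(c2, s, rod, lj).torque[2]
            np.testing.assert_allclose(wr.torque, tz2 * basis.n_z, rtol=0, atol=1e-12)
            # agreement with the original local description, allowing for the
            # conditioning of the global->polar round trip near the stiff wall
            fl = force_on_sphere(c, s, rod, lj).force
            np.testing.assert_allclose(
                ws.force, fl[0] * n_x + fl[1] * n_h, atol=1e-12 + 3e-6 * np.abs(fl).max()
            )
            tz = torque_on_rod(c, s, rod, lj).torque[2]
            torque_scale = np.abs(fl).max() * c.L + abs(tz)
            np.testing.assert_allclose(
                wr.torque, tz * np.cross(n_x, n_h), atol=1e-12 + 1e-5 * torque_scale
            )

    def test_translation_invariance(self, lj):
        rng = random.Random(32)
        c, s, rod = make_config(rng)
        g, _, _ = self._random_global(rng, c)
        shift = np.array([3.0, -7.0, 11.0])
        g2 = GlobalConfig(g.sphere_center + shift, g.rod_end_O + shift, g.rod_end_L + shift)
        ws1, wr1 = wrench_global(g, s, rod, lj)
        ws2, wr2 = wrench_global(g2, s, rod, lj)
        np.testing.assert_allclose(ws1.force, ws2.force, rtol=1e-10, atol=1e-14)
        np.testing.assert_allclose(wr1.torque, wr2.torque, rtol=1e-10, atol=1e-14)

    def test_work_matches_energy_change(self, lj):
        """F . dx = -dW to second order for a small rigid displacement of
        the sphere in the global frame."""
        rng = random.Random(33)
        c, s, rod = make_config(rng, margin=0.5)
        g, n_x, n_h = self._random_global(rng, c)
        ws, _ = wrench_global(g, s, rod, lj)
        step = 1e-6 * lj.sigma
        direction = np.array([0.3, -0.5, 0.81])
        direction /= np.linalg.norm(direction)

        def energy(gc):
            from rodsphere import local_config_from_global

            cc, _ = local_config_from_global(gc)
            return finite_rod_potential(cc, s, rod, lj).W

        dW = energy(
            GlobalConfig(g.sphere_center + step * direction, g.rod_end_O, g.rod_end_L)
        ) - energy(GlobalConfig(g.sphere_center - step * direction, g.rod_end_O, g.rod_end_L))
        work = float(np.dot(ws.force, direction)) * 2 * step
        assert work == pytest.approx(-dW, rel=1e-5, abs=1e-14)

    def test_overlap_propagates(self, lj):
        g = GlobalConfig(np.array([1.0, 1.0, 0.0]), np.zeros(3), np.array([4.0, 0.0, 0.0]))
        with pytest.raises(OverlapError):
            wrench_global(g, Sphere(a=3.0), Rod(L=4.0), lj)
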