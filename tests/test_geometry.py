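"""Framed-curve geometry: splines, Bishop transport, integrators."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from emflight.geometry import (
    CenterlineCurve,
    FramedCurve,
    FrameState,
    StepConfig,
    Steering,
    adaptive_step,
    advance_parabola,
    closest_point,
    complete_frame,
    fit_bspline,
    integrate_euler,
    integrate_parabola,
    rotate_flip_frame,
    transport_bishop_frame,
)

GAUSS = np.polynomial.legendre.leggauss(16)


def _parabola_arclen(t0, k0, sigma):
    pts = 0.5 * sigma * (GAUSS[0] + 1.0)
    v = np.linalg.norm(t0[None, :] + pts[:, None] * k0[None, :], axis=1)
    return 0.5 * sigma * float(v @ GAUSS[1])


# ---------------------------------------------------------------------------
# B-spline fitting
# ---------------------------------------------------------------------------


class TestFitBspline:
    def test_straight_line_zero_curvature_and_length(self):
        nodes = np.stack([np.linspace(0, 3, 6), np.zeros(6), np.zeros(6)], axis=1)
        c = fit_bspline(nodes, degree=4)
        assert abs(c.length - 3.0) < 1e-6
        assert np.max(c.kappa(np.linspace(0, 3, 50))) < 1e-9

    def test_circle_curvature(self, circle_curve):
        # analytic: kappa = 1/R = 0.5 for R = 2 um, checked at 50 interior points
        s = np.linspace(0.3, circle_curve.length - 0.3, 50)
        k = circle_curve.kappa(s)
        assert np.all(np.abs(k - 0.5) < 0.005)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError, match="degree"):
            fit_bspline(np.zeros((3, 3)) + np.arange(3)[:, None], degree=4)

    def test_coincident_nodes_rejected(self):
        nodes = np.stack([np.array([0, 1, 1, 2, 3, 4.0]), np.zeros(6), np.zeros(6)], axis=1)
        with pytest.raises(ValueError, match="coincident"):
            fit_bspline(nodes, degree=4)

    def test_lsq_smoothing_stays_close_to_nodes(self, rng):
        s = np.linspace(0, 10, 40)
        nodes = np.stack([s, np.sin(0.5 * s), np.zeros_like(s)], axis=1)
        nodes += rng.normal(0, 0.01, nodes.shape)
        c = fit_bspline(nodes, degree=4, tol=0.05)
        d = np.linalg.norm(c.position(np.linspace(0, c.length, 200))[:, :2], axis=1)
        assert c.length < 12.0  # no wild oscillation


# ---------------------------------------------------------------------------
# Bishop transport
# ---------------------------------------------------------------------------


class TestBishopTransport:
    def test_straight_line_constant_frame(self, straight_curve):
        init = complete_frame(straight_curve.tangent(0.0))
        init = FrameState(straight_curve.position(0.0), init.t, init.n1, init.n2)
        pairs = transport_bishop_frame(straight_curve, init, np.linspace(0, 30, 10))
        for f, s in pairs:
            assert np.allclose(f.n1, pairs[0][0].n1, atol=1e-9)
            assert abs(s.k1) < 1e-9 and abs(s.k2) < 1e-9

    def test_planar_circle_k2_vanishes(self, circle_curve):
        c = circle_curve
        f0 = complete_frame(c.tangent(0.0), n1_hint=-c.position(0.0))
        init = FrameState(c.position(0.0), c.tangent(0.0), f0.n1, f0.n2)
        pairs = transport_bishop_frame(c, init, np.linspace(0, c.length, 20))
        k1 = np.array([s.k1 for _, s in pairs])
        k2 = np.array([s.k2 for _, s in pairs])
        # rotation-minimizing frame of a planar curve stays in-plane
        assert np.max(np.abs(k2)) < 1e-6
        assert np.all(np.abs(k1[2:-2] - 0.5) < 0.01)

    def test_helix_total_squared_curvature_matches_frenet(self):
        # helix r=1, pitch 2*pi*b with b=0.5: kappa_F = r/(r^2+b^2) everywhere
        r, b = 1.0, 0.5
        u = np.linspace(0, 4 * np.pi, 400)
        nodes = np.stack([r * np.cos(u), r * np.sin(u), b * u], axis=1)
        c = fit_bspline(nodes, degree=4)
        s = np.linspace(0.5, c.length - 0.5, 200)
        init = complete_frame(c.tangent(s[0]))
        init = FrameState(c.position(s[0]), c.tangent(s[0]), init.n1, init.n2)
        pairs = transport_bishop_frame(c, init, s)
        k_sq = np.array([st.k1**2 + st.k2**2 for _, st in pairs])
        kappa_f = r / (r**2 + b**2)
        total = np.trapezoid(k_sq, s)
        expected = kappa_f**2 * (s[-1] - s[0])
        assert abs(total - expected) / expected < 1e-4

    def test_misaligned_initial_tangent_rejected(self, circle_curve):
        bad = complete_frame([0.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="tangent"):
            transport_bishop_frame(circle_curve, bad, [0.0, 1.0])


# ---------------------------------------------------------------------------
# Adaptive step
# ---------------------------------------------------------------------------


class TestAdaptiveStep:
    def test_zero_curvature_gives_default_step(self):
        cfg = StepConfig(d=11.24e-3, p=1.0, f=1.0)
        assert adaptive_step(0.0, cfg) == pytest.approx(11.24e-3)

    def test_half_step_at_kappa_two_per_p(self):
        cfg = StepConfig(d=10e-3, p=1.0, f=1.0)
        assert adaptive_step(2.0, cfg) == pytest.approx(5e-3)

    def test_factor_scales_linearly(self):
        for kappa in (0.0, 0.7, 2.0):
            s1 = adaptive_step(kappa, StepConfig(d=10e-3, f=1.0))
            s5 = adaptive_step(kappa, StepConfig(d=10e-3, f=5.0))
            assert s5 == pytest.approx(5.0 * s1)

    def test_monotone_decreasing_and_bounded(self):
        cfg = StepConfig(d=10e-3)
        ks = np.linspace(0, 10, 50)
        vals = [adaptive_step(k, cfg) for k in ks]
        assert np.all(np.diff(vals) < 0)
        assert np.all(np.asarray(vals) <= cfg.f * cfg.d + 1e-15)

    def test_negative_curvature_rejected(self):
        with pytest.raises(ValueError):
            adaptive_step(-0.1, StepConfig())


# ---------------------------------------------------------------------------
# Integrators
# ---------------------------------------------------------------------------


def _rk_oracle(state, steer, ds):
    """High-accuracy integration of the Bishop ODEs along the fixed parabola."""
    k0 = steer.curvature_vector(state)
    t0 = state.t
    sig_end = brentq(lambda s: _parabola_arclen(t0, k0, s) - ds, 0.0, 10.0 * ds)

    def rhs(sig, y):
        t = t0 + sig * k0
        v = np.linalg.norm(t)
        T = t / v
        kw = (k0 - T * float(T @ k0)) / v**2
        n1 = y[3:6]
        return np.concatenate([T * v, -(float(kw @ n1)) * T * v])

    y0 = np.concatenate([state.position, state.n1])
    sol = solve_ivp(rhs, (0, sig_end), y0, rtol=1e-12, atol=1e-14, method="DOP853")
    return sol.y[:3, -1], sol.y[3:6, -1]


class TestIntegrators:
    def test_euler_straight_advance(self):
        st = complete_frame([1, 0, 0])
        out = integrate_euler(st, Steering(0.0, 0.0), 0.1)
        assert np.allclose(out.position, [0.1, 0, 0])
        assert np.allclose(out.t, st.t) and np.allclose(out.n1, st.n1)

    def test_euler_small_step_matches_rk(self):
        st = complete_frame([1, 0, 0])
        steer = Steering(1.0, 0.0)
        out = integrate_euler(st, steer, 1e-4)
        pos, _ = _rk_oracle(st, steer, 1e-4)
        assert np.linalg.norm(out.position - pos) <= 1e-8

    def test_euler_orthonormal_after_random_steps(self, rng):
        for _ in range(200):
            t = rng.normal(size=3)
            st = complete_frame(t)
            steer = Steering(rng.normal() * 1.5, rng.normal() * 1.5)
            out = integrate_euler(st, steer, 0.05)
            assert out.orthonormality_residual() < 1e-12

    def test_euler_warns_on_coarse_step(self):
        st = complete_frame([1, 0, 0])
        with pytest.warns(UserWarning, match="coarse"):
            integrate_euler(st, Steering(3.0, 0.0), 0.5)

    def test_parabola_zero_curvature_equals_euler(self):
        st = complete_frame([0, 1, 0])
        a = integrate_parabola(st, Steering(0.0, 0.0), 0.3)
        b = integrate_euler(st, Steering(0.0, 0.0), 0.3)
        assert np.allclose(a.position, b.position, atol=1e-12)
        assert np.allclose(a.n1, b.n1, atol=1e-12)

    @pytest.mark.parametrize("k1,k2", [(1.0, 0.0), (0.6, -0.9), (2.0, 0.5)])
    def test_parabola_matches_rk_oracle(self, k1, k2):
        st = complete_frame([1, 0, 0])
        steer = Steering(k1, k2)
        out = integrate_parabola(st, steer, 0.5)
        pos, n1 = _rk_oracle(st, steer, 0.5)
        assert np.linalg.norm(out.position - pos) <= 1e-8
        assert np.linalg.norm(out.n1 - n1) <= 1e-6

    def test_parabola_exact_composition_unlike_euler(self):
        # one step of ds along a fixed parabola vs two steps of ds/2 along the
        # same parabola: the exact advance composes to machine precision,
        # forward Euler on the same construction shows O(ds) error.
        st = complete_frame([1, 0, 0])
        steer = Steering(1.0, 0.4)
        ds = 0.5
        one = integrate_parabola(st, steer, ds)
        half = integrate_parabola(st, steer, ds / 2)
        k0 = steer.curvature_vector(st)
        sig = brentq(lambda s: _parabola_arclen(st.t, k0, s) - ds / 2, 0, 2 * ds)
        v = np.linalg.norm(st.t + sig * k0)
        # continuation of the same parabola from the half point carries a
        # tangential curvature component: k' = k0 / v^2
        two = advance_parabola(half, k0 / v**2, ds / 2)
        assert np.linalg.norm(one.position - two.position) <= 1e-9
        assert np.linalg.norm(one.n1 - two.n1) <= 1e-9

        def euler_endpoint(n):
            s_done, stx = 0.0, st
            for _ in range(n):
                sg = brentq(lambda s: _parabola_arclen(st.t, k0, s) - s_done,
                            0, 2 * ds) if s_done else 0.0
                t = st.t + sg * k0
                vv = np.linalg.norm(t)
                T = t / vv
                kw = (k0 - T * float(T @ k0)) / vv**2
                stx = integrate_euler(stx, Steering(float(kw @ stx.n1),
                                                    float(kw @ stx.n2)), ds / n)
                s_done += ds / n
            return stx.position

        err8 = np.linalg.norm(euler_endpoint(8) - one.position)
        err16 = np.linalg.norm(euler_endpoint(16) - one.position)
        assert err8 > 1e-3  # Euler is visibly inexact here
        assert 1.6 < err8 / err16 < 2.5  # first-order convergence

    def test_parabola_orthonormal_for_random_steps(self, rng):
        for _ in range(200):
            st = complete_frame(rng.normal(size=3))
            steer = Steering(rng.normal() * 2, rng.normal() * 2)
            out = integrate_parabola(st, steer, float(rng.uniform(0.01, 0.5)))
            assert out.orthonormality_residual() < 1e-9
            assert float(out.t @ np.cross(out.n1, out.n2)) > 0


# ---------------------------------------------------------------------------
# Rotations / flips
# ---------------------------------------------------------------------------


class TestRotateFlip:
    def test_identity(self):
        st = complete_frame([0, 0, 1])
        out = rotate_flip_frame(st, 0.0, flip=False)
        assert np.allclose(out.n1, st.n1) and np.allclose(out.n2, st.n2)

    def test_quarter_turn(self):
        st = complete_frame([0, 0, 1])
        out = rotate_flip_frame(st, np.pi / 2)
        assert np.allclose(out.n1, st.n2, atol=1e-12)
        assert np.allclose(out.n2, -st.n1, atol=1e-12)

    def test_curvature_vector_invariant_under_joint_rotation(self, rng):
        # rotating the frame and co-rotating (k1, k2) leaves k unchanged
        for _ in range(20):
            st = complete_frame(rng.normal(size=3))
            k1, k2 = rng.normal(size=2)
            theta = rng.uniform(0, 2 * np.pi)
            flip = bool(rng.integers(0, 2))
            k_before = k1 * st.n1 + k2 * st.n2
            st2 = rotate_flip_frame(st, theta, flip)
            c, s = np.cos(theta), np.sin(theta)
            k1p = c * k1 + s * k2
            k2p = -s * k1 + c * k2
            if flip:
                k2p = -k2p
            k_after = k1p * st2.n1 + k2p * st2.n2
            assert np.linalg.norm(k_after - k_before) <= 1e-12


# ---------------------------------------------------------------------------
# Closest point
# ---------------------------------------------------------------------------


class TestClosestPoint:
    def test_point_on_curve(self, circle_curve):
        x = circle_curve.position(2.0)
        s, pt = closest_point(circle_curve, x)
        assert np.linalg.norm(pt - x) <= 1e-9

    def test_orthogonal_projection_on_segment(self):
        nodes = np.stack([np.linspace(0, 1, 6), np.zeros(6), np.zeros(6)], axis=1)
        c = fit_bspline(nodes, degree=4)
        s, pt = closest_point(c, [0.3, 0.4, 0.0])
        assert abs(s - 0.3) < 1e-6
        assert np.linalg.norm(pt - [0.3, 0, 0]) < 1e-6

    def test_against_brute_force(self, circle_curve, rng):
        s_grid = np.arange(0.0, circle_curve.length, 1e-4)
        pts = circle_curve.position(s_grid)
        for _ in range(20):
            x = rng.uniform(-3, 3, size=3) * np.array([1, 1, 0.3])
            s, _ = closest_point(circle_curve, x)
            brute = s_grid[np.argmin(((pts - x) ** 2).sum(axis=1))]
            assert abs(s - brute) < 1e-3

    def test_infinite_query_rejected(self, circle_curve):
        with pytest.raises(ValueError):
            closest_point(circle_curve, [np.inf, 0, 0])


class TestFramedCurve:
    def test_frames_orthonormal_along_curve(self, circle_curve):
        fc = FramedCurve(circle_curve)
        for s in np.linspace(0, fc.length, 15):
            f = fc.frame_at(s)
            assert f.orthonormality_residual() < 1e-9
            assert np.allclose(f.position, circle_curve.position(s), atol=1e-9)
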