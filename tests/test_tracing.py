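"""Flight tracing, bidirectional validation, uncertainty machinery."""

import numpy as np
import pytest

from emflight.geometry import (
    FramedCurve,
    FrameState,
    StepConfig,
    Steering,
    complete_frame,
    fit_bspline,
    rotate_flip_frame,
)
from emflight.model import MCSamples
from emflight.synthetic import SkeletonFragment, ToyAgglomeration
from emflight.tracing import (
    OracleSteerer,
    SkeletonTarget,
    StopRules,
    apply_corrections,
    fibonacci_sphere,
    smooth_uncertainties,
    trace,
    uncertainty_score,
    validate_bidirectional,
    ValidatedTracing,
)


STEP = StepConfig(d=0.02, f=2.0)


class TestTrace:
    def test_oracle_follows_straight_tube_20um(self, rng):
        nodes = np.stack([np.linspace(0, 22, 12), np.zeros(12), np.zeros(12)], axis=1)
        fc = FramedCurve(fit_bspline(nodes, 4))
        steerer = OracleSteerer(fc, s_c=0.4)
        seed = fc.frame_at(0.5)
        seed = FrameState(seed.position + 0.05 * seed.n1, seed.t, seed.n1, seed.n2)
        target = SkeletonTarget(np.array([[21.5, 0, 0]]), np.array([1]), radius=0.2)
        tr = trace(steerer, None, seed, STEP, StopRules(max_steps=2000, target=target))
        assert tr.stop_reason == "reached_object"
        assert tr.arc_length > 20.0
        dev = np.abs(tr.positions[:, 1:]).max()
        assert dev < 0.2  # stays within one tube radius of the centerline

    def test_deterministic_repeat(self, straight_framed):
        steerer = OracleSteerer(straight_framed, s_c=0.4)
        seed = straight_framed.frame_at(1.0)
        a = trace(steerer, None, seed, STEP, StopRules(max_steps=100), seed=3)
        b = trace(steerer, None, seed, STEP, StopRules(max_steps=100), seed=3)
        assert np.array_equal(a.positions, b.positions)

    def test_random_rotation_mode_same_path_decorrelated_frames(self, straight_framed):
        steerer = OracleSteerer(straight_framed, s_c=0.4)
        seed = straight_framed.frame_at(1.0)
        seed = FrameState(seed.position + 0.05 * seed.n1, seed.t, seed.n1, seed.n2)
        rules = StopRules(max_steps=300)
        normal = trace(steerer, None, seed, STEP, rules, mode="normal", seed=0)
        devs_n, devs_r, coss = [], [], []
        for s in range(10):
            rr = trace(steerer, None, seed, STEP, rules, mode="random_rotation", seed=s)
            devs_r.append(np.abs(rr.positions[:, 1:]).max())
            coss.extend(
                abs(float(a.n1 @ b.n1))
                for a, b in zip(rr.states[:-1], rr.states[1:])
            )
        dev_normal = np.abs(normal.positions[:, 1:]).max()
        # paths statistically identical: deviation within 2x of normal mode
        assert np.mean(devs_r) < 2.0 * max(dev_normal, 0.05)
        # consecutive frames decorrelate
        assert np.mean(coss) < 0.8

    def test_seed_outside_volume_rejected(self, tube_scene):
        st = complete_frame([0, 0, 1.0])
        st = FrameState(np.array([50.0, 50.0, 50.0]), st.t, st.n1, st.n2)
        with pytest.raises(ValueError, match="outside"):
            trace(OracleSteerer(tube_scene.neurites[0].framed), tube_scene.volume,
                  st, STEP, StopRules(max_steps=10))

    def test_reaches_target_object(self, straight_framed):
        steerer = OracleSteerer(straight_framed, s_c=0.4)
        seed = straight_framed.frame_at(1.0)
        target = SkeletonTarget(np.array([[8.0, 0, 0], [8.1, 0, 0]]),
                                np.array([7, 7]), radius=0.2)
        tr = trace(steerer, None, seed, STEP,
                   StopRules(max_steps=2000, target=target))
        assert tr.stop_reason == "reached_object"
        assert tr.reached_id == 7
        assert tr.positions[-1][0] < 8.3


class TestInvariance:
    """Rotations/flips about the tangent applied jointly to frame and
    curvatures leave the traced path unchanged."""

    def _manual_trace(self, seed_state, steer_fn, n_steps, ds=0.05):
        from emflight.geometry import integrate_parabola

        states = [seed_state]
        for _ in range(n_steps):
            st = states[-1]
            states.append(integrate_parabola(st, steer_fn(st), ds))
        return states

    @pytest.mark.parametrize("theta,flip", [(0.7, False), (2.1, True), (np.pi / 2, False)])
    def test_traced_path_invariant(self, theta, flip, circle_curve):
        fc = FramedCurve(circle_curve)
        steerer = OracleSteerer(fc, s_c=0.3)

        def steer_plain(st):
            return steerer.steer(st, None)[0]

        seed = fc.frame_at(0.5)
        seed = FrameState(seed.position + 0.03 * seed.n1, seed.t, seed.n1, seed.n2)
        path_a = self._manual_trace(seed, steer_plain, 60)
        # transformed seed frame; the oracle policy is frame-covariant, so the
        # steering co-rotates automatically and positions must coincide
        seed_b = rotate_flip_frame(seed, theta, flip)
        path_b = self._manual_trace(seed_b, steer_plain, 60)
        for a, b in zip(path_a, path_b):
            assert np.linalg.norm(a.position - b.position) <= 1e-9
            assert np.linalg.norm(a.t - b.t) <= 1e-9


class TestValidation:
    def test_straight_tube_forward_backward_agree(self, straight_framed):
        steerer = OracleSteerer(straight_framed, s_c=0.4)
        seed = straight_framed.frame_at(1.0)
        target = SkeletonTarget(np.array([[20.0, 0, 0]]), np.array([1]), radius=0.2)
        fwd = trace(steerer, None, seed, STEP, StopRules(max_steps=3000, target=target))
        assert fwd.stop_reason == "reached_object"
        seed_target = SkeletonTarget(np.array([[1.0, 0, 0]]), np.array([0]), radius=0.3)
        vt = validate_bidirectional(steerer, None, fwd, seed_target, step_cfg=STEP,
                                    stop_rules=StopRules(max_steps=3000))
        assert vt.agreed

    def test_merge_onto_crossing_tube_fails_validation(self):
        # X junction: flight from tube A merges onto crossing tube B near the
        # junction; the backward flight follows B instead of returning to A
        a_nodes = np.stack([np.linspace(0, 10, 12), np.zeros(12), np.zeros(12)], axis=1)
        b_nodes = np.stack([
            np.full(12, 5.0) + np.linspace(-5, 5, 12) * 0.3,
            np.linspace(-5, 5, 12), np.zeros(12),
        ], axis=1)
        fa = FramedCurve(fit_bspline(a_nodes, 4))
        fb = FramedCurve(fit_bspline(b_nodes, 4))
        # forward steerer follows B after the junction (simulates a merge):
        steerer_b = OracleSteerer(fb, s_c=0.4)
        seed = fb.frame_at(0.5)
        target = SkeletonTarget(fb.curve.position(np.linspace(10, 11, 5) * fb.length / 11),
                                np.full(5, 2), radius=0.3)
        fwd = trace(steerer_b, None, seed, STEP, StopRules(max_steps=4000, target=target))
        assert fwd.stop_reason == "reached_object"
        # the seed object sits on tube A, far from B's far end
        seed_target = SkeletonTarget(np.array([[1.0, 0.0, 0.0]]), np.array([0]),
                                     radius=0.3)
        vt = validate_bidirectional(steerer_b, None, fwd, seed_target, step_cfg=STEP,
                                    stop_rules=StopRules(max_steps=4000))
        assert not vt.agreed

    def test_zero_agreement_radius_rejects_inexact_paths(self, straight_framed):
        steerer = OracleSteerer(straight_framed, s_c=0.4)
        seed = straight_framed.frame_at(1.0)
        seed = FrameState(seed.position + 0.05 * seed.n1, seed.t, seed.n1, seed.n2)
        target = SkeletonTarget(np.array([[15.0, 0, 0]]), np.array([1]), radius=0.2)
        fwd = trace(steerer, None, seed, STEP, StopRules(max_steps=3000, target=target))
        seed_target = SkeletonTarget(np.array([[1.0, 0.05, 0.0]]), np.array([0]), radius=0.3)
        vt = validate_bidirectional(steerer, None, fwd, seed_target,
                                    agreement_radius=0.0, step_cfg=STEP,
                                    stop_rules=StopRules(max_steps=3000))
        assert not vt.agreed

    def test_forward_not_terminated_reports_reason(self, straight_framed):
        steerer = OracleSteerer(straight_framed, s_c=0.4)
        seed = straight_framed.frame_at(1.0)
        fwd = trace(steerer, None, seed, STEP, StopRules(max_steps=20))
        seed_target = SkeletonTarget(np.array([[1.0, 0, 0]]), np.array([0]))
        vt = validate_bidirectional(steerer, None, fwd, seed_target, step_cfg=STEP)
        assert not vt.agreed and "max_steps" in vt.reason


class TestUncertaintyScore:
    def test_identical_samples_zero(self):
        s = MCSamples(np.tile([[0.5, 0.3]], (16, 1)))
        assert uncertainty_score(s) == pytest.approx(0.0, abs=1e-12)

    def test_known_covariance_eigenvalues(self, rng):
        # samples with covariance eigenvalues {4 kbar^2, kbar^2}: u = 2
        kbar = 0.8
        n = 20000
        x = rng.normal(0, 2 * kbar, n)
        y = rng.normal(0, kbar, n)
        # shift far so mean curvature ~ norm of mean; center at (K, 0)
        K = 1000.0  # mean curvature dominates sample spread
        s = MCSamples(np.stack([K + x, y], axis=1))
        mean_kappa = float(np.linalg.norm(np.stack([K + x, y], axis=1), axis=1).mean())
        expected = 2 * kbar / mean_kappa
        assert uncertainty_score(s) == pytest.approx(expected, rel=0.05)

    def test_scale_invariance(self, rng):
        k = rng.normal(size=(64, 2)) + [2.0, -1.0]
        u1 = uncertainty_score(MCSamples(k))
        u2 = uncertainty_score(MCSamples(3.7 * k))
        assert u1 == pytest.approx(u2, abs=1e-9)

    def test_vanishing_mean_curvature_infinite(self):
        s = MCSamples(np.zeros((8, 2)))
        assert uncertainty_score(s) == np.inf


class TestSmoothing:
    def test_uniform_uncertainties_unchanged(self):
        t = fibonacci_sphere(64)
        u = np.full(64, 0.37)
        u_hat = smooth_uncertainties(t, u)
        assert np.allclose(u_hat, 0.37)

    def test_isolated_orientation_keeps_raw_value(self):
        t = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0]])
        u = np.array([0.5, 1.5, 2.5])
        u_hat = smooth_uncertainties(t, u)
        assert np.allclose(u_hat, u)  # all pairwise angles >= 90 degrees

    def test_two_close_orientations_average(self):
        a = np.deg2rad(20.0)
        t = np.array([[1.0, 0, 0], [np.cos(a), np.sin(a), 0]])
        u = np.array([0.0, 1.0])
        u_hat = smooth_uncertainties(t, u)
        # each has exactly one neighbour with normalized weight 1:
        # u_hat = u_i/2 + u_j/2
        assert u_hat[0] == pytest.approx(0.5)
        assert u_hat[1] == pytest.approx(0.5)


class TestFibonacciSphere:
    def test_unit_vectors_roughly_equidistant(self):
        t = fibonacci_sphere(256)
        assert np.allclose(np.linalg.norm(t, axis=1), 1.0, atol=1e-12)
        # nearest-neighbour angles are narrowly distributed
        cos = t @ t.T
        np.fill_diagonal(cos, -1)
        nn = np.rad2deg(np.arccos(np.clip(cos.max(axis=1), -1, 1)))
        assert nn.std() < 0.25 * nn.mean()


class TestApplyCorrections:
    def _aggl_and_tracings(self):
        frags = [
            SkeletonFragment(i, np.array([[float(i), 0, 0], [float(i) + 0.5, 0, 0]]), (0,))
            for i in range(5)
        ]
        aggl = ToyAgglomeration(frags, {f.fragment_id: (0,) for f in frags}, [], [])

        def vt(seed, tgt, u, agreed=True):
            v = ValidatedTracing(None, None, agreed, u)
            v.seed_fragment, v.target_fragment = seed, tgt
            return v

        return aggl, vt

    def test_full_percentile_applies_all_agreed(self):
        aggl, vt = self._aggl_and_tracings()
        tracings = [vt(0, 1, 0.1), vt(2, 3, 0.5), vt(3, 4, 0.9, agreed=False)]
        out = apply_corrections(aggl, tracings, percentile=1.0)
        comps = out.components()
        # 5 fragments, 2 applied links -> 3 components (hand-computed union)
        assert len(comps) == 3

    def test_zero_percentile_no_change(self):
        aggl, vt = self._aggl_and_tracings()
        out = apply_corrections(aggl, [vt(0, 1, 0.1)], percentile=0.0)
        assert len(out.components()) == 5

    def test_percentile_filters_most_uncertain(self):
        aggl, vt = self._aggl_and_tracings()
        tracings = [vt(0, 1, 0.1), vt(1, 2, 0.2), vt(2, 3, 0.3), vt(3, 4, 10.0)]
        out = apply_corrections(aggl, tracings, percentile=0.5)
        assert (3, 4) not in out.tracing_links
        assert (0, 1) in out.tracing_links

    def test_invalid_percentile_rejected(self):
        aggl, vt = self._aggl_and_tracings()
        with pytest.raises(ValueError):
            apply_corrections(aggl, [], percentile=1.5)
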