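"""Membrane-avoiding corrective flight policy and training-target generation.

Given the agent's (possibly off-centerline, misaligned) pose and the closest
point on the ground-truth centerline, the policy returns the steering that
minimizes the predicted future gap

    Gamma_T(s) = Gamma + s T + (s^2/2) K,

where Gamma = gamma - gamma_agent, T = t - t_agent and K = k - k_agent, at
the convergence distance s_c.  The stationarity condition
grad_k ||Gamma_T(s_c)||^2 = 0 has the closed-form solution

    k_agent = P_{n1,n2}( (2/s_c^2) [Gamma + s_c t] + k ),

with P the projection onto the agent's normal plane.  During training s_c
is set dynamically to the distance to the plasma membrane along the flight
direction, which teaches the network obstacle avoidance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import FramedCurve, FrameState, Steering, closest_point
from .sampling import VolumeGrid, trilinear

__all__ = [
    "TrainingTarget",
    "corrective_steering",
    "corrective_steering_vec",
    "membrane_distance",
    "perturb_state",
    "make_training_target",
    "KAPPA_MAX",
]

# Turns tighter than twice the inverse projection-plane size are unresolvable
# within the field of view; targets are clipped there (2/p with p = 1 um).
KAPPA_MAX = 2.0


@dataclass(frozen=True)
class TrainingTarget:
    """Supervised target: corrective steering plus auxiliary membrane distance."""

    steering: Steering
    membrane_distance: float

    def __post_init__(self):
        if self.membrane_distance < 0:
            raise ValueError("membrane_distance must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.steering.k1, self.steering.k2, self.membrane_distance], dtype=float
        )


def corrective_steering_vec(
    ref_point: np.ndarray,
    ref_tangent: np.ndarray,
    ref_kvec: np.ndarray,
    agent: FrameState,
    s_c: float,
    kappa_max: float | None = None,
) -> Steering:
    """Closed-form corrective steering from world-space centerline data."""
    if s_c <= 0:
        raise ValueError("convergence distance s_c must be positive")
    gamma = np.asarray(ref_point, float) - agent.position
    v = (2.0 / s_c**2) * (gamma + s_c * np.asarray(ref_tangent, float)) + np.asarray(
        ref_kvec, float
    )
    k1 = float(v @ agent.n1)
    k2 = float(v @ agent.n2)
    if kappa_max is not None:
        kappa = float(np.hypot(k1, k2))
        if kappa > kappa_max:
            scale = kappa_max / kappa
            k1, k2 = k1 * scale, k2 * scale
    return Steering(k1, k2)


def corrective_steering(
    ref_state: FrameState,
    ref_steer: Steering,
    agent_state: FrameState,
    s_c: float,
    kappa_max: float | None = None,
) -> Steering:
    """Corrective steering given the frame/steering at the closest centerline point."""
    kvec = ref_steer.curvature_vector(ref_state)
    return corrective_steering_vec(
        ref_state.position, ref_state.t, kvec, agent_state, s_c, kappa_max
    )


def membrane_distance(
    mask: VolumeGrid,
    pos: np.ndarray,
    direction: np.ndarray,
    max_range: float,
    threshold: float = 0.5,
) -> tuple[float, bool]:
    """Distance along ``direction`` to the first ray sample outside the mask.

    The ray is sampled at a quarter of the smallest voxel dimension with
    trilinear interpolation of the binary mask; the first sample below the
    threshold marks the membrane.  Returns (distance capped at max_range,
    started_inside flag); a start outside the mask reports (0.0, False).
    """
    pos = np.asarray(pos, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    v0, _ = trilinear(mask, pos, pad_value=0.0)
    if v0 < threshold:
        return 0.0, False
    spacing = float(mask.voxel_size_um.min()) / 4.0
    n = int(np.ceil(max_range / spacing))
    ts = spacing * np.arange(1, n + 1)
    pts = pos[None, :] + ts[:, None] * direction[None, :]
    vals, _ = trilinear(mask, pts, pad_value=0.0)
    outside = np.nonzero(vals < threshold)[0]
    if len(outside) == 0:
        return max_range, True
    return min(float(ts[outside[0]]), max_range), True


@dataclass(frozen=True)
class PerturbLimits:
    """Off-centerline training perturbation magnitudes."""

    max_offset: float = 0.16  # um; default ~0.8 x typical thin-axon radius
    max_angle: float = np.deg2rad(45.0)


def perturb_state(
    curve_state: FrameState,
    mask: VolumeGrid | None,
    rng: np.random.Generator,
    limits: PerturbLimits,
    max_tries: int = 100,
) -> tuple[FrameState, bool]:
    """Sample an off-centerline, off-direction pose around a centerline pose.

    Position is drawn uniformly in the normal disc (rejection-sampled to stay
    inside the mask when one is given); the direction is drawn uniformly in a
    cone about the tangent and the whole frame is rotated accordingly so it
    stays orthonormal.  Returns (state, ok); ``ok`` is False if rejection
    sampling failed and the unperturbed state was returned.
    """
    if limits.max_offset == 0.0 and limits.max_angle == 0.0:
        return curve_state, True
    for _ in range(max_tries):
        # uniform in disc
        r = limits.max_offset * np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * np.pi)
        pos = (
            curve_state.position
            + r * np.cos(phi) * curve_state.n1
            + r * np.sin(phi) * curve_state.n2
        )
        # uniform in cone about t
        cos_max = np.cos(limits.max_angle)
        c = rng.uniform(cos_max, 1.0)
        psi = rng.uniform(0.0, 2.0 * np.pi)
        s = np.sqrt(max(0.0, 1.0 - c * c))
        t_new = (
            c * curve_state.t
            + s * np.cos(psi) * curve_state.n1
            + s * np.sin(psi) * curve_state.n2
        )
        t_new /= np.linalg.norm(t_new)
        if mask is not None:
            inside, _ = trilinear(mask, pos, pad_value=0.0)
            if inside < 0.5:
                continue
        # rotate frame with the minimal rotation taking t to t_new
        axis = np.cross(curve_state.t, t_new)
        sin_a = np.linalg.norm(axis)
        if sin_a < 1e-12:
            n1, n2 = curve_state.n1, curve_state.n2
        else:
            axis = axis / sin_a
            cos_a = float(curve_state.t @ t_new)
            n1 = _rotate(curve_state.n1, axis, cos_a, sin_a)
            n1 = n1 - float(n1 @ t_new) * t_new
            n1 /= np.linalg.norm(n1)
            n2 = np.cross(t_new, n1)
        return FrameState(pos, t_new, n1, n2), True
    return curve_state, False


def _rotate(v, axis, cos_a, sin_a):
    return v * cos_a + np.cross(axis, v) * sin_a + axis * float(axis @ v) * (1 - cos_a)


def make_training_target(
    framed: FramedCurve,
    agent_state: FrameState,
    mask: VolumeGrid | None,
    max_range: float,
    s_c_floor: float,
    s_c_cap: float | None = None,
    kappa_max: float = KAPPA_MAX,
    fallback_s_c: float | None = None,
    s_hint: float | None = None,
) -> TrainingTarget:
    """Build a supervised (steering, membrane distance) pair for a pose.

    The convergence distance is the membrane distance along the flight
    direction, floored at one step length (the closed form diverges as
    s_c -> 0) and capped at the patch z field of view.
    """
    if mask is not None:
        d_m, inside = membrane_distance(mask, agent_state.position, agent_state.t, max_range)
        if not inside:
            d_m = 0.0
    else:
        d_m = fallback_s_c if fallback_s_c is not None else max_range
    s_c = max(d_m, s_c_floor)
    if s_c_cap is not None:
        s_c = min(s_c, s_c_cap)
    bounds = None if s_hint is None else (s_hint - 0.5, s_hint + 0.5)
    s_star, _ = closest_point(framed.curve, agent_state.position,
                              coarse_n=128 if bounds else 512, bounds=bounds)
    ref = framed.frame_at(s_star)
    kvec = framed.curve.curvature_vector(s_star)
    steer = corrective_steering_vec(ref.position, ref.t, kvec, agent_state, s_c, kappa_max)
    return TrainingTarget(steer, float(d_m))
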