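"""Recurrent flight inference and uncertainty-ranked error correction.

A tracer repeatedly: extracts the frame-aligned patch at the current pose,
asks a steerer for Bishop curvatures, advances by the curvature-adaptive
step along the steering parabola, and optionally applies a random rotation
about the tangent (which decorrelates consecutive inputs at no cost, since
rotations about t are invariance transformations of the steering problem).

Steerers come in two flavours: a network steerer wrapping the steering CNN,
and an oracle steerer that computes the analytic flight policy from ground
truth — the latter isolates the tracing framework from learning quality in
tests.  Bidirectional validation re-traces a finished flight backwards and
only accepts it if the return flight re-enters the seed object along the
same path; Monte-Carlo-dropout uncertainties rank validated tracings so
corrections can be applied conservatively (split resolution traded against
introduced mergers).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    FramedCurve,
    FrameState,
    StepConfig,
    Steering,
    adaptive_step,
    closest_point,
    complete_frame,
    integrate_parabola,
    rotate_flip_frame,
)
from .model import MCSamples, SteeringNet, mc_predict, predict
from .policy import KAPPA_MAX, corrective_steering_vec, membrane_distance
from .sampling import PatchGeometry, VolumeGrid, extract_aligned_patch
from .synthetic import SkeletonFragment, ToyAgglomeration

__all__ = [
    "Trace",
    "StopRules",
    "SkeletonTarget",
    "LabelTarget",
    "NetworkSteerer",
    "OracleSteerer",
    "trace",
    "ValidatedTracing",
    "validate_bidirectional",
    "uncertainty_score",
    "smooth_uncertainties",
    "fibonacci_sphere",
    "DirectionCandidates",
    "predict_direction",
    "attach_spine",
    "apply_corrections",
    "resolve_splits",
]


# ---------------------------------------------------------------------------
# Stop rules and targets
# ---------------------------------------------------------------------------


class SkeletonTarget:
    """'Another reconstructed object': skeleton nodes reached within a radius."""

    def __init__(self, points: np.ndarray, ids: np.ndarray, radius: float = 0.15,
                 ignore: set | None = None):
        self.tree = cKDTree(np.asarray(points, float))
        self.ids = np.asarray(ids)
        self.radius = radius
        self.ignore = ignore or set()

    def hit(self, pos: np.ndarray):
        idx = self.tree.query_ball_point(pos, self.radius)
        for i in idx:
            if self.ids[i] not in self.ignore:
                return self.ids[i]
        return None


class LabelTarget:
    """'Another reconstructed object': nearest-voxel lookup in a label volume."""

    def __init__(self, labels: VolumeGrid, ignore: set | None = None):
        self.labels = labels
        self.ignore = set(ignore or set()) | {0}

    def hit(self, pos: np.ndarray):
        idx = np.rint(self.labels.world_to_index(pos)).astype(int)
        shape = self.labels.intensities.shape
        if np.any(idx < 0) or np.any(idx >= shape):
            return None
        lab = int(self.labels.intensities[tuple(idx)])
        return lab if lab not in self.ignore else None


@dataclass
class StopRules:
    """Termination conditions for a flight.

    A flight stops on: leaving the volume, reaching the target object,
    exceeding max_steps, re-entering its own path (self loop), or the
    predicted membrane distance staying below one step length for
    ``low_confidence_steps`` consecutive steps.
    """

    max_steps: int = 5000
    target: SkeletonTarget | LabelTarget | None = None
    self_loop_radius: float | None = None  # default 2x patch half-size set by tracer
    self_loop_lag: int = 20
    low_confidence_steps: int = 5
    min_steps_before_target: int = 3


@dataclass
class Trace:
    states: list[FrameState]
    steerings: list[Steering]
    uncertainties: list[float] | None
    stop_reason: str  # reached_object | left_volume | max_steps | self_loop | low_confidence
    reached_id: int | None = None
    arc_length: float = 0.0

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([s.position for s in self.states])

    def max_uncertainty(self) -> float:
        if not self.uncertainties:
            return 0.0
        return float(np.max(self.uncertainties))


# ---------------------------------------------------------------------------
# Steerers
# ---------------------------------------------------------------------------


class NetworkSteerer:
    """Wraps the steering CNN: patch extraction + prediction (+ MC uncertainty)."""

    def __init__(self, net: SteeringNet, geom: PatchGeometry | None = None,
                 mc_samples: int = 0, seed: int = 0):
        self.net = net
        if geom is None:
            shape = net.cfg.input_shape
            geom = PatchGeometry(shape=shape)
        self.geom = geom
        self.mc_samples = mc_samples
        self._rng = np.random.default_rng(seed)

    def steer(self, state: FrameState, volume: VolumeGrid):
        patch = extract_aligned_patch(volume, state, self.geom)
        if patch.left_volume:
            return None, None
        steering = predict(self.net, patch)
        u = None
        if self.mc_samples >= 2:
            sub = int(self._rng.integers(0, 2**31 - 1))
            samples = mc_predict(self.net, patch, self.mc_samples, seed=sub)
            u = uncertainty_score(samples)
        return steering, u


class OracleSteerer:
    """Analytic flight policy computed from ground-truth centerlines.

    Substituting this for the CNN isolates the tracing framework (stepping,
    stop rules, validation, metrics) from learning quality.  Steering is
    direction-aware: the reference tangent is flipped to match the agent's
    travel direction.
    """

    def __init__(self, framed: FramedCurve | list[FramedCurve], s_c: float = 0.4,
                 mask: VolumeGrid | None = None, max_range: float | None = None,
                 kappa_max: float = KAPPA_MAX, index_spacing: float = 0.02):
        self.curves = framed if isinstance(framed, list) else [framed]
        self.s_c = s_c
        self.mask = mask
        self.max_range = max_range or 2.0 * s_c
        self.kappa_max = kappa_max
        # spatial index over all centerlines for fast closest-point queries
        pts, cid, svals = [], [], []
        for i, fc in enumerate(self.curves):
            s = np.arange(0.0, fc.length, index_spacing)
            pts.append(fc.curve.position(s))
            cid.append(np.full(len(s), i))
            svals.append(s)
        self._tree = cKDTree(np.concatenate(pts))
        self._cid = np.concatenate(cid)
        self._s = np.concatenate(svals)
        self._spacing = index_spacing

    def steer(self, state: FrameState, volume: VolumeGrid | None = None):
        _, j = self._tree.query(state.position)
        fc = self.curves[int(self._cid[j])]
        s0 = float(self._s[j])
        s_star, pt = closest_point(
            fc.curve, state.position, coarse_n=32,
            bounds=(s0 - 2 * self._spacing, s0 + 2 * self._spacing),
        )
        t_ref = fc.curve.tangent(s_star)
        if float(t_ref @ state.t) < 0.0:
            t_ref = -t_ref
        kvec = fc.curve.curvature_vector(s_star)
        s_c = self.s_c
        d_m = None
        if self.mask is not None:
            d_m, inside = membrane_distance(self.mask, state.position, state.t, self.max_range)
            if inside and d_m > 0:
                s_c = max(d_m, 1e-2)
        steer = corrective_steering_vec(pt, t_ref, kvec, state, s_c, self.kappa_max)
        return replace(steer, membrane_distance=d_m), None


# ---------------------------------------------------------------------------
# Tracing
# ---------------------------------------------------------------------------


def trace(
    steerer,
    volume: VolumeGrid | None,
    seed_state: FrameState,
    step_cfg: StepConfig = StepConfig(),
    stop_rules: StopRules | None = None,
    mode: str = "normal",
    seed: int = 0,
) -> Trace:
    """Run recurrent flight inference from a seed pose.

    In ``random_rotation`` mode the frame is rotated by U(0, 2*pi) about the
    tangent after every integration step; the traced path is statistically
    unchanged (rotations are invariance transformations) while consecutive
    patch orientations decorrelate.
    """
    if mode not in ("normal", "random_rotation"):
        raise ValueError("mode must be 'normal' or 'random_rotation'")
    rules = stop_rules or StopRules()
    rng = np.random.default_rng(seed)
    if volume is not None and not volume.contains(seed_state.position):
        raise ValueError("seed position outside volume")

    self_loop_radius = rules.self_loop_radius
    if self_loop_radius is None:
        # must stay below the distance covered by self_loop_lag steps or a
        # straight flight would immediately trigger it
        self_loop_radius = min(0.25, 0.4 * rules.self_loop_lag * step_cfg.f * step_cfg.d)

    states = [seed_state]
    steerings: list[Steering] = []
    uncertainties: list[float] = []
    have_u = False
    low_conf = 0
    arc = 0.0
    stop_reason = "max_steps"
    reached = None

    for step_i in range(rules.max_steps):
        state = states[-1]
        if volume is not None and not volume.contains(state.position):
            stop_reason = "left_volume"
            break
        if rules.target is not None and step_i >= rules.min_steps_before_target:
            hit = rules.target.hit(state.position)
            if hit is not None:
                stop_reason = "reached_object"
                reached = hit
                break
        out = steerer.steer(state, volume)
        steering, u = out
        if steering is None:
            stop_reason = "left_volume"
            break
        if u is not None:
            have_u = True
            uncertainties.append(float(u))
        ds = adaptive_step(steering.kappa, step_cfg)
        if (
            steering.membrane_distance is not None
            and steering.membrane_distance < ds
        ):
            low_conf += 1
            if low_conf >= rules.low_confidence_steps:
                stop_reason = "low_confidence"
                steerings.append(steering)
                break
        else:
            low_conf = 0
        new_state = integrate_parabola(state, steering, ds)
        if mode == "random_rotation":
            new_state = rotate_flip_frame(new_state, rng.uniform(0.0, 2.0 * np.pi))
        # self-loop check against sufficiently old path points
        if len(states) > rules.self_loop_lag:
            old = np.asarray([s.position for s in states[: -rules.self_loop_lag]])
            if np.min(np.linalg.norm(old - new_state.position, axis=1)) < self_loop_radius:
                stop_reason = "self_loop"
                steerings.append(steering)
                states.append(new_state)
                arc += ds
                break
        states.append(new_state)
        steerings.append(steering)
        arc += ds

    return Trace(states, steerings, uncertainties if have_u else None,
                 stop_reason, reached, arc)


# ---------------------------------------------------------------------------
# Bidirectional validation
# ---------------------------------------------------------------------------


@dataclass
class ValidatedTracing:
    forward: Trace
    backward: Trace | None
    agreed: bool
    tracing_uncertainty: float
    seed_fragment: int | None = None
    target_fragment: int | None = None
    reason: str = ""


def validate_bidirectional(
    steerer,
    volume: VolumeGrid | None,
    forward: Trace,
    seed_target: SkeletonTarget | LabelTarget,
    agreement_radius: float = 0.25,
    coverage: float = 0.8,
    step_cfg: StepConfig = StepConfig(),
    stop_rules: StopRules | None = None,
    mode: str = "normal",
    seed: int = 0,
) -> ValidatedTracing:
    """Confirm a forward flight by tracing the same location backwards.

    The backward flight starts at the forward end point with reversed
    tangent and must (a) re-enter the seed object and (b) stay within
    ``agreement_radius`` of the forward path for at least ``coverage`` of
    its points.  The tracing uncertainty combines the two directions with
    min(max-over-steps), so a tracing is only as uncertain as its more
    confident direction.
    """
    if forward.stop_reason != "reached_object":
        return ValidatedTracing(forward, None, False, np.inf,
                                reason=f"forward stopped: {forward.stop_reason}")
    rules = replace(stop_rules or StopRules(), target=seed_target)
    back_seed = forward.states[-1].reversed()
    backward = trace(steerer, volume, back_seed, step_cfg, rules, mode=mode, seed=seed)
    agreed = backward.stop_reason == "reached_object"
    if agreed and len(backward.states) > 1:
        fwd_tree = cKDTree(forward.positions)
        d, _ = fwd_tree.query(backward.positions)
        agreed = float((d <= agreement_radius).mean()) >= coverage
    u = min(forward.max_uncertainty(), backward.max_uncertainty())
    return ValidatedTracing(forward, backward, bool(agreed), u)


# ---------------------------------------------------------------------------
# Monte-Carlo-dropout uncertainty
# ---------------------------------------------------------------------------


def uncertainty_score(samples: MCSamples, eps: float = 1e-12) -> float:
    """sqrt(largest eigenvalue of the curvature covariance) / mean curvature.

    Scale-invariant: doubling all sampled curvatures leaves the score
    unchanged.  A vanishing mean curvature returns +inf (direction carries
    no information there).
    """
    k = np.asarray(samples.curvature_samples, dtype=float)
    if len(k) < 2:
        raise ValueError("need at least 2 samples for a covariance")
    mean_kappa = float(np.linalg.norm(k, axis=1).mean())
    if mean_kappa <= eps:
        return np.inf
    cov = np.cov(k.T)
    lam = float(np.linalg.eigvalsh(np.atleast_2d(cov))[-1])
    return float(np.sqrt(max(lam, 0.0)) / mean_kappa)


def smooth_uncertainties(orientations: np.ndarray, u: np.ndarray,
                         angle_limit_deg: float = 30.0, power: int = 16) -> np.ndarray:
    """Angular smoothing of per-orientation uncertainties.

    w_ij = <t_i|t_j>^power for neighbours within the angle limit (j != i),
    normalized to sum 1 over j; u_hat_i = u_i/2 + (1/2) sum_j w_ij_hat u_j.
    Orientations without any neighbour keep their raw uncertainty.
    """
    t = np.asarray(orientations, dtype=float)
    u = np.asarray(u, dtype=float)
    cos = np.clip(t @ t.T, -1.0, 1.0)
    w = np.where(cos > np.cos(np.deg2rad(angle_limit_deg)), cos**power, 0.0)
    np.fill_diagonal(w, 0.0)
    sums = w.sum(axis=1)
    u_hat = u.copy()
    has_nb = sums > 0
    # finite-neighbour average; infinities among neighbours propagate
    with np.errstate(invalid="ignore"):
        nb_avg = np.where(has_nb, (w @ np.nan_to_num(u, posinf=np.inf)) / np.where(has_nb, sums, 1.0), 0.0)
    u_hat[has_nb] = 0.5 * u[has_nb] + 0.5 * nb_avg[has_nb]
    return u_hat


def fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly equidistant unit orientations (deterministic)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


@dataclass
class DirectionCandidates:
    orientations: np.ndarray  # (I, 3)
    u: np.ndarray
    u_hat: np.ndarray
    ranking: np.ndarray
    candidates: list[int]  # indices of chosen start orientations


def predict_direction(
    net: SteeringNet,
    volume: VolumeGrid,
    position: np.ndarray,
    I: int = 256,
    M: int = 128,
    seed: int = 0,
    geom: PatchGeometry | None = None,
    second_candidate_angle_deg: float = 110.0,
) -> DirectionCandidates:
    """Choose start orientation(s) at a position with no given direction.

    Samples I near-equidistant orientations, runs M-sample Monte-Carlo
    dropout per orientation, scores and angularly smooths the uncertainties,
    and returns the minimal-uncertainty orientation plus a second candidate
    more than 110 degrees away (spine necks may point either way).
    """
    position = np.asarray(position, dtype=float)
    orient = fibonacci_sphere(I)
    if geom is None:
        geom = PatchGeometry(shape=net.cfg.input_shape)
    u = np.full(I, np.inf)
    rng = np.random.default_rng(seed)
    subseeds = rng.integers(0, 2**31 - 1, size=I)
    for i in range(I):
        frame = complete_frame(orient[i])
        state = FrameState(position, frame.t, frame.n1, frame.n2)
        patch = extract_aligned_patch(volume, state, geom)
        if patch.left_volume:
            continue
        samples = mc_predict(net, patch, M, seed=int(subseeds[i]))
        u[i] = uncertainty_score(samples)
    u_hat = smooth_uncertainties(orient, u)
    ranking = np.argsort(u_hat, kind="stable")
    candidates: list[int] = []
    if np.isfinite(u_hat[ranking[0]]):
        first = int(ranking[0])
        candidates.append(first)
        min_cos = np.cos(np.deg2rad(second_candidate_angle_deg))
        far = (orient @ orient[first]) < min_cos
        far &= np.isfinite(u_hat)
        if np.any(far):
            idx = np.nonzero(far)[0]
            candidates.append(int(idx[np.argmin(u_hat[far])]))
    return DirectionCandidates(orient, u, u_hat, ranking, candidates)


# ---------------------------------------------------------------------------
# Spine-head attachment
# ---------------------------------------------------------------------------


@dataclass
class SpineAttachment:
    head_position: np.ndarray
    dendrite_id: int | None
    uncertainty: float
    candidates_tried: int = 0


def attach_spine(
    net: SteeringNet,
    volume: VolumeGrid,
    spine_head_position: np.ndarray,
    dendrite_labels: VolumeGrid,
    I: int = 64,
    M: int = 32,
    seed: int = 0,
    step_cfg: StepConfig = StepConfig(),
    stop_rules: StopRules | None = None,
    geom: PatchGeometry | None = None,
) -> SpineAttachment:
    """Trace from a spine head down its neck to the dendritic shaft of origin.

    No start orientation is given: direction candidates come from
    Monte-Carlo-dropout uncertainty over sampled orientations; each
    candidate is flown until a dendrite label is reached.  The attachment
    with the lowest tracing uncertainty wins; failing all candidates the
    head is reported unattached (a valid outcome).
    """
    head = np.asarray(spine_head_position, dtype=float)
    cand = predict_direction(net, volume, head, I=I, M=M, seed=seed, geom=geom)
    target = LabelTarget(dendrite_labels)
    rules = replace(stop_rules or StopRules(max_steps=600), target=target)
    steerer = NetworkSteerer(net, geom=geom, mc_samples=M, seed=seed)
    best: tuple[int, float] | None = None
    tried = 0
    for ci in cand.candidates:
        tried += 1
        frame = complete_frame(cand.orientations[ci])
        state = FrameState(head, frame.t, frame.n1, frame.n2)
        tr = trace(steerer, volume, state, step_cfg, rules, seed=seed)
        if tr.stop_reason != "reached_object":
            continue
        u = tr.max_uncertainty()
        if best is None or u < best[1]:
            best = (int(tr.reached_id), u)
    if best is None:
        return SpineAttachment(head, None, np.inf, tried)
    return SpineAttachment(head, best[0], best[1], tried)


# ---------------------------------------------------------------------------
# Agglomeration correction
# ---------------------------------------------------------------------------


def resolve_splits(
    steerer,
    volume: VolumeGrid | None,
    aggl: ToyAgglomeration,
    step_cfg: StepConfig = StepConfig(),
    reach_radius: float = 0.15,
    agreement_radius: float = 0.25,
    max_steps: int = 1500,
    max_flight_length: float | None = 5.0,
    seed: int = 0,
) -> list[ValidatedTracing]:
    """Seed flights at fragment endpoints and validate the connections found.

    For each fragment end, a flight is launched outward until it reaches a
    node of another fragment; the connection is then confirmed by a backward
    flight.  Split gaps are local, so flights are capped at
    ``max_flight_length`` (um) — long wandering flights are far more likely
    to manufacture mergers than to resolve genuine splits.  Returns one
    ValidatedTracing per endpoint flight that reached an object (agreed or
    not); apply_corrections consumes them.
    """
    all_nodes = np.concatenate([f.nodes for f in aggl.fragments])
    all_ids = np.concatenate(
        [np.full(len(f.nodes), f.fragment_id) for f in aggl.fragments]
    )
    results: list[ValidatedTracing] = []
    rules_tpl = StopRules(max_steps=max_steps)
    if max_flight_length is not None:
        rules_tpl.max_steps = min(max_steps, int(max_flight_length / (step_cfg.f * step_cfg.d) * 2))
    for frag in aggl.fragments:
        if len(frag.nodes) < 2:
            continue
        for end in (0, -1):
            p_end = frag.nodes[end]
            p_prev = frag.nodes[1 if end == 0 else -2]
            t = p_end - p_prev
            nt = np.linalg.norm(t)
            if nt < 1e-9:
                continue
            t /= nt
            frame = complete_frame(t)
            state = FrameState(p_end, frame.t, frame.n1, frame.n2)
            target = SkeletonTarget(all_nodes, all_ids, radius=reach_radius,
                                    ignore={frag.fragment_id})
            rules = replace(rules_tpl, target=target)
            fwd = trace(steerer, volume, state, step_cfg, rules, seed=seed)
            if fwd.stop_reason != "reached_object":
                continue
            seed_target = SkeletonTarget(frag.nodes,
                                         np.full(len(frag.nodes), frag.fragment_id),
                                         radius=reach_radius)
            vt = validate_bidirectional(
                steerer, volume, fwd, seed_target,
                agreement_radius=agreement_radius, step_cfg=step_cfg,
                stop_rules=rules_tpl, seed=seed,
            )
            vt.seed_fragment = frag.fragment_id
            vt.target_fragment = int(fwd.reached_id)
            results.append(vt)
    return results


def apply_corrections(
    aggl: ToyAgglomeration,
    validated: list[ValidatedTracing],
    percentile: float,
) -> ToyAgglomeration:
    """Union fragments linked by agreed tracings up to an uncertainty percentile.

    Only agreed tracings participate; the ``percentile`` of their
    uncertainty distribution caps which ones are applied (0 applies none,
    1 applies all), trading split resolution against the risk of introduced
    mergers.  Returns a new agglomeration with tracing links added.
    """
    if not (0.0 <= percentile <= 1.0):
        raise ValueError("percentile must lie in (0, 1]")
    agreed = [v for v in validated if v.agreed and v.seed_fragment is not None]
    links: list[tuple[int, int]] = []
    if agreed and percentile > 0.0:
        us = np.asarray([v.tracing_uncertainty for v in agreed], dtype=float)
        cutoff = np.quantile(us, percentile)
        for v, u in zip(agreed, us):
            if u <= cutoff:
                links.append((int(v.seed_fragment), int(v.target_fragment)))
    return ToyAgglomeration(
        aggl.fragments,
        aggl.truth_map,
        aggl.induced_splits,
        aggl.induced_merges,
        merge_links=list(aggl.merge_links),
        tracing_links=sorted(set(links)),
    )
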