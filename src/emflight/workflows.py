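"""End-to-end workflows: training-set generation, training, and correction.

These compose the lower-level modules into the runs a user actually does:
sample supervised (patch, steering) pairs from a synthetic scene, train the
steering network, measure its curvature error on held-out neurites, and run
flight-based split resolution with bidirectional validation on a toy
agglomeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import FrameState, StepConfig, complete_frame
from .model import SteeringNet, TrainConfig, build_and_init, train
from .policy import PerturbLimits, make_training_target, perturb_state
from .sampling import PatchGeometry, extract_aligned_patch
from .synthetic import SyntheticScene, ToyAgglomeration
from .tracing import NetworkSteerer, apply_corrections, resolve_splits
from .evaluation import SplitMergeConfig, error_rates

__all__ = [
    "make_training_data",
    "curvature_error",
    "split_resolution",
    "CorrectionOutcome",
]


def make_training_data(
    scene: SyntheticScene,
    geom: PatchGeometry,
    n_samples: int,
    seed: int = 0,
    limits: PerturbLimits | None = None,
    neurite_indices: list[int] | None = None,
    s_c_floor: float = 0.05,
    max_range: float | None = None,
    on_centerline_fraction: float = 0.3,
    offset_radius_factor: float = 0.5,
):
    """Sample supervised (patch, state, target) triples from a scene.

    Arc-length positions are drawn uniformly (length-weighted) over the
    chosen neurites; each pose is perturbed off-centerline and
    off-direction within the neurite mask, the corrective steering target
    is computed by the flight policy with the membrane distance as dynamic
    convergence distance, and the aligned patch is extracted.
    """
    rng = np.random.default_rng(seed)
    indices = neurite_indices if neurite_indices is not None else list(range(len(scene.neurites)))
    lengths = np.array([scene.neurites[i].length for i in indices])
    probs = lengths / lengths.sum()
    if limits is None:
        limits = PerturbLimits()
    if max_range is None:
        max_range = geom.z_extent
    patches, states, targets = [], [], []
    margin = 0.3
    while len(patches) < n_samples:
        ni = indices[rng.choice(len(indices), p=probs)]
        neurite = scene.neurites[ni]
        if neurite.length <= 2 * margin:
            continue
        s = rng.uniform(margin, neurite.length - margin)
        frame = neurite.framed.frame_at(s)
        mask = scene.mask_grid(ni)
        r_local = float(neurite.radius_at(s))
        if rng.uniform() < on_centerline_fraction:
            state, ok = frame, True
        else:
            lim = PerturbLimits(
                max_offset=min(limits.max_offset, offset_radius_factor * r_local),
                max_angle=limits.max_angle,
            )
            state, ok = perturb_state(frame, mask, rng, lim)
        if not ok:
            continue
        target = make_training_target(
            neurite.framed, state, mask, max_range=max_range,
            s_c_floor=s_c_floor, s_c_cap=geom.z_extent, s_hint=s,
        )
        patch = extract_aligned_patch(scene.volume, state, geom)
        if patch.left_volume:
            continue
        patches.append(patch.intensities)
        states.append(
            np.concatenate([state.position, state.t, state.n1, state.n2])
        )
        targets.append(target.as_array())
    return (
        np.asarray(patches, dtype=np.float32),
        np.asarray(states),
        np.asarray(targets),
    )


def curvature_error(
    net: SteeringNet,
    scene: SyntheticScene,
    geom: PatchGeometry,
    neurite_indices: list[int],
    n_eval: int = 100,
    seed: int = 0,
    mode: str = "policy",
    limits: PerturbLimits | None = None,
    offset_radius_factor: float = 0.5,
    s_c_floor: float = 0.12,
    symmetrized: bool = True,
) -> float:
    """Median curvature error |k_hat - k| (1/um) on held-out neurites.

    ``mode='policy'`` samples poses from the training distribution
    (off-centerline, off-direction) and compares against the flight-policy
    target — the quantity the network is asked to recover.
    ``mode='centerline'`` uses exact on-centerline aligned poses with the
    curve's own curvature as reference.
    """
    rng = np.random.default_rng(seed)
    errs = []
    from .model import predict, predict_symmetrized

    predictor = predict_symmetrized if symmetrized else predict
    if limits is None:
        limits = PerturbLimits()
    while len(errs) < n_eval:
        ni = neurite_indices[rng.integers(0, len(neurite_indices))]
        neurite = scene.neurites[ni]
        if neurite.length < 1.0:
            continue
        s = rng.uniform(0.3, neurite.length - 0.3)
        frame = neurite.framed.frame_at(s)
        if mode == "centerline":
            state = frame
            steer = neurite.framed.steering_at(s, frame)
            k_ref = np.array([steer.k1, steer.k2])
        else:
            mask = scene.mask_grid(ni)
            r_local = float(neurite.radius_at(s))
            lim = PerturbLimits(
                max_offset=min(limits.max_offset, offset_radius_factor * r_local),
                max_angle=limits.max_angle,
            )
            state, ok = perturb_state(frame, mask, rng, lim)
            if not ok:
                continue
            tgt = make_training_target(
                neurite.framed, state, mask, max_range=geom.z_extent,
                s_c_floor=s_c_floor, s_c_cap=geom.z_extent, s_hint=s,
            )
            k_ref = np.array([tgt.steering.k1, tgt.steering.k2])
        patch = extract_aligned_patch(scene.volume, state, geom)
        if patch.left_volume:
            continue
        pred = predictor(net, patch)
        errs.append(np.hypot(pred.k1 - k_ref[0], pred.k2 - k_ref[1]))
    return float(np.median(errs))


@dataclass
class CorrectionOutcome:
    splits_before: float
    splits_after: float
    merges_introduced: int
    merges_introduced_per_mm: float
    resolved_fraction: float
    gt_path_length_mm: float


def split_resolution(
    steerer,
    scene: SyntheticScene,
    aggl: ToyAgglomeration,
    step_cfg: StepConfig,
    percentile: float = 1.0,
    reach_radius: float = 0.15,
    agreement_radius: float = 0.25,
    seed: int = 0,
    eval_cfg: SplitMergeConfig = SplitMergeConfig(),
) -> CorrectionOutcome:
    """Resolve toy splits by validated flights and score the outcome.

    Flights are seeded at fragment endpoints, confirmed by backward
    tracing, filtered to the requested uncertainty percentile and applied;
    split/merge rates before and after are compared against ground truth.
    """
    before = error_rates(aggl, scene.neurites, eval_cfg)
    validated = resolve_splits(
        steerer, scene.volume, aggl, step_cfg,
        reach_radius=reach_radius, agreement_radius=agreement_radius, seed=seed,
    )
    corrected = apply_corrections(aggl, validated, percentile)
    after = error_rates(corrected, scene.neurites, eval_cfg)
    resolved = 0.0
    if before.split_count > 0:
        resolved = (before.split_count - after.split_count) / before.split_count
    return CorrectionOutcome(
        splits_before=before.split_count,
        splits_after=after.split_count,
        merges_introduced=after.merges_introduced,
        merges_introduced_per_mm=after.merges_introduced / after.gt_path_length_mm
        if after.gt_path_length_mm
        else 0.0,
        resolved_fraction=resolved,
        gt_path_length_mm=after.gt_path_length_mm,
    )
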