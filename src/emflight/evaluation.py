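"""Connectomic error metrics: reset-based model selection and split/merge rates.

Model selection runs recurrent inference along unbranched ground-truth
branches from both ends.  A first (softer) threshold pair on distance and
angle to the ground truth marks a tracing "experimental" — progress is not
credited; a second (harder) pair triggers a reset to the closest
ground-truth point before the experimental phase began.  Each reset counts
as two errors (one split, for abandoning the neurite of interest, plus one
merge, for steering into a wrong process).

Split/merge evaluation scores agglomerations against ground-truth
skeletons: merge errors are path excursions beyond 2.2 um from the source
neurite; pre-existing mergers weigh 0.5 (each usually joins two neurites),
tracing-introduced mergers weigh 1.0 (sparse evaluations cannot see the
partner); split counting is gated to agglomerates overlapping the ground
truth by more than 2.5 um so dust fragments do not dominate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import FramedCurve, FrameState, StepConfig, Steering, adaptive_step, \
    closest_point, integrate_parabola
from .synthetic import SkeletonFragment, ToyAgglomeration

__all__ = [
    "EvalThresholds",
    "ErrorReport",
    "reset_error_eval",
    "detect_merge_errors",
    "error_rates",
    "spine_attachment_metrics",
]


@dataclass(frozen=True)
class EvalThresholds:
    """Two-tier thresholds for reset-based evaluation (um / rad)."""

    experimental_distance: float = 1.0
    experimental_angle: float = np.deg2rad(60.0)
    reset_distance: float = 2.0
    reset_angle: float = np.deg2rad(120.0)

    def __post_init__(self):
        if (
            self.reset_distance < self.experimental_distance
            or self.reset_angle < self.experimental_angle
        ):
            raise ValueError("reset thresholds must be >= experimental thresholds")


@dataclass
class ErrorReport:
    splits_per_mm: float = 0.0
    merges_per_mm: float = 0.0
    resets: float = 0.0
    reset_errors_per_mm: float = 0.0
    gt_path_length_mm: float = 0.0
    covered_fraction: float = 1.0
    split_count: float = 0.0
    merge_count_weighted: float = 0.0
    merges_pre: int = 0
    merges_introduced: int = 0


# ---------------------------------------------------------------------------
# Reset-based evaluation
# ---------------------------------------------------------------------------


def _directed_frame(framed: FramedCurve, s: float, forward: bool) -> FrameState:
    f = framed.frame_at(s)
    return f if forward else f.reversed()


def reset_error_eval(
    steerer,
    branch: FramedCurve,
    thresholds: EvalThresholds = EvalThresholds(),
    step_cfg: StepConfig = StepConfig(),
    volume=None,
    end_tolerance: float | None = None,
    max_steps: int = 20000,
    max_resets: int = 100,
) -> tuple[float, float]:
    """Reset-based error rate of a tracer on one linear ground-truth branch.

    Runs recurrent inference from both ends.  Returns (resets,
    reset_errors_per_mm) with errors = 2 * resets (each reset is one split
    plus one merge).  A tracer failing immediately at a seed reports inf.
    """
    L = branch.length
    tol = end_tolerance if end_tolerance is not None else max(4 * step_cfg.f * step_cfg.d, 0.05)
    total_resets = 0
    for forward in (True, False):
        s_seed = 0.0 if forward else L
        state = _directed_frame(branch, s_seed, forward)
        s_good = s_seed
        experimental = False
        resets_dir = 0
        done = False
        for _ in range(max_steps):
            out = steerer.steer(state, volume)
            steering = out[0] if isinstance(out, tuple) else out
            if steering is None:
                return np.inf, np.inf
            ds = adaptive_step(steering.kappa, step_cfg)
            state = integrate_parabola(state, steering, ds)
            s_star, pt = closest_point(branch.curve, state.position)
            dist = float(np.linalg.norm(pt - state.position))
            t_gt = branch.curve.tangent(s_star)
            if not forward:
                t_gt = -t_gt
            angle = float(np.arccos(np.clip(state.t @ t_gt, -1.0, 1.0)))
            if dist > thresholds.reset_distance or angle > thresholds.reset_angle:
                resets_dir += 1
                total_resets += 1
                state = _directed_frame(branch, s_good, forward)
                experimental = False
                if resets_dir >= max_resets:
                    break
                continue
            if dist > thresholds.experimental_distance or angle > thresholds.experimental_angle:
                experimental = True
            else:
                experimental = False
                s_good = s_star
            if not experimental:
                if forward and s_star >= L - tol:
                    done = True
                elif not forward and s_star <= tol:
                    done = True
            if done:
                break
    rate = 2.0 * total_resets / (L / 1000.0)
    return float(total_resets), float(rate)


# ---------------------------------------------------------------------------
# Split / merge evaluation
# ---------------------------------------------------------------------------


def _gt_trees(gt_neurites, spacing: float = 0.05):
    trees = []
    lengths = []
    for g in gt_neurites:
        if isinstance(g, np.ndarray):
            pts = g
            lengths.append(float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()))
        else:  # FramedCurve / Neurite-like with .curve
            curve = g.curve if hasattr(g, "curve") else g
            s = np.arange(0.0, curve.length, spacing)
            pts = curve.position(s)
            lengths.append(float(curve.length))
        trees.append(cKDTree(pts))
    return trees, lengths


def _fragment_source(frag_nodes: np.ndarray, trees, assign_radius: float) -> int:
    counts = []
    med = []
    for t in trees:
        d, _ = t.query(frag_nodes)
        counts.append(int((d <= assign_radius).sum()))
        med.append(float(np.median(d)))
    if max(counts) > 0:
        return int(np.argmax(counts))
    return int(np.argmin(med))


def detect_merge_errors(
    fragment_skeletons: list[SkeletonFragment],
    gt_neurites,
    excursion_threshold: float = 2.2,
    assign_radius: float = 1.0,
) -> list[tuple[int, int, int]]:
    """Detect merge errors as path excursions beyond the threshold distance.

    Each fragment is assigned to the ground-truth neurite it overlaps most;
    a contiguous run of its nodes all further than ``excursion_threshold``
    from that neurite counts as one merge error.  Excursions shorter than
    the threshold are a documented blind spot of this heuristic.  Returns a
    list of (fragment_id, run_start, run_end) tuples.
    """
    if not gt_neurites:
        raise ValueError("ground truth must not be empty")
    trees, _ = _gt_trees(gt_neurites)
    merges = []
    for frag in fragment_skeletons:
        src = _fragment_source(frag.nodes, trees, assign_radius)
        d, _ = trees[src].query(frag.nodes)
        far = d > excursion_threshold
        in_run = False
        start = 0
        for i, f in enumerate(far):
            if f and not in_run:
                in_run, start = True, i
            elif not f and in_run:
                merges.append((frag.fragment_id, start, i))
                in_run = False
        if in_run:
            merges.append((frag.fragment_id, start, len(far)))
    return merges


@dataclass(frozen=True)
class SplitMergeConfig:
    overlap_gate: float = 2.5  # um of overlap required for split counting
    assign_radius: float = 1.0  # node-to-gt matching radius
    merge_excursion: float = 2.2  # um


def _link_merges(links, frag_by_id, trees, cfg) -> int:
    """Merge contacts among fragment links, detected geometrically.

    A link (fa, fb) is a merge error when fb lies entirely beyond the
    excursion threshold from fa's own source neurite (and vice versa — the
    check is symmetric for well-separated neurites).  Counting per contact
    rather than per component keeps chains of merges countable one by one.
    """
    n = 0
    for fa_id, fb_id in links:
        fa, fb = frag_by_id[fa_id], frag_by_id[fb_id]
        src_a = _fragment_source(fa.nodes, trees, cfg.assign_radius)
        d, _ = trees[src_a].query(fb.nodes)
        if np.all(d > cfg.merge_excursion):
            n += 1
    return n


def _internal_merges(fragments, trees, cfg) -> int:
    """Excursion runs inside single fragments (path-based merge errors)."""
    n = 0
    for f in fragments:
        src = _fragment_source(f.nodes, trees, cfg.assign_radius)
        d, _ = trees[src].query(f.nodes)
        n += _count_runs(d > cfg.merge_excursion)
    return n


def _count_runs(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    m = mask.astype(int)
    return int(m[0] + np.clip(np.diff(m), 0, None).sum())


def _matched_length(nodes: np.ndarray, matched: np.ndarray) -> float:
    """Path length of the matched portion of a node chain."""
    if len(nodes) < 2:
        return 0.0
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    both = matched[:-1] & matched[1:]
    return float(seg[both].sum())


def error_rates(
    aggl: ToyAgglomeration,
    gt_neurites,
    cfg: SplitMergeConfig = SplitMergeConfig(),
) -> ErrorReport:
    """Split and merge error rates of an agglomeration against ground truth.

    Split count per neurite = (number of gated agglomerates overlapping it)
    minus one, floored at zero; an agglomerate passes the gate when its
    overlap path length exceeds ``overlap_gate``.  Merge errors detected as
    excursions: those already present from the initial agglomeration weigh
    0.5, those introduced by applied tracings weigh 1.0.  Rates are per mm
    of ground-truth path length.
    """
    trees, lengths = _gt_trees(gt_neurites)
    total_mm = sum(lengths) / 1000.0
    frag_by_id = {f.fragment_id: f for f in aggl.fragments}

    import networkx as nx

    def comps(links):
        g = nx.Graph()
        g.add_nodes_from(frag_by_id)
        g.add_edges_from(links)
        return list(nx.connected_components(g))

    full_components = comps(aggl.merge_links + aggl.tracing_links)

    # per-(component, gt) overlap path length, on the full agglomeration
    n_gt = len(trees)
    split_count = 0.0
    covered = np.zeros(n_gt)
    for comp in full_components:
        overlap = np.zeros(n_gt)
        for fid in comp:
            f = frag_by_id[fid]
            for gi, t in enumerate(trees):
                d, _ = t.query(f.nodes)
                overlap[gi] += _matched_length(f.nodes, d <= cfg.assign_radius)
        for gi in range(n_gt):
            if overlap[gi] > cfg.overlap_gate:
                covered[gi] += overlap[gi]
    for gi in range(n_gt):
        n_over = 0
        for comp in full_components:
            ov = 0.0
            for fid in comp:
                f = frag_by_id[fid]
                d, _ = trees[gi].query(f.nodes)
                ov += _matched_length(f.nodes, d <= cfg.assign_radius)
            if ov > cfg.overlap_gate:
                n_over += 1
        split_count += max(0, n_over - 1)

    # merge errors counted per contact: pre-existing ones weigh 0.5 (each
    # joins two neurites, both of which are evaluated), tracing-introduced
    # ones weigh 1.0 (sparse evaluations cannot see the partner object)
    merges_pre = _link_merges(aggl.merge_links, frag_by_id, trees, cfg) \
        + _internal_merges(aggl.fragments, trees, cfg)
    merges_introduced = _link_merges(aggl.tracing_links, frag_by_id, trees, cfg)
    weighted = 0.5 * merges_pre + 1.0 * merges_introduced

    covered_fraction = float(
        np.clip(covered / np.maximum(lengths, 1e-12), 0.0, 1.0).mean()
    ) if n_gt else 0.0

    return ErrorReport(
        splits_per_mm=split_count / total_mm if total_mm else 0.0,
        merges_per_mm=weighted / total_mm if total_mm else 0.0,
        gt_path_length_mm=total_mm,
        covered_fraction=covered_fraction,
        split_count=split_count,
        merge_count_weighted=weighted,
        merges_pre=merges_pre,
        merges_introduced=merges_introduced,
    )


# ---------------------------------------------------------------------------
# Spine attachment metrics
# ---------------------------------------------------------------------------


def spine_attachment_metrics(
    results: dict, gt_attachments: dict
) -> tuple[float, float]:
    """(recall, precision) of spine-head attachment.

    ``results`` maps head id -> attached trunk id or None; ``gt_attachments``
    maps head id -> true trunk id, or None for heads that cannot be attached
    even manually.  Unattachable heads left unattached are true negatives:
    they appear in neither denominator.  recall = correct / attachable;
    precision = correct / attached (NaN when nothing was attached).
    """
    correct = attached = attachable = 0
    for head, truth in gt_attachments.items():
        res = results.get(head)
        if truth is not None:
            attachable += 1
        if res is not None:
            attached += 1
            if truth is not None and res == truth:
                correct += 1
    recall = correct / attachable if attachable else float("nan")
    precision = correct / attached if attached else float("nan")
    return recall, precision
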