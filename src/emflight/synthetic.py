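"""Synthetic EM-like volumes with known ground truth.

Real volume EM of neuropil shows bright intracellular lumen bounded by dark
plasma membranes, densely packed tubular processes (axon radii from tens of
nm to ~1 um), varicosities (local swellings), branch points, anisotropic
voxels and occasional per-section misalignment.  This module generates
volumes with exactly those features from smooth random-walk centerlines, so
every downstream component (patch sampling, flight policy, steering net,
tracer, error metrics) can be exercised against exact ground truth.

It deliberately does not emulate organelle texture, myelin, or the noise
statistics of any particular microscope; conclusions drawn from these
fixtures are about the tracing machinery, not about real-tissue difficulty.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .geometry import CenterlineCurve, FramedCurve, FrameState, complete_frame, fit_bspline
from .sampling import VolumeGrid

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "SkeletonFragment",
    "ToyAgglomeration",
    "generate_scene",
    "straight_tube_scene",
    "make_toy_agglomeration",
]


@dataclass(frozen=True)
class SceneConfig:
    """Generation parameters for a synthetic scene (lengths in um, sizes in voxels)."""

    shape: tuple[int, int, int] = (128, 128, 64)
    voxel_size_nm: tuple[float, float, float] = (11.24, 11.24, 28.0)
    n_neurites: int = 5
    radius_range: tuple[float, float] = (0.05, 1.0)
    tortuosity: float = 0.25  # stddev (rad) of per-step direction change
    step_length: float | None = None  # random-walk step; default 4x min voxel
    varicosity_rate: float = 0.5  # per um
    varicosity_factor: tuple[float, float] = (2.0, 3.0)
    varicosity_extent: float = 0.5  # um
    branch_rate: float = 0.0  # per um
    membrane_thickness: float = 0.02  # um (~20 nm)
    lumen_intensity: float = 0.7
    membrane_intensity: float = 0.2
    extracellular_intensity: float = 0.35
    noise_sigma: float = 0.05
    shot_noise: float = 0.0  # extra intensity-proportional noise scale
    misalignment_rate: float = 0.0  # probability per z section
    misalignment_max_shift: int = 2  # voxels
    target_fill: float | None = None  # add distractors until this foreground fraction
    min_separation_factor: float = 1.0  # reject centerlines closer than this x (r_i+r_j)
    rasterize: bool = True

    @property
    def voxel_um(self) -> np.ndarray:
        return np.asarray(self.voxel_size_nm, dtype=float) / 1000.0

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.shape, dtype=float) * self.voxel_um


@dataclass
class Neurite:
    """Ground-truth neurite: framed centerline plus arc-length radius profile."""

    framed: FramedCurve
    radius_s: np.ndarray
    radius_v: np.ndarray

    @property
    def curve(self) -> CenterlineCurve:
        return self.framed.curve

    @property
    def length(self) -> float:
        return self.framed.length

    def radius_at(self, s) -> np.ndarray:
        return np.interp(np.asarray(s, dtype=float), self.radius_s, self.radius_v)


@dataclass
class SyntheticScene:
    volume: VolumeGrid | None
    neurites: list[Neurite]
    masks: dict[int, np.ndarray]  # per-neurite boolean volumes
    labels: np.ndarray | None  # instance labels, 0 = background
    config: SceneConfig
    seed: int
    misaligned_sections: list[tuple[int, int, int]] = field(default_factory=list)

    def mask_grid(self, idx: int) -> VolumeGrid:
        if not hasattr(self, "_mask_grids"):
            self._mask_grids = {}
        if idx not in self._mask_grids:
            self._mask_grids[idx] = VolumeGrid(
                self.masks[idx].astype(np.float32),
                self.volume.voxel_size,
                self.volume.origin,
            )
        return self._mask_grids[idx]

    def total_path_length_mm(self) -> float:
        return sum(n.length for n in self.neurites) / 1000.0


def _random_centerline(cfg: SceneConfig, rng: np.random.Generator, extent: np.ndarray):
    step = cfg.step_length or 4.0 * float(cfg.voxel_um.min())
    margin = 0.05 * extent
    pos = rng.uniform(margin, extent - margin)
    # mild bias along the longest volume axis keeps walks from balling up
    d = rng.normal(size=3)
    d[int(np.argmax(extent))] += 3.0 * np.sign(rng.uniform() - 0.5)
    d /= np.linalg.norm(d)
    pts = [pos.copy()]
    n_max = int(2.0 * extent.max() / step)
    for _ in range(n_max):
        ang = rng.normal(0.0, cfg.tortuosity)
        axis = rng.normal(size=3)
        axis -= (axis @ d) * d
        na = np.linalg.norm(axis)
        if na > 1e-12:
            axis /= na
            d = d * np.cos(ang) + axis * np.sin(ang)
            d /= np.linalg.norm(d)
        pos = pos + step * d
        if np.any(pos < 0.0) or np.any(pos > extent):
            break
        pts.append(pos.copy())
    return np.asarray(pts)


def _radius_profile(cfg: SceneConfig, rng: np.random.Generator, length: float):
    base = rng.uniform(*cfg.radius_range)
    s = np.linspace(0.0, length, max(int(length / 0.05), 8))
    r = np.full_like(s, base)
    n_var = rng.poisson(cfg.varicosity_rate * length)
    for _ in range(n_var):
        center = rng.uniform(0.0, length)
        amp = rng.uniform(*cfg.varicosity_factor) - 1.0
        width = cfg.varicosity_extent / 4.0  # fusiform bump, ~extent wide overall
        r += base * amp * np.exp(-0.5 * ((s - center) / width) ** 2)
    return s, r


def generate_scene(cfg: SceneConfig, seed: int = 0) -> SyntheticScene:
    """Generate a deterministic synthetic scene from a config and seed.

    Centerlines are spline-smoothed random walks with per-point radii
    (including fusiform varicosities); the volume paints a bright lumen, a
    dark membrane shell of ~20 nm and mid-grey extracellular space, then
    adds Gaussian (and optionally shot) noise and per-section misalignment.
    Infeasible packing returns fewer neurites than requested.
    """
    rng = np.random.default_rng(seed)
    extent = cfg.extent_um
    neurites: list[Neurite] = []
    dense_pts: list[np.ndarray] = []
    dense_radius: list[np.ndarray] = []
    dense_id: list[np.ndarray] = []

    def try_add(existing_tree):
        nodes = _random_centerline(cfg, rng, extent)
        if len(nodes) < 8:
            return None
        sub = nodes[:: max(len(nodes) // 40, 1)]
        if len(sub) < 6:
            sub = nodes
        curve = fit_bspline(sub, degree=4)
        rs, rv = _radius_profile(cfg, rng, curve.length)
        s_dense = np.arange(0.0, curve.length, max(cfg.voxel_um.min() * 2.0, 0.02))
        pts = curve.position(s_dense)
        radii = np.interp(s_dense, rs, rv)
        if existing_tree is not None:
            d, idx = existing_tree.query(pts)
            r_other = np.concatenate(dense_radius)[idx]
            min_sep = cfg.min_separation_factor * (radii + r_other) + cfg.membrane_thickness
            if np.any(d < min_sep):
                return None
        framed = FramedCurve(curve, grid_n=max(int(curve.length / 0.1), 16))
        return Neurite(framed, rs, rv), pts, radii

    n_target = cfg.n_neurites
    attempts = 0
    tree = None
    while len(neurites) < n_target and attempts < 20 * n_target:
        attempts += 1
        res = try_add(tree)
        if res is None:
            continue
        neu, pts, radii = res
        neurites.append(neu)
        dense_pts.append(pts)
        dense_radius.append(radii)
        dense_id.append(np.full(len(pts), len(neurites) - 1, dtype=int))
        tree = cKDTree(np.concatenate(dense_pts))

    # optional distractor packing up to a target foreground fill fraction
    if cfg.target_fill is not None and cfg.rasterize:
        for _ in range(200):
            if _fill_fraction(cfg, dense_pts, dense_radius) >= cfg.target_fill:
                break
            res = try_add(tree)
            if res is None:
                continue
            neu, pts, radii = res
            neurites.append(neu)
            dense_pts.append(pts)
            dense_radius.append(radii)
            dense_id.append(np.full(len(pts), len(neurites) - 1, dtype=int))
            tree = cKDTree(np.concatenate(dense_pts))

    if not neurites:
        raise RuntimeError("could not place any neurite in the volume")

    if not cfg.rasterize:
        return SyntheticScene(None, neurites, {}, None, cfg, seed)

    volume, masks, labels, shifted = _rasterize(
        cfg, rng, np.concatenate(dense_pts), np.concatenate(dense_radius),
        np.concatenate(dense_id), len(neurites),
    )
    return SyntheticScene(volume, neurites, masks, labels, cfg, seed, shifted)


def _fill_fraction(cfg, dense_pts, dense_radius):
    # cheap estimate: sum of tube volumes / volume extent (ignores overlap)
    vol = 0.0
    for pts, radii in zip(dense_pts, dense_radius):
        if len(pts) < 2:
            continue
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        vol += float((np.pi * radii[:-1] ** 2 * seg).sum())
    return vol / float(np.prod(cfg.extent_um))


def _rasterize(cfg, rng, pts, radii, ids, n_neurites):
    shape = cfg.shape
    vox = cfg.voxel_um
    centers = [(np.arange(n) + 0.5) * v for n, v in zip(shape, vox)]
    grid = np.stack(np.meshgrid(*centers, indexing="ij"), axis=-1).reshape(-1, 3)
    tree = cKDTree(pts)
    # query within the largest possible tube radius
    r_max = float(radii.max()) + cfg.membrane_thickness
    dist, idx = tree.query(grid, distance_upper_bound=r_max + float(vox.max()))
    hit = np.isfinite(dist)
    r_here = np.zeros(len(grid))
    nid = np.full(len(grid), -1, dtype=int)
    r_here[hit] = radii[idx[hit]]
    nid[hit] = ids[idx[hit]]

    inside = hit & (dist < r_here)
    lumen = hit & (dist < r_here - cfg.membrane_thickness)
    membrane = inside & ~lumen

    intens = np.full(len(grid), cfg.extracellular_intensity, dtype=np.float32)
    intens[lumen] = cfg.lumen_intensity
    intens[membrane] = cfg.membrane_intensity
    intens += rng.normal(0.0, cfg.noise_sigma, size=len(grid)).astype(np.float32)
    if cfg.shot_noise > 0:
        intens += (
            cfg.shot_noise
            * np.sqrt(np.clip(intens, 0.0, None))
            * rng.normal(size=len(grid)).astype(np.float32)
        )
    intens = np.clip(intens, 0.0, 1.0).reshape(shape)

    labels = np.where(inside, nid + 1, 0).reshape(shape).astype(np.int32)
    masks = {i: (labels == i + 1) for i in range(n_neurites)}

    shifted = []
    if cfg.misalignment_rate > 0:
        for z in range(shape[2]):
            if rng.uniform() < cfg.misalignment_rate:
                sx = int(rng.integers(-cfg.misalignment_max_shift, cfg.misalignment_max_shift + 1))
                sy = int(rng.integers(-cfg.misalignment_max_shift, cfg.misalignment_max_shift + 1))
                if sx or sy:
                    intens[:, :, z] = np.roll(intens[:, :, z], (sx, sy), axis=(0, 1))
                    shifted.append((z, sx, sy))

    volume = VolumeGrid(intens, np.asarray(cfg.voxel_size_nm), np.zeros(3))
    return volume, masks, labels, shifted


def straight_tube_scene(
    radius: float = 0.2,
    length: float = 5.0,
    voxel_size_nm: tuple[float, float, float] = (22.0, 22.0, 44.0),
    lateral_extent: float = 1.2,
    noise_sigma: float = 0.05,
    seed: int = 0,
    axis: int = 2,
) -> SyntheticScene:
    """A single straight tube along a volume axis — the canonical fixture."""
    vox = np.asarray(voxel_size_nm) / 1000.0
    shape = [int(np.ceil(2 * lateral_extent / v)) for v in vox]
    shape[axis] = int(np.ceil(length / vox[axis]))
    cfg = SceneConfig(
        shape=tuple(shape),
        voxel_size_nm=voxel_size_nm,
        n_neurites=1,
        radius_range=(radius, radius),
        varicosity_rate=0.0,
        tortuosity=0.0,
        noise_sigma=noise_sigma,
    )
    rng = np.random.default_rng(seed)
    extent = cfg.extent_um
    start = 0.5 * extent
    start[axis] = 0.0
    end = start.copy()
    end[axis] = extent[axis]
    nodes = np.linspace(start, end, 12)
    curve = fit_bspline(nodes, degree=4)
    framed = FramedCurve(curve, grid_n=64)
    rs = np.array([0.0, curve.length])
    rv = np.array([radius, radius])
    neurite = Neurite(framed, rs, rv)
    s_dense = np.arange(0.0, curve.length, vox.min() * 2.0)
    pts = curve.position(s_dense)
    radii = np.full(len(s_dense), radius)
    volume, masks, labels, shifted = _rasterize(
        cfg, rng, pts, radii, np.zeros(len(pts), dtype=int), 1
    )
    return SyntheticScene(volume, [neurite], masks, labels, cfg, seed, shifted)


def spine_scene(
    two_trunks: bool = False,
    neck_radius: float = 0.07,
    head_radius: float = 0.22,
    trunk_radius: float = 0.45,
    voxel_size_nm: tuple[float, float, float] = (20.0, 20.0, 30.0),
    noise_sigma: float = 0.04,
    seed: int = 0,
) -> tuple[SyntheticScene, np.ndarray, dict]:
    """Dendritic trunk(s) + thin spine neck + head — the attachment fixture.

    Returns (scene, head_position_um, info).  The neck runs from trunk 0's
    surface up to the head; with ``two_trunks`` a distractor trunk sits on
    the far side of the head.  info records which trunk the neck belongs to
    and the label values of the trunks.
    """
    vox = np.asarray(voxel_size_nm) / 1000.0
    extent = np.array([3.2, 3.2, 3.0])
    shape = tuple(int(np.ceil(e / v)) for e, v in zip(extent, vox))
    cfg = SceneConfig(shape=shape, voxel_size_nm=voxel_size_nm,
                      noise_sigma=noise_sigma, membrane_thickness=0.02)
    rng = np.random.default_rng(seed)

    pts, radii, ids = [], [], []

    def add_segment(p0, p1, r0, r1, nid, n=None):
        p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
        if n is None:
            n = max(int(np.linalg.norm(p1 - p0) / (vox.min() * 1.5)), 4)
        ts = np.linspace(0.0, 1.0, n)
        pts.append(p0[None] + ts[:, None] * (p1 - p0)[None])
        radii.append(r0 + ts * (r1 - r0))
        ids.append(np.full(n, nid, dtype=int))

    cx = extent[0] / 2.0
    z_trunk = 0.6
    # trunk 0 along y
    add_segment([cx, 0.1, z_trunk], [cx, extent[1] - 0.1, z_trunk],
                trunk_radius, trunk_radius, 0)
    z_head = z_trunk + trunk_radius + 0.9
    head = np.array([cx, extent[1] / 2.0, z_head])
    if two_trunks:
        # distractor trunk above the head, NOT connected to the neck
        add_segment([cx, 0.1, z_head + head_radius + 0.55],
                    [cx, extent[1] - 0.1, z_head + head_radius + 0.55],
                    trunk_radius, trunk_radius, 1)
    neck_id = 2 if two_trunks else 1
    # neck from trunk surface to head, plus the head bulge
    add_segment([cx, extent[1] / 2.0, z_trunk + 0.8 * trunk_radius], head,
                neck_radius, neck_radius, neck_id)
    add_segment(head, head + [0, 0, 1e-3], head_radius, head_radius, neck_id, n=4)

    pts = np.concatenate(pts)
    radii = np.concatenate(radii)
    ids = np.concatenate(ids)
    n_obj = neck_id + 1
    volume, masks, labels, shifted = _rasterize(cfg, rng, pts, radii, ids, n_obj)

    # trunk-only label volume for attachment targets, from trunk geometry
    # alone (instance labels assign trunk-interior voxels near the neck entry
    # to the neck, which is not what "reached the dendrite" means)
    trunk_sel = ids < neck_id if neck_id > 1 else ids == 0
    centers = [(np.arange(n) + 0.5) * v for n, v in zip(shape, vox)]
    grid = np.stack(np.meshgrid(*centers, indexing="ij"), axis=-1).reshape(-1, 3)
    ttree = cKDTree(pts[trunk_sel])
    dist, idx = ttree.query(grid)
    tid = ids[trunk_sel][idx]
    trad = radii[trunk_sel][idx]
    trunk_labels = np.where(dist < trad, tid + 1, 0).reshape(shape).astype(np.int32)

    # ground-truth framed curve of the neck path (head -> trunk) for oracles
    neck_nodes = np.linspace(head, [cx, extent[1] / 2.0, z_trunk], 12)
    neck_curve = fit_bspline(neck_nodes, degree=4)
    neck = Neurite(FramedCurve(neck_curve, grid_n=32),
                   np.array([0.0, neck_curve.length]),
                   np.array([neck_radius, neck_radius]))
    scene = SyntheticScene(volume, [neck], masks, labels, cfg, seed, shifted)
    info = {"true_trunk_label": 1, "trunk_labels": [1, 2] if two_trunks else [1],
            "neck_label": neck_id + 1,
            "dendrite_labels": VolumeGrid(trunk_labels, np.asarray(voxel_size_nm),
                                          np.zeros(3))}
    return scene, head, info


# ---------------------------------------------------------------------------
# Toy agglomeration
# ---------------------------------------------------------------------------


@dataclass
class SkeletonFragment:
    """A piece of reconstructed skeleton: an ordered chain of nodes."""

    fragment_id: int
    nodes: np.ndarray  # (n, 3) um
    source_neurites: tuple[int, ...]  # ground-truth neurite(s) contributing
    introduced_by_tracing: bool = False

    @property
    def path_length(self) -> float:
        if len(self.nodes) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.nodes, axis=0), axis=1).sum())


@dataclass
class ToyAgglomeration:
    """A constructively corrupted reconstruction with known error lists."""

    fragments: list[SkeletonFragment]
    truth_map: dict[int, tuple[int, ...]]
    induced_splits: list[tuple[int, float]]  # (neurite index, arc length of cut)
    induced_merges: list[tuple[int, int]]  # merged (neurite_a, neurite_b)
    merge_links: list[tuple[int, int]] = field(default_factory=list)
    tracing_links: list[tuple[int, int]] = field(default_factory=list)

    def components(self):
        """Connected components over fragments given merge + tracing links."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(f.fragment_id for f in self.fragments)
        g.add_edges_from(self.merge_links)
        g.add_edges_from(self.tracing_links)
        return list(nx.connected_components(g))


def make_toy_agglomeration(
    scene: SyntheticScene,
    split_rate: float,
    merge_rate: float,
    seed: int = 0,
    node_spacing: float = 0.05,
    min_segment: float | None = None,
    max_merges_per_fragment: int = 1,
) -> ToyAgglomeration:
    """Corrupt the ground truth with Poisson-placed splits and cross-neurite merges.

    Splits cut each skeleton at Poisson(split_rate per mm) arc lengths;
    merges link nearest-neighbour fragment pairs from distinct neurites at
    Poisson(merge_rate per mm of total path).  Every induced error is
    recorded so metric implementations can be validated exactly.
    """
    if split_rate < 0 or merge_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    fragments: list[SkeletonFragment] = []
    induced_splits: list[tuple[int, float]] = []
    frag_id = 0
    for ni, neurite in enumerate(scene.neurites):
        L = neurite.length
        n_cuts = rng.poisson(split_rate * L / 1000.0)
        cuts = np.sort(rng.uniform(0.0, L, size=n_cuts))
        # drop cuts that would create segments shorter than min_segment
        gap = min_segment if min_segment is not None else 2 * node_spacing
        keep = []
        prev = 0.0
        for c in cuts:
            if c - prev > gap and L - c > gap:
                keep.append(c)
                prev = c
        bounds = np.concatenate([[0.0], keep, [L]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            s = np.arange(a, b, node_spacing)
            if len(s) < 2:
                s = np.array([a, b])
            nodes = neurite.curve.position(s)
            fragments.append(SkeletonFragment(frag_id, nodes, (ni,)))
            frag_id += 1
        induced_splits.extend((ni, float(c)) for c in keep)

    # cross-neurite merges: link nearest fragment of a different neurite
    total_mm = scene.total_path_length_mm()
    n_merges = rng.poisson(merge_rate * total_mm)
    merge_links: list[tuple[int, int]] = []
    induced_merges: list[tuple[int, int]] = []
    if len({f.source_neurites[0] for f in fragments}) > 1:
        used: dict[int, int] = {}
        for _ in range(n_merges):
            candidates = [
                f for f in fragments
                if used.get(f.fragment_id, 0) < max_merges_per_fragment
            ]
            if not candidates:
                break
            fa = candidates[rng.integers(0, len(candidates))]
            others = [
                f for f in fragments
                if f.source_neurites[0] != fa.source_neurites[0]
                and used.get(f.fragment_id, 0) < max_merges_per_fragment
            ]
            best, best_d = None, np.inf
            for f in others:
                d, _ = cKDTree(f.nodes).query(fa.nodes)
                dm = float(d.min())
                if dm < best_d:
                    best, best_d = f, dm
            if best is None:
                continue
            merge_links.append((fa.fragment_id, best.fragment_id))
            induced_merges.append(
                (int(fa.source_neurites[0]), int(best.source_neurites[0]))
            )
            used[fa.fragment_id] = used.get(fa.fragment_id, 0) + 1
            used[best.fragment_id] = used.get(best.fragment_id, 0) + 1

    truth_map = {f.fragment_id: f.source_neurites for f in fragments}
    return ToyAgglomeration(fragments, truth_map, induced_splits, induced_merges, merge_links)
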