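"""File formats: SWC / NML skeletons, volume containers, training samples.

All public APIs use physical micrometres; voxel indices are 0-based with
voxel centres at (i + 0.5) * voxel_size.  SWC columns are the standard
(id, type, x, y, z, radius, parent); NML is the webKnossos-style XML with
<thing>/<nodes>/<edges> trees, mapped to/from SWC forests.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .sampling import VolumeGrid

__all__ = [
    "SkeletonNode",
    "SkeletonForest",
    "read_swc",
    "write_swc",
    "read_nml",
    "write_nml",
    "read_volume",
    "write_volume",
    "save_training_set",
    "load_training_set",
]


@dataclass
class SkeletonNode:
    node_id: int
    node_type: int
    position: np.ndarray  # um
    radius: float
    parent: int  # -1 for roots


@dataclass
class SkeletonForest:
    """A forest of skeleton trees (SWC semantics: each node has one parent)."""

    nodes: dict[int, SkeletonNode] = field(default_factory=dict)

    def roots(self) -> list[int]:
        return [nid for nid, n in self.nodes.items() if n.parent == -1]

    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for nid, n in self.nodes.items():
            if n.parent != -1:
                ch[n.parent].append(nid)
        return ch

    def trees(self) -> list[list[int]]:
        """Node ids grouped per tree, in preorder."""
        ch = self.children()
        out = []
        for r in sorted(self.roots()):
            stack, order = [r], []
            while stack:
                nid = stack.pop()
                order.append(nid)
                stack.extend(sorted(ch[nid], reverse=True))
            out.append(order)
        return out

    def validate(self) -> None:
        for nid, n in self.nodes.items():
            if n.parent != -1 and n.parent not in self.nodes:
                raise ValueError(f"node {nid} references missing parent {n.parent}")

    @classmethod
    def from_polyline(cls, points: np.ndarray, radius: float = 0.1,
                      start_id: int = 1, node_type: int = 2) -> "SkeletonForest":
        f = cls()
        prev = -1
        for i, p in enumerate(np.asarray(points, float)):
            nid = start_id + i
            f.nodes[nid] = SkeletonNode(nid, node_type, p, radius, prev)
            prev = nid
        return f


def read_swc(path) -> SkeletonForest:
    forest = SkeletonForest()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        try:
            nid, ntype = int(parts[0]), int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            parent = int(parts[6])
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: {e}") from None
        forest.nodes[nid] = SkeletonNode(nid, ntype, np.array([x, y, z]), r, parent)
    forest.validate()
    return forest


def write_swc(path, forest: SkeletonForest) -> None:
    lines = ["# id type x y z radius parent (um)"]
    for nid in sorted(forest.nodes):
        n = forest.nodes[nid]
        x, y, z = n.position
        lines.append(
            f"{nid} {n.node_type} {x:.6f} {y:.6f} {z:.6f} {n.radius:.6f} {n.parent}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_nml(path) -> SkeletonForest:
    """Read a webKnossos-style NML file into an SWC-style forest."""
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as e:
        raise ValueError(f"{path}: malformed XML: {e}") from None
    forest = SkeletonForest()
    edges = []
    for thing in root.iter("thing"):
        for node in thing.iter("node"):
            nid = int(node.attrib["id"])
            pos = np.array(
                [float(node.attrib["x"]), float(node.attrib["y"]), float(node.attrib["z"])]
            )
            r = float(node.attrib.get("radius", 0.1))
            forest.nodes[nid] = SkeletonNode(nid, 0, pos, r, -1)
        for e in thing.iter("edge"):
            edges.append((int(e.attrib["source"]), int(e.attrib["target"])))
    # orient edges into parent pointers (BFS per connected piece)
    adj: dict[int, list[int]] = {nid: [] for nid in forest.nodes}
    for a, b in edges:
        if a not in forest.nodes or b not in forest.nodes:
            raise ValueError(f"{path}: edge references missing node {a}-{b}")
        adj[a].append(b)
        adj[b].append(a)
    seen: set[int] = set()
    for start in sorted(forest.nodes):
        if start in seen:
            continue
        seen.add(start)
        queue = [start]
        while queue:
            cur = queue.pop(0)
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    forest.nodes[nb].parent = cur
                    queue.append(nb)
    return forest


def write_nml(path, forest: SkeletonForest, scale_nm=(1000.0, 1000.0, 1000.0)) -> None:
    """Write a forest as NML; one <thing> per tree, coordinates in um."""
    root = ET.Element("things")
    params = ET.SubElement(root, "parameters")
    ET.SubElement(
        params, "scale",
        x=str(scale_nm[0]), y=str(scale_nm[1]), z=str(scale_nm[2]),
    )
    for ti, tree in enumerate(forest.trees(), start=1):
        thing = ET.SubElement(root, "thing", id=str(ti), name=f"tree{ti}")
        nodes_el = ET.SubElement(thing, "nodes")
        edges_el = ET.SubElement(thing, "edges")
        for nid in tree:
            n = forest.nodes[nid]
            ET.SubElement(
                nodes_el, "node", id=str(nid),
                x=repr(float(n.position[0])), y=repr(float(n.position[1])),
                z=repr(float(n.position[2])), radius=repr(float(n.radius)),
            )
            if n.parent != -1:
                ET.SubElement(edges_el, "edge", source=str(n.parent), target=str(nid))
    ET.ElementTree(root).write(str(path), xml_declaration=True, encoding="unicode")


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------


def write_volume(path, volume: VolumeGrid, dataset: str = "raw") -> None:
    """Write a volume as HDF5 (.h5/.hdf5), zarr (.zarr) or raw + JSON sidecar."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            d = f.create_dataset(dataset, data=volume.intensities)
            d.attrs["voxel_size_nm"] = volume.voxel_size
            d.attrs["origin_um"] = volume.origin
    elif path.suffix == ".zarr":
        import zarr

        g = zarr.open_group(str(path), mode="w")
        arr = g.create_array(dataset, shape=volume.intensities.shape,
                             dtype=volume.intensities.dtype)
        arr[:] = volume.intensities
        arr.attrs["voxel_size_nm"] = [float(v) for v in volume.voxel_size]
        arr.attrs["origin_um"] = [float(v) for v in volume.origin]
    else:
        volume.intensities.astype(np.float32).tofile(path)
        sidecar = {
            "shape": list(volume.intensities.shape),
            "dtype": "float32",
            "voxel_size_nm": [float(v) for v in volume.voxel_size],
            "origin_um": [float(v) for v in volume.origin],
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_volume(path, dataset: str = "raw") -> VolumeGrid:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            d = f[dataset]
            return VolumeGrid(d[:], np.asarray(d.attrs["voxel_size_nm"]),
                              np.asarray(d.attrs["origin_um"]))
    if path.suffix == ".zarr":
        import zarr

        g = zarr.open_group(str(path), mode="r")
        arr = g[dataset]
        return VolumeGrid(arr[:], np.asarray(arr.attrs["voxel_size_nm"]),
                          np.asarray(arr.attrs["origin_um"]))
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    data = np.fromfile(path, dtype=sidecar["dtype"]).reshape(sidecar["shape"])
    return VolumeGrid(data, np.asarray(sidecar["voxel_size_nm"]),
                      np.asarray(sidecar["origin_um"]))


# ---------------------------------------------------------------------------
# Scene bundles
# ---------------------------------------------------------------------------


def save_scene_bundle(path, scene) -> None:
    """Write a synthetic scene as one HDF5 bundle.

    Layout: ``raw`` (volume + voxel/origin attrs), ``label`` (instance
    labels), ``masks/<i>`` (per-neurite boolean volumes), ``skeletons/<i>``
    (dense centerline nodes + radii, um), and the generation parameters as
    a JSON attribute.
    """
    from dataclasses import asdict

    with h5py.File(path, "w") as f:
        d = f.create_dataset("raw", data=scene.volume.intensities, compression="gzip")
        d.attrs["voxel_size_nm"] = scene.volume.voxel_size
        d.attrs["origin_um"] = scene.volume.origin
        f.create_dataset("label", data=scene.labels, compression="gzip")
        mg = f.create_group("masks")
        for i, m in scene.masks.items():
            mg.create_dataset(str(i), data=m, compression="gzip")
        sg = f.create_group("skeletons")
        for i, n in enumerate(scene.neurites):
            s = np.arange(0.0, n.length, 0.05)
            pts = n.curve.position(s)
            radii = n.radius_at(s)
            sg.create_dataset(str(i), data=np.column_stack([pts, radii]))
        f.attrs["params"] = json.dumps(asdict(scene.config))
        f.attrs["seed"] = scene.seed


def load_scene_bundle(path):
    """Read back the volume, labels, masks and skeletons of a scene bundle."""
    with h5py.File(path, "r") as f:
        volume = VolumeGrid(f["raw"][:], np.asarray(f["raw"].attrs["voxel_size_nm"]),
                            np.asarray(f["raw"].attrs["origin_um"]))
        labels = f["label"][:]
        masks = {int(k): v[:].astype(bool) for k, v in f["masks"].items()}
        skeletons = {int(k): v[:] for k, v in f["skeletons"].items()}
        params = json.loads(f.attrs["params"])
        seed = int(f.attrs["seed"])
    return volume, labels, masks, skeletons, params, seed


# ---------------------------------------------------------------------------
# Training samples
# ---------------------------------------------------------------------------


def save_training_set(path, patches: np.ndarray, states: np.ndarray,
                      targets: np.ndarray, meta: dict | None = None) -> None:
    """Serialize training samples: patches, 12-float states, 3-float targets."""
    with h5py.File(path, "w") as f:
        f.create_dataset("patches", data=patches.astype(np.float32), compression="gzip")
        f.create_dataset("states", data=states.astype(np.float64))
        f.create_dataset("targets", data=targets.astype(np.float64))
        if meta:
            f.attrs["meta"] = json.dumps(meta)


def load_training_set(path):
    with h5py.File(path, "r") as f:
        patches = f["patches"][:]
        states = f["states"][:]
        targets = f["targets"][:]
        meta = json.loads(f.attrs["meta"]) if "meta" in f.attrs else {}
    return patches, states, targets, meta
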