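"""Neurite-aligned patch extraction from anisotropic EM volumes.

The steering network sees the volume through a 96 x 96 x 16 block of
trilinearly interpolated intensities whose first two axes span the plane
normal to the flight direction (size ``p``, default 1 um) and whose third
axis runs along the tangent.  The agent's position is placed at the centre
of the fourth z-plane, so the field of view is asymmetric: more context
lies ahead of the agent than behind it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import FrameState

__all__ = ["VolumeGrid", "PatchGeometry", "AlignedPatch", "trilinear", "extract_aligned_patch"]


@dataclass
class VolumeGrid:
    """A 3D scalar grid in physical coordinates.

    ``intensities[i, j, k]`` is the sample at physical position
    origin + (i+0.5, j+0.5, k+0.5) * voxel_size, i.e. voxel centres sit at
    half-integer multiples of the (possibly anisotropic) voxel size.
    voxel_size is in nm, origin and all query positions in um.
    """

    intensities: np.ndarray
    voxel_size: np.ndarray  # nm, shape (3,)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))  # um

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be positive componentwise")

    @property
    def voxel_size_um(self) -> np.ndarray:
        return self.voxel_size / 1000.0

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.intensities.shape) * self.voxel_size_um

    def world_to_index(self, x: np.ndarray) -> np.ndarray:
        """Physical um -> fractional voxel index (voxel centres at integers)."""
        return (np.asarray(x, dtype=float) - self.origin) / self.voxel_size_um - 0.5

    def contains(self, x: np.ndarray) -> np.ndarray:
        idx = self.world_to_index(np.atleast_2d(x))
        hi = np.asarray(self.intensities.shape) - 0.5
        ok = np.all((idx >= -0.5) & (idx <= hi), axis=1)
        return ok if np.asarray(x).ndim > 1 else bool(ok[0])


def trilinear(volume: VolumeGrid, x, pad_value: float | None = None):
    """Trilinear interpolation at physical positions x (um).

    Out-of-bounds samples return ``pad_value`` (volume mean by default).
    Returns (values, in_bounds_mask); scalars for a single query point.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    pts = np.atleast_2d(x)
    idx = volume.world_to_index(pts)
    if pad_value is None:
        pad_value = float(volume.intensities.mean())
    hi = np.asarray(volume.intensities.shape) - 1.0
    inb = np.all((idx >= 0.0) & (idx <= hi), axis=1)
    # edge samples within half a voxel of the boundary are clamped (still
    # "in bounds" physically but outside the centre lattice)
    phys_ok = np.all((idx >= -0.5) & (idx <= hi + 0.5), axis=1)
    data = volume.intensities
    if data.dtype == bool:
        data = data.astype(np.float32)
    vals = ndimage.map_coordinates(data, idx.T, order=1, mode="nearest").astype(float)
    vals = np.where(phys_ok, vals, pad_value)
    if single:
        return float(vals[0]), bool(phys_ok[0])
    return vals, phys_ok


@dataclass(frozen=True)
class PatchGeometry:
    """Sampling geometry of the aligned patch.

    shape : (in-plane, in-plane, along-tangent) sample counts.
    p : physical in-plane size (um); sample spacing is p / shape[0].
    z_spacing : plane spacing along the tangent (um).
    anchor_plane : 0-based index of the plane containing the agent position.
    """

    shape: tuple[int, int, int] = (96, 96, 16)
    p: float = 1.0
    z_spacing: float = 0.7 / 16.0
    anchor_plane: int = 3

    @property
    def z_extent(self) -> float:
        return self.shape[2] * self.z_spacing


# spine necks are much thinner than axons; a separate tighter geometry is
# used for the spine-attachment model
SPINE_GEOMETRY = PatchGeometry(p=0.5, z_spacing=0.025)


@dataclass
class AlignedPatch:
    """Normalized, neurite-aligned intensity block (the CNN input)."""

    intensities: np.ndarray
    geometry: PatchGeometry
    oob_fraction: float = 0.0
    degenerate: bool = False

    @property
    def left_volume(self) -> bool:
        return self.oob_fraction > 0.5


def _sample_offsets(geom: PatchGeometry) -> np.ndarray:
    na, nb, nc = geom.shape
    a = (np.arange(na) - (na - 1) / 2.0) * (geom.p / na)
    b = (np.arange(nb) - (nb - 1) / 2.0) * (geom.p / na)
    c = (np.arange(nc) - geom.anchor_plane) * geom.z_spacing
    return a, b, c


def extract_aligned_patch(
    volume: VolumeGrid,
    state: FrameState,
    geom: PatchGeometry = PatchGeometry(),
    pad_value: float | None = None,
) -> AlignedPatch:
    """Extract the frame-aligned patch around the agent's pose.

    Sample (a, b, c) maps to
        position + (a - (A-1)/2) * p/A * n1 + (b - (B-1)/2) * p/A * n2
                 + (c - anchor) * z_spacing * t,
    evaluated by trilinear interpolation, then normalized to zero mean and
    unit variance per patch.
    """
    a, b, c = _sample_offsets(geom)
    offsets = (
        a[:, None, None, None] * state.n1[None, None, None, :]
        + b[None, :, None, None] * state.n2[None, None, None, :]
        + c[None, None, :, None] * state.t[None, None, None, :]
    )
    pts = state.position[None, None, None, :] + offsets
    vals, ok = trilinear(volume, pts.reshape(-1, 3), pad_value=pad_value)
    vals = vals.reshape(geom.shape)
    oob = 1.0 - float(ok.mean())
    mean = float(vals.mean())
    std = float(vals.std())
    degenerate = std < 1e-6
    vals = (vals - mean) / (std + 1e-6)
    return AlignedPatch(vals.astype(np.float32), geom, oob, degenerate)
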