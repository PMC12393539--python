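"""Mother-centriole reference frame, cylindrical coordinates and meshing.

The analysis measures everything in a cylinder-aligned frame: the origin sits
at the centre of the MC distal face, the axis points distally (towards the
appendages and any growing cilium), and an arbitrary-but-fixed reference
direction perpendicular to the axis defines azimuth theta = 0. Azimuths are
right-handed about the axis and reported in degrees in [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .volume_io import LabelVolume

__all__ = [
    "CentrioleFrame",
    "DATip",
    "fit_centriole_frame",
    "to_cylindrical",
    "from_cylindrical",
    "detect_da_tips",
    "extract_surface_mesh",
    "point_to_triangles_distance",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class CentrioleFrame:
    """Cylindrical reference frame anchored on the MC distal end.

    ``origin_nm`` is the centre of the distal face (world nm), ``axis`` the
    distal-pointing unit vector, ``reference`` the unit vector defining
    theta = 0 (perpendicular to ``axis``).
    """

    origin_nm: np.ndarray
    axis: np.ndarray
    reference: np.ndarray
    mc_radius_nm: float
    mc_length_nm: float

    def __post_init__(self) -> None:
        self.origin_nm = np.asarray(self.origin_nm, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if abs(np.linalg.norm(self.axis) - 1) > 1e-9:
            raise ValueError("axis must be a unit vector")
        if abs(np.linalg.norm(self.reference) - 1) > 1e-9:
            raise ValueError("reference must be a unit vector")
        if abs(float(self.axis @ self.reference)) > 1e-9:
            raise ValueError("reference must be orthogonal to axis")
        if self.mc_radius_nm <= 0 or self.mc_length_nm <= 0:
            raise ValueError("mc_radius_nm and mc_length_nm must be positive")

    @property
    def binormal(self) -> np.ndarray:
        """Third right-handed basis vector (axis x reference completes it)."""
        return np.cross(self.axis, self.reference)

    def to_dict(self) -> dict:
        return {
            "origin_nm": self.origin_nm.tolist(),
            "axis": self.axis.tolist(),
            "reference": self.reference.tolist(),
            "mc_radius_nm": float(self.mc_radius_nm),
            "mc_length_nm": float(self.mc_length_nm),
        }


@dataclass
class DATip:
    """Distal-appendage tip: the docking reference point of one appendage."""

    da_id: int
    tip_point_nm: np.ndarray
    theta_deg: float
    radial_nm: float
    z_nm: float = field(default=0.0)


def _orthogonal_reference(axis: np.ndarray) -> np.ndarray:
    """World +x projected off-axis; +y fallback when near-parallel."""
    for seed in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])):
        ref = seed - (seed @ axis) * axis
        norm = np.linalg.norm(ref)
        if norm > 1e-3:
            return ref / norm
    raise RuntimeError("could not build a reference direction")  # pragma: no cover


def fit_centriole_frame(volume: LabelVolume, min_mc_voxels: int = 50) -> CentrioleFrame:
    """Fit the MC frame from the ``mc_body`` and ``da`` labels.

    The axis is the dominant principal direction of the MC voxel centres,
    oriented so the DA centroid projects towards the positive (distal) end.
    The origin combines the maximal axial coordinate over MC voxel centres
    (the distal face) with the perpendicular centroid of the distal-most 10%
    slab (the lateral centre of the face).
    """
    mc_idx = np.argwhere(volume.mask("mc_body"))
    if len(mc_idx) < min_mc_voxels:
        raise ValueError(f"need >= {min_mc_voxels} mc_body voxels, found {len(mc_idx)}")
    da_idx = np.argwhere(volume.mask("da"))
    if len(da_idx) == 0:
        raise ValueError(
            "no 'da' label present: the distal end cannot be inferred; "
            "provide a frame explicitly"
        )
    pts = volume.world_coords(mc_idx)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[2] < 1.2 * evals[1]:
        raise ValueError(
            "mc_body has no dominant axis (eigenvalue ratio "
            f"{evals[2] / max(evals[1], 1e-12):.2f} < 1.2)"
        )
    axis = evecs[:, 2]
    da_centroid = volume.world_coords(da_idx).mean(axis=0)
    if (da_centroid - centroid) @ axis < 0:
        axis = -axis

    t = centered @ axis
    t_max, t_min = float(t.max()), float(t.min())
    slab = t >= t_max - 0.1 * (t_max - t_min)
    perp = centered[slab] - np.outer(t[slab], axis)
    origin = centroid + perp.mean(axis=0) + t_max * axis

    radial = np.linalg.norm(centered - np.outer(t, axis), axis=1)
    radius = float(radial.max()) + volume.voxel_size_nm / 2.0
    length = t_max - t_min + volume.voxel_size_nm

    return CentrioleFrame(
        origin_nm=origin,
        axis=axis,
        reference=_orthogonal_reference(axis),
        mc_radius_nm=radius,
        mc_length_nm=length,
    )


def to_cylindrical(points_nm: np.ndarray, frame: CentrioleFrame) -> np.ndarray:
    """World points -> ``(r_nm, theta_deg, z_nm)`` in the MC frame.

    theta is measured from ``frame.reference``, right-handed about the axis,
    in [0, 360); a point exactly on the axis gets theta = 0 by convention.
    """
    pts = np.atleast_2d(np.asarray(points_nm, dtype=float)) - frame.origin_nm
    z = pts @ frame.axis
    x = pts @ frame.reference
    y = pts @ frame.binormal
    r = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    theta[r == 0] = 0.0
    return np.column_stack([r, theta, z])


def from_cylindrical(cyl: np.ndarray, frame: CentrioleFrame) -> np.ndarray:
    """Inverse of :func:`to_cylindrical`."""
    cyl = np.atleast_2d(np.asarray(cyl, dtype=float))
    r, theta, z = cyl[:, 0], np.radians(cyl[:, 1]), cyl[:, 2]
    return (
        frame.origin_nm
        + np.outer(r * np.cos(theta), frame.reference)
        + np.outer(r * np.sin(theta), frame.binormal)
        + np.outer(z, frame.axis)
    )


def detect_da_tips(volume: LabelVolume, frame: CentrioleFrame) -> list[DATip]:
    """One tip per 26-connected DA component: the voxel centre farthest from
    the MC axis (ties: larger z, then lexicographic index). Sorted by theta."""
    mask = volume.mask("da")
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        raise ValueError("no distal-appendage components found")
    tips: list[DATip] = []
    for comp in range(1, n + 1):
        idx = np.argwhere(labels == comp)
        pts = volume.world_coords(idx)
        cyl = to_cylindrical(pts, frame)
        # lexicographic ties resolved by argwhere's row order
        order = np.lexsort((np.arange(len(idx))[::-1], cyl[:, 2], cyl[:, 0]))
        best = order[-1]
        tips.append(
            DATip(
                da_id=0,
                tip_point_nm=pts[best],
                theta_deg=float(cyl[best, 1]),
                radial_nm=float(cyl[best, 0]),
                z_nm=float(cyl[best, 2]),
            )
        )
    tips.sort(key=lambda tip: tip.theta_deg)
    for i, tip in enumerate(tips):
        tip.da_id = i
    return tips


def extract_surface_mesh(
    volume: LabelVolume | None = None,
    label: int | None = None,
    mask: np.ndarray | None = None,
    voxel_size_nm: float | None = None,
    origin_nm: np.ndarray | None = None,
):
    """Triangulated 0.5-level isosurface of a binary mask, vertices in world nm.

    Either pass ``volume`` + ``label`` or a boolean ``mask`` + ``voxel_size_nm``.
    The mask is zero-padded so surfaces touching the array border close.
    Returns ``(vertices (n,3) xyz nm, faces (m,3))``.
    """
    if mask is None:
        if volume is None or label is None:
            raise ValueError("pass either (volume, label) or (mask, voxel_size_nm)")
        mask = volume.data == label
        voxel_size_nm = volume.voxel_size_nm
    if voxel_size_nm is None:
        raise ValueError("voxel_size_nm required with an explicit mask")
    if not mask.any():
        raise ValueError("empty mask has no surface")
    padded = np.pad(mask.astype(np.uint8), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = (verts - 1.0) * voxel_size_nm  # remove padding offset; (z,y,x)
    verts = verts[:, ::-1]  # -> (x, y, z) world nm
    if origin_nm is not None:
        verts = verts + np.asarray(origin_nm, dtype=float)
    return verts, faces


def point_to_triangles_distance(point: np.ndarray, vertices: np.ndarray, faces: np.ndarray) -> float:
    """Exact minimum Euclidean distance from a point to a triangle soup.

    Vectorized closest-point computation: the unclamped barycentric interior
    point where valid, plus the three clamped edge projections.
    """
    p = np.asarray(point, dtype=float)
    tri = vertices[faces]
    B, E0, E1 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    D = B - p
    a = np.einsum("ij,ij->i", E0, E0)
    b = np.einsum("ij,ij->i", E0, E1)
    c = np.einsum("ij,ij->i", E1, E1)
    d = np.einsum("ij,ij->i", E0, D)
    e = np.einsum("ij,ij->i", E1, D)
    det = np.maximum(a * c - b * b, 1e-300)
    s = b * e - c * d
    t = b * d - a * e
    inside = (s >= 0) & (t >= 0) & (s + t <= det)
    dmin = np.full(len(tri), np.inf)
    if inside.any():
        q = B[inside] + (s[inside] / det[inside])[:, None] * E0[inside]
        q += (t[inside] / det[inside])[:, None] * E1[inside]
        dmin[inside] = np.linalg.norm(q - p, axis=1)

    def _edge(P0, Ev):
        denom = np.maximum(np.einsum("ij,ij->i", Ev, Ev), 1e-300)
        tt = np.clip(-np.einsum("ij,ij->i", P0 - p, Ev) / denom, 0.0, 1.0)
        return np.linalg.norm(P0 + tt[:, None] * Ev - p, axis=1)

    dmin = np.minimum(dmin, _edge(B, E0))
    dmin = np.minimum(dmin, _edge(B, E1))
    dmin = np.minimum(dmin, _edge(tri[:, 1], tri[:, 2] - tri[:, 1]))
    return float(dmin.min())
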