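"""Synthetic voxel phantoms of the mother centriole and its docked membranes.

Each phantom is a voxelized scene built from analytic primitives — an MC
cylinder (~300 nm diameter x 500 nm height), nine radial distal appendages,
and membrane structures rendered as thin shells: spheres (distal-appendage
vesicles), partial torus arcs (C-shaped ciliary vesicles with a prescribed
angular gap), closed toroids, distal caps (ciliary vesicles), axial tubes
(cilia) and planar sheets (plasma membrane). Every quantity the analysis
later measures — gap angle, tip-to-membrane minimal distance, surface area,
stage — is also computed in closed form from the generating parameters, so
the voxel pipeline can be validated against exact ground truth.

Membranes are rendered as shells whose half-width is
``max(voxel/2, bilayer/2)`` with a 5 nm default bilayer: a real membrane is
thinner than a 9 nm voxel, so its segmentation is one voxel thick at the
study resolution and proportionally thicker at finer sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .classify import STAGES
from .geometry import CentrioleFrame
from .volume_io import DEFAULT_LABEL_MAP, LabelVolume

__all__ = [
    "MembranePrimitive",
    "PlasmaMembraneSpec",
    "PhantomSpec",
    "GroundTruth",
    "build_phantom",
    "sample_cohort",
    "random_rotation",
    "random_stage_spec",
    "STAGES",
]

DOCK_THRESHOLD_NM = 30.0  # membrane docked if <= 30 nm from a DA distal end


@dataclass
class MembranePrimitive:
    """One analytic membrane structure, in MC-frame coordinates (nm).

    kind-specific fields:

    * ``sphere``: ``center`` (x, y, z) and ``radius_nm``;
    * ``arc_torus`` / ``toroid``: ``major_radius_nm`` R, ``tube_radius_nm`` r,
      ``arc_start_deg`` and ``arc_span_deg`` (toroid: span 360), ``z_offset_nm``;
    * ``cap``: sphere of ``radius_nm`` centred on the frame origin, kept where
      z >= ``standoff_nm`` (a dome over the distal end);
    * ``axial_tube``: open cylinder of ``radius_nm`` about the axis from
      ``z_offset_nm`` to ``z_offset_nm + length_nm``;
    * ``sheet``: disk of ``radius_nm`` at height ``z_offset_nm``, normal tilted
      ``tilt_deg`` about the binormal.
    """

    kind: str
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius_nm: float = 0.0
    major_radius_nm: float = 0.0
    tube_radius_nm: float = 0.0
    arc_start_deg: float = 0.0
    arc_span_deg: float = 360.0
    z_offset_nm: float = 0.0
    length_nm: float = 0.0
    standoff_nm: float = 0.0
    tilt_deg: float = 0.0
    filled: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "arc_torus", "toroid", "cap", "axial_tube", "sheet"):
            raise ValueError(f"unknown membrane kind {self.kind!r}")
        if self.kind == "arc_torus" and not (0 < self.arc_span_deg < 360):
            raise ValueError("arc_torus span must lie in (0, 360)")
        if self.kind == "toroid":
            self.arc_span_deg = 360.0
        if self.kind in ("arc_torus", "toroid"):
            if not 0 < self.tube_radius_nm < self.major_radius_nm:
                raise ValueError("torus requires 0 < tube radius < major radius")
            if tuple(self.center) != (0.0, 0.0, 0.0):
                raise ValueError(
                    "torus primitives are centred on the MC axis; use z_offset_nm"
                )

    # -- analytic ground truth -------------------------------------------

    def analytic_area_nm2(self) -> float:
        if self.kind == "sphere":
            return 4.0 * np.pi * self.radius_nm**2
        if self.kind in ("arc_torus", "toroid"):
            full = 4.0 * np.pi**2 * self.major_radius_nm * self.tube_radius_nm
            return full * self.arc_span_deg / 360.0
        if self.kind == "cap":
            return 2.0 * np.pi * self.radius_nm * (self.radius_nm - self.standoff_nm)
        if self.kind == "axial_tube":
            return 2.0 * np.pi * self.radius_nm * self.length_nm
        if self.kind == "sheet":
            return np.pi * self.radius_nm**2
        raise AssertionError(self.kind)

    def true_gap_deg(self) -> float | None:
        if self.kind == "arc_torus":
            return 360.0 - self.arc_span_deg
        if self.kind == "toroid":
            return 0.0
        return None

    def min_distance_to(self, point: np.ndarray) -> float:
        """Exact distance from a frame-coordinate point to the mid-surface."""
        p = np.asarray(point, dtype=float)
        if self.kind == "sphere":
            return abs(np.linalg.norm(p - np.asarray(self.center)) - self.radius_nm)
        if self.kind in ("arc_torus", "toroid"):
            rho = np.hypot(p[0], p[1])
            theta = np.degrees(np.arctan2(p[1], p[0])) % 360.0
            rel = (theta - self.arc_start_deg) % 360.0
            d_sector = np.inf
            if rel <= self.arc_span_deg or self.kind == "toroid":
                d_sector = abs(
                    np.hypot(rho - self.major_radius_nm, p[2] - self.z_offset_nm)
                    - self.tube_radius_nm
                )
            if self.kind == "toroid":
                return float(d_sector)
            ends = []
            for phi_deg in (self.arc_start_deg, self.arc_start_deg + self.arc_span_deg):
                phi = np.radians(phi_deg)
                c = np.array(
                    [
                        self.major_radius_nm * np.cos(phi),
                        self.major_radius_nm * np.sin(phi),
                        self.z_offset_nm,
                    ]
                )
                n = np.array([-np.sin(phi), np.cos(phi), 0.0])  # arc tangent
                ends.append(_point_to_circle(p, c, n, self.tube_radius_nm))
            return float(min(d_sector, *ends))
        if self.kind == "cap":
            norm = np.linalg.norm(p)
            if norm > 0 and self.radius_nm * p[2] / norm >= self.standoff_nm:
                return abs(norm - self.radius_nm)
            rim_r = float(np.sqrt(max(self.radius_nm**2 - self.standoff_nm**2, 0.0)))
            return _point_to_circle(
                p, np.array([0.0, 0.0, self.standoff_nm]), np.array([0.0, 0.0, 1.0]), rim_r
            )
        if self.kind == "axial_tube":
            rho = np.hypot(p[0], p[1])
            z0, z1 = self.z_offset_nm, self.z_offset_nm + self.length_nm
            if z0 <= p[2] <= z1:
                return abs(rho - self.radius_nm)
            dz = min(abs(p[2] - z0), abs(p[2] - z1))
            return float(np.hypot(rho - self.radius_nm, dz))
        if self.kind == "sheet":
            tilt = np.radians(self.tilt_deg)
            n = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
            e1 = np.array([np.cos(tilt), 0.0, -np.sin(tilt)])
            e2 = np.array([0.0, 1.0, 0.0])
            rel = p - np.array([0.0, 0.0, self.z_offset_nm])
            h = rel @ n
            u, v = rel @ e1, rel @ e2
            ruv = np.hypot(u, v)
            if ruv <= self.radius_nm:
                return abs(float(h))
            return float(np.hypot(ruv - self.radius_nm, h))
        raise AssertionError(self.kind)


def _point_to_circle(p: np.ndarray, center: np.ndarray, normal: np.ndarray, radius: float) -> float:
    d = p - center
    h = d @ normal
    d_plane = d - h * normal
    norm = np.linalg.norm(d_plane)
    if norm < 1e-12:
        return float(np.hypot(radius, h))
    return float(np.hypot(norm - radius, h))


@dataclass
class PlasmaMembraneSpec:
    """Plasma membrane: a tilted plane above (or cutting) the distal region."""

    offset_nm: float = 100.0  # plane height on the axis, above the distal end
    tilt_deg: float = 0.0  # tilt about the binormal; 0 = perpendicular to axis

    def normal(self) -> np.ndarray:
        tilt = np.radians(self.tilt_deg)
        return np.array([np.sin(tilt), 0.0, np.cos(tilt)])

    def distance_to(self, point: np.ndarray) -> float:
        p0 = np.array([0.0, 0.0, self.offset_nm])
        return abs(float((np.asarray(point, float) - p0) @ self.normal()))


@dataclass
class PhantomSpec:
    """Generating parameters for one phantom cell.

    Defaults reproduce the study conditions: a 300 nm x 500 nm MC with nine
    distal appendages, voxelized isotropically at 9 nm.
    """

    mc_diameter_nm: float = 300.0
    mc_length_nm: float = 500.0
    n_da: int = 9
    da_length_nm: float = 75.0
    da_pin_radius_nm: float = 10.0
    da_tip_offset_nm: float = 50.0
    da_theta0_deg: float = 0.0
    voxel_size_nm: float = 9.0
    bilayer_thickness_nm: float = 5.0
    membranes: list[MembranePrimitive] = field(default_factory=list)
    pm: PlasmaMembraneSpec | None = None
    rotation: np.ndarray | None = None  # 3x3 frame->world; None = identity
    margin_voxels: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mc_diameter_nm, self.mc_length_nm, self.voxel_size_nm) <= 0:
            raise ValueError("MC dimensions and voxel size must be positive")
        if self.n_da < 1:
            raise ValueError("need at least one distal appendage")

    @property
    def mc_radius_nm(self) -> float:
        return self.mc_diameter_nm / 2.0

    @property
    def da_tip_radius_nm(self) -> float:
        return self.mc_radius_nm + self.da_length_nm

    @property
    def shell_half_width_nm(self) -> float:
        return max(self.voxel_size_nm / 2.0, self.bilayer_thickness_nm / 2.0)

    def da_tip_points(self) -> np.ndarray:
        """Exact DA tip points in frame coordinates, one row per appendage."""
        theta = np.radians(self.da_theta0_deg + 360.0 * np.arange(self.n_da) / self.n_da)
        r = self.da_tip_radius_nm
        return np.column_stack(
            [r * np.cos(theta), r * np.sin(theta), np.full(self.n_da, -self.da_tip_offset_nm)]
        )


@dataclass
class GroundTruth:
    """Closed-form truth for every quantity the analysis measures."""

    frame: CentrioleFrame
    da_tip_points_nm: np.ndarray  # world coordinates, (n_da, 3)
    da_tip_theta_deg: np.ndarray
    true_gap_deg: list[float | None]
    analytic_surface_area_nm2: list[float]
    true_min_distance_nm: np.ndarray  # (n_membranes, n_da)
    docked: list[bool]
    true_stage: str
    pm_tip_distance_nm: np.ndarray | None = None


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det fixed)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] = -q[:, 2]
    return q


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------

def _frame_bounds(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned bounding box of all primitives in frame coordinates."""
    tip_r = spec.da_tip_radius_nm
    lo = np.array([-tip_r, -tip_r, -spec.mc_length_nm])
    hi = np.array([tip_r, tip_r, 0.0])
    pad = spec.shell_half_width_nm + 2 * spec.voxel_size_nm
    for m in spec.membranes:
        if m.kind == "sphere":
            c, r = np.asarray(m.center), m.radius_nm + pad
            lo = np.minimum(lo, c - r)
            hi = np.maximum(hi, c + r)
        elif m.kind in ("arc_torus", "toroid"):
            ext = m.major_radius_nm + m.tube_radius_nm + pad
            lo = np.minimum(lo, [-ext, -ext, m.z_offset_nm - m.tube_radius_nm - pad])
            hi = np.maximum(hi, [ext, ext, m.z_offset_nm + m.tube_radius_nm + pad])
        elif m.kind == "cap":
            r = m.radius_nm + pad
            lo = np.minimum(lo, [-r, -r, m.standoff_nm - pad])
            hi = np.maximum(hi, [r, r, r])
        elif m.kind == "axial_tube":
            r = m.radius_nm + pad
            lo = np.minimum(lo, [-r, -r, m.z_offset_nm - pad])
            hi = np.maximum(hi, [r, r, m.z_offset_nm + m.length_nm + pad])
        elif m.kind == "sheet":
            r = m.radius_nm + pad
            lo = np.minimum(lo, [-r, -r, m.z_offset_nm - r])
            hi = np.maximum(hi, [r, r, m.z_offset_nm + r])
    if spec.pm is not None:
        hi[2] = max(hi[2], spec.pm.offset_nm + abs(np.sin(np.radians(spec.pm.tilt_deg))) * max(
            hi[0] - lo[0], hi[1] - lo[1]
        ) + pad)
    return lo, hi


def _radial_pin_mask(
    fx: np.ndarray,
    fy: np.ndarray,
    fz: np.ndarray,
    theta: float,
    rho0: float,
    rho1: float,
    pin_radius: float,
    z_da: float,
) -> np.ndarray:
    """Flat-ended radial cylinder at azimuth ``theta``, spanning radii
    ``[rho0, rho1]`` at height ``z_da`` — the distal face sits exactly at the
    analytic tip radius."""
    s = fx * np.cos(theta) + fy * np.sin(theta)
    lateral = np.hypot(-fx * np.sin(theta) + fy * np.cos(theta), fz - z_da)
    return (s >= rho0) & (s <= rho1) & (lateral <= pin_radius)


def build_phantom(spec: PhantomSpec) -> tuple[LabelVolume, GroundTruth]:
    """Voxelize a phantom and return it with its analytic ground truth.

    Labels follow :data:`ciliomorph.volume_io.DEFAULT_LABEL_MAP` with total
    precedence mc_body > da > membrane > pm; membranes overlapping the MC body
    are an error, membranes touching an appendage cede those voxels to it.
    """
    v = spec.voxel_size_nm
    rot = np.eye(3) if spec.rotation is None else np.asarray(spec.rotation, dtype=float)
    lo, hi = _frame_bounds(spec)
    corners = np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    wcorners = corners @ rot.T
    margin = spec.margin_voxels * v
    world_min = wcorners.min(axis=0) - margin
    # frame origin placed on the voxel grid so that axis-aligned phantoms have
    # exactly representable tip points
    origin_world = np.ceil(-world_min / v) * v
    world_max = wcorners.max(axis=0) + margin + origin_world
    shape_xyz = np.ceil(world_max / v).astype(int) + 1

    ix = np.arange(shape_xyz[0]) * v
    iy = np.arange(shape_xyz[1]) * v
    iz = np.arange(shape_xyz[2]) * v
    # voxel-centre world coordinates, evaluated in frame coordinates
    X, Y, Z = np.meshgrid(ix, iy, iz, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]) - origin_world
    fpts = pts @ rot  # world -> frame (rot columns are frame basis in world)
    fx, fy, fz = fpts[:, 0], fpts[:, 1], fpts[:, 2]
    rho = np.hypot(fx, fy)

    h = spec.shell_half_width_nm
    labels = np.zeros(len(fpts), dtype=np.uint8)

    if spec.pm is not None:
        n = spec.pm.normal()
        signed = fpts @ n - spec.pm.offset_nm * n[2]
        labels[np.abs(signed) <= h] = DEFAULT_LABEL_MAP["pm"]

    mem_mask = np.zeros(len(fpts), dtype=bool)
    for m in spec.membranes:
        mem_mask |= _primitive_mask(m, fpts, fx, fy, fz, rho, h)
    labels[mem_mask] = DEFAULT_LABEL_MAP["membrane"]

    theta_k = np.radians(spec.da_theta0_deg + 360.0 * np.arange(spec.n_da) / spec.n_da)
    z_da = -spec.da_tip_offset_nm
    for th in theta_k:
        pin = _radial_pin_mask(
            fx,
            fy,
            fz,
            th,
            max(spec.mc_radius_nm - 2 * v, 0.0),
            spec.da_tip_radius_nm,
            spec.da_pin_radius_nm,
            z_da,
        )
        labels[pin] = DEFAULT_LABEL_MAP["da"]

    mc_mask = (rho <= spec.mc_radius_nm) & (fz >= -spec.mc_length_nm) & (fz <= 0.0)
    if (mem_mask & mc_mask).any():
        raise ValueError("membrane primitive overlaps the MC body")
    labels[mc_mask] = DEFAULT_LABEL_MAP["mc_body"]

    grid = labels.reshape(shape_xyz[0], shape_xyz[1], shape_xyz[2]).transpose(2, 1, 0)
    volume = LabelVolume(data=np.ascontiguousarray(grid), voxel_size_nm=v)

    truth = _ground_truth(spec, rot, origin_world)
    return volume, truth


def _primitive_mask(m, fpts, fx, fy, fz, rho, h):
    if m.kind == "sphere":
        d = np.linalg.norm(fpts - np.asarray(m.center, dtype=float), axis=1)
        return d <= m.radius_nm + h if m.filled else np.abs(d - m.radius_nm) <= h
    if m.kind in ("arc_torus", "toroid"):
        d = np.hypot(rho - m.major_radius_nm, fz - m.z_offset_nm)
        band = d <= m.tube_radius_nm + h if m.filled else np.abs(d - m.tube_radius_nm) <= h
        if m.kind == "toroid":
            return band
        theta = np.degrees(np.arctan2(fy, fx)) % 360.0
        rel = (theta - m.arc_start_deg) % 360.0
        return band & (rel <= m.arc_span_deg)
    if m.kind == "cap":
        d = np.linalg.norm(fpts, axis=1)
        band = d <= m.radius_nm + h if m.filled else np.abs(d - m.radius_nm) <= h
        return band & (fz >= m.standoff_nm)
    if m.kind == "axial_tube":
        band = np.abs(rho - m.radius_nm) <= h
        return band & (fz >= m.z_offset_nm) & (fz <= m.z_offset_nm + m.length_nm)
    if m.kind == "sheet":
        tilt = np.radians(m.tilt_deg)
        n = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
        e1 = np.array([np.cos(tilt), 0.0, -np.sin(tilt)])
        rel = fpts - np.array([0.0, 0.0, m.z_offset_nm])
        height = rel @ n
        ruv = np.hypot(rel @ e1, fy)
        return (np.abs(height) <= h) & (ruv <= m.radius_nm)
    raise AssertionError(m.kind)


def _ground_truth(spec: PhantomSpec, rot: np.ndarray, origin_world: np.ndarray) -> GroundTruth:
    axis_w = rot @ np.array([0.0, 0.0, 1.0])
    ref_w = rot @ np.array([1.0, 0.0, 0.0])
    frame = CentrioleFrame(
        origin_nm=origin_world,
        axis=axis_w,
        reference=ref_w,
        mc_radius_nm=spec.mc_radius_nm,
        mc_length_nm=spec.mc_length_nm,
    )
    tips_f = spec.da_tip_points()
    tips_w = tips_f @ rot.T + origin_world
    tip_theta = (spec.da_theta0_deg + 360.0 * np.arange(spec.n_da) / spec.n_da) % 360.0

    n_mem = len(spec.membranes)
    dist = np.zeros((n_mem, spec.n_da))
    gaps: list[float | None] = []
    areas: list[float] = []
    docked: list[bool] = []
    for i, m in enumerate(spec.membranes):
        for j in range(spec.n_da):
            dist[i, j] = m.min_distance_to(tips_f[j])
        gaps.append(m.true_gap_deg())
        areas.append(m.analytic_area_nm2())
        considered = np.ones(spec.n_da, dtype=bool)
        if m.kind == "arc_torus":
            rel = (tip_theta - m.arc_start_deg) % 360.0
            considered = rel <= m.arc_span_deg  # tips inside the gap excluded
        docked.append(bool(dist[i, considered].min() <= DOCK_THRESHOLD_NM) if considered.any() else False)

    stage = _true_stage(spec, docked)
    pm_dist = None
    if spec.pm is not None:
        pm_dist = np.array([spec.pm.distance_to(t) for t in tips_f])
    return GroundTruth(
        frame=frame,
        da_tip_points_nm=tips_w,
        da_tip_theta_deg=tip_theta,
        true_gap_deg=gaps,
        analytic_surface_area_nm2=areas,
        true_min_distance_nm=dist,
        docked=docked,
        true_stage=stage,
        pm_tip_distance_nm=pm_dist,
    )


def _true_stage(spec: PhantomSpec, docked: Sequence[bool], cilium_axial_extent_nm: float = 500.0) -> str:
    stage = "NAKED"
    order = {s: i for i, s in enumerate(STAGES)}
    for m, dk in zip(spec.membranes, docked):
        if not dk:
            continue
        if m.kind == "axial_tube" and m.z_offset_nm + m.length_nm > cilium_axial_extent_nm:
            cand = "CILIUM"
        elif m.kind == "cap":
            cand = "CV"
        elif m.kind == "toroid":
            cand = "TCV"
        elif m.kind == "arc_torus" and 360.0 - m.arc_span_deg < 180.0:
            cand = "CCV"
        else:
            cand = "DAV"
        if order[cand] > order[stage]:
            stage = cand
    return stage


# ---------------------------------------------------------------------------
# Cohorts and the per-stage randomized suite
# ---------------------------------------------------------------------------

def sample_cohort(
    template: PhantomSpec,
    n_cells: int,
    parameter_ranges: dict[str, tuple[float, float]],
    rng_seed: int,
) -> list[tuple[LabelVolume, GroundTruth]]:
    """Draw ``n_cells`` phantoms with uniformly sampled parameters.

    Supported range keys: ``mc_diameter_nm``, ``mc_length_nm``, ``da_length_nm``
    (template fields) and ``gap_deg`` (rewrites the span of every arc-torus
    membrane to ``360 - gap``). Deterministic given ``rng_seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    known = {"mc_diameter_nm", "mc_length_nm", "da_length_nm", "gap_deg"}
    unknown = set(parameter_ranges) - known
    if unknown:
        raise ValueError(f"unsupported parameter ranges: {sorted(unknown)}")
    for key, (lo, hi) in parameter_ranges.items():
        if not hi >= lo:
            raise ValueError(f"empty range for {key!r}")
    rng = np.random.default_rng(rng_seed)
    out = []
    for i in range(n_cells):
        spec = replace(template, membranes=[replace(m) for m in template.membranes])
        for key, (lo, hi) in sorted(parameter_ranges.items()):
            value = float(rng.uniform(lo, hi))
            if key == "gap_deg":
                for m in spec.membranes:
                    if m.kind == "arc_torus":
                        m.arc_span_deg = 360.0 - value
            else:
                setattr(spec, key, value)
        spec.rng_seed = rng_seed * 1000 + i
        out.append(build_phantom(spec))
    return out


def _docked_sphere(spec: PhantomSpec, tip_theta_deg: float, radius: float, standoff: float) -> MembranePrimitive:
    """Sphere whose surface sits ``standoff`` nm outside a DA tip."""
    th = np.radians(tip_theta_deg)
    c_rho = spec.da_tip_radius_nm + standoff + radius
    return MembranePrimitive(
        kind="sphere",
        center=(c_rho * np.cos(th), c_rho * np.sin(th), -spec.da_tip_offset_nm),
        radius_nm=radius,
    )


def random_stage_spec(stage: str, rng: np.random.Generator, voxel_size_nm: float = 9.0) -> PhantomSpec:
    """A randomized phantom of a given stage: random orientation, and stage
    parameters drawn from documented ranges that keep the defining structure
    docked and clear of classification boundaries."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    spec = PhantomSpec(voxel_size_nm=voxel_size_nm, rotation=random_rotation(rng))
    tip_r = spec.da_tip_radius_nm  # 225 nm at defaults
    z_tip = -spec.da_tip_offset_nm
    if stage == "NAKED":
        pass
    elif stage == "DAV":
        n = int(rng.integers(1, 4))
        tips = rng.choice(spec.n_da, size=n, replace=False)
        for k in tips:
            spec.membranes.append(
                _docked_sphere(
                    spec,
                    360.0 * k / spec.n_da,
                    radius=float(rng.uniform(40, 80)),
                    standoff=float(rng.uniform(5, 25)),
                )
            )
    elif stage in ("CCV", "TCV"):
        # place the torus tube centre at (tube radius + standoff) from the tip
        # ring, in a mostly-distal direction, so the defining structure is
        # docked without enclosing the appendage tips or touching the MC wall
        tube = float(rng.uniform(28, 40))
        standoff = float(rng.uniform(5, 25))
        psi = np.radians(float(rng.uniform(70, 110)))
        major = tip_r + (tube + standoff) * np.cos(psi)
        z0 = z_tip + (tube + standoff) * np.sin(psi)
        kwargs = dict(major_radius_nm=major, tube_radius_nm=tube, z_offset_nm=z0)
        if stage == "CCV":
            gap = float(rng.uniform(60, 170))
            spec.membranes.append(
                MembranePrimitive(
                    kind="arc_torus",
                    arc_start_deg=float(rng.uniform(0, 360)),
                    arc_span_deg=360.0 - gap,
                    **kwargs,
                )
            )
        else:
            spec.membranes.append(MembranePrimitive(kind="toroid", **kwargs))
    elif stage == "CV":
        spec.membranes.append(
            MembranePrimitive(
                kind="cap",
                radius_nm=float(rng.uniform(235, 255)),
                standoff_nm=float(rng.uniform(-65, -55)),
            )
        )
    elif stage == "CILIUM":
        spec.membranes.append(
            MembranePrimitive(
                kind="axial_tube",
                radius_nm=tip_r - float(rng.uniform(8, 20)),
                length_nm=float(rng.uniform(600, 750)),
                z_offset_nm=z_tip,
            )
        )
    _, truth = _check_stage(spec, stage)
    return spec


def _check_stage(spec: PhantomSpec, stage: str):
    """Assert the analytic ground truth of a generated spec matches ``stage``."""
    tips = spec.da_tip_points()
    docked = []
    for m in spec.membranes:
        d = [m.min_distance_to(t) for t in tips]
        docked.append(min(d) <= DOCK_THRESHOLD_NM if d else False)
    got = _true_stage(spec, docked)
    if got != stage:
        raise AssertionError(f"generated spec has true stage {got}, wanted {stage}")
    return spec, got
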