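"""Ciliogenesis membrane-stage classification.

One stage is reported per mother centriole, the most advanced membrane
structure winning (a CCV coexisting with leftover DAVs classifies the cell
as CCV):

``NAKED`` no docked membrane; ``DAV`` docked vesicles each covering less than
half the circumference; ``CCV`` a docked C-shaped membrane with an angular
gap below 180 deg; ``TCV`` a closed toroid encircling the MC; ``CV`` a vesicle
capping the distal end; ``CILIUM`` a docked membrane extending axially beyond
the MC's own length.

The CV cap-occupancy criterion (>= 90% of the distal disk covered by upward
rays) and the cilium axial-extent threshold (500 nm) are numeric conventions
of this package — the underlying taxonomy is morphological — and both are
exposed in :class:`~ciliomorph.metrics.AnalysisConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import CentrioleFrame, DATip, extract_surface_mesh, point_to_triangles_distance, to_cylindrical
from .metrics import (
    AnalysisConfig,
    DockingResult,
    GapResult,
    MembraneComponent,
    _component_thickness,
    estimate_surface_area,
)
from .volume_io import LabelVolume

__all__ = ["STAGES", "StageClassification", "classify_mc_stage", "detect_pm_docking"]

logger = logging.getLogger(__name__)

STAGES = ("NAKED", "DAV", "CCV", "TCV", "CV", "CILIUM")


@dataclass
class StageClassification:
    stage: str
    classifying_component_id: int | None
    pm_docked_da_ids: list[int] = field(default_factory=list)
    evidence: dict = field(default_factory=dict)


def _axial_extent(component: MembraneComponent, frame: CentrioleFrame) -> float:
    """Maximum height of the component above the distal end."""
    z = to_cylindrical(component.voxel_points_nm, frame)[:, 2]
    return float(z.max())


def _cap_occupancy(
    component: MembraneComponent, frame: CentrioleFrame, config: AnalysisConfig
) -> float:
    """Fraction of the distal disk whose upward rays meet the component.

    The disk of radius ``mc_radius`` just above the distal end is sampled on
    a voxel-pitch grid; a sample is covered when some component voxel above
    the distal plane lies within 1.5 voxels of the sample's axial ray.
    """
    v = component.voxel_size_nm
    cyl = to_cylindrical(component.voxel_points_nm, frame)
    above = cyl[:, 2] > 0
    if not above.any():
        return 0.0
    rel = component.voxel_points_nm[above] - frame.origin_nm
    ux = rel @ frame.reference
    uy = rel @ frame.binormal
    tree = cKDTree(np.column_stack([ux, uy]))
    r = frame.mc_radius_nm
    grid = np.arange(-r, r + v / 2, v)
    gx, gy = np.meshgrid(grid, grid)
    inside = gx**2 + gy**2 <= r**2
    samples = np.column_stack([gx[inside], gy[inside]])
    d, _ = tree.query(samples, k=1)
    return float(np.mean(d <= 1.5 * v))


def _encircles_axis(
    component: MembraneComponent,
    gap: GapResult | None,
    frame: CentrioleFrame,
    config: AnalysisConfig,
) -> bool:
    """Closed-loop test: near-zero gap plus a winding path clear of the axis.

    A dense blob sitting on the axis also covers every azimuth; requiring all
    surface points to stay outside a fraction of the MC radius distinguishes
    a genuine toroid encircling the centriole.
    """
    if gap is None:
        return False
    cyl = to_cylindrical(component.mesh_vertices_nm, frame)
    min_r = float(cyl[:, 0].min())
    if min_r < config.encircle_min_radius_fraction * frame.mc_radius_nm:
        return False
    closure = config.tcv_closure_deg
    if closure is None:
        mean_r = float(cyl[:, 0].mean())
        closure = np.degrees(component.voxel_size_nm / max(mean_r, 1e-9))
    return gap.gap_deg <= closure


def classify_mc_stage(
    components: Sequence[MembraneComponent],
    docking: Mapping[int, DockingResult],
    gaps: Mapping[int, GapResult | None],
    frame: CentrioleFrame,
    config: AnalysisConfig | None = None,
) -> StageClassification:
    """Assign the stage by a most-advanced-wins decision ladder over docked
    components: CILIUM > CV > TCV > CCV > DAV > NAKED."""
    config = config or AnalysisConfig()
    ids = {c.component_id for c in components}
    if not set(docking).issuperset(ids) or not set(gaps).issuperset(ids):
        raise ValueError("docking/gap results do not cover all component ids")
    docked = [c for c in components if docking[c.component_id].docked]

    evidence: dict = {
        "n_components": len(components),
        "n_docked": len(docked),
        "max_axial_extent_nm": None,
        "max_cap_occupancy": None,
        "min_gap_deg": None,
        "max_coverage_deg": None,
    }
    if not docked:
        return StageClassification(stage="NAKED", classifying_component_id=None, evidence=evidence)

    extents = {c.component_id: _axial_extent(c, frame) for c in docked}
    evidence["max_axial_extent_nm"] = max(extents.values())
    for cid, ext in extents.items():
        if ext > config.cilium_axial_extent_nm:
            return StageClassification(stage="CILIUM", classifying_component_id=cid, evidence=evidence)

    occupancy = {c.component_id: _cap_occupancy(c, frame, config) for c in docked}
    evidence["max_cap_occupancy"] = max(occupancy.values())
    for cid, occ in occupancy.items():
        if occ >= config.cv_occupancy_fraction:
            return StageClassification(stage="CV", classifying_component_id=cid, evidence=evidence)

    docked_gaps = {c.component_id: gaps[c.component_id] for c in docked}
    finite = [g.gap_deg for g in docked_gaps.values() if g is not None]
    if finite:
        evidence["min_gap_deg"] = min(finite)
        evidence["max_coverage_deg"] = 360.0 - min(finite)
    for c in docked:
        if _encircles_axis(c, docked_gaps[c.component_id], frame, config):
            return StageClassification(stage="TCV", classifying_component_id=c.component_id, evidence=evidence)
    for c in docked:
        g = docked_gaps[c.component_id]
        if g is not None and g.gap_deg < config.dav_ccv_gap_deg:
            return StageClassification(stage="CCV", classifying_component_id=c.component_id, evidence=evidence)
    return StageClassification(
        stage="DAV", classifying_component_id=docked[0].component_id, evidence=evidence
    )


def detect_pm_docking(
    volume: LabelVolume,
    tips: Sequence[DATip],
    config: AnalysisConfig | None = None,
) -> list[int]:
    """DA ids whose tip lies within the docking threshold of the plasma
    membrane; empty when no ``pm`` label is present."""
    config = config or AnalysisConfig()
    mask = volume.mask("pm")
    if not mask.any():
        logger.info("no plasma-membrane label present; PM docking not assessed")
        return []
    v = volume.voxel_size_nm
    verts, faces = extract_surface_mesh(mask=mask, voxel_size_nm=v)
    area = estimate_surface_area(mask, v)
    correction = _component_thickness(int(mask.sum()), area, v) / 2.0
    docked = []
    for tip in tips:
        d = point_to_triangles_distance(tip.tip_point_nm, verts, faces) + correction
        if d <= config.dock_threshold_nm:
            docked.append(tip.da_id)
    return docked
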