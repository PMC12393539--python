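"""Membrane detection filters, gap statistic, docking, areas, enlargement."""

import numpy as np
import pytest

from ciliomorph.geometry import DATip, detect_da_tips, fit_centriole_frame, to_cylindrical
from ciliomorph.metrics import (
    AnalysisConfig,
    circular_gap,
    compute_gap,
    detect_membrane_components,
    docking_assessment,
    enlargement_flags,
    estimate_surface_area,
    summarize_docked_membranes,
)
from ciliomorph.phantoms import MembranePrimitive, PhantomSpec, build_phantom, _docked_sphere
from ciliomorph.volume_io import LabelVolume

from conftest import arc_spec, docked_sphere_spec


def brute_force_gap(theta_deg):
    """Exhaustive maximum circular spacing: for each sample, the smallest
    positive circular distance to any other sample defines the arc starting
    there; the gap is the largest such arc."""
    theta = np.asarray(theta_deg, dtype=float) % 360.0
    if theta.size == 1:
        return 360.0
    best = 0.0
    for t in theta:
        deltas = (theta - t) % 360.0
        deltas = deltas[deltas > 0]
        best = max(best, float(deltas.min()) if deltas.size else 360.0)
    return best


class TestCircularGap:
    def test_matches_brute_force_on_random_multisets(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 100))
            theta = rng.uniform(0, 360, size=n)
            if rng.random() < 0.3:  # inject duplicates
                theta[: n // 2] = theta[n // 2 : n // 2 + n // 2]
            gap, _ = circular_gap(theta)
            assert gap == pytest.approx(brute_force_gap(theta), abs=1e-12)

    def test_wrap_around_included(self):
        gap, interval = circular_gap([10.0, 350.0])
        assert gap == pytest.approx(340.0)
        assert interval == (10.0, 350.0)

    def test_single_angle_full_gap(self):
        assert circular_gap([77.0])[0] == 360.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            circular_gap([])

    def test_interval_is_empty_arc(self, rng):
        theta = rng.uniform(0, 360, size=50)
        gap, (start, end) = circular_gap(theta)
        rel = (theta - start) % 360.0
        inside = (rel > 1e-9) & (rel < gap - 1e-9)
        assert not inside.any()


class TestDetectComponents:
    def test_filters_small_and_single_slice(self):
        spec = PhantomSpec()
        for i, d in enumerate((18, 28, 36, 90)):
            spec.membranes.append(
                MembranePrimitive(kind="sphere", center=(350 + 180 * i, 200, -50), radius_nm=d / 2)
            )
        vol, _ = build_phantom(spec)
        data = vol.data.copy()
        data[data.shape[0] // 2, 2:6, 2:6] = vol.label_map["membrane"]  # 1-slice artifact
        vol = LabelVolume(data=data, voxel_size_nm=vol.voxel_size_nm, label_map=vol.label_map)
        comps, excluded = detect_membrane_components(vol, return_excluded=True)
        diams = sorted(c.diameter_nm for c in comps)
        assert len(diams) == 2
        assert diams[0] == pytest.approx(36.0, abs=vol.voxel_size_nm)
        assert diams[1] == pytest.approx(90.0, abs=vol.voxel_size_nm)
        assert len(excluded) == 3
        assert any("z_slice_count" in reason for _, reason in excluded)
        assert all(c.z_slice_count >= 2 for c in comps)

    def test_exclusion_reasons_logged(self, caplog):
        spec = PhantomSpec()
        spec.membranes.append(MembranePrimitive(kind="sphere", center=(400, 0, -50), radius_nm=12))
        vol, _ = build_phantom(spec)
        with caplog.at_level("INFO", logger="ciliomorph.metrics"):
            comps = detect_membrane_components(vol)
        assert comps == []
        assert any("excluded" in rec.message for rec in caplog.records)

    def test_no_membrane_label_is_empty_not_error(self, default_phantom):
        vol, _ = default_phantom
        assert detect_membrane_components(vol) == []

    def test_diameter_within_one_voxel(self):
        vol, _ = build_phantom(docked_sphere_spec(standoff_nm=15, radius_nm=45))
        (comp,) = detect_membrane_components(vol)
        assert comp.diameter_nm == pytest.approx(90.0, abs=vol.voxel_size_nm)
        assert comp.surface_area_nm2 > 0
        assert comp.n_voxels == len(comp.voxel_indices)


class TestComputeGap:
    @pytest.mark.parametrize("gap_true", [45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0])
    def test_arc_gap_within_6deg(self, gap_true):
        vol, truth = build_phantom(arc_spec(gap_true))
        frame = truth.frame
        (comp,) = detect_membrane_components(vol)
        res = compute_gap(comp, frame)
        assert res.gap_deg == pytest.approx(gap_true, abs=6.0)
        assert res.gap_deg + res.coverage_deg == pytest.approx(360.0, abs=1e-9)

    def test_monotone_in_span(self):
        gaps = []
        for gap_true in (45.0, 135.0, 225.0, 315.0):
            vol, truth = build_phantom(arc_spec(gap_true))
            (comp,) = detect_membrane_components(vol)
            gaps.append(compute_gap(comp, truth.frame).gap_deg)
        assert all(a < b for a, b in zip(gaps, gaps[1:]))

    def test_closed_toroid_near_zero_gap(self):
        vol, truth = build_phantom(arc_spec(0.0))
        (comp,) = detect_membrane_components(vol)
        res = compute_gap(comp, truth.frame)
        assert res.gap_deg < 3.0

    def test_voxel_theta_source_agrees(self):
        vol, truth = build_phantom(arc_spec(153.0))
        (comp,) = detect_membrane_components(vol)
        mesh_gap = compute_gap(comp, truth.frame, theta_source="mesh").gap_deg
        voxel_gap = compute_gap(comp, truth.frame, theta_source="voxels").gap_deg
        assert mesh_gap == pytest.approx(voxel_gap, abs=4.0)

    def test_gap_interval_start_in_range(self):
        vol, truth = build_phantom(arc_spec(153.0, arc_start_deg=30.0))
        (comp,) = detect_membrane_components(vol)
        res = compute_gap(comp, truth.frame)
        # empty arc should cover the constructed gap [237, 390) mod 360
        mid_gap = (30.0 + 207.0 + 153.0 / 2.0) % 360.0
        rel = (mid_gap - res.gap_interval[0]) % 360.0
        assert 0.0 < rel < res.gap_deg


class TestDocking:
    def _tips_from_truth(self, truth):
        cyl = to_cylindrical(truth.da_tip_points_nm, truth.frame)
        return [
            DATip(da_id=i, tip_point_nm=truth.da_tip_points_nm[i], theta_deg=float(cyl[i, 1]),
                  radial_nm=float(cyl[i, 0]), z_nm=float(cyl[i, 2]))
            for i in range(len(cyl))
        ]

    @pytest.mark.parametrize("standoff,expect_docked", [(0.0, True), (10.0, True), (20.0, True), (50.0, False)])
    def test_standoff_within_one_voxel(self, standoff, expect_docked):
        """Full detected chain (fitted frame + detected tips), as in analysis.

        At standoff 0 the contact voxels are claimed by the higher-precedence
        da label, so only the detected-tip measurement stays within a voxel.
        """
        vol, truth = build_phantom(docked_sphere_spec(standoff))
        (comp,) = detect_membrane_components(vol)
        frame = fit_centriole_frame(vol)
        tips = detect_da_tips(vol, frame)
        res = docking_assessment(comp, tips)
        assert res.docked is expect_docked
        assert res.min_distance_considered_nm == pytest.approx(standoff, abs=vol.voxel_size_nm)

    def test_sphere_45_at_65_gives_20(self):
        """Analytic center-distance minus radius as oracle (spec example)."""
        vol, truth = build_phantom(docked_sphere_spec(20.0, radius_nm=45.0))
        (comp,) = detect_membrane_components(vol)
        res = docking_assessment(comp, self._tips_from_truth(truth))
        assert res.min_distance_considered_nm == pytest.approx(20.0, abs=9.0)

    def test_gap_interval_tips_excluded(self):
        """DAs strictly inside the C gap do not vote on docking."""
        vol, truth = build_phantom(arc_spec(153.0, arc_start_deg=10.0))
        (comp,) = detect_membrane_components(vol)
        tips = self._tips_from_truth(truth)
        gap = compute_gap(comp, truth.frame)
        res = docking_assessment(comp, tips, gap=gap)
        # true gap arc is theta in (217, 370); DA tips at 240, 280, 320, 360
        # are analytically inside it (40 deg grid from 0)
        inside_true = {6, 7, 8, 0}
        assert inside_true.issuperset(res.excluded_da_ids)
        assert len(res.excluded_da_ids) >= 3
        assert res.docked
        assert set(res.min_distance_nm) == set(range(9))

    def test_all_tips_in_gap_cannot_dock(self):
        vol, truth = build_phantom(docked_sphere_spec(5.0))
        (comp,) = detect_membrane_components(vol)
        tips = self._tips_from_truth(truth)
        from ciliomorph.metrics import GapResult

        full_gap = GapResult(component_id=comp.component_id, gap_deg=359.0,
                             gap_interval=(350.0, 349.0), n_theta_samples=10)
        res = docking_assessment(comp, tips, gap=full_gap)
        assert not res.docked
        assert res.closest_da_id is None

    def test_empty_tips_rejected(self):
        vol, truth = build_phantom(docked_sphere_spec(5.0))
        (comp,) = detect_membrane_components(vol)
        with pytest.raises(ValueError, match="tip"):
            docking_assessment(comp, [])


class TestSurfaceArea:
    def test_sphere_within_10pct_and_converges(self):
        errors = {}
        for v in (9.0, 3.0):
            spec = PhantomSpec(voxel_size_nm=v)
            spec.membranes.append(MembranePrimitive(kind="sphere", center=(400, 0, -50), radius_nm=100))
            vol, _ = build_phantom(spec)
            (comp,) = detect_membrane_components(vol)
            true = 4 * np.pi * 100**2
            errors[v] = abs(comp.surface_area_nm2 - true) / true
        assert errors[9.0] < 0.10
        assert errors[3.0] < errors[9.0]

    def test_torus_within_10pct(self):
        spec = PhantomSpec()
        spec.membranes.append(
            MembranePrimitive(kind="toroid", major_radius_nm=160, tube_radius_nm=40, z_offset_nm=250)
        )
        vol, _ = build_phantom(spec)
        (comp,) = detect_membrane_components(vol)
        true = 4 * np.pi**2 * 160 * 40
        assert comp.surface_area_nm2 == pytest.approx(true, rel=0.10)

    def test_disjoint_components_additive(self):
        spec = PhantomSpec()
        spec.membranes.append(MembranePrimitive(kind="sphere", center=(400, 0, -50), radius_nm=60))
        spec.membranes.append(MembranePrimitive(kind="sphere", center=(400, 250, -50), radius_nm=40))
        vol, _ = build_phantom(spec)
        comps = detect_membrane_components(vol)
        combined = estimate_surface_area(vol.mask("membrane"), vol.voxel_size_nm)
        assert sum(c.surface_area_nm2 for c in comps) == pytest.approx(combined, rel=1e-6)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_surface_area(np.zeros((4, 4, 4), dtype=bool), 9.0)

    def test_isosurface_mode_runs(self):
        vol, _ = build_phantom(docked_sphere_spec(15.0))
        area = estimate_surface_area(vol.mask("membrane"), vol.voxel_size_nm, mode="isosurface")
        assert area > 0


class TestEnlargement:
    def test_hand_computed_example(self):
        """Reference {50,60,70}e3: mean 60e3, sample SD 10e3, threshold 70e3."""
        flags = enlargement_flags([75e3, 70e3, 65e3], [50e3, 60e3, 70e3])
        assert flags == [True, False, False]

    def test_equal_to_mean_not_flagged(self):
        assert enlargement_flags([60e3], [50e3, 60e3, 70e3]) == [False]

    def test_multiplier_honoured(self):
        config = AnalysisConfig(enlargement_sd_multiplier=2.0)
        assert enlargement_flags([75e3], [50e3, 60e3, 70e3], config) == [False]

    def test_reference_too_small(self):
        with pytest.raises(ValueError, match="reference"):
            enlargement_flags([1.0], [1.0])


class TestSummaries:
    def test_counts_and_totals(self):
        spec = PhantomSpec()
        spec.membranes.append(_docked_sphere(spec, 0.0, 50.0, 10.0))
        spec.membranes.append(_docked_sphere(spec, 120.0, 60.0, 15.0))
        spec.membranes.append(_docked_sphere(spec, 240.0, 55.0, 80.0))  # undocked
        vol, truth = build_phantom(spec)
        frame = fit_centriole_frame(vol)
        tips = detect_da_tips(vol, frame)
        comps = detect_membrane_components(vol)
        docking = [docking_assessment(c, tips) for c in comps]
        summary = summarize_docked_membranes(comps, docking)
        assert summary["n_docked"] == 2
        analytic = 4 * np.pi * (50.0**2 + 60.0**2)
        assert summary["total_area_nm2"] == pytest.approx(analytic, rel=0.10)
        assert summary["mean_docking_distance_nm"] == pytest.approx(12.5, abs=9.0)

    def test_no_docked(self, default_phantom):
        summary = summarize_docked_membranes([], [])
        assert summary["n_docked"] == 0
        assert summary["total_area_nm2"] == 0.0
        assert summary["mean_docking_distance_nm"] is None


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            AnalysisConfig(dock_threshold_nm=0)
        with pytest.raises(ValueError):
            AnalysisConfig(dav_ccv_gap_deg=360)
        with pytest.raises(ValueError):
            AnalysisConfig(membrane_mode="plasma")

    def test_to_dict_round_trip(self):
        config = AnalysisConfig(dock_threshold_nm=25.0)
        assert AnalysisConfig(**config.to_dict()) == config
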