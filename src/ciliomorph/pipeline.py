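"""Per-cell analysis, cohort aggregation and group comparisons.

``analyze_cell`` composes the full measurement chain — frame fit, appendage
tips, membrane detection, docking, gap angles, areas, stage — into one
deterministic report. ``aggregate_cohort`` pools reports into per-group
summaries (stage frequency tables, docking distances as mean +- SEM, vesicle
counts and areas as mean +- SD) and ``compare_groups`` applies the unpaired
two-tailed Student t test (two groups) or one-way ANOVA (more).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .classify import StageClassification, classify_mc_stage, detect_pm_docking
from .geometry import fit_centriole_frame, detect_da_tips
from .metrics import (
    AnalysisConfig,
    compute_gap,
    detect_membrane_components,
    docking_assessment,
    summarize_docked_membranes,
)
from .volume_io import LabelVolume

__all__ = [
    "CellReport",
    "CohortSummary",
    "GroupComparison",
    "analyze_cell",
    "aggregate_cohort",
    "compare_groups",
    "holm_bonferroni",
    "significance_stars",
    "two_group_power_simulation",
]

logger = logging.getLogger(__name__)

_COMPONENT_COLUMNS = [
    "cell_id",
    "component_id",
    "n_voxels",
    "diameter_nm",
    "z_slice_count",
    "surface_area_nm2",
    "gap_deg",
    "coverage_deg",
    "min_docking_distance_nm",
    "closest_da_id",
    "docked",
    "excluded_da_ids",
    "enlarged",
]


@dataclass
class CellReport:
    """Everything measured on one cell; reproducible from volume + config."""

    cell_id: str
    stage: str
    classifying_component_id: int | None
    pm_docked_da_ids: list[int]
    components: list[dict]
    excluded_components: list[tuple[int, str]]
    per_da_min_distance_nm: dict[int, float]
    summary: dict
    frame: dict
    evidence: dict
    config: dict
    group: str | None = None
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "group": self.group,
            "stage": self.stage,
            "classifying_component_id": self.classifying_component_id,
            "pm_docked_da_ids": self.pm_docked_da_ids,
            "components": self.components,
            "excluded_components": [list(e) for e in self.excluded_components],
            "per_da_min_distance_nm": {str(k): v for k, v in self.per_da_min_distance_nm.items()},
            "summary": self.summary,
            "frame": self.frame,
            "evidence": self.evidence,
            "config": self.config,
            "version": self.version,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [{k: c.get(k) for k in _COMPONENT_COLUMNS} for c in self.components]
        return pd.DataFrame(rows, columns=_COMPONENT_COLUMNS)


def analyze_cell(
    volume: LabelVolume,
    config: AnalysisConfig | None = None,
    cell_id: str = "cell",
    group: str | None = None,
) -> CellReport:
    """Run the full measurement chain on one label volume."""
    config = config or AnalysisConfig()
    try:
        frame = fit_centriole_frame(volume)
        tips = detect_da_tips(volume, frame)
        components, excluded = detect_membrane_components(volume, config, return_excluded=True)
        gaps, docking = {}, {}
        for comp in components:
            try:
                gap = compute_gap(comp, frame, theta_source=config.theta_source)
            except ValueError:
                gap = None
            gaps[comp.component_id] = gap
            docking[comp.component_id] = docking_assessment(comp, tips, config, gap=gap)
        stage = classify_mc_stage(components, docking, gaps, frame, config)
        stage.pm_docked_da_ids = detect_pm_docking(volume, tips, config)
    except Exception as err:
        raise RuntimeError(f"analysis of cell {cell_id!r} failed: {err}") from err

    rows = []
    for comp in components:
        dock = docking[comp.component_id]
        gap = gaps[comp.component_id]
        rows.append(
            {
                "cell_id": cell_id,
                "component_id": comp.component_id,
                "n_voxels": comp.n_voxels,
                "diameter_nm": round(comp.diameter_nm, 3),
                "z_slice_count": comp.z_slice_count,
                "surface_area_nm2": round(comp.surface_area_nm2, 1),
                "gap_deg": round(gap.gap_deg, 3) if gap else None,
                "coverage_deg": round(gap.coverage_deg, 3) if gap else None,
                "min_docking_distance_nm": round(dock.min_distance_considered_nm, 3)
                if np.isfinite(dock.min_distance_considered_nm)
                else None,
                "closest_da_id": dock.closest_da_id,
                "docked": dock.docked,
                "excluded_da_ids": dock.excluded_da_ids,
                "enlarged": None,  # filled at cohort level against a reference group
            }
        )

    # per-appendage minimal distance over docked components, gap-excluded
    per_da: dict[int, float] = {}
    for tip in tips:
        dists = [
            docking[c.component_id].min_distance_nm[tip.da_id]
            for c in components
            if docking[c.component_id].docked
            and tip.da_id not in docking[c.component_id].excluded_da_ids
        ]
        if dists:
            per_da[tip.da_id] = float(min(dists))

    return CellReport(
        cell_id=cell_id,
        group=group,
        stage=stage.stage,
        classifying_component_id=stage.classifying_component_id,
        pm_docked_da_ids=stage.pm_docked_da_ids,
        components=rows,
        excluded_components=excluded,
        per_da_min_distance_nm=per_da,
        summary=summarize_docked_membranes(components, list(docking.values()), config),
        frame=frame.to_dict(),
        evidence=stage.evidence,
        config=config.to_dict(),
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    groups: dict[str, dict]
    comparisons: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"groups": self.groups, "comparisons": self.comparisons}


def _mean_sd_sem(values: Sequence[float]) -> dict:
    arr = np.asarray(list(values), dtype=float)
    out = {"n": int(arr.size), "mean": float(arr.mean()) if arr.size else None}
    if arr.size >= 2:
        sd = float(arr.std(ddof=1))
        out["sd"] = sd
        out["sem"] = sd / float(np.sqrt(arr.size))
    else:  # SD/SEM undefined for n < 2: absent, not zero
        out["sd"] = None
        out["sem"] = None
    return out


def aggregate_cohort(
    reports: Sequence[CellReport],
    grouping: Mapping[str, str] | None = None,
    reference_group: str | None = None,
    config: AnalysisConfig | None = None,
) -> CohortSummary:
    """Pool per-cell reports into per-group summaries.

    Docking distances pool each cell's per-appendage minimal distances.
    When ``reference_group`` is given, per-component enlargement flags are
    set against that group's docked-component areas (mean + k SD rule).
    """
    config = config or AnalysisConfig()
    groups: dict[str, list[CellReport]] = {}
    for rep in reports:
        if grouping is not None:
            if rep.cell_id not in grouping:
                raise ValueError(f"cell {rep.cell_id!r} missing from grouping map")
            rep.group = grouping[rep.cell_id]
        groups.setdefault(rep.group or "all", []).append(rep)

    if reference_group is not None:
        if reference_group not in groups:
            raise ValueError(f"reference group {reference_group!r} has no reports")
        ref_areas = [
            c["surface_area_nm2"]
            for rep in groups[reference_group]
            for c in rep.components
            if c["docked"]
        ]
        if len(ref_areas) >= 2:
            from .metrics import enlargement_flags

            for rep in reports:
                docked_rows = [c for c in rep.components if c["docked"]]
                flags = enlargement_flags(
                    [c["surface_area_nm2"] for c in docked_rows], ref_areas, config
                )
                for row, flag in zip(docked_rows, flags):
                    row["enlarged"] = flag

    out: dict[str, dict] = {}
    for name, reps in sorted(groups.items()):
        stage_counts = {s: 0 for s in ("NAKED", "DAV", "CCV", "TCV", "CV", "CILIUM")}
        for rep in reps:
            stage_counts[rep.stage] += 1
        docking_pool = [d for rep in reps for d in rep.per_da_min_distance_nm.values()]
        dav_counts = [rep.summary["n_docked"] for rep in reps]
        per_comp_areas = [a for rep in reps for a in rep.summary["areas_nm2"]]
        total_areas = [rep.summary["total_area_nm2"] for rep in reps]
        out[name] = {
            "n_cells": len(reps),
            "stage_counts": stage_counts,
            "stage_frequencies": {
                s: c / len(reps) for s, c in stage_counts.items()
            },
            "docking_distance_nm": _mean_sd_sem(docking_pool),
            "docked_count": _mean_sd_sem(dav_counts),
            "component_area_nm2": _mean_sd_sem(per_comp_areas),
            "total_docked_area_nm2": _mean_sd_sem(total_areas),
            "n_enlarged": sum(
                1 for rep in reps for c in rep.components if c.get("enlarged")
            ),
        }
    return CohortSummary(groups=out)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    df: float | tuple[float, float]
    stars: str


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    samples: Mapping[str, Sequence[float]],
    test: str = "auto",
    equal_var: bool = True,
) -> GroupComparison:
    """Unpaired two-tailed Student t (2 groups) or one-way ANOVA (>= 2).

    ``test='auto'`` picks the t test for exactly two groups and ANOVA
    otherwise. ``equal_var=False`` switches to Welch's t.
    """
    arrays = [np.asarray(list(v), dtype=float) for v in samples.values()]
    if test == "auto":
        test = "t_test" if len(arrays) == 2 else "anova"
    if test == "t_test":
        if len(arrays) != 2:
            raise ValueError("t test requires exactly two groups")
        if any(a.size < 2 for a in arrays):
            raise ValueError("t test requires n >= 2 per group")
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=equal_var)
        df = arrays[0].size + arrays[1].size - 2 if equal_var else float(res.df)
        return GroupComparison(
            test="t_test" if equal_var else "welch_t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            df=df,
            stars=significance_stars(float(res.pvalue)),
        )
    if test == "anova":
        if len(arrays) < 2:
            raise ValueError("ANOVA requires at least two groups")
        if any(a.size < 2 for a in arrays):
            raise ValueError("ANOVA requires n >= 2 per group")
        res = stats.f_oneway(*arrays)
        k, n = len(arrays), sum(a.size for a in arrays)
        return GroupComparison(
            test="anova",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            df=(k - 1, n - k),
            stars=significance_stars(float(res.pvalue)),
        )
    raise ValueError(f"unknown test {test!r}")


def holm_bonferroni(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional multiple-testing control;
    no correction is applied by default, matching the source analyses)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p)
    m = p.size
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted.tolist()


def two_group_power_simulation(
    mean_a: float,
    mean_b: float,
    cv: float,
    n_per_group: int,
    n_replicates: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of replicates where the Student t test rejects at ``alpha``
    for two lognormal groups with given means and coefficient of variation.

    Used to validate the pipeline's statistical sensitivity on synthetic
    total-docked-area cohorts.
    """
    rng = np.random.default_rng(seed)
    sigma2 = np.log(1.0 + cv**2)
    sigma = np.sqrt(sigma2)
    rejections = 0
    for _ in range(n_replicates):
        a = rng.lognormal(np.log(mean_a) - sigma2 / 2, sigma, n_per_group)
        b = rng.lognormal(np.log(mean_b) - sigma2 / 2, sigma, n_per_group)
        res = compare_groups({"a": a, "b": b}, test="t_test")
        if res.p_value < alpha:
            rejections += 1
    return rejections / n_replicates
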