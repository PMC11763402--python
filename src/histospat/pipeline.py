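"""Stage orchestration: cohort → per-ROI PCF → patient means → clustering →
group labels → association tests, with deterministic per-stage seeding.

Each stage is a plain function over PatientRecords so the pipeline can be
driven from the CLI, a notebook, or the test suite.  Randomness is always
derived from a master seed combined with the stage name, so re-running a
stage with the same configuration reproduces its output exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .clustering import ClusteringResult, ContingencyResult, contingency_test, label_groups, select_k
from .geometry import SetCovariance, rasterize_window
from .ingest import PatientRecord
from .pcf import PCFEstimatorConfig, RadiiGrid, cohort_pcf_matrix, estimate_pcf, make_radii_grid, patient_mean_pcf

__all__ = ["PipelineResult", "stage_seed", "compute_patient_pcfs", "cluster_cohort", "association_tests", "run_pipeline"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 (master seed ⊕ stage name)."""
    return (master_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineResult:
    matrix: np.ndarray
    patient_ids: list[str]
    radii: np.ndarray
    clustering: ClusteringResult
    groups: np.ndarray | None
    tests: dict[str, ContingencyResult] = field(default_factory=dict)


def compute_patient_pcfs(
    records: list[PatientRecord],
    grid: RadiiGrid | None = None,
    cfg: PCFEstimatorConfig | None = None,
) -> list[PatientRecord]:
    """Estimate each ROI's PCF and store per-patient mean curves in place.

    The set-covariance raster is computed once per ROI window.
    """
    grid = grid or make_radii_grid()
    cfg = cfg or PCFEstimatorConfig()
    for rec in records:
        curves = []
        for pat in rec.roi_patterns:
            mask = rasterize_window(pat.window, cfg.raster_resolution)
            sc = SetCovariance(mask, cfg.raster_resolution)
            curves.append(estimate_pcf(pat, grid, cfg, set_cov=sc))
        rec.mean_pcf = patient_mean_pcf(curves)
    return records


def cluster_cohort(
    records: list[PatientRecord],
    k_max: int = 10,
    n_restarts: int = 25,
    seed: int = 0,
) -> PipelineResult:
    """Assemble the cohort PCF matrix, select K, and label spatial groups."""
    matrix, ids, radii = cohort_pcf_matrix(records)
    clustering = select_k(matrix, k_max=k_max, n_restarts=n_restarts, seed=seed)
    groups = label_groups(clustering, matrix, radii)
    if groups is not None:
        for rec, g in zip(records, groups):
            rec.spatial_group = int(g)
    return PipelineResult(
        matrix=matrix, patient_ids=ids, radii=radii, clustering=clustering, groups=groups
    )


def association_tests(records: list[PatientRecord], method: str = "chi2") -> dict[str, ContingencyResult]:
    """2×2 association tests: spatial group vs metastasis, grade vs metastasis."""
    tests: dict[str, ContingencyResult] = {}
    met = np.array([r.metastatic for r in records])
    grade = np.array([r.grade for r in records])
    grade_table = np.array(
        [
            [int(((grade == 2) & ~met).sum()), int(((grade == 2) & met).sum())],
            [int(((grade == 3) & ~met).sum()), int(((grade == 3) & met).sum())],
        ]
    )
    tests["grade_vs_metastasis"] = contingency_test(grade_table, method)
    groups = np.array([r.spatial_group for r in records], dtype=object)
    if not any(g is None for g in groups):
        groups = groups.astype(int)
        group_table = np.array(
            [
                [int(((groups == 1) & ~met).sum()), int(((groups == 1) & met).sum())],
                [int(((groups == 2) & ~met).sum()), int(((groups == 2) & met).sum())],
            ]
        )
        tests["group_vs_metastasis"] = contingency_test(group_table, method)
    return tests


def run_pipeline(
    records: list[PatientRecord],
    grid: RadiiGrid | None = None,
    pcf_cfg: PCFEstimatorConfig | None = None,
    k_max: int = 10,
    n_restarts: int = 25,
    seed: int = 0,
    test_method: str = "chi2",
) -> PipelineResult:
    """PCF estimation → clustering → group labels → association tests."""
    compute_patient_pcfs(records, grid, pcf_cfg)
    result = cluster_cohort(records, k_max=k_max, n_restarts=n_restarts, seed=stage_seed(seed, "cluster"))
    result.tests = association_tests(records, method=test_method)
    return result
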