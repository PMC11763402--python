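"""Cochran-subsample resampling of point patterns and interaction-distance
comparisons.

Each tumor pattern is augmented with simulated "random cells": a CSR pattern
at the tumor intensity laid over the same window, with the originals
re-marked ``cells`` and the simulated points ``random_cells``.  For each
mark, many realizations are drawn by subsampling the points without
replacement to the Cochran sample size

    n0 = z² p (1 − p) / e²,   n = ceil(n0 / (1 + (n0 − 1)/N)),

capped at the population size N (defaults z = 1.96, p = 0.5, e = 0.05, the
estimator's canonical constants).  Every realization receives a profile
Geyer fit over radii taken from its own nearest-neighbor distance deciles
and saturations {1, 2, 3}; the fitted interaction radii are averaged into a
per-pattern mean interaction distance, and group-level distributions of
those means are compared by Welch's t-test (or a rank-sum test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry import (
    InsufficientPointsError,
    PointPattern,
    simulate_csr,
)
from .geyer import DummyGrid, GeyerFit, candidate_radii, make_dummy_grid, profile_fit

__all__ = [
    "RealizationSet",
    "InteractionComparison",
    "augment_with_random_cells",
    "cochran_sample_size",
    "make_realizations",
    "fit_realization_set",
    "mean_interaction_distance",
    "compare_interaction_distances",
]


@dataclass
class RealizationSet:
    """Subsample realizations of one pattern/mark plus their fits."""

    source_id: str
    mark: str
    n_realizations: int
    subsample_size: int
    realizations: list[PointPattern]
    fits: list[GeyerFit | None] = field(default_factory=list)

    @property
    def n_converged(self) -> int:
        return sum(1 for f in self.fits if f is not None and f.converged)


@dataclass
class InteractionComparison:
    group_a: str
    group_b: str
    means_a: np.ndarray
    means_b: np.ndarray
    test: str
    statistic: float
    p_value: float


def augment_with_random_cells(
    p: PointPattern, seed: int | np.random.Generator | None = None
) -> PointPattern:
    """Overlay CSR "random cells" at the pattern's tumor intensity.

    Original points are re-marked ``cells``; the window and original
    coordinates are unchanged.
    """
    tumor = p.points[np.isin(p.marks, ("tumor", "cells"))]
    if len(tumor) < 2:
        raise InsufficientPointsError("augmentation needs >= 2 tumor points")
    lam = len(tumor) / p.window.area
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sim = simulate_csr(p.window, lam, rng, mark="random_cells")
    pts = np.vstack([tumor, sim.points])
    marks = np.concatenate(
        [np.full(len(tumor), "cells", dtype=object), np.full(len(sim), "random_cells", dtype=object)]
    )
    return PointPattern(p.window, pts, marks)


def cochran_sample_size(
    n_population: int, z: float = 1.96, p: float = 0.5, e: float = 0.05
) -> int:
    """Cochran's sample size with finite-population correction, capped at N."""
    if n_population < 1:
        raise ValueError("population must be >= 1")
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if e <= 0:
        raise ValueError("margin of error e must be > 0")
    n0 = z**2 * p * (1 - p) / e**2
    n = math.ceil(n0 / (1 + (n0 - 1) / n_population))
    return min(n, n_population)


def make_realizations(
    p: PointPattern,
    mark: str,
    n_real: int = 500,
    seed: int | np.random.Generator | None = None,
    z: float = 1.96,
    prop: float = 0.5,
    e: float = 0.05,
) -> RealizationSet:
    """Draw `n_real` Cochran-sized subsamples (without replacement) of one mark."""
    sel = p.marks == mark
    pts = p.points[sel]
    if len(pts) < 2:
        raise InsufficientPointsError(f"mark {mark!r} has fewer than 2 points")
    n_c = cochran_sample_size(len(pts), z=z, p=prop, e=e)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reals = []
    for _ in range(n_real):
        idx = rng.choice(len(pts), size=n_c, replace=False)
        reals.append(PointPattern(p.window, pts[idx], np.full(n_c, mark, dtype=object)))
    return RealizationSet(
        source_id="", mark=mark, n_realizations=n_real, subsample_size=n_c, realizations=reals
    )


def fit_realization_set(
    rs: RealizationSet,
    sats=(1, 2, 3),
    spacing: float | None = None,
    dummy_grid: DummyGrid | None = None,
) -> RealizationSet:
    """Profile-fit every realization (radii from its own NN-distance deciles).

    Failed fits are recorded as None and excluded from downstream summaries.
    """
    if not rs.realizations:
        raise ValueError("realization set is empty")
    if dummy_grid is None:
        dummy_grid = make_dummy_grid(rs.realizations[0].window, spacing)
    fits: list[GeyerFit | None] = []
    for q in rs.realizations:
        try:
            r_grid = candidate_radii(q)
            fits.append(profile_fit(q, r_grid=r_grid, sats=sats, dummy_grid=dummy_grid))
        except Exception:  # noqa: BLE001 - logged as a failed realization
            fits.append(None)
    rs.fits = fits
    if rs.n_converged == 0:
        raise RuntimeError("all realization fits failed")
    return rs


def mean_interaction_distance(rs: RealizationSet) -> float:
    """Mean selected interaction radius r over converged realization fits (µm)."""
    rr = [f.params.r for f in rs.fits if f is not None and f.converged]
    if not rr:
        raise ValueError("no converged fits in realization set")
    return float(np.mean(rr))


def compare_interaction_distances(
    a, b, test: str = "welch", label_a: str = "a", label_b: str = "b"
) -> InteractionComparison:
    """Two-sided comparison of two lists of per-pattern mean interaction
    distances (Welch's t by default, Wilcoxon rank-sum as alternative)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per group")
    if test == "welch":
        if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_ind(a, b, equal_var=False)
    elif test == "wilcoxon":
        stat, p = stats.ranksums(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return InteractionComparison(
        group_a=label_a,
        group_b=label_b,
        means_a=a,
        means_b=b,
        test=test,
        statistic=float(stat),
        p_value=float(p),
    )
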