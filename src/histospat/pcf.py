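"""Ripley's K and kernel pair-correlation estimation with translation
edge correction.

The pair correlation function g(r) is the density of point pairs at
separation r relative to a homogeneous Poisson process of the same
intensity: g = 1 under complete spatial randomness (CSR), > 1 indicates
clustering at scale r, < 1 inhibition.  Equivalently g(r) = K'(r)/(2πr)
where K is Ripley's K-function.

Both estimators use the translation edge correction: an ordered pair at
displacement v contributes weight 1/γ_W(v), with γ_W(v) = |W ∩ (W+v)| the
set covariance of the window.  This is the natural correction for windows
with interior holes, where distance-to-boundary corrections are awkward.

    K̂(r) = (1/λ̂²) Σ_{i≠j} 1[d_ij ≤ r] / γ_W(x_j − x_i)
    ĝ(r) = (1/(2πr λ̂²)) Σ_{i≠j} k_h(r − d_ij) / γ_W(x_j − x_i)

with the unbiased pair intensity λ̂² = n(n−1)/|W|², the Epanechnikov kernel
k_h(t) = (3/(4h))(1 − (t/h)²) for |t| ≤ h, and Stoyan's bandwidth rule
h = c/√λ̂ (default c = 0.15).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    InsufficientPointsError,
    PointPattern,
    SetCovariance,
    rasterize_window,
)

__all__ = [
    "RadiiGrid",
    "PCFCurve",
    "PCFEstimatorConfig",
    "make_radii_grid",
    "ripley_k",
    "estimate_pcf",
    "patient_mean_pcf",
    "cohort_pcf_matrix",
]


@dataclass(frozen=True)
class RadiiGrid:
    """Closed arithmetic grid of evaluation radii (µm)."""

    r_min: float = 0.5
    r_max: float = 35.0
    step: float = 0.5

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if not 0 < self.r_min <= self.r_max:
            raise ValueError("need 0 < r_min <= r_max")

    @property
    def values(self) -> np.ndarray:
        n = int(np.floor((self.r_max - self.r_min) / self.step + 1e-9)) + 1
        return self.r_min + self.step * np.arange(n)

    def __len__(self) -> int:
        return len(self.values)


def make_radii_grid(r_min: float = 0.5, r_max: float = 35.0, step: float = 0.5) -> RadiiGrid:
    """Grid r_min, r_min+step, ... never exceeding r_max (defaults: 70 radii)."""
    return RadiiGrid(r_min, r_max, step)


@dataclass
class PCFCurve:
    """Pair-correlation estimates on a radii grid.

    `flagged` marks radii where the estimate is unreliable (fewer than two
    points, or r below the kernel bandwidth); the values are still stored.
    """

    grid: RadiiGrid
    g: np.ndarray
    n_points: int
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        if len(self.g) != len(self.grid):
            raise ValueError("g length must match grid length")
        if self.flagged is None:
            self.flagged = np.zeros(len(self.g), dtype=bool)
        else:
            self.flagged = np.asarray(self.flagged, dtype=bool)


@dataclass(frozen=True)
class PCFEstimatorConfig:
    """Kernel, bandwidth rule, and edge-correction settings.

    bandwidth_coef is Stoyan's c in h = c/√λ̂; raster_resolution (µm/px)
    controls the set-covariance raster.
    """

    bandwidth_coef: float = 0.15
    raster_resolution: float = 1.0

    def __post_init__(self):
        if self.bandwidth_coef <= 0:
            raise ValueError("bandwidth coefficient must be > 0")

    def bandwidth(self, lam: float) -> float:
        return self.bandwidth_coef / np.sqrt(lam)


def _pair_data(p: PointPattern, cfg: PCFEstimatorConfig, set_cov: SetCovariance | None):
    """Sorted pair distances and translation weights 1/γ_W for i≠j pairs."""
    if len(p) < 2:
        raise InsufficientPointsError("pair statistics need >= 2 points")
    if set_cov is None:
        mask = rasterize_window(p.window, cfg.raster_resolution)
        set_cov = SetCovariance(mask, cfg.raster_resolution)
    x = p.points
    diff = x[None, :, :] - x[:, None, :]  # v_ij = x_j - x_i
    iu = np.triu_indices(len(x), k=1)
    v = diff[iu]
    d = np.hypot(v[:, 0], v[:, 1])
    gam = set_cov(v)
    ok = gam > 0
    # each unordered pair stands for two ordered pairs; γ_W(v) = γ_W(−v)
    wgt = np.zeros(len(v))
    wgt[ok] = 2.0 / gam[ok]
    order = np.argsort(d)
    return d[order], wgt[order]


def ripley_k(
    p: PointPattern,
    grid: RadiiGrid,
    cfg: PCFEstimatorConfig | None = None,
    set_cov: SetCovariance | None = None,
) -> np.ndarray:
    """Translation-corrected K̂(r) on the grid (µm²); non-decreasing in r."""
    cfg = cfg or PCFEstimatorConfig()
    d, wgt = _pair_data(p, cfg, set_cov)
    n = len(p)
    area = p.window.area
    lam2 = n * (n - 1) / area**2
    csum = np.concatenate([[0.0], np.cumsum(wgt)])
    idx = np.searchsorted(d, grid.values, side="right")
    return csum[idx] / lam2


def estimate_pcf(
    p: PointPattern,
    grid: RadiiGrid | None = None,
    cfg: PCFEstimatorConfig | None = None,
    set_cov: SetCovariance | None = None,
) -> PCFCurve:
    """Kernel estimate of the pair correlation function on the grid."""
    grid = grid or make_radii_grid()
    cfg = cfg or PCFEstimatorConfig()
    d, wgt = _pair_data(p, cfg, set_cov)
    n = len(p)
    area = p.window.area
    lam = n / area
    lam2 = n * (n - 1) / area**2
    h = cfg.bandwidth(lam)
    rs = grid.values
    g = np.empty(len(rs))
    lo = np.searchsorted(d, rs - h, side="left")
    hi = np.searchsorted(d, rs + h, side="right")
    for k, r in enumerate(rs):
        dd = d[lo[k] : hi[k]]
        ww = wgt[lo[k] : hi[k]]
        t = (r - dd) / h
        kern = 0.75 * (1.0 - t * t) / h
        g[k] = (kern * ww).sum() / (2.0 * np.pi * r * lam2)
    g = np.clip(g, 0.0, None)
    flagged = rs < h
    if h >= grid.r_max:
        import warnings

        warnings.warn(f"kernel bandwidth h={h:.2f} µm exceeds r_max={grid.r_max}")
    return PCFCurve(grid=grid, g=g, n_points=n, flagged=flagged)


def patient_mean_pcf(curves: list[PCFCurve]) -> PCFCurve:
    """Pointwise mean of a patient's per-ROI curves (typically three).

    At radii where some curves are flagged, the mean uses the unflagged
    values only; a radius flagged in every curve stays flagged and carries
    the plain mean.
    """
    if not curves:
        raise ValueError("no curves to average")
    g0 = curves[0].grid
    for c in curves[1:]:
        if c.grid != g0:
            raise ValueError("all curves must share one radii grid")
    G = np.vstack([c.g for c in curves])
    F = np.vstack([c.flagged for c in curves])
    n_ok = (~F).sum(axis=0)
    mean_all = G.mean(axis=0)
    with np.errstate(invalid="ignore"):
        mean_ok = np.where(n_ok > 0, (G * ~F).sum(axis=0) / np.maximum(n_ok, 1), mean_all)
    return PCFCurve(
        grid=g0,
        g=mean_ok,
        n_points=int(sum(c.n_points for c in curves)),
        flagged=n_ok == 0,
    )


def cohort_pcf_matrix(cohort) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Stack per-patient mean PCFs into a (patients × radii) matrix.

    Returns (matrix, patient_ids, radii); rows follow the cohort order.
    """
    rows, ids = [], []
    grid = None
    for rec in cohort:
        if rec.mean_pcf is None:
            raise ValueError(f"patient {rec.patient_id} has no mean PCF")
        if grid is None:
            grid = rec.mean_pcf.grid
        elif rec.mean_pcf.grid != grid:
            raise ValueError("patients have mismatched radii grids")
        rows.append(rec.mean_pcf.g)
        ids.append(rec.patient_id)
    return np.vstack(rows), ids, grid.values
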