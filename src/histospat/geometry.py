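"""Observation windows, point patterns, and elementary spatial geometry.

The observation region for every analysis in this package is a *window*: an
axis-aligned square (the region annotation drawn on the slide) minus a union
of polygonal holes (necrosis, vessels, and artifacts cleaved out of the
annotation).  Coordinates are in micrometers with the origin at the top-left
corner of the image and y increasing downward, matching the convention of
digital-pathology detection exports.  All statistics computed downstream are
translation- and reflection-invariant, so no axis flip is ever performed.

Containment convention: the outer square boundary is *inclusive*, hole
boundaries are *exclusive* (a point exactly on a hole edge is kept).  This
gives a deterministic rule for boundary detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import shapely
from scipy.fft import next_fast_len
from shapely.geometry import Polygon, box

__all__ = [
    "Window",
    "PointPattern",
    "SetCovariance",
    "window_area",
    "point_in_window",
    "rasterize_window",
    "set_covariance",
    "pairwise_distances",
    "nearest_neighbor_distances",
    "intensity",
    "simulate_csr",
]

MARKS = ("tumor", "non_tumor", "random_cell", "cells", "random_cells")


class InvalidWindowError(ValueError):
    """Raised for degenerate windows (zero side, zero area)."""


class InsufficientPointsError(ValueError):
    """Raised when an operation needs more points than the pattern has."""


@dataclass(frozen=True)
class Window:
    """Axis-aligned square observation region minus a union of holes.

    Parameters
    ----------
    origin : (float, float)
        Top-left corner (x0, y0) of the square, in µm.
    side : float
        Side length of the square, in µm (must be > 0).
    holes : tuple of (n, 2) arrays
        Vertex rings of the holes, each a simple polygon with every vertex
        inside the outer square.  Overlapping holes are handled by union.
    raster_resolution : float
        Default µm-per-pixel used when the window is rasterized.
    """

    origin: tuple[float, float] = (0.0, 0.0)
    side: float = 750.0
    holes: tuple[np.ndarray, ...] = ()
    raster_resolution: float = 1.0

    def __post_init__(self):
        if not np.isfinite(self.side) or self.side <= 0:
            raise InvalidWindowError(f"window side must be > 0, got {self.side}")
        holes = tuple(np.asarray(h, dtype=float) for h in self.holes)
        x0, y0 = self.origin
        for h in holes:
            if h.ndim != 2 or h.shape[1] != 2 or h.shape[0] < 3:
                raise InvalidWindowError("each hole must be an (n>=3, 2) vertex ring")
            if (
                h[:, 0].min() < x0
                or h[:, 0].max() > x0 + self.side
                or h[:, 1].min() < y0
                or h[:, 1].max() > y0 + self.side
            ):
                raise InvalidWindowError("hole vertex outside the outer square")
        object.__setattr__(self, "holes", holes)
        if self.area <= 0:
            raise InvalidWindowError("window has zero area (holes cover the square)")

    @property
    def outer_vertices(self) -> np.ndarray:
        """The 4 corners of the square, counter-clockwise from the origin."""
        x0, y0 = self.origin
        s = self.side
        return np.array([[x0, y0], [x0 + s, y0], [x0 + s, y0 + s], [x0, y0 + s]])

    @property
    def _outer_poly(self) -> Polygon:
        x0, y0 = self.origin
        return box(x0, y0, x0 + self.side, y0 + self.side)

    @cached_property
    def _holes_union(self):
        if not self.holes:
            return None
        polys = [shapely.make_valid(Polygon(h)) for h in self.holes]
        hu = shapely.union_all(polys)
        shapely.prepare(hu)
        return hu

    @cached_property
    def polygon(self) -> Polygon:
        """Shapely polygon of the region (outer minus hole union)."""
        hu = self._holes_union
        return self._outer_poly if hu is None else self._outer_poly.difference(hu)

    @cached_property
    def area(self) -> float:
        """Exact polygon area in µm²."""
        return float(self.polygon.area)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized containment test (outer inclusive, holes exclusive)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x0, y0 = self.origin
        inside = (
            (pts[:, 0] >= x0)
            & (pts[:, 0] <= x0 + self.side)
            & (pts[:, 1] >= y0)
            & (pts[:, 1] <= y0 + self.side)
        )
        hu = self._holes_union
        if hu is not None and inside.any():
            geoms = shapely.points(pts[inside])
            # contains_properly: interior only, so hole *boundaries* stay in.
            in_hole = shapely.contains_properly(hu, geoms)
            idx = np.flatnonzero(inside)
            inside[idx[in_hole]] = False
        return inside


@dataclass
class PointPattern:
    """A marked point set observed inside a :class:`Window`.

    Marks distinguish observed tumor / non-tumor nuclei from simulated
    completely-spatially-random augmentation points.
    """

    window: Window
    points: np.ndarray
    marks: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if pts.size and not np.isfinite(pts).all():
            raise ValueError("point coordinates must be finite")
        if self.marks is None:
            marks = np.full(len(pts), "tumor", dtype=object)
        else:
            marks = np.asarray(self.marks, dtype=object)
        if len(marks) != len(pts):
            raise ValueError("marks length must equal number of points")
        bad = set(marks) - set(MARKS)
        if bad:
            raise ValueError(f"unknown marks: {sorted(bad)}")
        if len(pts) and not self.window.contains(pts).all():
            raise ValueError("pattern has points outside the window or inside holes")
        self.points = pts
        self.marks = marks

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, mark: str | None = None) -> "PointPattern":
        """Sub-pattern of points carrying `mark` (all points if None)."""
        if mark is None:
            return PointPattern(self.window, self.points.copy(), self.marks.copy())
        keep = self.marks == mark
        return PointPattern(self.window, self.points[keep], self.marks[keep])


def window_area(w: Window) -> float:
    """Area of the window (outer square minus hole union) in µm²."""
    return w.area


def point_in_window(w: Window, pt) -> bool:
    """True iff `pt` lies in the window (outer inclusive, holes exclusive)."""
    return bool(w.contains(np.asarray(pt, dtype=float).reshape(1, 2))[0])


def rasterize_window(w: Window, res: float | None = None) -> np.ndarray:
    """Binary mask of the window on a square grid of `res` µm per pixel.

    A mask cell is True iff its *center* lies in the window.  Rows index y,
    columns index x, cell (i, j) has center (x0 + (j+.5)res, y0 + (i+.5)res).
    """
    if res is None:
        res = w.raster_resolution
    if res <= 0:
        raise ValueError(f"raster resolution must be > 0, got {res}")
    n = max(1, int(round(w.side / res)))
    x0, y0 = w.origin
    cx = x0 + (np.arange(n) + 0.5) * res
    cy = y0 + (np.arange(n) + 0.5) * res
    mask = np.ones((n, n), dtype=bool)
    hu = w._holes_union
    if hu is not None:
        # Only pixels under a hole bounding box can be False.
        minx, miny, maxx, maxy = hu.bounds
        j0, j1 = np.searchsorted(cx, [minx, maxx])
        i0, i1 = np.searchsorted(cy, [miny, maxy])
        j1 = min(j1 + 1, n)
        i1 = min(i1 + 1, n)
        if j1 > j0 and i1 > i0:
            xs, ys = np.meshgrid(cx[j0:j1], cy[i0:i1])
            pts = shapely.points(np.column_stack([xs.ravel(), ys.ravel()]))
            in_hole = shapely.contains_properly(hu, pts).reshape(i1 - i0, j1 - j0)
            mask[i0:i1, j0:j1] = ~in_hole
    # Pixels whose center leaves the outer square cannot occur by construction
    # (grid covers exactly [x0, x0+side] when side/res is integral; otherwise
    # the last partial pixel center may poke out by < res/2 -- clip it).
    if n * res > w.side:
        keep_x = cx <= x0 + w.side
        keep_y = cy <= y0 + w.side
        mask &= keep_x[None, :]
        mask &= keep_y[:, None]
    return mask


class SetCovariance:
    """Set covariance γ_W(v) = |W ∩ (W + v)| of a rasterized window.

    Computed once by FFT autocorrelation of the binary mask; evaluated at
    arbitrary displacements by bilinear interpolation.  Used as the
    translation edge-correction weight for pair statistics: a pair at
    displacement v is down-weighted by γ_W(v), the area over which that
    displacement could have been observed.
    """

    def __init__(self, mask: np.ndarray, res: float):
        if res <= 0:
            raise ValueError("res must be > 0")
        self.res = float(res)
        m = np.asarray(mask, dtype=float)
        n0, n1 = m.shape
        shape = (2 * n0 - 1, 2 * n1 - 1)
        fshape = [next_fast_len(s, real=True) for s in shape]
        F = np.fft.rfft2(m, fshape)
        acf = np.fft.irfft2(F * np.conj(F), fshape)
        # Circular correlation holds the linear autocorrelation at lag
        # l mod fshape; re-index to an image centered on lag zero.
        idx0 = (np.arange(shape[0]) - (n0 - 1)) % fshape[0]
        idx1 = (np.arange(shape[1]) - (n1 - 1)) % fshape[1]
        acf = acf[np.ix_(idx0, idx1)]
        # zero border so lags at the edge of the support interpolate to 0
        self._img = np.pad(np.clip(acf, 0.0, None) * self.res**2, 1)
        self._c0 = n0  # index of lag zero (rows = dy, cols = dx)
        self._c1 = n1

    def __call__(self, v: np.ndarray) -> np.ndarray:
        """γ_W at displacement(s) v (µm); bilinear lookup, 0 outside support."""
        v = np.atleast_2d(np.asarray(v, dtype=float))
        fj = v[:, 0] / self.res + self._c1
        fi = v[:, 1] / self.res + self._c0
        img = self._img
        i0 = np.floor(fi).astype(int)
        j0 = np.floor(fj).astype(int)
        ti = fi - i0
        tj = fj - j0
        out = np.zeros(len(v))
        valid = (i0 >= 0) & (i0 < img.shape[0] - 1) & (j0 >= 0) & (j0 < img.shape[1] - 1)
        i0v, j0v = i0[valid], j0[valid]
        tiv, tjv = ti[valid], tj[valid]
        out[valid] = (
            img[i0v, j0v] * (1 - tiv) * (1 - tjv)
            + img[i0v + 1, j0v] * tiv * (1 - tjv)
            + img[i0v, j0v + 1] * (1 - tiv) * tjv
            + img[i0v + 1, j0v + 1] * tiv * tjv
        )
        return out


def set_covariance(mask: np.ndarray, v, res: float = 1.0) -> float:
    """Area |W ∩ (W + v)| in µm² for a single displacement v."""
    sc = SetCovariance(mask, res)
    return float(sc(np.asarray(v, dtype=float).reshape(1, 2))[0])


def pairwise_distances(p: PointPattern) -> np.ndarray:
    """Symmetric Euclidean distance matrix (µm), zero diagonal."""
    if len(p) < 1:
        raise InsufficientPointsError("need at least 1 point")
    from scipy.spatial.distance import pdist, squareform

    if len(p) == 1:
        return np.zeros((1, 1))
    return squareform(pdist(p.points))


def nearest_neighbor_distances(p: PointPattern) -> np.ndarray:
    """Distance from each point to its nearest other point (µm)."""
    if len(p) < 2:
        raise InsufficientPointsError("nearest-neighbor distances need >= 2 points")
    from scipy.spatial import cKDTree

    tree = cKDTree(p.points)
    d, _ = tree.query(p.points, k=2)
    return d[:, 1]


def intensity(p: PointPattern, mark: str | None = None) -> float:
    """Empirical intensity (points per µm²), optionally for one mark."""
    area = p.window.area
    if area <= 0:
        raise InvalidWindowError("zero-area window")
    n = len(p) if mark is None else int((p.marks == mark).sum())
    return n / area


def _uniform_in_window(w: Window, n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform points on the window, by rejection against the holes."""
    x0, y0 = w.origin
    out = np.empty((0, 2))
    # acceptance ratio = area fraction; oversample accordingly
    frac = max(w.area / w.side**2, 1e-3)
    while len(out) < n:
        m = max(16, int((n - len(out)) / frac * 1.2) + 8)
        cand = rng.uniform(0, w.side, size=(m, 2)) + np.array([x0, y0])
        out = np.vstack([out, cand[w.contains(cand)]])
    return out[:n]


def simulate_csr(
    w: Window,
    lam: float,
    seed: int | np.random.Generator | None = None,
    mark: str = "random_cell",
) -> PointPattern:
    """Homogeneous Poisson (CSR) pattern at intensity `lam` (µm⁻²)."""
    if lam < 0:
        raise ValueError(f"intensity must be >= 0, got {lam}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = rng.poisson(lam * w.area)
    pts = _uniform_in_window(w, n, rng) if n else np.empty((0, 2))
    return PointPattern(w, pts, np.full(n, mark, dtype=object))
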