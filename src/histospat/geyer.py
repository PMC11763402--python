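"""Geyer saturation point process: simulation and maximum-pseudolikelihood
fitting.

The Geyer saturation process is a Gibbs (Markov) point process with
unnormalized density

    f(x) ∝ β^{n(x)} γ^{U(x)},   U(x) = Σ_i min(s, t_i),

where t_i is the number of other points within the interaction radius r of
point i and s is the saturation threshold.  Capping each point's neighbor
count at s keeps the density integrable for γ > 1, so the same family
models clustering (γ > 1) and inhibition (γ < 1); γ = 1 reduces to a
homogeneous Poisson process with intensity β.

Fitting maximizes the log pseudolikelihood

    log PL(β, γ) = Σ_i log λ(x_i; x∖x_i) − ∫_W λ(u; x) du,

where λ(u; x) = β γ^{U(x∪{u}) − U(x)} is the Papangelou conditional
intensity.  The integral is approximated with a Berman–Turner quadrature,
which turns the problem into a weighted Poisson log-linear model in
(log β, log γ); that model is solved by Newton/IRLS.  The interaction
radius r and saturation s are not regular parameters: they are profiled
over a grid, and the fit with the smallest AIC (2k − 2 log PL with k = 2)
is selected.

Simulation uses a birth–death Metropolis–Hastings chain started from CSR,
implemented as a numba kernel for speed; the pure-Python conditional
intensity above serves as its independent check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .geometry import (
    InsufficientPointsError,
    PointPattern,
    Window,
    nearest_neighbor_distances,
    point_in_window,
    rasterize_window,
    simulate_csr,
)

__all__ = [
    "GeyerParams",
    "GeyerFit",
    "Quadrature",
    "DummyGrid",
    "make_dummy_grid",
    "saturation_statistic",
    "conditional_intensity",
    "simulate_geyer",
    "berman_turner_quadrature",
    "fit_geyer",
    "candidate_radii",
    "profile_fit",
]


@dataclass(frozen=True)
class GeyerParams:
    """(β, γ, r, s): baseline intensity, interaction, radius, saturation."""

    beta: float
    gamma: float
    r: float
    sat: int

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.r <= 0:
            raise ValueError("interaction radius must be > 0")
        if self.sat < 1 or int(self.sat) != self.sat:
            raise ValueError("saturation must be an integer >= 1")


@dataclass
class GeyerFit:
    params: GeyerParams
    log_pseudolikelihood: float
    aic: float
    n_quadrature: int
    converged: bool
    degenerate: bool = False  # no identifiable interaction (e.g. no close pairs)


def _neighbor_counts(d: np.ndarray, r: float) -> np.ndarray:
    """t_i = number of other points within distance r (d: square matrix)."""
    close = d <= r
    np.fill_diagonal(close, False)
    return close.sum(axis=1)


def saturation_statistic(p: PointPattern, r: float, sat: int) -> float:
    """U(x) = Σ_i min(sat, t_i) with t_i the r-close neighbor count."""
    if len(p) < 2:
        return 0.0
    d = squareform(pdist(p.points))
    t = _neighbor_counts(d, r)
    return float(np.minimum(t, sat).sum())


def conditional_intensity(u, p: PointPattern, params: GeyerParams) -> float:
    """Papangelou conditional intensity λ(u; x) = β γ^{U(x∪u) − U(x)}.

    The exponent is evaluated directly: min(s, t(u)) plus one unit for every
    r-close neighbor whose own count is still below saturation.
    """
    u = np.asarray(u, dtype=float).reshape(2)
    if not point_in_window(p.window, u):
        raise ValueError("location u lies outside the window")
    if len(p) == 0:
        return params.beta
    d_u = np.hypot(*(p.points - u).T)
    close_u = d_u <= params.r
    if len(p) >= 2:
        t = _neighbor_counts(squareform(pdist(p.points)), params.r)
    else:
        t = np.zeros(1, dtype=int)
    delta = min(params.sat, int(close_u.sum())) + int((t[close_u] < params.sat).sum())
    return params.beta * params.gamma**delta


# ---------------------------------------------------------------------------
# Birth-death Metropolis-Hastings simulation (numba kernel)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _in_any_hole(px, py, hx, hy, hoff):
    """Even-odd ray casting over the concatenated hole rings."""
    for h in range(len(hoff) - 1):
        a, b = hoff[h], hoff[h + 1]
        inside = False
        j = b - 1
        for i in range(a, b):
            if (hy[i] > py) != (hy[j] > py):
                xi = (hx[j] - hx[i]) * (py - hy[i]) / (hy[j] - hy[i]) + hx[i]
                if px < xi:
                    inside = not inside
            j = i
        if inside:
            return True
    return False


@njit(cache=True)
def _geyer_mh(
    x, y, n0, beta, log_gamma, r, sat, ox, oy, side, hx, hy, hoff, area, n_iter, seed
):
    np.random.seed(seed)
    cap = len(x)
    n = n0
    r2 = r * r
    t = np.zeros(cap, dtype=np.int64)
    for i in range(n):
        for j in range(i):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx * dx + dy * dy <= r2:
                t[i] += 1
                t[j] += 1
    close = np.empty(cap, dtype=np.int64)
    for _ in range(n_iter):
        if np.random.random() < 0.5:  # birth
            if n >= cap:
                continue
            ux = ox + np.random.random() * side
            uy = oy + np.random.random() * side
            tries = 0
            while _in_any_hole(ux, uy, hx, hy, hoff):
                ux = ox + np.random.random() * side
                uy = oy + np.random.random() * side
                tries += 1
                if tries > 10000:
                    break
            tu = 0
            inc = 0
            for i in range(n):
                dx = x[i] - ux
                dy = y[i] - uy
                if dx * dx + dy * dy <= r2:
                    close[tu] = i
                    tu += 1
                    if t[i] < sat:
                        inc += 1
            delta = min(sat, tu) + inc
            lam = beta * math.exp(delta * log_gamma)
            if np.random.random() < area * lam / (n + 1):
                for k in range(tu):
                    t[close[k]] += 1
                x[n] = ux
                y[n] = uy
                t[n] = tu
                n += 1
        else:  # death
            if n == 0:
                continue
            i = int(np.random.random() * n)
            if i == n:
                i = n - 1
            tu = 0
            dec = 0
            for j in range(n):
                if j == i:
                    continue
                dx = x[j] - x[i]
                dy = y[j] - y[i]
                if dx * dx + dy * dy <= r2:
                    close[tu] = j
                    tu += 1
                    if t[j] <= sat:  # t_j without i is t_j - 1 < sat
                        dec += 1
            delta = min(sat, tu) + dec
            lam = beta * math.exp(delta * log_gamma)
            if np.random.random() < n / (area * lam):
                for k in range(tu):
                    t[close[k]] -= 1
                n -= 1
                if i != n:
                    x[i] = x[n]
                    y[i] = y[n]
                    t[i] = t[n]
    return n


def simulate_geyer(
    w: Window,
    params: GeyerParams,
    n_iter: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> PointPattern:
    """Simulate a Geyer saturation process by birth-death MH.

    The chain starts from a CSR(β) pattern and runs `n_iter` proposals
    (births and deaths equally likely); the final state is returned with
    mark ``tumor``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    init = simulate_csr(w, params.beta, rng)
    area = w.area
    # generous capacity: saturated conditional intensity times head-room
    lam_hi = params.beta * max(1.0, params.gamma) ** (2 * params.sat)
    cap = int(max(1024, 8 * lam_hi * area, 4 * len(init)))
    x = np.zeros(cap)
    y = np.zeros(cap)
    x[: len(init)] = init.points[:, 0]
    y[: len(init)] = init.points[:, 1]
    if w.holes:
        hx = np.concatenate([h[:, 0] for h in w.holes])
        hy = np.concatenate([h[:, 1] for h in w.holes])
        hoff = np.cumsum([0] + [len(h) for h in w.holes])
    else:
        hx = np.zeros(0)
        hy = np.zeros(0)
        hoff = np.zeros(1, dtype=np.int64)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    n = _geyer_mh(
        x,
        y,
        len(init),
        params.beta,
        math.log(params.gamma),
        params.r,
        int(params.sat),
        w.origin[0],
        w.origin[1],
        w.side,
        hx,
        hy,
        np.asarray(hoff, dtype=np.int64),
        area,
        int(n_iter),
        kernel_seed,
    )
    pts = np.column_stack([x[:n], y[:n]])
    return PointPattern(w, pts, np.full(n, "tumor", dtype=object))


# ---------------------------------------------------------------------------
# Berman-Turner quadrature and pseudolikelihood fitting
# ---------------------------------------------------------------------------


@dataclass
class DummyGrid:
    """Reusable per-window dummy-point layout for Berman-Turner quadrature."""

    window: Window = field(repr=False)
    spacing: float
    n_tiles: int
    tile: float
    tile_area: np.ndarray  # (n_tiles, n_tiles), sums to the window area
    dummies: np.ndarray  # (nd, 2)


@dataclass
class Quadrature:
    """Data + dummy locations with counting weights summing to |W|."""

    points: np.ndarray  # (nq, 2), data points first
    weights: np.ndarray
    is_data: np.ndarray
    window: Window = field(repr=False, default=None)  # type: ignore[assignment]


def make_dummy_grid(w: Window, spacing: float | None = None) -> DummyGrid:
    """Tile the window and place one dummy point per non-empty tile.

    Dummy points sit at tile centers, nudged onto the nearest in-window
    raster pixel when the center falls inside a hole.  Precomputing this
    once per window lets many subsampled patterns share it.
    """
    if spacing is None:
        spacing = w.side / 128
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if spacing > w.side:
        raise ValueError("spacing larger than the window side")
    n_tiles = max(1, int(round(w.side / spacing)))
    tile = w.side / n_tiles
    res = w.raster_resolution
    mask = rasterize_window(w, res)
    x0, y0 = w.origin

    npx = mask.shape[0]
    px_tile = np.minimum((np.arange(npx) * res / tile).astype(int), n_tiles - 1)
    # pixel counts per tile via two grouped sums
    colsum = np.zeros((npx, n_tiles))
    np.add.at(colsum.T, px_tile, mask.T.astype(float))
    tile_area = np.zeros((n_tiles, n_tiles))
    np.add.at(tile_area, px_tile, colsum)
    tile_area *= res**2
    tile_area *= w.area / tile_area.sum()  # exact mass conservation

    ti, tj = np.nonzero(tile_area > 0)
    cx = x0 + (tj + 0.5) * tile
    cy = y0 + (ti + 0.5) * tile
    centers = np.column_stack([cx, cy])
    good = w.contains(centers)
    for k in np.flatnonzero(~good):
        rows = np.flatnonzero(px_tile == ti[k])
        cols = np.flatnonzero(px_tile == tj[k])
        hits = np.argwhere(mask[np.ix_(rows, cols)])
        if len(hits) == 0:
            tile_area[ti[k], tj[k]] = 0.0
            continue
        i, j = hits[len(hits) // 2]
        centers[k] = (x0 + (cols[j] + 0.5) * res, y0 + (rows[i] + 0.5) * res)
        good[k] = True
    dummies = centers[good]
    tile_area *= w.area / tile_area.sum()
    return DummyGrid(
        window=w, spacing=spacing, n_tiles=n_tiles, tile=tile, tile_area=tile_area, dummies=dummies
    )


def berman_turner_quadrature(
    p: PointPattern, spacing: float | None = None, grid: DummyGrid | None = None
) -> Quadrature:
    """Counting-weight quadrature: each tile's window area is split equally
    among the data and dummy points it contains, so weights sum to |W|."""
    w = p.window
    if grid is None:
        grid = make_dummy_grid(w, spacing)
    x0, y0 = w.origin
    pts = np.vstack([p.points, grid.dummies]) if len(p) else grid.dummies
    is_data = np.zeros(len(pts), dtype=bool)
    is_data[: len(p)] = True
    n_tiles, tile = grid.n_tiles, grid.tile
    ti_all = np.minimum(((pts[:, 1] - y0) / tile).astype(int), n_tiles - 1)
    tj_all = np.minimum(((pts[:, 0] - x0) / tile).astype(int), n_tiles - 1)
    counts = np.zeros((n_tiles, n_tiles), dtype=int)
    np.add.at(counts, (ti_all, tj_all), 1)
    areas = grid.tile_area[ti_all, tj_all]
    # a data point can sit in a window sliver too thin for any raster pixel
    # center; give such tiles one pixel of area instead of a zero weight
    areas = np.maximum(areas, w.raster_resolution**2)
    weights = areas / counts[ti_all, tj_all]
    # mass in occupied tiles only; rescale so the total is the window area
    weights *= w.area / weights.sum()
    return Quadrature(points=pts, weights=weights, is_data=is_data, window=w)


class _FitContext:
    """Sparse neighbor structure shared across a profile grid of (r, sat).

    Holds the quadrature plus all data-data and dummy-data pairs within
    `r_max`, so each (r, sat) covariate is a handful of bincounts.
    """

    def __init__(self, p: PointPattern, r_max: float, spacing: float | None = None,
                 grid: DummyGrid | None = None):
        self.pattern = p
        self.quad = berman_turner_quadrature(p, spacing, grid)
        self.n = len(p)
        tree = cKDTree(p.points)
        pairs = tree.query_pairs(r_max, output_type="ndarray")
        self.pi = pairs[:, 0]
        self.pj = pairs[:, 1]
        self.pd = np.hypot(*(p.points[self.pi] - p.points[self.pj]).T) if len(pairs) else np.zeros(0)
        dummies = self.quad.points[~self.quad.is_data]
        self.nd = len(dummies)
        coo = cKDTree(dummies).sparse_distance_matrix(tree, r_max, output_type="coo_matrix")
        self.qi = coo.row
        self.qj = coo.col
        self.qd = np.hypot(*(dummies[self.qi] - p.points[self.qj]).T) if coo.nnz else np.zeros(0)

    def covariate(self, r: float, sat: int) -> np.ndarray:
        """c(u_q): exponent of the conditional intensity at every quad point.

        At a data point x_i this is U(x) − U(x∖x_i); at a dummy u it is
        U(x∪u) − U(x).
        """
        n, nd = self.n, self.nd
        m = self.pd <= r
        pi, pj = self.pi[m], self.pj[m]
        t = np.bincount(pi, minlength=n) + np.bincount(pj, minlength=n)
        c_data = np.minimum(t, sat).astype(float)
        # neighbor j seen from x∖i has count t_j − 1; it gains a unit iff t_j ≤ sat
        gain = t <= sat
        c_data += np.bincount(pi[gain[pj]], minlength=n)
        c_data += np.bincount(pj[gain[pi]], minlength=n)
        mu = self.qd <= r
        qi, qj = self.qi[mu], self.qj[mu]
        tu = np.bincount(qi, minlength=nd)
        c_dummy = np.minimum(tu, sat).astype(float)
        c_dummy += np.bincount(qi[t[qj] < sat], minlength=nd)
        return np.concatenate([c_data, c_dummy])


def _poisson_irls(y, w, c, max_iter: int = 100, tol: float = 1e-9):
    """Weighted Poisson log-linear fit of E[y] = exp(b0 + b1 c); returns
    (b0, b1, converged)."""
    X = np.column_stack([np.ones_like(c), c])
    b = np.array([math.log(max(y @ w, 1e-300) / w.sum()), 0.0])
    for _ in range(max_iter):
        eta = np.clip(X @ b, -500, 500)
        mu = np.exp(eta)
        Ww = w * mu
        grad = X.T @ (w * (y - mu))
        H = (X * Ww[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return b[0], b[1], False
        # dampen huge steps (near-separation configurations)
        nrm = np.abs(step).max()
        if nrm > 5:
            step *= 5 / nrm
        b = b + step
        if np.abs(step).max() < tol:
            return b[0], b[1], True
    return b[0], b[1], False


def _fit_at(ctx: _FitContext, r: float, sat: int) -> GeyerFit:
    c = ctx.covariate(r, sat)
    quad = ctx.quad
    wq = quad.weights
    y = quad.is_data.astype(float) / wq
    degenerate = np.ptp(c) == 0
    if degenerate:
        b0 = math.log(ctx.n / ctx.pattern.window.area)
        b1 = 0.0
        conv = True
    else:
        b0, b1, conv = _poisson_irls(y, wq, c)
    lam_data = np.exp(np.clip(b0 + b1 * c[quad.is_data], -500, 500))
    lam_all = np.exp(np.clip(b0 + b1 * c, -500, 500))
    log_pl = float(np.log(np.maximum(lam_data, 1e-300)).sum() - (wq * lam_all).sum())
    aic = 2 * 2 - 2 * log_pl
    params = GeyerParams(beta=math.exp(b0), gamma=math.exp(b1), r=r, sat=int(sat))
    return GeyerFit(
        params=params,
        log_pseudolikelihood=log_pl,
        aic=aic,
        n_quadrature=len(wq),
        converged=bool(conv),
        degenerate=bool(degenerate),
    )


def fit_geyer(
    p: PointPattern,
    r: float,
    sat: int,
    spacing: float | None = None,
    dummy_grid: DummyGrid | None = None,
) -> GeyerFit:
    """Maximum-pseudolikelihood Geyer fit at fixed (r, sat)."""
    if len(p) < 10:
        raise InsufficientPointsError("Geyer fitting needs at least 10 points")
    ctx = _FitContext(p, r_max=r, spacing=spacing, grid=dummy_grid)
    return _fit_at(ctx, float(r), int(sat))


def candidate_radii(p: PointPattern, quantiles: np.ndarray | None = None) -> np.ndarray:
    """Candidate interaction radii: deciles of the nearest-neighbor distances."""
    nn = nearest_neighbor_distances(p)
    if np.all(nn == 0):
        raise ValueError("all points coincident: no usable interaction radii")
    q = quantiles if quantiles is not None else np.arange(0.1, 0.91, 0.1)
    r = np.unique(np.quantile(nn, q))
    r = r[r > 0]
    if len(r) == 0:
        raise ValueError("no positive candidate radii")
    return r


def profile_fit(
    p: PointPattern,
    r_grid: np.ndarray | None = None,
    sats=(1, 2, 3),
    spacing: float | None = None,
    dummy_grid: DummyGrid | None = None,
) -> GeyerFit:
    """Profile pseudolikelihood over (r, sat); minimum-AIC converged fit.

    Ties in AIC break toward smaller r, then smaller saturation (the grid is
    scanned in that order and only strict improvements replace the incumbent).
    """
    if len(p) < 10:
        raise InsufficientPointsError("Geyer fitting needs at least 10 points")
    r_grid = candidate_radii(p) if r_grid is None else np.asarray(r_grid, dtype=float)
    if len(r_grid) == 0 or len(sats) == 0:
        raise ValueError("empty profile grid")
    ctx = _FitContext(p, r_max=float(np.max(r_grid)), spacing=spacing, grid=dummy_grid)
    best = None
    failures = []
    for r in np.sort(r_grid):
        for s in sorted(sats):
            fit = _fit_at(ctx, float(r), int(s))
            if not fit.converged:
                failures.append((float(r), int(s)))
                continue
            if best is None or fit.aic < best.aic - 1e-12:
                best = fit
    if best is None:
        raise RuntimeError(f"no converged Geyer fit; failed combinations: {failures}")
    return best
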