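"""Geyer saturation process: statistic, conditional intensity, simulation,
quadrature, pseudolikelihood fitting, and profile selection."""

import numpy as np
import pytest
from scipy import stats

from histospat.geometry import (
    InsufficientPointsError,
    PointPattern,
    Window,
    nearest_neighbor_distances,
    simulate_csr,
)
from histospat.geyer import (
    GeyerParams,
    berman_turner_quadrature,
    candidate_radii,
    conditional_intensity,
    fit_geyer,
    make_dummy_grid,
    profile_fit,
    saturation_statistic,
    simulate_geyer,
)

W200 = Window(side=200.0)


class TestSaturationStatistic:
    def test_no_close_pairs(self):
        p = PointPattern(W200, np.array([[10.0, 10.0], [100.0, 100.0]]))
        assert saturation_statistic(p, 5.0, 1) == 0.0

    def test_one_close_pair(self):
        p = PointPattern(W200, np.array([[10.0, 10.0], [15.0, 10.0]]))
        assert saturation_statistic(p, 10.0, 1) == 2.0

    def test_triangle_saturation_arithmetic(self):
        p = PointPattern(W200, np.array([[10.0, 10.0], [12.0, 10.0], [11.0, 12.0]]))
        assert saturation_statistic(p, 50.0, 1) == 3.0
        assert saturation_statistic(p, 50.0, 2) == 6.0


class TestConditionalIntensity:
    def test_poisson_reduction_constant_beta(self):
        p = PointPattern(W200, np.random.default_rng(0).uniform(0, 200, (20, 2)))
        prm = GeyerParams(beta=3e-4, gamma=1.0, r=10.0, sat=2)
        for u in [(5.0, 5.0), (100.0, 100.0), (199.0, 3.0)]:
            assert conditional_intensity(u, p, prm) == pytest.approx(3e-4)

    def test_far_location_equals_beta(self):
        p = PointPattern(W200, np.array([[10.0, 10.0], [12.0, 10.0]]))
        prm = GeyerParams(beta=2e-4, gamma=1.7, r=8.0, sat=1)
        assert conditional_intensity((150.0, 150.0), p, prm) == pytest.approx(2e-4)

    def test_outside_window_rejected(self):
        p = PointPattern(W200, np.array([[10.0, 10.0], [12.0, 10.0]]))
        prm = GeyerParams(beta=2e-4, gamma=1.7, r=8.0, sat=1)
        with pytest.raises(ValueError):
            conditional_intensity((500.0, 500.0), p, prm)

    def test_u_difference_oracle_1000_configs(self):
        """λ(u;x) must equal β γ^(U(x∪u) − U(x)) with both U values computed
        independently by the saturation statistic."""
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = int(rng.integers(2, 15))
            pts = rng.uniform(0, 200, (n, 2))
            p = PointPattern(W200, pts)
            prm = GeyerParams(
                beta=float(rng.uniform(1e-5, 1e-3)),
                gamma=float(rng.uniform(0.2, 3.0)),
                r=float(rng.uniform(5.0, 60.0)),
                sat=int(rng.integers(1, 4)),
            )
            u = rng.uniform(0, 200, 2)
            lam = conditional_intensity(u, p, prm)
            dU = saturation_statistic(
                PointPattern(W200, np.vstack([pts, u])), prm.r, prm.sat
            ) - saturation_statistic(p, prm.r, prm.sat)
            assert lam == pytest.approx(prm.beta * prm.gamma**dU, rel=1e-10)


class TestSimulation:
    def test_poisson_reduction_count_distribution(self, default_window):
        """At γ = 1 the chain must leave the Poisson(β|W|) law invariant."""
        prm = GeyerParams(beta=7e-4, gamma=1.0, r=10.0, sat=2)
        counts = np.array(
            [len(simulate_geyer(default_window, prm, n_iter=20_000, seed=s)) for s in range(200)]
        )
        mu = prm.beta * default_window.area
        assert abs(counts.mean() - mu) < 3 * np.sqrt(mu / 200)
        # chi-square goodness of fit against Poisson on binned counts
        edges = stats.poisson.ppf([0.0, 0.2, 0.4, 0.6, 0.8, 1.0], mu)
        edges[0], edges[-1] = -np.inf, np.inf
        obs = np.histogram(counts, bins=edges)[0]
        exp = np.diff(stats.poisson.cdf(edges, mu)) * len(counts)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, len(obs) - 1) > 0.01

    def test_clustering_regime_reduces_nn_distance(self, default_window):
        prm = GeyerParams(beta=4e-4, gamma=1.5, r=10.0, sat=2)
        rng = np.random.default_rng(2)
        nn_g, nn_c = [], []
        for s in range(10):
            pg = simulate_geyer(default_window, prm, seed=s)
            nn_g.append(nearest_neighbor_distances(pg).mean())
            pc = simulate_csr(default_window, len(pg) / default_window.area, rng)
            nn_c.append(nearest_neighbor_distances(pc).mean())
        assert np.mean(nn_g) < np.mean(nn_c)

    def test_inhibition_regime_reduces_close_pairs(self, default_window):
        prm = GeyerParams(beta=7e-4, gamma=0.2, r=15.0, sat=1)
        rng = np.random.default_rng(3)
        pairs_g, pairs_c = [], []
        for s in range(8):
            pg = simulate_geyer(default_window, prm, seed=s)
            pairs_g.append(saturation_statistic(pg, 15.0, 10**9) / 2)
            pc = simulate_csr(default_window, len(pg) / default_window.area, rng)
            pairs_c.append(saturation_statistic(pc, 15.0, 10**9) / 2)
        assert np.mean(pairs_g) < np.mean(pairs_c)

    def test_points_respect_holes(self, holed_window):
        prm = GeyerParams(beta=5e-4, gamma=1.3, r=9.0, sat=2)
        p = simulate_geyer(holed_window, prm, seed=4)
        assert holed_window.contains(p.points).all()

    def test_invalid_n_iter(self, default_window):
        with pytest.raises(ValueError):
            simulate_geyer(default_window, GeyerParams(1e-4, 1.0, 5.0, 1), n_iter=0)


class TestQuadrature:
    def test_mass_conservation(self, default_window):
        p = simulate_csr(default_window, 3e-4, seed=5, mark="tumor")
        q = berman_turner_quadrature(p)
        assert q.weights.sum() == pytest.approx(default_window.area, rel=1e-3)

    def test_mass_conservation_with_holes(self, holed_window):
        p = simulate_csr(holed_window, 3e-4, seed=6, mark="tumor")
        q = berman_turner_quadrature(p)
        assert q.weights.sum() == pytest.approx(holed_window.area, rel=1e-3)

    def test_empty_pattern_dummy_only(self, default_window):
        q = berman_turner_quadrature(PointPattern(default_window, np.empty((0, 2))))
        assert not q.is_data.any()
        assert q.weights.sum() == pytest.approx(default_window.area, rel=1e-3)

    def test_spacing_larger_than_window_rejected(self, default_window):
        p = simulate_csr(default_window, 3e-4, seed=7, mark="tumor")
        with pytest.raises(ValueError):
            berman_turner_quadrature(p, spacing=1000.0)

    def test_refinement_stability(self, default_window):
        """Halving the dummy spacing moves (β̂, γ̂) by < 2%."""
        prm = GeyerParams(beta=5.4e-4, gamma=1.5, r=10.0, sat=2)
        p = simulate_geyer(default_window, prm, seed=8)
        f1 = fit_geyer(p, 10.0, 2, spacing=default_window.side / 128)
        f2 = fit_geyer(p, 10.0, 2, spacing=default_window.side / 256)
        assert abs(f2.params.gamma - f1.params.gamma) / f1.params.gamma < 0.02
        assert abs(f2.params.beta - f1.params.beta) / f1.params.beta < 0.02


class TestFitting:
    def test_csr_gamma_near_one(self, default_window):
        gams = [
            fit_geyer(simulate_csr(default_window, 7e-4, seed=s, mark="tumor"), 9.0, 2).params.gamma
            for s in range(50)
        ]
        assert 0.85 <= np.median(gams) <= 1.15

    def test_parameter_recovery_gamma(self, default_window):
        prm = GeyerParams(beta=5.4e-4, gamma=1.5, r=10.0, sat=2)
        gams = [
            fit_geyer(simulate_geyer(default_window, prm, seed=s), 10.0, 2).params.gamma
            for s in range(50)
        ]
        assert abs(np.median(gams) - 1.5) <= 0.2

    def test_optimum_beats_poisson_submodel_on_clustered_data(self, default_window):
        import math

        prm = GeyerParams(beta=5.4e-4, gamma=1.6, r=9.0, sat=2)
        p = simulate_geyer(default_window, prm, seed=9)
        fit = fit_geyer(p, 9.0, 2)
        # log PL of the best (beta, gamma=1) fit: homogeneous Poisson MPLE
        n = len(p)
        area = default_window.area
        log_pl_pois = n * math.log(n / area) - n
        assert fit.log_pseudolikelihood >= log_pl_pois

    def test_insufficient_points(self, default_window):
        p = PointPattern(default_window, np.random.default_rng(0).uniform(0, 750, (5, 2)))
        with pytest.raises(InsufficientPointsError):
            fit_geyer(p, 10.0, 1)


class TestCandidateRadii:
    def test_equal_nn_distances_single_candidate(self):
        # square lattice: every NN distance is the lattice step
        g = np.arange(10.0, 200.0, 20.0)
        xs, ys = np.meshgrid(g, g)
        p = PointPattern(W200, np.column_stack([xs.ravel(), ys.ravel()]))
        r = candidate_radii(p)
        np.testing.assert_allclose(r, [20.0])

    def test_decile_arithmetic_on_uniform_vector(self):
        # points on a line at exponentially growing gaps -> NN vector known
        pts = np.column_stack([np.linspace(5, 195, 100), np.full(100, 100.0)])
        p = PointPattern(W200, pts)
        nn = nearest_neighbor_distances(p)
        r = candidate_radii(p)
        np.testing.assert_allclose(r, np.unique(np.quantile(nn, np.arange(0.1, 0.91, 0.1))))

    def test_candidates_within_nn_range(self, default_window):
        p = simulate_csr(default_window, 5e-4, seed=10, mark="tumor")
        nn = nearest_neighbor_distances(p)
        r = candidate_radii(p)
        assert (r >= nn.min() - 1e-12).all() and (r <= nn.max() + 1e-12).all()

    def test_coincident_points_rejected(self):
        p = PointPattern(W200, np.tile([[50.0, 50.0]], (5, 1)))
        with pytest.raises(ValueError):
            candidate_radii(p)


class TestProfileFit:
    def test_recovers_interaction_radius(self, default_window):
        prm = GeyerParams(beta=5.4e-4, gamma=1.5, r=10.0, sat=2)
        selected = []
        for s in range(50):
            p = simulate_geyer(default_window, prm, seed=s)
            best = profile_fit(p, r_grid=[6.0, 8.0, 10.0, 12.0, 14.0])
            selected.append(best.params.r)
        vals, counts = np.unique(selected, return_counts=True)
        modal_r = vals[np.argmax(counts)]
        assert abs(modal_r - 10.0) <= 2.0  # within one grid step

    def test_single_cell_grid_returns_that_fit(self, default_window):
        p = simulate_csr(default_window, 5e-4, seed=11, mark="tumor")
        best = profile_fit(p, r_grid=[12.0], sats=(2,))
        assert best.params.r == 12.0 and best.params.sat == 2

    def test_returned_fit_is_aic_argmin(self, default_window):
        p = simulate_csr(default_window, 5e-4, seed=12, mark="tumor")
        grid = [5.0, 10.0, 15.0]
        best = profile_fit(p, r_grid=grid)
        for r in grid:
            for s in (1, 2, 3):
                f = fit_geyer(p, r, s)
                if f.converged:
                    assert best.aic <= f.aic + 1e-9
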