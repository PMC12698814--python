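"""Trait probability densities, bandwidths and functional indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafvar import (
    bootstrap_tree_means,
    estimate_tpd,
    fdiv,
    fric,
    intraspecific_overlap,
    make_grid,
    overlap,
    plugin_bandwidth,
    population_tpd,
    tree_tpd,
)
from leafvar.tpd import TPD, TraitGrid


def brute_force_tpd(points, grid, H, alpha=0.95):
    """Independent double-loop kernel estimate with explicit thresholding."""
    points = np.atleast_2d(points)
    H = np.atleast_2d(H)
    d = points.shape[1]
    Hinv = np.linalg.inv(H)
    norm = (2 * np.pi) ** (-d / 2) / np.sqrt(np.linalg.det(H))
    dens = np.zeros(grid.n_cells)
    for i, c in enumerate(grid.centers):
        acc = 0.0
        for x in points:
            diff = c - x
            acc += np.exp(-0.5 * diff @ Hinv @ diff)
        dens[i] = norm * acc / len(points)
    prob = dens * grid.cell_volume
    prob /= prob.sum()
    order = np.argsort(prob, kind="stable")
    cum = np.cumsum(prob[order])
    prob[order[cum <= (1 - alpha) + 1e-12]] = 0.0
    return prob / prob.sum()


class TestGrid:
    def test_cell_count_and_volume(self, rng):
        grid = make_grid(rng.standard_normal((30, 2)), cells_per_dim=50)
        assert grid.n_cells == 2500
        widths = [e[1] - e[0] for e in grid.edges]
        assert grid.cell_volume == pytest.approx(widths[0] * widths[1])

    def test_zero_padding_matches_data_bounds(self, rng):
        pts = rng.standard_normal((30, 2))
        grid = make_grid(pts, pad_frac=0.0)
        for d in range(2):
            assert grid.edges[d][0] == pytest.approx(pts[:, d].min())
            assert grid.edges[d][-1] == pytest.approx(pts[:, d].max())

    def test_zero_range_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError):
            make_grid(pts)


class TestBandwidth:
    def test_scaling_equivariance(self, rng):
        pts = rng.standard_normal((40, 2))
        H1 = plugin_bandwidth(pts).H
        H2 = plugin_bandwidth(3.0 * pts).H
        assert np.allclose(H2, 9.0 * H1, rtol=1e-4)

    def test_shrinks_with_sample_size(self):
        traces_small, traces_big = [], []
        for s in range(20):
            rng = np.random.default_rng(s)
            traces_small.append(np.trace(plugin_bandwidth(rng.standard_normal((50, 2))).H))
            traces_big.append(np.trace(plugin_bandwidth(rng.standard_normal((5000, 2))).H))
        assert np.mean(traces_big) < np.mean(traces_small)

    def test_collinear_points_fall_back(self):
        x = np.arange(12.0)
        res = plugin_bandwidth(np.column_stack([x, 2 * x]))
        assert res.fallback
        assert np.all(np.linalg.eigvalsh(res.H) > 0)

    def test_tiny_sample_falls_back(self, rng):
        res = plugin_bandwidth(rng.standard_normal((4, 2)))
        assert res.fallback

    def test_symmetric_positive_definite(self, rng):
        H = plugin_bandwidth(rng.standard_normal((100, 2))).H
        assert np.allclose(H, H.T)
        assert np.all(np.linalg.eigvalsh(H) > 0)


class TestEstimateTPD:
    def test_matches_brute_force_oracle(self, rng):
        pts = rng.standard_normal((18, 2))
        grid = make_grid(pts, cells_per_dim=20)
        H = plugin_bandwidth(pts).H
        t = estimate_tpd(pts, grid, H, alpha=0.95)
        expected = brute_force_tpd(pts, grid, H, alpha=0.95)
        assert np.abs(t.prob - expected).max() < 1e-10

    def test_oracle_match_one_dimension(self, rng):
        pts = rng.standard_normal((15, 1))
        grid = make_grid(pts, cells_per_dim=20)
        H = plugin_bandwidth(pts).H
        t = estimate_tpd(pts, grid, H)
        assert np.abs(t.prob - brute_force_tpd(pts, grid, H)).max() < 1e-10

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000), alpha=st.sampled_from([0.8, 0.95, 1.0]))
    def test_sums_to_one_and_nonnegative(self, seed, alpha):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((12, 2))
        grid = make_grid(pts, cells_per_dim=15)
        t = estimate_tpd(pts, grid, alpha=alpha)
        assert t.prob.sum() == pytest.approx(1.0, abs=1e-9)
        assert (t.prob >= 0).all()

    def test_alpha_one_keeps_all_cells(self, rng):
        pts = rng.standard_normal((12, 2))
        grid = make_grid(pts, cells_per_dim=10)
        t = estimate_tpd(pts, grid, alpha=1.0)
        assert (t.prob > 0).all()

    def test_separated_clusters_give_disjoint_regions(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.05, (10, 2))
        b = rng.normal(8, 0.05, (10, 2))
        pts = np.vstack([a, b])
        grid = make_grid(pts, cells_per_dim=40)
        t = estimate_tpd(pts, grid, alpha=0.95)
        occ2d = (t.prob > 0).reshape(grid.shape)
        rows = np.where(occ2d.any(axis=1))[0]
        # occupied rows split into two separated groups
        assert np.any(np.diff(rows) > 5)


class TestIndices:
    def _uniform_tpd(self, prob_cells):
        grid = TraitGrid(edges=(np.linspace(0, 5, 6), np.linspace(0, 5, 6)))
        p = np.zeros(grid.n_cells)
        p[prob_cells] = 1.0
        return TPD(grid, p / p.sum(), np.eye(2), 1.0, 0)

    def test_fric_counts_occupied_cells(self):
        t = self._uniform_tpd([0, 3, 7, 12])
        assert fric(t) == pytest.approx(4 * t.grid.cell_volume)

    def test_fric_monotone_in_support(self):
        small = self._uniform_tpd([0, 3])
        big = self._uniform_tpd([0, 3, 7, 12])
        assert fric(small) <= fric(big)

    def test_fric_nonincreasing_in_alpha(self, rng):
        pts = rng.standard_normal((15, 2))
        grid = make_grid(pts, cells_per_dim=20)
        H = plugin_bandwidth(pts).H
        assert fric(estimate_tpd(pts, grid, H, alpha=0.95)) <= fric(
            estimate_tpd(pts, grid, H, alpha=1.0)
        )

    def test_fdiv_one_for_equidistant_ring(self):
        grid = TraitGrid(edges=(np.linspace(-2.5, 2.5, 6), np.linspace(-2.5, 2.5, 6)))
        centers = grid.centers
        dist = np.sqrt((centers**2).sum(axis=1))
        ring = np.isclose(dist, dist[np.argmin(np.abs(dist - 1.5))])
        p = ring / ring.sum()
        t = TPD(grid, p, np.eye(2), 1.0, 0)
        assert fdiv(t) == pytest.approx(1.0)

    def test_fdiv_low_when_mass_central(self):
        grid = TraitGrid(edges=(np.linspace(0, 5, 6), np.linspace(0, 5, 6)))
        centers = grid.centers
        g = centers.mean(axis=0)
        nearest = np.argmin(((centers - g) ** 2).sum(axis=1))
        p = np.full(grid.n_cells, 1e-9)
        p[nearest] = 1.0
        t = TPD(grid, p / p.sum(), np.eye(2), 1.0, 0)
        assert fdiv(t) < 0.5

    def test_fdiv_uniform_closed_form(self):
        t = self._uniform_tpd(list(range(25)))
        centers = t.grid.centers
        g = centers.mean(axis=0)
        dist = np.sqrt(((centers - g) ** 2).sum(axis=1))
        dbar = dist.mean()
        expected = dbar / (np.abs(dist - dbar).mean() + dbar)
        assert fdiv(t) == pytest.approx(expected)

    def test_fdiv_single_cell_rejected(self):
        t = self._uniform_tpd([5])
        with pytest.raises(ValueError):
            fdiv(t)

    def test_overlap_identities(self, rng):
        pts = rng.standard_normal((12, 2))
        grid = make_grid(pts, cells_per_dim=15)
        a = estimate_tpd(pts, grid)
        b = estimate_tpd(pts + 0.5, grid)
        assert overlap(a, a) == pytest.approx(1.0)
        assert overlap(a, b) == pytest.approx(overlap(b, a))
        disjoint_a = self._uniform_tpd([0, 1])
        disjoint_b = self._uniform_tpd([20, 21])
        assert overlap(disjoint_a, disjoint_b) == 0.0

    def test_overlap_grid_mismatch_rejected(self, rng):
        pts = rng.standard_normal((12, 2))
        a = estimate_tpd(pts, make_grid(pts, 10))
        b = estimate_tpd(pts, make_grid(pts, 12))
        with pytest.raises(ValueError):
            overlap(a, b)


class TestUnits:
    def test_degenerate_tree_gets_fallback_and_tiny_fric(self):
        pts = np.tile([1.0, 2.0], (12, 1))
        grid = TraitGrid(edges=(np.linspace(0, 3, 31), np.linspace(0, 3, 31)))
        t = tree_tpd(pts, grid)
        assert t.fallback_bandwidth
        assert fric(t) <= 4 * grid.cell_volume

    def test_identical_trees_overlap_one(self, rng):
        pts = rng.standard_normal((12, 2))
        grid = make_grid(pts, 20)
        a, b = tree_tpd(pts, grid), tree_tpd(pts, grid)
        assert overlap(a, b) == pytest.approx(1.0)

    def test_fric_grows_with_dispersion(self, rng):
        pts = rng.standard_normal((12, 2))
        grid = make_grid(np.vstack([pts, 2 * pts]), 30)
        assert fric(tree_tpd(2 * pts, grid)) > fric(tree_tpd(pts, grid))

    def test_too_few_leaves_rejected(self, rng):
        grid = make_grid(rng.standard_normal((10, 2)), 10)
        with pytest.raises(ValueError):
            tree_tpd(rng.standard_normal((4, 2)), grid)

    def test_population_min_trees_boundary(self, rng):
        pts = rng.standard_normal((3, 2))
        grid = make_grid(rng.standard_normal((20, 2)) * 2, 20)
        population_tpd(pts, grid)  # 3 trees (mortality plot) works
        with pytest.raises(ValueError):
            population_tpd(pts[:2], grid)


class TestBootstrap:
    def test_converges_to_arithmetic_mean(self, rng):
        pts = rng.standard_normal((12, 2))
        m = bootstrap_tree_means(pts, B=10_000, seed=0)
        # Monte-Carlo SE of the mean of B bootstrap-resample means
        se = pts.std(axis=0, ddof=0) / np.sqrt(12) / np.sqrt(10_000)
        assert np.all(np.abs(m - pts.mean(axis=0)) < 3 * se)

    def test_identical_leaves_exact(self):
        pts = np.tile([0.3, -1.2], (6, 1))
        out = bootstrap_tree_means(pts, B=50, seed=1)
        assert np.allclose(out, [0.3, -1.2], rtol=0, atol=1e-12)

    def test_deterministic(self, rng):
        pts = rng.standard_normal((10, 2))
        assert np.array_equal(
            bootstrap_tree_means(pts, seed=7), bootstrap_tree_means(pts, seed=7)
        )

    def test_invalid_B_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_tree_means(rng.standard_normal((5, 2)), B=0)


class TestIntraspecificOverlap:
    def test_enumerated_mean(self):
        grid = TraitGrid(edges=(np.linspace(0, 5, 6), np.linspace(0, 5, 6)))

        def unit(cells):
            p = np.zeros(grid.n_cells)
            p[cells] = 1.0
            return TPD(grid, p / p.sum(), np.eye(2), 1.0, 0)

        a = unit([0, 1])
        b = unit([0, 1])  # identical to a
        c = unit([20, 21])  # disjoint
        assert intraspecific_overlap([a, b, c]) == pytest.approx(1.0 / 3.0)

    def test_all_identical_gives_one(self, rng):
        pts = rng.standard_normal((12, 2))
        grid = make_grid(pts, 15)
        tpds = [tree_tpd(pts, grid) for _ in range(3)]
        assert intraspecific_overlap(tpds) == pytest.approx(1.0)

    def test_single_tree_rejected(self, rng):
        pts = rng.standard_normal((12, 2))
        grid = make_grid(pts, 10)
        with pytest.raises(ValueError):
            intraspecific_overlap([tree_tpd(pts, grid)])
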