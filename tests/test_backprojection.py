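"""Searchlight back-projection: membership, t-statistics, weights,
normalization, rendering, and brute-force oracle equivalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import visuomap as vm
from visuomap.backprojection import (T_DEGENERATE_SENTINEL, backproject,
                                     cell_t_statistic, cell_weight,
                                     normalize_weights, render_heatmap,
                                     vertices_in_searchlight)


def brute_force_map(table, values, grid, radius=1.0, ecc_max=8.6):
    """Independent oracle: explicit loops, explicit mean/sd formulas."""
    gx, gy = grid.meshgrid()
    t = np.zeros(grid.shape)
    n = np.zeros(grid.shape, int)
    w = np.zeros(grid.shape)
    xs = table["x"].to_numpy()
    ys = table["y"].to_numpy()
    for iy in range(grid.shape[0]):
        for ix in range(grid.shape[1]):
            cx, cy = gx[iy, ix], gy[iy, ix]
            if np.hypot(cx, cy) > ecc_max:
                continue
            d = np.sqrt((xs - cx) ** 2 + (ys - cy) ** 2)
            inside = d < radius
            k = int(inside.sum())
            n[iy, ix] = k
            if k >= 2:
                v = values[inside]
                m = v.sum() / k
                sd = np.sqrt(((v - m) ** 2).sum() / (k - 1))
                t[iy, ix] = m / (sd / np.sqrt(k)) if sd > 0 else 0.0
                w[iy, ix] = (1.0 - d[inside] / radius).sum()
    return t, n, w


class TestMembership:
    def test_inclusion_by_distance(self):
        table = pd.DataFrame({"x": [0.5, 1.2, 0.0], "y": [0.0, 0.0, 0.0]})
        got = vertices_in_searchlight((0.0, 0.0), table, radius=1.0)
        assert list(got.index) == [0, 2]

    def test_boundary_is_strict(self):
        table = pd.DataFrame({"x": [1.0], "y": [0.0]})
        assert len(vertices_in_searchlight((0.0, 0.0), table, 1.0)) == 0

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"x": rng.uniform(-3, 3, 400),
                              "y": rng.uniform(-3, 3, 400)})
        for center in [(0.0, 0.0), (1.3, -2.1), (2.9, 2.9)]:
            d = np.hypot(table.x - center[0], table.y - center[1])
            assert len(vertices_in_searchlight(center, table)) == \
                int((d < 1.0).sum())


class TestCellT:
    @pytest.mark.parametrize("betas,expected", [
        ([1.0, -1.0], 0.0),          # zero mean
        ([3.7], 0.0),                # single vertex rule
        ([], 0.0),                   # empty cell
        ([1.0, 2.0, 3.0], 3.4641016151377544),  # mean 2, sd 1, n 3
    ])
    def test_examples(self, betas, expected):
        assert cell_t_statistic(np.array(betas)) == pytest.approx(expected)

    def test_zero_sd_returns_signed_sentinel(self):
        assert cell_t_statistic(np.array([2.0, 2.0])) == T_DEGENERATE_SENTINEL
        assert cell_t_statistic(np.array([-2.0, -2.0])) == \
            -T_DEGENERATE_SENTINEL

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=30))
    def test_matches_scipy_one_sample_t(self, betas):
        betas = np.asarray(betas)
        if betas.std(ddof=1) == 0:
            return
        expected = stats.ttest_1samp(betas, 0.0).statistic
        assert cell_t_statistic(betas) == pytest.approx(expected, rel=1e-12)


class TestCellWeight:
    def test_two_vertices_at_center(self):
        assert cell_weight(np.array([0.0, 0.0])) == 2.0

    def test_single_vertex_rule(self):
        assert cell_weight(np.array([0.3])) == 0.0

    def test_center_plus_half_radius(self):
        assert cell_weight(np.array([0.0, 0.5]), radius=1.0) == 1.5

    def test_reciprocal_scheme(self):
        assert cell_weight(np.array([0.5, 0.5]), radius=1.0,
                           scheme="reciprocal") == 4.0

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            cell_weight(np.array([0.1, 0.2]), scheme="quadratic")


class TestNormalizeWeights:
    def test_p25_maps_to_one(self):
        raw = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        p25 = np.percentile(raw, 25)
        w = normalize_weights(raw)
        assert w[1] == pytest.approx(min(1.0 / p25, 1.0))
        assert w[0] == 0.0

    def test_values_above_p25_clipped(self):
        raw = np.array([1.0, 1.0, 1.0, 3.0])
        w = normalize_weights(raw)
        assert w[3] == 1.0

    def test_degenerate_all_zero_p25(self):
        raw = np.array([0.0, 0.0, 0.0, 0.0, 5.0])
        w = normalize_weights(raw)
        assert w[4] == 1.0
        assert np.all(w[:4] == 0.0)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        raw = rng.exponential(2.0, 500)
        w = normalize_weights(raw)
        assert w.min() >= 0.0 and w.max() <= 1.0


@pytest.fixture(scope="module")
def small_map(diamond_masks, v1_population):
    from visuomap.synth import simulate_differential_betas
    table = simulate_differential_betas(
        v1_population.iloc[:600], diamond_masks,
        {"segments": -0.5, "background": 0.5}, noise_sd=0.5, seed=1)
    est = vm.SearchlightBackProjection(extent=4.0, step=0.25)
    return table, est.fit(table).map_


@pytest.fixture(scope="module")
def rendered_map(v1_population, diamond_masks):
    from visuomap.synth import simulate_differential_betas
    table = simulate_differential_betas(
        v1_population.iloc[:800], diamond_masks,
        {"segments": -0.5, "background": 0.5}, noise_sd=0.3, seed=0)
    return backproject(table)


class TestBackProjection:

    def test_oracle_equivalence(self, small_map):
        """Per-cell t, n and raw weight equal an explicit-loop oracle."""
        table, bp = small_map
        t, n, w = brute_force_map(table, table["dbeta"].to_numpy(),
                                  bp.grid, radius=1.0, ecc_max=8.6)
        assert np.array_equal(n, bp.n)
        assert np.abs(t - bp.t).max() < 1e-10
        assert np.abs(w - bp.w_raw).max() < 1e-10

    def test_single_vertex_cells_zeroed(self, small_map):
        _, bp = small_map
        single = bp.n == 1
        assert np.all(bp.t[single] == 0.0)
        assert np.all(bp.w_raw[single] == 0.0)
        assert np.all(bp.w[single] == 0.0)

    def test_grid_has_171_centers_per_axis(self, v1_population):
        est = vm.SearchlightBackProjection()
        grid = est._grid()
        assert grid.shape == (171, 171)

    def test_traversal_restricted_to_ecc_cap(self, small_map):
        _, bp = small_map
        ecc = bp.grid.eccentricity()
        assert np.all(ecc[bp.traversed] <= 8.6)
        assert np.all(bp.t[~bp.traversed] == 0.0)

    def test_single_participant_equals_pooled_of_one(self, small_map):
        table, bp = small_map
        pooled = backproject({"P1": table}, extent=4.0, step=0.25)
        assert np.array_equal(pooled.t, bp.t)

    def test_mirror_symmetric_input_gives_symmetric_map(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0.2, 3.5, 300)
        y = rng.uniform(-3.5, 3.5, 300)
        v = rng.normal(0, 1, 300)
        table = pd.DataFrame({"x": np.r_[x, -x], "y": np.r_[y, y],
                              "dbeta": np.r_[v, v]})
        bp = backproject(table, extent=4.0, step=0.5)
        assert np.abs(bp.t - bp.t[:, ::-1]).max() < 1e-9

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"x": rng.uniform(-2, 2, 200),
                              "y": rng.uniform(-2, 2, 200),
                              "dbeta": rng.normal(size=200)})
        shifted = table.assign(x=table.x + 0.5)
        a = vm.SearchlightBackProjection(extent=3.0, step=0.5,
                                         ecc_max=np.inf).fit(table).map_
        b = vm.SearchlightBackProjection(extent=3.0, step=0.5,
                                         ecc_max=np.inf).fit(shifted).map_
        # shifting vertices and reading one grid column over are identical
        assert np.allclose(b.t[:, 1:], a.t[:, :-1], atol=1e-10)
        assert np.allclose(b.w_raw[:, 1:], a.w_raw[:, :-1], atol=1e-10)

    def test_adding_mean_vertex_does_not_decrease_abs_t(self):
        rng = np.random.default_rng(4)
        betas = rng.normal(0.5, 1.0, 20)
        t0 = cell_t_statistic(betas)
        t1 = cell_t_statistic(np.r_[betas, betas.mean()])
        assert abs(t1) >= abs(t0) - 1e-12
        assert np.r_[betas, betas.mean()].mean() == pytest.approx(
            betas.mean())

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            vm.SearchlightBackProjection().fit(
                pd.DataFrame(columns=["x", "y", "dbeta"]))


class TestRender:

    def test_image_matches_grid_shape(self, rendered_map):
        img = render_heatmap(rendered_map, cap=25.0)
        assert img.shape == (171, 171, 3)

    def test_t_clipped_at_cap(self, rendered_map):
        """Cells beyond the cap render at the cap color."""
        bp = rendered_map
        capped = render_heatmap(bp, cap=0.5)
        # find a strongly positive, fully saturated cell
        iy, ix = np.unravel_index(
            np.argmax(np.where(bp.w >= 1.0, bp.t, -np.inf)), bp.t.shape)
        assert bp.t[iy, ix] > 0.5
        from matplotlib import pyplot as plt
        top_color = plt.get_cmap("RdBu_r")(1.0)[:3]
        assert np.allclose(capped[iy, ix], top_color, atol=1e-6)

    def test_zero_weight_cells_background(self, rendered_map):
        bp = rendered_map
        img = render_heatmap(bp, cap=25.0, background=(1.0, 1.0, 1.0))
        zero_w = (bp.w == 0) | ~bp.traversed
        assert np.allclose(img[zero_w], 1.0)

    def test_nonpositive_cap_rejected(self, rendered_map):
        with pytest.raises(ValueError):
            render_heatmap(rendered_map, cap=0.0)
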