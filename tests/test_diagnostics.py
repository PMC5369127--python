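"""Composite construction, block aggregation and the diagnostic suite."""

import numpy as np
import pytest
from shapely.geometry import box

from cumrisk import build_referent_grid
from cumrisk.diagnostics import (composite_indicator,
                                 contribution_above_percentile,
                                 correlation_matrix, fit_rank_distribution,
                                 heteroscedasticity_ratio,
                                 population_weighted_aggregate,
                                 transform_slope)
from cumrisk.grid import RasterField, ZoneMap
from cumrisk.standardize import standardize_values
from conftest import make_standardized
from oracle_utils import brute_force_spearman


@pytest.fixture
def two_cell_grid():
    return build_referent_grid((0, 0, 2000, 1000), 1000)


class TestCompositeIndicator:
    def test_cellwise_addition(self, two_cell_grid):
        a = make_standardized(two_cell_grid, [[0.2, 0.8]], dimension="a")
        b = make_standardized(two_cell_grid, [[0.3, 0.1]], dimension="b")
        comp = composite_indicator([a, b])
        np.testing.assert_allclose(comp.field.values, [[0.5, 0.9]])

    def test_k_identical_fields_scale(self, small_grid):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 1, small_grid.n_cells)
        fields = [make_standardized(small_grid, scores, dimension=f"d{i}")
                  for i in range(4)]
        comp = composite_indicator(fields)
        np.testing.assert_allclose(comp.field.values,
                                   4 * fields[0].field.values, atol=1e-12)
        assert comp.field.values.max() <= 4.0

    def test_exact_decomposition(self, small_grid):
        rng = np.random.default_rng(1)
        fields = [make_standardized(small_grid,
                                    rng.uniform(0, 1, small_grid.n_cells),
                                    dimension=f"d{i}") for i in range(4)]
        comp = composite_indicator(fields)
        total = sum(f.field.values for f in fields)
        np.testing.assert_allclose(comp.field.values, total, atol=1e-12)

    def test_mixed_methods_rejected(self, two_cell_grid):
        a = make_standardized(two_cell_grid, [[0.2, 0.8]],
                              method="normal_score")
        b = make_standardized(two_cell_grid, [[0.3, 0.1]],
                              method="percentile_rank")
        with pytest.raises(ValueError, match="mixed"):
            composite_indicator([a, b])


class TestPopulationWeightedAggregate:
    def _blocks(self, grid):
        xmin, ymin, xmax, ymax = grid.extent
        mid = (xmin + xmax) / 2
        return ZoneMap(ids=["west", "east"],
                       polygons=[box(xmin, ymin, mid, ymax),
                                 box(mid, ymin, xmax, ymax)],
                       attributes=[0.0, 0.0])

    def test_uniform_population_gives_plain_mean(self, small_grid):
        rng = np.random.default_rng(2)
        comp = composite_indicator(
            [make_standardized(small_grid, rng.uniform(0, 1, small_grid.n_cells),
                               dimension=f"d{i}") for i in range(2)])
        pop = RasterField(grid=small_grid, values=np.ones(small_grid.shape))
        out = population_weighted_aggregate(comp, pop, self._blocks(small_grid))
        west = comp.field.values[:, :5].mean()
        assert out[out.block_id == "west"].value.iloc[0] == pytest.approx(west)

    def test_single_populated_cell_dominates(self, two_cell_grid):
        comp = composite_indicator(
            [make_standardized(two_cell_grid, [[0.9, 0.1]], dimension="a"),
             make_standardized(two_cell_grid, [[0.9, 0.1]], dimension="b")])
        pop = RasterField(grid=two_cell_grid, values=np.array([[0.0, 50.0]]))
        blocks = ZoneMap(ids=["all"], polygons=[box(0, 0, 2000, 1000)],
                         attributes=[0.0])
        out = population_weighted_aggregate(comp, pop, blocks)
        assert out.value.iloc[0] == pytest.approx(0.2)

    def test_weighted_mean_arithmetic(self, two_cell_grid):
        comp = composite_indicator(
            [make_standardized(two_cell_grid, [[0.5, 1.0]], dimension=d)
             for d in "abcd"])
        # composites are (2, 4); population (1, 3) → weighted mean 3.5
        pop = RasterField(grid=two_cell_grid, values=np.array([[1.0, 3.0]]))
        blocks = ZoneMap(ids=["all"], polygons=[box(0, 0, 2000, 1000)],
                         attributes=[0.0])
        out = population_weighted_aggregate(comp, pop, blocks)
        assert out.value.iloc[0] == pytest.approx(3.5)

    def test_zero_population_block_flagged(self, small_grid):
        rng = np.random.default_rng(3)
        comp = composite_indicator(
            [make_standardized(small_grid, rng.uniform(0, 1, small_grid.n_cells),
                               dimension=f"d{i}") for i in range(2)])
        pop = RasterField(grid=small_grid, values=np.zeros(small_grid.shape))
        out = population_weighted_aggregate(comp, pop, self._blocks(small_grid))
        assert out.zero_population.all()
        assert out.value.between(comp.field.values.min(),
                                 comp.field.values.max()).all()

    def test_weighted_means_bounded_by_member_extremes(self, small_grid):
        rng = np.random.default_rng(4)
        comp = composite_indicator(
            [make_standardized(small_grid, rng.uniform(0, 1, small_grid.n_cells),
                               dimension=f"d{i}") for i in range(3)])
        pop = RasterField(grid=small_grid,
                          values=rng.lognormal(0, 1, small_grid.shape))
        out = population_weighted_aggregate(comp, pop, self._blocks(small_grid))
        assert (out.value >= comp.field.values.min() - 1e-12).all()
        assert (out.value <= comp.field.values.max() + 1e-12).all()


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self, small_grid):
        rng = np.random.default_rng(5)
        f = RasterField(grid=small_grid, values=rng.normal(size=small_grid.shape))
        out = correlation_matrix([f, f], names=["a", "b"])
        assert out.loc["a", "b"] == pytest.approx(1.0)

    def test_negation_gives_minus_one(self, small_grid):
        rng = np.random.default_rng(6)
        v = rng.normal(size=small_grid.shape)
        a = RasterField(grid=small_grid, values=v)
        b = RasterField(grid=small_grid, values=-v)
        out = correlation_matrix([a, b], names=["a", "b"])
        assert out.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_brute_force_spearman(self):
        g = build_referent_grid((0, 0, 6000, 5000), 1000)   # 30 cells
        rng = np.random.default_rng(7)
        va = rng.integers(0, 10, g.shape).astype(float)     # with ties
        vb = rng.normal(size=g.shape)
        out = correlation_matrix([RasterField(grid=g, values=va),
                                  RasterField(grid=g, values=vb)],
                                 names=["a", "b"])
        expected = brute_force_spearman(va.ravel(), vb.ravel())
        assert out.loc["a", "b"] == pytest.approx(expected, abs=1e-12)

    def test_constant_field_reported_missing(self, small_grid):
        rng = np.random.default_rng(8)
        a = RasterField(grid=small_grid, values=np.ones(small_grid.shape))
        b = RasterField(grid=small_grid, values=rng.normal(size=small_grid.shape))
        out = correlation_matrix([a, b], names=["a", "b"])
        assert np.isnan(out.loc["a", "b"])


class TestContribution:
    def test_identical_fields_share_equally(self, small_grid):
        rng = np.random.default_rng(9)
        scores = rng.uniform(0.1, 1, small_grid.n_cells)
        comp = composite_indicator(
            [make_standardized(small_grid, scores, dimension=f"d{i}")
             for i in range(4)])
        out = contribution_above_percentile(comp, 0.9)
        np.testing.assert_allclose(out.contribution_pct, 25.0, atol=1e-9)

    def test_dominant_field_takes_all(self, small_grid):
        rng = np.random.default_rng(10)
        scores = rng.uniform(0.1, 1, small_grid.n_cells)
        comp = composite_indicator(
            [make_standardized(small_grid, scores, dimension="big"),
             make_standardized(small_grid, np.zeros(small_grid.n_cells),
                               dimension="null")])
        out = contribution_above_percentile(comp, 0.9).set_index("dimension")
        assert out.loc["big", "contribution_pct"] == pytest.approx(100.0)
        assert out.loc["null", "contribution_pct"] == pytest.approx(0.0)

    @pytest.mark.parametrize("pooled", [False, True])
    def test_contributions_sum_to_hundred(self, small_grid, pooled):
        rng = np.random.default_rng(11)
        comp = composite_indicator(
            [make_standardized(small_grid, rng.uniform(0, 1, small_grid.n_cells),
                               dimension=f"d{i}") for i in range(4)])
        out = contribution_above_percentile(comp, 0.9, pooled=pooled)
        assert out.contribution_pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_bad_quantile_rejected(self, small_grid):
        comp = composite_indicator(
            [make_standardized(small_grid,
                               np.linspace(0, 1, small_grid.n_cells),
                               dimension=f"d{i}") for i in range(2)])
        with pytest.raises(ValueError):
            contribution_above_percentile(comp, 1.2)


class TestTransformSlope:
    def test_linear_curve_constant_slope(self):
        raw = np.linspace(0, 10, 101)
        scores = 0.08 * raw + 0.1
        slopes = transform_slope(raw, scores, window=11)
        valid = slopes[~np.isnan(slopes)]
        np.testing.assert_allclose(valid, 0.08, atol=1e-12)

    def test_constant_scores_zero_slope(self):
        raw = np.linspace(0, 10, 51)
        slopes = transform_slope(raw, np.full(51, 0.4), window=7)
        valid = slopes[~np.isnan(slopes)]
        np.testing.assert_allclose(valid, 0.0, atol=1e-15)

    def test_window_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            transform_slope(np.arange(5.0), np.arange(5.0), window=7)

    def test_percentile_flattens_top_decile_of_heavy_tail(self):
        from cumrisk import generate_tail_contrast_pair

        heavy, _ = generate_tail_contrast_pair(2000, seed=5)
        raw = np.sort(heavy)
        means = {}
        for method in ("normal_score", "percentile_rank"):
            scores, _ = standardize_values(raw, None, method)
            slopes = transform_slope(raw, scores, window=51)
            means[method] = np.nanmean(slopes[int(0.9 * len(raw)):])
        assert means["percentile_rank"] < means["normal_score"]


class TestHeteroscedasticityRatio:
    def test_hand_computed_percentile_case(self, small_grid):
        g = build_referent_grid((0, 0, 5000, 1000), 1000)
        values = np.array([[0.0, 0, 0, 5, 9]])
        bg = values == 0
        scores, bg_val = standardize_values(values, bg, "percentile_rank")
        sf = make_standardized(g, scores, dimension="water",
                               background_mask=bg, background_value=bg_val)
        assert heteroscedasticity_ratio(sf) == pytest.approx(0.3 / 0.7)

    def test_single_background_cell_is_formula_cancellation(self):
        g = build_referent_grid((0, 0, 10_000, 1000), 1000)
        values = np.concatenate([[0.0], np.arange(1.0, 10.0)])
        bg = values == 0
        scores, bg_val = standardize_values(values, bg, "percentile_rank")
        sf = make_standardized(g, scores, dimension="water",
                               background_mask=bg, background_value=bg_val)
        # Hazen numerators: (0.5/n) / (1.5/n), independent of n
        assert heteroscedasticity_ratio(sf) == pytest.approx(0.5 / 1.5)

    def test_no_background_rejected(self, small_grid):
        sf = make_standardized(small_grid,
                               np.linspace(0, 1, small_grid.n_cells))
        with pytest.raises(ValueError):
            heteroscedasticity_ratio(sf)


class TestFitRankDistribution:
    def test_normal_sample_ranked_first(self):
        for seed in range(10):
            x = np.random.default_rng(seed).normal(size=5000)
            out = fit_rank_distribution(x)
            assert out.family.iloc[0] == "normal", f"seed {seed}"

    def test_uniform_sample_ranked_first(self):
        for seed in range(10):
            x = np.random.default_rng(100 + seed).uniform(size=5000)
            out = fit_rank_distribution(x)
            assert out.family.iloc[0] == "uniform", f"seed {seed}"

    def test_ks_statistic_bounded(self):
        x = np.random.default_rng(3).lognormal(size=200)
        out = fit_rank_distribution(x)
        assert ((out.ks_statistic >= 0) & (out.ks_statistic <= 1)).all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_rank_distribution(np.arange(10.0))
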