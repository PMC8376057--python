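"""Fragmentation, diversity, distance and trend summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from habsel.landscape import GridPatchMap, Observation, PolygonPatchMap, SurveySquare
from habsel.metrics import (
    change_summary,
    diversity_table,
    patchify,
    seasonal_distance_summary,
    shannon_index,
    trend_correlation,
)
from habsel.resampling import BootstrapSpec


def brute_force_components(cells: np.ndarray, connectivity: int) -> int:
    """Independent flood-fill component count over all codes."""
    seen = np.zeros(cells.shape, dtype=bool)
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    n = 0
    for r in range(cells.shape[0]):
        for c in range(cells.shape[1]):
            if seen[r, c]:
                continue
            n += 1
            stack = [(r, c)]
            seen[r, c] = True
            while stack:
                rr, cc = stack.pop()
                for dr, dc in steps:
                    r2, c2 = rr + dr, cc + dc
                    if (0 <= r2 < cells.shape[0] and 0 <= c2 < cells.shape[1]
                            and not seen[r2, c2]
                            and cells[r2, c2] == cells[rr, cc]):
                        seen[r2, c2] = True
                        stack.append((r2, c2))
    return n


class TestPatchify:
    def test_uniform_square_is_one_patch(self, uniform_grid):
        patches = patchify(uniform_grid)
        assert patches == [("arable", pytest.approx(4.0))]  # 200 m square

    @pytest.mark.parametrize("connectivity,expected", [(4, 4), (8, 2)])
    def test_checkerboard_against_flood_fill(self, toy_square, connectivity,
                                             expected):
        cells = np.array([[0, 1], [1, 0]], dtype=np.int16)
        pmap = GridPatchMap(toy_square, 2017, "rough", cells, ("A", "B"),
                            100.0)
        patches = patchify(pmap, connectivity=connectivity)
        assert len(patches) == expected
        assert len(patches) == brute_force_components(cells, connectivity)

    def test_random_grids_match_flood_fill(self, toy_square):
        rng = np.random.default_rng(9)
        for connectivity in (4, 8):
            for _ in range(5):
                cells = rng.integers(0, 3, size=(12, 12)).astype(np.int16)
                pmap = GridPatchMap(toy_square, 2017, "rough", cells,
                                    ("A", "B", "C"), 200 / 12)
                assert (len(patchify(pmap, connectivity))
                        == brute_force_components(cells, connectivity))

    def test_patch_areas_sum_to_map_area(self, toy_square):
        rng = np.random.default_rng(10)
        cells = rng.integers(0, 4, size=(50, 50)).astype(np.int16)
        pmap = GridPatchMap(toy_square, 2017, "rough", cells,
                            ("A", "B", "C", "D"), 4.0)
        total = sum(a for _, a in patchify(pmap))
        assert total == pytest.approx(pmap.total_area_ha, abs=pmap.cell_area_ha)

    def test_polygon_patches_merge_touching_same_code(self, toy_square):
        left = box(0, 0, 100, 200)
        right = box(100, 0, 200, 200)
        merged = PolygonPatchMap(toy_square, 2017, "rough",
                                 [(left, "A"), (right, "A")])
        split = PolygonPatchMap(toy_square, 2017, "rough",
                                [(left, "A"), (right, "B")])
        assert len(patchify(merged)) == 1
        assert len(patchify(split)) == 2


class TestShannonIndex:
    @pytest.mark.parametrize("proportions,expected", [
        ([1.0], 0.0),
        ([0.5, 0.5], math.log(2)),
        ([0.25] * 4, math.log(4)),
        ({"a": 0.5, "b": 0.5, "c": 0.0}, math.log(2)),  # 0 ln 0 := 0
    ])
    def test_closed_forms(self, proportions, expected):
        assert shannon_index(proportions) == pytest.approx(expected, abs=1e-12)

    def test_negative_proportion_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([1.2, -0.2])

    def test_bounded_by_log_richness(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            k = rng.integers(2, 8)
            p = rng.dirichlet(np.ones(k))
            assert shannon_index(p) <= math.log(k) + 1e-12

    def test_maximised_only_by_uniform(self):
        assert shannon_index([0.25] * 4) > shannon_index([0.4, 0.3, 0.2, 0.1])


class TestChangeSummary:
    def test_single_square_single_patch(self, uniform_grid):
        out = change_summary({2017: {"sqA": uniform_grid}})
        row = out.iloc[0]
        assert row["avg_patches_per_unit"] == 1
        assert row["avg_patch_area_ha"] == pytest.approx(4.0)
        assert row["total_infrastructure_ha"] == 0.0

    def test_infrastructure_scope_filters_codes(self, road_grid):
        out = change_summary({2017: {"sqA": road_grid}})
        row = out.iloc[0]
        # one 10 m x 200 m road = 0.2 ha of infrastructure
        assert row["avg_infra_patches_per_unit"] == 1
        assert row["total_infrastructure_ha"] == pytest.approx(0.2)

    def test_empty_scope_year_flagged_not_zero(self, uniform_grid):
        out = change_summary({2017: {"sqA": uniform_grid}}, observations=[],
                             scope="per_partridge")
        row = out.iloc[0]
        assert bool(row["empty"]) and row["n_units"] == 0
        assert math.isnan(row["avg_patches_per_unit"])

    def test_permutation_invariant_in_square_order(self, toy_square):
        rng = np.random.default_rng(4)
        sq2 = SurveySquare("sqB", (500.0, 100.0), 200.0)
        m1 = GridPatchMap(toy_square, 2017, "rough",
                          rng.integers(0, 2, (20, 20)).astype(np.int16),
                          ("A", "B"), 10.0)
        m2 = GridPatchMap(sq2, 2017, "rough",
                          rng.integers(0, 2, (20, 20)).astype(np.int16),
                          ("A", "B"), 10.0)
        a = change_summary({2017: {"sqA": m1, "sqB": m2}})
        b = change_summary({2017: {"sqB": m2, "sqA": m1}})
        pd.testing.assert_frame_equal(a, b)

    def test_recovers_generator_fragmentation_trend(self):
        """A tripled patch-count trend between two synthetic years shows up
        in the summary: the count ratio lands in the generator's own
        self-check band, the summary matches directly measured per-square
        patch counts within 10%, and mean patch area shrinks inversely."""
        from habsel.metrics import patchify
        from habsel.synthetic import default_scenario, generate_landscape
        from dataclasses import replace

        count_ratios, area_ratios = [], []
        for seed in range(5):
            sc = replace(default_scenario(seed=seed), years=(2001, 2017),
                         patch_count={2001: 4, 2017: 12},
                         infra_count={2001: 0.0, 2017: 0.0})
            maps = {y: generate_landscape(sc, y) for y in sc.years}
            out = change_summary(maps).set_index("year")
            for y in sc.years:
                measured = np.mean([len(patchify(m))
                                    for m in maps[y].values()])
                assert out.loc[y, "avg_patches_per_unit"] == \
                    pytest.approx(measured, rel=0.10)
            count_ratios.append(out.loc[2017, "avg_patches_per_unit"]
                                / out.loc[2001, "avg_patches_per_unit"])
            area_ratios.append(out.loc[2001, "avg_patch_area_ha"]
                               / out.loc[2017, "avg_patch_area_ha"])
        assert 2.4 <= np.mean(count_ratios) <= 3.6
        assert np.mean(area_ratios) == pytest.approx(np.mean(count_ratios),
                                                     rel=0.25)


class TestDistanceSummary:
    def test_points_on_roads_have_zero_median(self, road_grid):
        obs = [Observation(f"o{i}", "sqA", (100.0, 20.0 + 10 * i), 2017,
                           season, "individual")
               for i, season in enumerate(["winter", "spring"] * 3)]
        out = seasonal_distance_summary(obs, {"sqA": road_grid})
        used = out[out["type"] == "used"]
        assert (used["median_m"] == 0).all()

    def test_constructed_winter_nearer_than_spring(self, road_grid):
        """Winter points placed beside the road, spring points far away."""
        winter = [Observation(f"w{i}", "sqA", (110.0 + i, 100.0), 2017,
                              "winter", "individual") for i in range(5)]
        spring = [Observation(f"s{i}", "sqA", (180.0 + i, 100.0), 2017,
                              "spring", "individual") for i in range(5)]
        out = seasonal_distance_summary(winter + spring, {"sqA": road_grid})
        med = out[out["type"] == "used"].set_index("season")["median_m"]
        assert med["winter"] < med["spring"]

    def test_single_point_flagged_without_se(self, road_grid):
        obs = [Observation("o1", "sqA", (150.0, 100.0), 2017, "winter",
                           "individual")]
        out = seasonal_distance_summary(obs, {"sqA": road_grid})
        row = out[(out["type"] == "used")
                  & (out["season"] == "winter")].iloc[0]
        assert row["n"] == 1 and math.isnan(row["se_median_m"])

    def test_undefined_distances_counted_not_dropped_silently(
            self, uniform_grid):
        obs = [Observation("o1", "sqA", (100.0, 100.0), 2017, "winter",
                           "individual")]
        out = seasonal_distance_summary(obs, {"sqA": uniform_grid})
        assert (out["n_undefined"] > 0).any()
        assert (out["n"] == 0).all()


class TestDiversityTable:
    def test_used_vs_available_rows(self, half_plane_grid):
        obs = [Observation("o1", "sqA", (40.0, 100.0), 2017, "spring",
                           "territory")]
        out = diversity_table({"sqA": half_plane_grid}, obs, radius=20)
        by_type = out.set_index("type")["H"]
        assert by_type["available"] == pytest.approx(math.log(2), abs=1e-9)
        assert by_type["used"] == pytest.approx(0.0, abs=1e-9)


class TestTrendCorrelation:
    def test_perfect_linear_trends(self):
        years = [2001, 2009, 2017]
        assert trend_correlation(years, [2 * y + 1 for y in years]) == \
            pytest.approx(1.0)
        assert trend_correlation(years, [-2 * y for y in years]) == \
            pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self):
        rng = np.random.default_rng(6)
        x = np.arange(2000, 2010, dtype=float)
        y = rng.normal(size=10)
        r = trend_correlation(x, y)
        direct = (((x - x.mean()) * (y - y.mean())).sum()
                  / math.sqrt(((x - x.mean()) ** 2).sum()
                              * ((y - y.mean()) ** 2).sum()))
        assert r == pytest.approx(direct, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            trend_correlation([2001, 2009, 2017], [5.0, 5.0, 5.0])
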