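"""Geometry layer: plot composition, reference plots, hedges, distances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from habsel.landscape import (
    CircularPlot,
    CoverageError,
    GridPatchMap,
    HedgeAttributes,
    Observation,
    SurveySquare,
    classify_super_hedge,
    distance_to_nearest_infrastructure,
    plot_composition,
    reference_plot,
)

from .conftest import rasterize_half_plane


class TestPlotComposition:
    def test_single_type_plot(self, uniform_grid):
        plot = CircularPlot(center=(100, 100), radius=50)
        comp = plot_composition(uniform_grid, plot)
        assert comp.as_dict() == {"arable": 1.0}

    @pytest.mark.parametrize("representation", ["grid", "polygons"])
    def test_half_plane_symmetry(self, representation, half_plane_grid,
                                 half_plane_polygons):
        """A plot centred on a straight boundary splits 50/50."""
        pmap = (half_plane_grid if representation == "grid"
                else half_plane_polygons)
        plot = CircularPlot(center=(100, 100), radius=60)
        comp = plot_composition(pmap, plot).as_dict()
        assert comp["A"] == pytest.approx(0.5, abs=0.01)
        assert comp["B"] == pytest.approx(0.5, abs=0.01)

    def test_grid_converges_to_polygon_composition(self, toy_square,
                                                   half_plane_polygons):
        """Rasterizations at shrinking cell size approach the exact
        polygon areas, and 1 m vs 0.25 m cells agree within 0.01."""
        plot = CircularPlot(center=(80, 100), radius=50)
        exact = plot_composition(half_plane_polygons, plot).as_dict()["A"]
        errors = []
        for cs in (4.0, 1.0, 0.25):
            g = rasterize_half_plane(toy_square, cs)
            got = plot_composition(g, plot).as_dict()["A"]
            errors.append(abs(got - exact))
        assert errors[2] <= errors[0] + 1e-9  # finer grids do not get worse
        assert errors[1] < 0.01 and errors[2] < 0.01
        g1 = plot_composition(rasterize_half_plane(toy_square, 1.0), plot)
        g2 = plot_composition(rasterize_half_plane(toy_square, 0.25), plot)
        assert g1.as_dict()["A"] == pytest.approx(g2.as_dict()["A"], abs=0.01)

    def test_proportions_sum_to_one(self, half_plane_grid):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = rng.uniform(10, 190, size=2)
            comp = plot_composition(half_plane_grid,
                                    CircularPlot(center=tuple(c), radius=40))
            vals = np.array(list(comp.as_dict().values()))
            assert abs(vals.sum() - 1.0) < 1e-9
            assert ((vals >= 0) & (vals <= 1)).all()

    def test_clipped_at_square_boundary(self, half_plane_grid):
        """An edge plot is renormalised over its clipped area."""
        comp = plot_composition(half_plane_grid,
                                CircularPlot(center=(2, 100), radius=30))
        assert comp.as_dict() == {"A": 1.0}

    def test_empty_intersection_is_error(self, half_plane_grid):
        with pytest.raises(CoverageError):
            plot_composition(half_plane_grid,
                             CircularPlot(center=(1000, 1000), radius=30))

    def test_unlabelled_area_above_tolerance_names_square(self, toy_square):
        cells = np.zeros((200, 200), dtype=np.int16)
        cells[:, 100:] = -1  # unlabelled right half
        pmap = GridPatchMap(toy_square, 2017, "rough", cells, ("A",), 1.0)
        with pytest.raises(CoverageError, match="sqA"):
            plot_composition(pmap, CircularPlot(center=(100, 100), radius=50))

    def test_relabelling_patch_ids_is_invisible(self, toy_square):
        """Composition depends on habitat codes only, not on which patch
        a cell belongs to (legend order permuted)."""
        rng = np.random.default_rng(1)
        cells = rng.integers(0, 3, size=(200, 200)).astype(np.int16)
        legend = ("A", "B", "C")
        m1 = GridPatchMap(toy_square, 2017, "rough", cells, legend, 1.0)
        perm = [2, 0, 1]
        remapped = np.array(perm, dtype=np.int16)[cells]
        legend2 = tuple(legend[perm.index(i)] for i in range(3))
        m2 = GridPatchMap(toy_square, 2017, "rough", remapped, legend2, 1.0)
        plot = CircularPlot(center=(100, 100), radius=60)
        assert (plot_composition(m1, plot).as_dict()
                == plot_composition(m2, plot).as_dict())


class TestReferencePlot:
    def test_centre_and_area(self):
        sq = SurveySquare("s", (0.0, 0.0), 618.0)
        plot = reference_plot(sq, radius=100.0)
        assert plot.center == (0.0, 0.0)
        assert plot.kind == "availability"
        assert plot.area_ha == pytest.approx(3.1416, abs=1e-3)

    def test_zero_radius_rejected(self):
        sq = SurveySquare("s", (0.0, 0.0), 618.0)
        with pytest.raises(ValueError):
            reference_plot(sq, radius=0.0)

    def test_one_plot_per_square(self):
        plots = [reference_plot(SurveySquare(f"s{i}", (i * 700.0, 0.0)))
                 for i in range(2)]
        assert plots[0].center != plots[1].center
        assert {p.source for p in plots} == {"s0", "s1"}


class TestSuperHedge:
    @pytest.mark.parametrize("height,width,cover,expected", [
        (5.0, 3.0, 0.80, True),   # all three strictly exceeded
        (4.0, 3.0, 0.80, False),  # height at boundary
        (5.0, 2.0, 0.80, False),  # width at boundary
        (5.0, 3.0, 0.70, False),  # cover at boundary
        (3.0, 1.0, 0.50, False),
    ])
    def test_strict_thresholds(self, height, width, cover, expected):
        h = HedgeAttributes(height=height, width=width,
                            understory_cover=cover)
        assert classify_super_hedge(h) is expected

    def test_negative_attribute_is_error(self):
        with pytest.raises(ValueError):
            HedgeAttributes(height=-1.0, width=2.0, understory_cover=0.5)


class TestObservation:
    def test_covey_needs_more_than_two_birds(self):
        with pytest.raises(ValueError, match="covey"):
            Observation("o1", "s", (0, 0), 2017, "winter", "covey",
                        group_size=2)
        obs = Observation("o1", "s", (0, 0), 2017, "winter", "covey",
                          group_size=3)
        assert obs.unit_id == "o1"  # defaults to obs_id


class TestInfrastructureDistance:
    def test_point_inside_road_is_zero(self, road_grid):
        assert distance_to_nearest_infrastructure((100, 50), road_grid) == 0.0

    def test_plane_distance_to_road_edge(self, road_grid):
        # road spans x in [95, 105]; a point at x=155 is 50 m from its edge
        d = distance_to_nearest_infrastructure((155.0, 100.0), road_grid)
        assert d == pytest.approx(50.0, abs=1.0)

    def test_no_infrastructure_returns_undefined(self, uniform_grid):
        with pytest.warns(UserWarning, match="no infrastructure"):
            d = distance_to_nearest_infrastructure((100, 100), uniform_grid)
        assert d is None

    def test_matches_brute_force_cell_centre_oracle(self, toy_square):
        """Distance agrees with the min over infrastructure cell centres
        within a cell-diagonal tolerance, on random toy maps."""
        rng = np.random.default_rng(42)
        cs = 4.0
        n = int(200 / cs)
        for _ in range(10):
            cells = np.zeros((n, n), dtype=np.int16)
            k = rng.integers(1, 6)
            rows = rng.integers(0, n, size=k)
            cols = rng.integers(0, n, size=k)
            cells[rows, cols] = 1
            pmap = GridPatchMap(toy_square, 2017, "rough", cells,
                                ("arable", "road"), cs)
            p = tuple(rng.uniform(0, 200, size=2))
            X, Y = pmap.cell_centers()
            centre_d = np.hypot(X[cells == 1] - p[0],
                                Y[cells == 1] - p[1]).min()
            got = distance_to_nearest_infrastructure(p, pmap)
            assert abs(got - centre_d) <= cs * math.sqrt(2)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(x1=st.floats(0, 200), y1=st.floats(0, 200),
           x2=st.floats(0, 200), y2=st.floats(0, 200))
    def test_lipschitz_in_query_point(self, x1, y1, x2, y2):
        """|d(p) - d(q)| <= |p - q| (1-Lipschitz)."""
        square = SurveySquare("sqA", centroid=(100.0, 100.0),
                              side_length=200.0)
        cells = np.zeros((200, 200), dtype=np.int16)
        cells[:, 95:105] = 1
        pmap = GridPatchMap(square, 2017, "rough", cells,
                            ("arable", "road"), 1.0)
        d1 = distance_to_nearest_infrastructure((x1, y1), pmap)
        d2 = distance_to_nearest_infrastructure((x2, y2), pmap)
        assert abs(d1 - d2) <= math.hypot(x1 - x2, y1 - y2) + 1e-9
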