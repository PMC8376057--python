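"""Spatial data model: survey squares, categorical patch maps, observations.

The study design is a set of square survey units (618 m side, one sixth of a
geographical minute) holding an annually remapped categorical land-cover
layer.  Habitat *use* is the composition of a circular plot (default 100 m
radius, ~3.14 ha) around each bird location; *availability* is the
composition of an equally sized reference plot at the square centre, or of
the whole square map.  Two interchangeable map representations are provided:
a regular grid of habitat codes (cell-centre membership) and a set of
non-overlapping labelled polygons (exact intersection areas via shapely).

All coordinates are planar metric (projected), y-up; areas are reported in
hectares (1 ha = 10,000 m²).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

M2_PER_HA = 10_000.0

#: habitat codes counted as human infrastructure at the rough scale
ROUGH_INFRASTRUCTURE = frozenset(
    {"road", "field_path", "settlement", "park", "power_pole", "windmill",
     "under_construction"}
)
FINE_INFRASTRUCTURE = frozenset({"field_path", "gravel_walk", "tarred_road"})


class UnknownHabitatError(KeyError):
    """An observation or map references a code outside the active vocabulary."""


class CoverageError(ValueError):
    """A plot or map has unlabelled area above the stated tolerance."""


@dataclass(frozen=True)
class HabitatType:
    """One category of the closed land-cover vocabulary at a given scale."""

    code: str
    scale: str  # "rough" | "fine"
    is_infrastructure: bool = False
    display_name: str = ""

    def __post_init__(self) -> None:
        if self.scale not in ("rough", "fine"):
            raise ValueError(f"scale must be 'rough' or 'fine', got {self.scale!r}")


def _vocab(scale: str, codes: Sequence[str], infra: frozenset) -> tuple[HabitatType, ...]:
    return tuple(
        HabitatType(c, scale, c in infra, c.replace("_", " ")) for c in codes
    )


#: land-cover categories distinguishable on annual maps / aerial photographs
ROUGH_SCALE_VOCABULARY = _vocab(
    "rough",
    ["arable", "meadow", "vineyard", "forest", "hedgerow", "water_body",
     "field_path", "road", "settlement", "park", "power_pole", "windmill",
     "under_construction"],
    ROUGH_INFRASTRUCTURE,
)

#: ground-truthed categories recorded by revisiting each plot on foot
FINE_SCALE_VOCABULARY = _vocab(
    "fine",
    ["winter_grain", "harvested_field", "without_crop", "meadow",
     "fallow_green_manure", "field_path", "gravel_walk", "tarred_road",
     "hedgerow_small_trees"],
    FINE_INFRASTRUCTURE,
)


def vocabulary_codes(vocab: Iterable[HabitatType]) -> tuple[str, ...]:
    codes = tuple(t.code for t in vocab)
    if len(set(codes)) != len(codes):
        raise ValueError("habitat codes must be unique within a scale")
    return codes


def infrastructure_codes(vocab: Iterable[HabitatType]) -> frozenset[str]:
    return frozenset(t.code for t in vocab if t.is_infrastructure)


@dataclass(frozen=True)
class SurveySquare:
    """One survey unit: an axis-aligned square identified by its centroid."""

    square_id: str
    centroid: tuple[float, float]
    side_length: float = 618.0

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError("side_length must be > 0")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        cx, cy = self.centroid
        h = self.side_length / 2.0
        return (cx - h, cy - h, cx + h, cy + h)

    @property
    def area_ha(self) -> float:
        return self.side_length**2 / M2_PER_HA

    def contains(self, x: float, y: float, tolerance: float = 0.0) -> bool:
        x0, y0, x1, y1 = self.bounds
        return (x0 - tolerance <= x <= x1 + tolerance
                and y0 - tolerance <= y <= y1 + tolerance)

    def polygon(self) -> Polygon:
        return box(*self.bounds)


@dataclass(frozen=True)
class HedgeAttributes:
    """Field-measured structure of a hedgerow."""

    height: float  # m
    width: float  # m
    understory_cover: float  # fraction of herbal ground cover, [0, 1]

    def __post_init__(self) -> None:
        if self.height < 0 or self.width < 0 or self.understory_cover < 0:
            raise ValueError("hedge attributes must be non-negative")
        if self.understory_cover > 1:
            raise ValueError("understory_cover is a fraction in [0, 1]")


@dataclass(frozen=True)
class SuperHedgeThresholds:
    """Strict lower bounds a hedge must exceed to count as a 'super hedge'."""

    height: float = 4.0
    width: float = 2.0
    understory_cover: float = 0.70


def classify_super_hedge(
    h: HedgeAttributes,
    thresholds: SuperHedgeThresholds = SuperHedgeThresholds(),
) -> bool:
    """True iff height, width and understory cover all *strictly* exceed
    their thresholds (defaults: >4 m, >2 m, >70 %)."""
    return (
        h.height > thresholds.height
        and h.width > thresholds.width
        and h.understory_cover > thresholds.understory_cover
    )


@dataclass(frozen=True)
class Observation:
    """One mapped bird record: an individual, pair, covey or territory.

    ``unit_id`` groups multiple locations of the same analysis unit (e.g. a
    covey mapped repeatedly); it defaults to ``obs_id`` for single-location
    records.
    """

    obs_id: str
    square_id: str
    location: tuple[float, float]
    year: int
    season: str  # "winter" | "spring"
    unit_kind: str  # "individual" | "pair" | "covey" | "territory"
    group_size: int = 1
    unit_id: str = ""

    def __post_init__(self) -> None:
        if not self.unit_id:
            object.__setattr__(self, "unit_id", self.obs_id)
        if self.season not in ("winter", "spring"):
            raise ValueError(f"season must be winter or spring, got {self.season!r}")
        if self.unit_kind not in ("individual", "pair", "covey", "territory"):
            raise ValueError(f"unknown unit_kind {self.unit_kind!r}")
        if self.group_size < 1:
            raise ValueError("group_size must be positive")
        if self.unit_kind == "covey" and self.group_size <= 2:
            raise ValueError("a covey has more than 2 individuals")


@dataclass(frozen=True)
class CircularPlot:
    """A circular sampling plot around a bird location or a square centre."""

    center: tuple[float, float]
    radius: float = 100.0
    kind: str = "use"  # "use" | "availability"
    source: str = ""  # obs_id, or square_id for reference plots

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("plot radius must be > 0")
        if self.kind not in ("use", "availability"):
            raise ValueError(f"plot kind must be use or availability, got {self.kind!r}")

    @property
    def area_ha(self) -> float:
        return math.pi * self.radius**2 / M2_PER_HA


def reference_plot(square: SurveySquare, radius: float = 100.0) -> CircularPlot:
    """Availability plot of the given radius at the square centre."""
    return CircularPlot(center=square.centroid, radius=radius,
                        kind="availability", source=square.square_id)


@dataclass(frozen=True)
class CompositionProfile:
    """Habitat-type area proportions of one plot (or one whole square).

    ``proportions`` holds the use fractions r_i for use plots and the
    availability fractions n_i for availability plots; they sum to 1.
    """

    proportions: Mapping[str, float]
    kind: str = "use"
    source: str = ""

    def __post_init__(self) -> None:
        vals = np.array(list(self.proportions.values()), dtype=float)
        if vals.size == 0:
            raise ValueError("empty composition")
        if (vals < -1e-12).any() or (vals > 1 + 1e-12).any():
            raise ValueError("proportions must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {vals.sum()!r}")

    def as_dict(self) -> dict[str, float]:
        return dict(self.proportions)


# ---------------------------------------------------------------------------
# Patch maps


class PatchMap:
    """Categorical land-cover map of one square in one year (abstract base)."""

    square: SurveySquare
    year: int
    scale: str

    @property
    def square_id(self) -> str:
        return self.square.square_id

    @property
    def total_area_ha(self) -> float:
        return self.square.area_ha

    def composition(self) -> dict[str, float]:
        """Whole-square habitat shares."""
        raise NotImplementedError

    def plot_fractions(self, plot: CircularPlot,
                       coverage_tolerance: float = 0.01) -> dict[str, float]:
        raise NotImplementedError

    def distance_to_codes(self, point: tuple[float, float],
                          codes: frozenset[str] | set[str]) -> float | None:
        raise NotImplementedError


class GridPatchMap(PatchMap):
    """Grid representation: habitat codes on a regular raster.

    ``cells`` is an int array of shape (nrows, ncols) indexing ``legend``;
    -1 marks unlabelled area.  Row 0 is the *southern* edge (y-up).  A cell
    belongs to a plot when its centre lies inside the circle.
    """

    def __init__(self, square: SurveySquare, year: int, scale: str,
                 cells: np.ndarray, legend: Sequence[str], cell_size: float):
        if cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        cells = np.asarray(cells)
        if cells.ndim != 2:
            raise ValueError("cells must be a 2-D array")
        if cells.max(initial=-1) >= len(legend):
            raise UnknownHabitatError("cell value outside legend")
        self.square = square
        self.year = year
        self.scale = scale
        self.cells = cells
        self.legend = tuple(legend)
        self.cell_size = float(cell_size)
        x0, y0, _, _ = square.bounds
        self._origin = (x0, y0)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, GridPatchMap)
                and self.square == other.square and self.year == other.year
                and self.scale == other.scale and self.legend == other.legend
                and self.cell_size == other.cell_size
                and np.array_equal(self.cells, other.cells))

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / M2_PER_HA

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell centre, shaped like ``cells``."""
        x0, y0 = self._origin
        nrows, ncols = self.cells.shape
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def _fractions_from_mask(self, mask: np.ndarray, what: str,
                             coverage_tolerance: float) -> dict[str, float]:
        sel = self.cells[mask]
        if sel.size == 0:
            raise CoverageError(
                f"{what} has empty intersection with square {self.square_id}")
        unlabelled = np.count_nonzero(sel < 0)
        if unlabelled / sel.size > coverage_tolerance:
            raise CoverageError(
                f"square {self.square_id}: {unlabelled / sel.size:.1%} of "
                f"{what} is unlabelled (tolerance {coverage_tolerance:.1%})")
        sel = sel[sel >= 0]
        counts = np.bincount(sel, minlength=len(self.legend))
        total = counts.sum()
        return {code: counts[i] / total
                for i, code in enumerate(self.legend) if counts[i] > 0}

    def composition(self) -> dict[str, float]:
        return self._fractions_from_mask(
            np.ones(self.cells.shape, dtype=bool), "square", 0.01)

    def plot_fractions(self, plot: CircularPlot,
                       coverage_tolerance: float = 0.01) -> dict[str, float]:
        px, py = plot.center
        X, Y = self.cell_centers()
        mask = (X - px) ** 2 + (Y - py) ** 2 <= plot.radius**2
        return self._fractions_from_mask(mask, "plot", coverage_tolerance)

    def distance_to_codes(self, point, codes) -> float | None:
        idx = [i for i, c in enumerate(self.legend) if c in codes]
        if not idx:
            return None
        mask = np.isin(self.cells, idx)
        if not mask.any():
            return None
        X, Y = self.cell_centers()
        half = self.cell_size / 2.0
        # distance from the point to each cell's square footprint
        dx = np.maximum(np.abs(X[mask] - point[0]) - half, 0.0)
        dy = np.maximum(np.abs(Y[mask] - point[1]) - half, 0.0)
        return float(np.hypot(dx, dy).min())

    def patches(self, connectivity: int = 4) -> list[tuple[str, float]]:
        """Maximal connected same-code regions as (code, area_ha)."""
        from scipy import ndimage

        if connectivity == 4:
            structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        elif connectivity == 8:
            structure = np.ones((3, 3), dtype=int)
        else:
            raise ValueError("connectivity must be 4 or 8")
        out: list[tuple[str, float]] = []
        for i, code in enumerate(self.legend):
            mask = self.cells == i
            if not mask.any():
                continue
            labelled, n = ndimage.label(mask, structure=structure)
            sizes = np.bincount(labelled.ravel())[1:]
            out.extend((code, float(s) * self.cell_area_ha) for s in sizes)
        return out

    def patches_in_plot(self, plot: CircularPlot,
                        connectivity: int = 4) -> list[tuple[str, float]]:
        """Patches of the map clipped to the circular plot."""
        px, py = plot.center
        X, Y = self.cell_centers()
        inside = (X - px) ** 2 + (Y - py) ** 2 <= plot.radius**2
        clipped = np.where(inside, self.cells, -1)
        sub = GridPatchMap(self.square, self.year, self.scale, clipped,
                           self.legend, self.cell_size)
        return sub.patches(connectivity)


class PolygonPatchMap(PatchMap):
    """Polygon representation: non-overlapping labelled polygons."""

    def __init__(self, square: SurveySquare, year: int, scale: str,
                 features: Sequence[tuple[Polygon, str]],
                 overlap_tolerance: float = 1e-6):
        self.square = square
        self.year = year
        self.scale = scale
        self.features = list(features)
        areas = sum(p.area for p, _ in self.features)
        union_area = unary_union([p for p, _ in self.features]).area
        if areas - union_area > overlap_tolerance * max(union_area, 1.0):
            raise ValueError(f"overlapping polygons in square {self.square_id}")

    def composition(self) -> dict[str, float]:
        sq = self.square.polygon()
        acc: dict[str, float] = {}
        for poly, code in self.features:
            a = poly.intersection(sq).area
            if a > 0:
                acc[code] = acc.get(code, 0.0) + a
        total = sum(acc.values())
        if total <= 0:
            raise CoverageError(f"square {self.square_id} has no labelled area")
        return {c: a / total for c, a in acc.items()}

    def plot_fractions(self, plot: CircularPlot,
                       coverage_tolerance: float = 0.01) -> dict[str, float]:
        circle = Point(*plot.center).buffer(plot.radius, quad_segs=96)
        clipped = circle.intersection(self.square.polygon())
        if clipped.is_empty or clipped.area == 0:
            raise CoverageError(
                f"plot has empty intersection with square {self.square_id}")
        acc: dict[str, float] = {}
        for poly, code in self.features:
            a = poly.intersection(clipped).area
            if a > 0:
                acc[code] = acc.get(code, 0.0) + a
        labelled = sum(acc.values())
        if (clipped.area - labelled) / clipped.area > coverage_tolerance:
            raise CoverageError(
                f"square {self.square_id}: "
                f"{(clipped.area - labelled) / clipped.area:.1%} of plot is "
                f"unlabelled (tolerance {coverage_tolerance:.1%})")
        return {c: a / labelled for c, a in acc.items()}

    def distance_to_codes(self, point, codes) -> float | None:
        geoms = [p for p, c in self.features if c in codes]
        if not geoms:
            return None
        pt = Point(*point)
        return float(min(pt.distance(g) for g in geoms))

    def patches(self, connectivity: int = 4) -> list[tuple[str, float]]:
        """Each polygon is one patch; touching same-code polygons merge."""
        by_code: dict[str, list[Polygon]] = {}
        for poly, code in self.features:
            by_code.setdefault(code, []).append(poly)
        out: list[tuple[str, float]] = []
        for code, polys in by_code.items():
            merged = unary_union(polys)
            parts = getattr(merged, "geoms", [merged])
            out.extend((code, p.area / M2_PER_HA) for p in parts)
        return out


# ---------------------------------------------------------------------------
# Operations on maps


def plot_composition(patch_map: PatchMap, plot: CircularPlot,
                     coverage_tolerance: float = 0.01) -> CompositionProfile:
    """Habitat composition of a circular plot, clipped at the square boundary.

    Proportions are renormalised over the clipped (and labelled) area and
    sum to 1.  Raises :class:`CoverageError` for an empty intersection or
    for unlabelled area above ``coverage_tolerance``.
    """
    fr = patch_map.plot_fractions(plot, coverage_tolerance)
    return CompositionProfile(proportions=fr, kind=plot.kind, source=plot.source)


def square_composition(patch_map: PatchMap) -> CompositionProfile:
    """Whole-square availability composition."""
    return CompositionProfile(proportions=patch_map.composition(),
                              kind="availability", source=patch_map.square_id)


def distance_to_nearest_infrastructure(
    point: tuple[float, float],
    patch_map: PatchMap,
    infra_codes: frozenset[str] | set[str] | None = None,
) -> float | None:
    """Euclidean distance (m) from a point to the nearest infrastructure
    patch boundary; 0 inside such a patch; None if the map holds none.

    ``infra_codes`` defaults to the built-in infrastructure set for the
    map's scale.
    """
    if infra_codes is None:
        infra_codes = (ROUGH_INFRASTRUCTURE if patch_map.scale == "rough"
                       else FINE_INFRASTRUCTURE)
    d = patch_map.distance_to_codes(point, infra_codes)
    if d is None:
        warnings.warn(
            f"square {patch_map.square_id}: no infrastructure present, "
            "distance undefined", stacklevel=2)
    return d
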