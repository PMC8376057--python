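"""Synthetic landscapes and selection-driven observations with known truth.

The generator emulates the statistical structure of the field study — 20
survey squares of 618 m side, a closed land-cover vocabulary at a rough or
fine scale, multi-year fragmentation and infrastructure growth, winter
coveys (>2 birds, sizes 3-15) and spring territories — without any real GIS
layer.  Landscapes are built per square and year in two stages:

1. *Background*: K seeded nuclei on a jittered lattice partition the square
   into nearest-nucleus (Voronoi-like) regions; nucleus habitat types are
   allocated across all squares by largest remainder on the target shares,
   so realized shares track targets and K controls the patch count.
2. *Infrastructure*: small square blocks of a configured area are pasted at
   random non-overlapping positions, with per-year counts controlling the
   infrastructure trend independently of the background grain.

Bird units are placed by a weighted selection model: a location falls in a
cell with probability proportional to the selection weight w of the cell's
habitat type (uniform within type).  Under this model the expected Manly
alpha for type i is w_i / sum_j w_j regardless of the availability shares,
and the implied electivity follows in closed form — the ground truth that
recovery tests compare the full pipeline against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .electivity import chesson_epsilon
from .landscape import (
    FINE_SCALE_VOCABULARY,
    ROUGH_SCALE_VOCABULARY,
    GridPatchMap,
    HabitatType,
    Observation,
    SurveySquare,
    vocabulary_codes,
)

__all__ = [
    "SyntheticScenario",
    "GroundTruth",
    "default_scenario",
    "recovery_scenario",
    "neutral_scenario",
    "fixture_scenario",
    "generate_landscape",
    "place_units",
    "scenario_ground_truth",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters for one synthetic study.

    background_shares are target area shares of the non-infrastructure
    types (sum to 1 before the infrastructure overlay); patch_count gives
    the background nuclei per square and year (the fragmentation trend);
    infra_count/infra_area_ha drive the infrastructure overlay per year.
    selection_weights hold one positive weight per habitat code and season.
    """

    name: str = "scenario"
    vocab: tuple[HabitatType, ...] = ROUGH_SCALE_VOCABULARY
    n_squares: int = 20
    side_length: float = 618.0
    cell_size: float = 6.0
    years: tuple[int, ...] = (2001, 2009, 2017)
    scale: str = "rough"
    background_shares: Mapping[str, float] = field(default_factory=dict)
    patch_count: Mapping[int, int] = field(default_factory=dict)
    infra_count: Mapping[int, float] = field(default_factory=dict)
    infra_area_ha: Mapping[int, float] = field(default_factory=dict)
    selection_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict)
    units: Mapping[str, int] = field(default_factory=dict)
    locations_per_unit: Mapping[str, int] = field(default_factory=dict)
    covey_size_range: tuple[int, int] = (3, 15)
    seed: int = 0

    def __post_init__(self) -> None:
        shares = np.array(list(self.background_shares.values()), dtype=float)
        if shares.size and abs(shares.sum() - 1.0) > 1e-9:
            raise ValueError("background_shares must sum to 1")
        if (shares < 0).any():
            raise ValueError("background_shares must be >= 0")
        for season, w in self.selection_weights.items():
            if any(v <= 0 for v in w.values()):
                raise ValueError(f"selection weights must be > 0 ({season})")
        lo, hi = self.covey_size_range
        if lo <= 2:
            raise ValueError("covey sizes must exceed 2 individuals")
        if hi < lo:
            raise ValueError("empty covey size range")

    @property
    def codes(self) -> tuple[str, ...]:
        return vocabulary_codes(self.vocab)

    def square(self, i: int) -> SurveySquare:
        # squares laid out on a row with a gap; only geometry matters
        step = self.side_length * 1.2
        return SurveySquare(square_id=f"sq{i:02d}",
                            centroid=(i * step, 0.0),
                            side_length=self.side_length)

    def squares(self) -> list[SurveySquare]:
        return [self.square(i) for i in range(self.n_squares)]


@dataclass(frozen=True)
class GroundTruth:
    """Analytic targets of a scenario under the placement model."""

    alpha: Mapping[str, pd.Series]  # season -> alpha over weighted codes
    epsilon: Mapping[str, pd.Series]  # season -> electivity
    composition: Mapping[int, Mapping[str, float]]  # year -> target shares
    patches_per_square: Mapping[int, float]  # year -> expected patch count


# ---------------------------------------------------------------------------
# ready-made scenarios

_BACKGROUND_ROUGH = {
    "arable": 0.60, "meadow": 0.15, "vineyard": 0.09, "forest": 0.06,
    "hedgerow": 0.06, "water_body": 0.04,
}

_WINTER_W = {
    "arable": 0.8, "meadow": 3.0, "vineyard": 0.2, "forest": 0.2,
    "hedgerow": 0.2, "water_body": 0.2, "field_path": 1.0, "road": 2.5,
    "settlement": 0.2, "park": 0.2, "power_pole": 0.2, "windmill": 0.2,
    "under_construction": 0.2,
}

_SPRING_W = {
    "arable": 2.5, "meadow": 0.5, "vineyard": 0.3, "forest": 0.2,
    "hedgerow": 0.3, "water_body": 0.2, "field_path": 0.5, "road": 0.3,
    "settlement": 0.2, "park": 0.2, "power_pole": 0.2, "windmill": 0.2,
    "under_construction": 0.2,
}


def default_scenario(seed: int = 0) -> SyntheticScenario:
    """Field-shaped scenario: 20 squares, rough vocabulary, three survey
    years with increasing fragmentation and infrastructure, winter coveys
    up-weighting meadows and roads, spring territories up-weighting arable
    land."""
    return SyntheticScenario(
        name="default",
        vocab=ROUGH_SCALE_VOCABULARY,
        background_shares=_BACKGROUND_ROUGH,
        patch_count={2001: 3, 2009: 7, 2017: 18},
        infra_count={2001: 1.3, 2009: 5.4, 2017: 8.7},
        infra_area_ha={2001: 0.12, 2009: 0.12, 2017: 0.12},
        selection_weights={"winter": _WINTER_W, "spring": _SPRING_W},
        units={"winter": 6, "spring": 20},
        locations_per_unit={"winter": 1, "spring": 1},
        seed=seed,
    )


_RECOVERY_CODES = ("winter_grain", "harvested_field", "without_crop",
                   "meadow", "fallow_green_manure", "hedgerow_small_trees")
_RECOVERY_W = {"harvested_field": 6.0, "winter_grain": 3.0,
               "without_crop": 2.5, "meadow": 2.0,
               "fallow_green_manure": 1.2, "hedgerow_small_trees": 1.0}


def _fine_subset(codes: Sequence[str]) -> tuple[HabitatType, ...]:
    by_code = {t.code: t for t in FINE_SCALE_VOCABULARY}
    return tuple(by_code[c] for c in codes)


def recovery_scenario(seed: int = 0, n_units: int = 40,
                      locations_per_unit: int = 40) -> SyntheticScenario:
    """Parameter-recovery scenario: 20 squares, m = 6 equally available
    types, graded selection weights spanning strong preference to strong
    avoidance.

    Units carry many locations and analyses should use a plot radius small
    against the patch grain, so that per-unit use profiles are consistent
    estimates of the placement weights (unit electivity is a nonlinear
    statistic; see the methods note for the bias argument).
    """
    m = len(_RECOVERY_CODES)
    return SyntheticScenario(
        name="recovery",
        vocab=_fine_subset(_RECOVERY_CODES),
        scale="fine",
        years=(2017,),
        background_shares={c: 1.0 / m for c in _RECOVERY_CODES},
        patch_count={2017: 6},
        infra_count={2017: 0.0},
        infra_area_ha={2017: 0.0},
        selection_weights={"spring": dict(_RECOVERY_W)},
        units={"spring": n_units},
        locations_per_unit={"spring": locations_per_unit},
        seed=seed,
    )


def neutral_scenario(seed: int = 0, n_units: int = 20,
                     locations_per_unit: int = 100) -> SyntheticScenario:
    """Null scenario: equal weights, so every true electivity is 0."""
    m = len(_RECOVERY_CODES)
    sc = recovery_scenario(seed, n_units, locations_per_unit)
    return replace(sc, name="neutral",
                   selection_weights={
                       "spring": {c: 1.0 for c in _RECOVERY_CODES}})


def fixture_scenario(seed: int = 0) -> SyntheticScenario:
    """Tiny 3-square, single-year dataset for unit tests and demos."""
    sc = default_scenario(seed)
    return replace(sc, name="fixture", n_squares=3, years=(2017,),
                   patch_count={2017: 5}, infra_count={2017: 2.0},
                   infra_area_ha={2017: 0.2},
                   units={"winter": 4, "spring": 6})


# ---------------------------------------------------------------------------
# landscape synthesis


def _rng_for(scenario: SyntheticScenario, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([scenario.seed, *key]))


def _allocate_nuclei(shares: Mapping[str, float], k: int, n_squares: int,
                     rng: np.random.Generator) -> list[str]:
    """Per-square stratified allocation of nucleus habitat types.

    Each square first receives floor(k * share) nuclei of every type, so
    dominant types are spread over all squares instead of piling up in a
    few; the fractional remainders are pooled across squares by largest
    remainder, shuffled, and dealt out round-robin.  Returns a flat list of
    k * n_squares codes, square by square.
    """
    codes = list(shares)
    base = {c: int(np.floor(k * shares[c])) for c in codes}
    leftover_per_square = k - sum(base.values())
    frac_quota = np.array([(k * shares[c] - base[c]) * n_squares
                           for c in codes])
    pool_counts = np.floor(frac_quota).astype(int)
    rem = leftover_per_square * n_squares - pool_counts.sum()
    if rem > 0:
        order = np.argsort(-(frac_quota - pool_counts))
        pool_counts[order[:rem]] += 1
    pool = [c for c, n in zip(codes, pool_counts) for _ in range(n)]
    rng.shuffle(pool)
    out: list[str] = []
    for i in range(n_squares):
        sq = [c for c, n in base.items() for _ in range(n)]
        sq += pool[i * leftover_per_square:(i + 1) * leftover_per_square]
        rng.shuffle(sq)
        out.extend(sq)
    return out


def _jittered_nuclei(k: int, side: float, rng: np.random.Generator) -> np.ndarray:
    """k nucleus positions on a jittered lattice within [0, side]^2."""
    g = int(np.ceil(np.sqrt(k)))
    spacing = side / g
    centers = [( (i + 0.5) * spacing, (j + 0.5) * spacing)
               for i in range(g) for j in range(g)]
    pick = rng.choice(len(centers), size=k, replace=False)
    pts = np.array([centers[p] for p in pick], dtype=float)
    pts += rng.uniform(-0.35 * spacing, 0.35 * spacing, size=pts.shape)
    return np.clip(pts, 0.0, side)


def generate_landscape(scenario: SyntheticScenario, year: int,
                       ) -> dict[str, GridPatchMap]:
    """Per-square categorical grid maps for one year; deterministic in the
    scenario seed.  Realized type shares track the targets (within a few
    percent once averaged over squares) and the background patch count per
    square follows ``scenario.patch_count[year]``."""
    if year not in scenario.years:
        raise ValueError(f"year {year} not in scenario years {scenario.years}")
    rng = _rng_for(scenario, year, 1)
    codes = scenario.codes
    code_index = {c: i for i, c in enumerate(codes)}
    n = int(round(scenario.side_length / scenario.cell_size))
    k = int(scenario.patch_count[year])
    nuclei_types = _allocate_nuclei(scenario.background_shares, k,
                                    scenario.n_squares, rng)
    infra_codes = [t.code for t in scenario.vocab if t.is_infrastructure]
    total_infra = int(round(scenario.infra_count.get(year, 0.0)
                            * scenario.n_squares))
    infra_per_square = np.bincount(
        rng.permutation(np.arange(scenario.n_squares).repeat(
            total_infra // scenario.n_squares + 1))[:total_infra],
        minlength=scenario.n_squares) if total_infra else np.zeros(
            scenario.n_squares, dtype=int)

    maps: dict[str, GridPatchMap] = {}
    # local cell-centre coordinates, shared by every square
    xs = (np.arange(n) + 0.5) * scenario.cell_size
    X, Y = np.meshgrid(xs, xs)
    for i, square in enumerate(scenario.squares()):
        types = nuclei_types[i * k:(i + 1) * k]
        pts = _jittered_nuclei(k, scenario.side_length, rng)
        d2 = ((X[..., None] - pts[:, 0]) ** 2
              + (Y[..., None] - pts[:, 1]) ** 2)
        nearest = d2.argmin(axis=2)
        # assign the type multiset to regions so same-type regions touch as
        # rarely as possible; otherwise they would merge into one patch and
        # the realized count would drift below the configured trend
        assignment = _anti_adjacent_assignment(nearest, k, types, rng)
        cells = np.array([code_index[t] for t in assignment],
                         dtype=np.int16)[nearest]
        cells = _paste_infrastructure(
            cells, int(infra_per_square[i]),
            scenario.infra_area_ha.get(year, 0.0), infra_codes,
            code_index, scenario.cell_size, rng)
        maps[square.square_id] = GridPatchMap(
            square, year, scenario.scale, cells, codes, scenario.cell_size)
    return maps


def _region_adjacency(nearest: np.ndarray, k: int) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(k)]
    for a, b in ((nearest[:, :-1], nearest[:, 1:]),
                 (nearest[:-1, :], nearest[1:, :])):
        pairs = np.unique(np.stack([a.ravel(), b.ravel()], axis=1), axis=0)
        for r1, r2 in pairs:
            if r1 != r2:
                adj[r1].add(int(r2))
                adj[r2].add(int(r1))
    return adj


def _anti_adjacent_assignment(nearest, k, types, rng) -> list[str]:
    """Greedy colouring: hand out the type multiset over the k regions,
    preferring types not already held by a neighbouring region."""
    adj = _region_adjacency(nearest, k)
    remaining: dict[str, int] = {}
    for t in types:
        remaining[t] = remaining.get(t, 0) + 1
    order = sorted(range(k), key=lambda r: -len(adj[r]))
    assigned: list[str | None] = [None] * k
    for r in order:
        neighbour_types = {assigned[nb] for nb in adj[r]
                           if assigned[nb] is not None}
        options = [t for t, c in remaining.items() if c > 0]
        free = [t for t in options if t not in neighbour_types]
        pool = free if free else options
        t = pool[rng.integers(0, len(pool))]
        assigned[r] = t
        remaining[t] -= 1
    return assigned  # type: ignore[return-value]


def _paste_infrastructure(cells, count, area_ha, infra_codes, code_index,
                          cell_size, rng):
    if count <= 0 or not infra_codes or area_ha <= 0:
        return cells
    n = cells.shape[0]
    side_cells = max(1, int(round(np.sqrt(area_ha * 10_000) / cell_size)))
    occupied = np.zeros_like(cells, dtype=bool)
    for _ in range(count):
        code = infra_codes[rng.integers(0, len(infra_codes))]
        for _attempt in range(50):
            r = rng.integers(0, n - side_cells + 1)
            c = rng.integers(0, n - side_cells + 1)
            window = occupied[r:r + side_cells, c:c + side_cells]
            if not window.any():
                cells[r:r + side_cells, c:c + side_cells] = code_index[code]
                window[:] = True
                break
    return cells


# ---------------------------------------------------------------------------
# bird placement


def place_units(scenario: SyntheticScenario,
                maps: Mapping[str, GridPatchMap],
                season: str, year: int) -> list[Observation]:
    """Selection-weighted placement of one season's units.

    Each unit lives in one square (chosen proportionally to the square's
    total weighted area) and drops its locations independently, each in a
    cell with probability proportional to the weight of the cell's habitat
    type, uniform within the cell.  Winter units are coveys with sizes
    uniform on the configured range; spring units are territories with one
    record each unless ``locations_per_unit`` says otherwise.
    """
    weights = scenario.selection_weights[season]
    rng = _rng_for(scenario, year, 2, 0 if season == "winter" else 1)
    any_map = next(iter(maps.values()))
    legend = any_map.legend
    present: set[str] = set()
    for pmap in maps.values():
        present.update(legend[i] for i in np.unique(pmap.cells) if i >= 0)
    missing = sorted(present - set(weights))
    if missing:
        raise ValueError(f"no selection weight for present type(s) {missing}")
    absent = sorted(set(weights) - present)
    if absent:
        warnings.warn(f"weighted type(s) {absent} absent from every square; "
                      "weights renormalized over present types", stacklevel=2)

    w_by_index = np.array([weights.get(c, 0.0) for c in legend])
    square_ids = sorted(maps)
    masses = np.array([w_by_index[maps[s].cells].sum() for s in square_ids])
    p_square = masses / masses.sum()

    n_units = scenario.units[season]
    n_locs = scenario.locations_per_unit.get(season, 1)
    lo, hi = scenario.covey_size_range
    out: list[Observation] = []
    unit_squares = rng.choice(len(square_ids), size=n_units, p=p_square)
    for u in range(n_units):
        sid = square_ids[unit_squares[u]]
        pmap = maps[sid]
        cw = w_by_index[pmap.cells].ravel()
        p_cell = cw / cw.sum()
        picks = rng.choice(cw.size, size=n_locs, p=p_cell)
        rows, cols = np.unravel_index(picks, pmap.cells.shape)
        x0, y0, _, _ = pmap.square.bounds
        if season == "winter":
            kind, gsize = "covey", int(rng.integers(lo, hi + 1))
        else:
            kind, gsize = "territory", 1
        unit_id = f"{year}-{season}-u{u:03d}"
        for j, (r, c) in enumerate(zip(rows, cols)):
            jx, jy = rng.uniform(0, scenario.cell_size, size=2)
            out.append(Observation(
                obs_id=f"{unit_id}-l{j:03d}", unit_id=unit_id,
                square_id=sid,
                location=(float(x0 + c * scenario.cell_size + jx),
                          float(y0 + r * scenario.cell_size + jy)),
                year=year, season=season, unit_kind=kind, group_size=gsize))
    return out


def scenario_ground_truth(scenario: SyntheticScenario) -> GroundTruth:
    """Closed-form targets: alpha_i = w_i / sum_j w_j per season, electivity
    through the standard transform, plus the configured composition and
    patch-count trends."""
    alpha: dict[str, pd.Series] = {}
    eps: dict[str, pd.Series] = {}
    for season, w in scenario.selection_weights.items():
        codes = sorted(w)
        a = np.array([w[c] for c in codes], dtype=float)
        a = a / a.sum()
        s = pd.Series(a, index=pd.Index(codes, name="habitat"), name="alpha")
        alpha[season] = s
        eps[season] = chesson_epsilon(s, m=len(s))
    composition = {}
    patches = {}
    for year in scenario.years:
        infra_share = (scenario.infra_count.get(year, 0.0)
                       * scenario.infra_area_ha.get(year, 0.0)
                       / scenario.square(0).area_ha)
        comp = {c: s * (1 - infra_share)
                for c, s in scenario.background_shares.items()}
        infra_codes = [t.code for t in scenario.vocab if t.is_infrastructure]
        for c in infra_codes:
            comp[c] = infra_share / len(infra_codes)
        composition[year] = comp
        patches[year] = (scenario.patch_count[year]
                         + scenario.infra_count.get(year, 0.0))
    return GroundTruth(alpha=alpha, epsilon=eps, composition=composition,
                       patches_per_square=patches)
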