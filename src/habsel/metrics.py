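"""Landscape diversity and change summaries.

Fragmentation is tracked by counting *areas* — maximal connected regions of
one land-cover type — and their mean size per square and year, overall and
for the infrastructure subset (roads, field paths, settlements, parks,
power poles, windmills, construction sites).  Diversity is the
Shannon–Wiener index H = -sum p ln p (natural log) over habitat-type
proportions.  Seasonal exposure to infrastructure is summarised by medians
of nearest-infrastructure distances with a bootstrap standard error.
Mixed-model fits on these responses are out of scope; a tidy per-unit
export is provided instead so they can be fitted externally.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import (
    CircularPlot,
    Observation,
    PatchMap,
    distance_to_nearest_infrastructure,
    infrastructure_codes,
    reference_plot,
)
from .resampling import BootstrapSpec, percentile_interval

__all__ = [
    "patchify",
    "change_summary",
    "shannon_index",
    "seasonal_distance_summary",
    "trend_correlation",
]

SCOPES = ("availability", "squares_with_presence", "per_partridge",
          "per_territory")


def patchify(patch_map: PatchMap, connectivity: int = 4) -> list[tuple[str, float]]:
    """List of (habitat code, area in ha), one entry per connected patch.

    Grid maps use 4- (default) or 8-neighbour connectivity; polygon maps
    treat each feature as a patch, merging same-code features that touch.
    """
    return patch_map.patches(connectivity)


def shannon_index(proportions) -> float:
    """Shannon–Wiener diversity H = -sum p ln p in nats (0 ln 0 := 0)."""
    if isinstance(proportions, Mapping):
        proportions = list(proportions.values())
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("proportions must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _patch_stats(patches: Sequence[tuple[str, float]],
                 infra: frozenset[str]) -> dict[str, float]:
    areas = [a for _, a in patches]
    infra_areas = [a for c, a in patches if c in infra]
    return {
        "n_patches": len(areas),
        "mean_patch_area_ha": float(np.mean(areas)) if areas else float("nan"),
        "n_infra_patches": len(infra_areas),
        "mean_infra_area_ha": (float(np.mean(infra_areas)) if infra_areas
                               else float("nan")),
        "infra_area_ha": float(np.sum(infra_areas)) if infra_areas else 0.0,
    }


def change_summary(
    maps_by_year: Mapping[int, Mapping[str, PatchMap]],
    observations: Sequence[Observation] = (),
    scope: str = "availability",
    vocab=None,
    radius: float = 100.0,
    connectivity: int = 4,
    area_average: str = "squares",
) -> pd.DataFrame:
    """Per-year fragmentation and infrastructure summary.

    Parameters
    ----------
    maps_by_year
        year -> {square_id -> PatchMap}.
    scope
        "availability": all squares; "squares_with_presence": squares with at
        least one observation that year; "per_partridge"/"per_territory":
        statistics of the circular plots around the year's observations
        (territories: spring records only).
    area_average
        "squares" (default) averages each square's mean patch area over
        squares; "patches" pools all patches before averaging.

    Returns one row per year with average patch counts/areas, the same for
    the infrastructure subset, total infrastructure area and the number of
    contributing units (0-unit years keep NaN summaries, flagged empty).
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    if area_average not in ("squares", "patches"):
        raise ValueError("area_average must be 'squares' or 'patches'")
    rows = []
    for year in sorted(maps_by_year):
        maps = maps_by_year[year]
        infra = (infrastructure_codes(vocab) if vocab is not None
                 else _default_infra(next(iter(maps.values()))))
        year_obs = [o for o in observations if o.year == year]
        if scope == "per_territory":
            year_obs = [o for o in year_obs if o.season == "spring"]

        if scope in ("availability", "squares_with_presence"):
            ids = sorted(maps)
            if scope == "squares_with_presence":
                present = {o.square_id for o in year_obs}
                ids = [s for s in ids if s in present]
            stats_list = [_patch_stats(maps[s].patches(connectivity), infra)
                          for s in ids]
        else:
            stats_list = []
            for o in year_obs:
                pmap = maps[o.square_id]
                plot = CircularPlot(center=o.location, radius=radius,
                                    kind="use", source=o.obs_id)
                stats_list.append(
                    _patch_stats(pmap.patches_in_plot(plot, connectivity),
                                 infra))
        rows.append(_summarise_year(year, scope, stats_list, area_average))
    return pd.DataFrame(rows)


def _default_infra(pmap: PatchMap) -> frozenset[str]:
    from .landscape import FINE_INFRASTRUCTURE, ROUGH_INFRASTRUCTURE

    return ROUGH_INFRASTRUCTURE if pmap.scale == "rough" else FINE_INFRASTRUCTURE


def _summarise_year(year, scope, stats_list, area_average):
    n = len(stats_list)
    row = {"year": year, "scope": scope, "n_units": n, "empty": n == 0}
    if n == 0:
        for k in ("avg_patches_per_unit", "avg_patch_area_ha",
                  "avg_infra_patches_per_unit", "avg_infra_area_ha",
                  "total_infrastructure_ha"):
            row[k] = float("nan")
        return row
    row["avg_patches_per_unit"] = float(np.mean([s["n_patches"]
                                                 for s in stats_list]))
    if area_average == "squares":
        per_unit = [s["mean_patch_area_ha"] for s in stats_list
                    if not math.isnan(s["mean_patch_area_ha"])]
        row["avg_patch_area_ha"] = float(np.mean(per_unit))
        infra_means = [s["mean_infra_area_ha"] for s in stats_list
                       if not math.isnan(s["mean_infra_area_ha"])]
        row["avg_infra_area_ha"] = (float(np.mean(infra_means))
                                    if infra_means else float("nan"))
    else:
        tot_patches = sum(s["n_patches"] for s in stats_list)
        tot_area = sum(s["mean_patch_area_ha"] * s["n_patches"]
                       for s in stats_list if s["n_patches"])
        row["avg_patch_area_ha"] = tot_area / tot_patches
        n_inf = sum(s["n_infra_patches"] for s in stats_list)
        row["avg_infra_area_ha"] = (sum(s["infra_area_ha"]
                                        for s in stats_list) / n_inf
                                    if n_inf else float("nan"))
    row["avg_infra_patches_per_unit"] = float(
        np.mean([s["n_infra_patches"] for s in stats_list]))
    row["total_infrastructure_ha"] = float(
        np.sum([s["infra_area_ha"] for s in stats_list]))
    return row


def diversity_table(
    maps: Mapping[str, PatchMap],
    observations: Sequence[Observation] = (),
    radius: float = 100.0,
) -> pd.DataFrame:
    """Long table of Shannon–Wiener indices: one row per unit and type.

    "available" rows hold H of each whole-square composition; "used" rows
    hold H of the plot composition around each observation.  This is the
    tidy export for external mixed-model fits (square as random factor).
    """
    from .landscape import plot_composition

    rows = []
    for sid in sorted(maps):
        rows.append({"unit_id": sid, "square_id": sid, "type": "available",
                     "H": shannon_index(maps[sid].composition())})
    for o in observations:
        plot = CircularPlot(center=o.location, radius=radius, kind="use",
                            source=o.obs_id)
        comp = plot_composition(maps[o.square_id], plot)
        rows.append({"unit_id": o.obs_id, "square_id": o.square_id,
                     "type": "used", "H": shannon_index(comp.as_dict())})
    return pd.DataFrame(rows)


def seasonal_distance_summary(
    observations: Sequence[Observation],
    maps: Mapping[str, PatchMap],
    squares: Mapping[str, object] | None = None,
    spec: BootstrapSpec | None = None,
    infra_codes: frozenset[str] | None = None,
) -> pd.DataFrame:
    """Median nearest-infrastructure distance for used vs availability
    points, split by season.

    Availability points are the square centres (reference plots).  The
    dispersion of each median is a 1000-resample percentile-bootstrap
    standard error.  Undefined distances (squares without any
    infrastructure) are excluded and counted in ``n_undefined``.
    """
    if spec is None:
        spec = BootstrapSpec(n_resamples=1000, seed=0, min_units=2)
    groups: dict[tuple[str, str], list[float]] = {}
    undefined: dict[tuple[str, str], int] = {}

    def _add(key, dist):
        if dist is None:
            undefined[key] = undefined.get(key, 0) + 1
        else:
            groups.setdefault(key, []).append(dist)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for o in observations:
            d = distance_to_nearest_infrastructure(o.location,
                                                   maps[o.square_id],
                                                   infra_codes)
            _add((o.season, "used"), d)
        for season in sorted({o.season for o in observations}):
            for sid in sorted(maps):
                pmap = maps[sid]
                d = distance_to_nearest_infrastructure(pmap.square.centroid,
                                                       pmap, infra_codes)
                _add((season, "availability"), d)
    rows = []
    for key in sorted(set(groups) | set(undefined)):
        season, kind = key
        vals = np.asarray(groups.get(key, []), dtype=float)
        n_undef = undefined.get(key, 0)
        if vals.size == 0:
            rows.append({"season": season, "type": kind, "n": 0,
                         "median_m": float("nan"), "se_median_m": float("nan"),
                         "n_undefined": n_undef})
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed or 0,
                                    hash_key(season + kind)]))
        med, se, _ = percentile_interval(vals, spec, statistic=np.median,
                                         rng=rng)
        rows.append({"season": season, "type": kind, "n": int(vals.size),
                     "median_m": med, "se_median_m": se,
                     "n_undefined": n_undef})
    return pd.DataFrame(rows)


def hash_key(text: str) -> int:
    import zlib

    return zlib.crc32(text.encode("utf-8"))


def trend_correlation(years, totals) -> float:
    """Pearson product-moment correlation between year and a yearly total."""
    x = np.asarray(years, dtype=float)
    y = np.asarray(totals, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 (year, total) pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in years or totals")
    r, _ = stats.pearsonr(x, y)
    return float(r)
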