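"""Readers and writers for the pipeline's plain-text exchange formats.

Observations travel as CSV (obs_id, square_id, x, y, year, season,
unit_kind, group_size[, unit_id]).  Grid patch maps are Esri ASCII grids
with a JSON sidecar carrying the square geometry and the integer->code
legend; polygon patch maps are GeoJSON FeatureCollections whose features
carry ``square_id``, ``year``, ``scale`` and ``habitat`` properties.  All
writers are deterministic so reruns produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape

from .landscape import (
    GridPatchMap,
    Observation,
    PatchMap,
    PolygonPatchMap,
    SurveySquare,
)

OBS_COLUMNS = ["obs_id", "square_id", "x", "y", "year", "season",
               "unit_kind", "group_size", "unit_id"]


# ---------------------------------------------------------------------------
# observations


def write_observations(observations: Iterable[Observation], path) -> Path:
    rows = [{
        "obs_id": o.obs_id, "square_id": o.square_id,
        "x": o.location[0], "y": o.location[1], "year": o.year,
        "season": o.season, "unit_kind": o.unit_kind,
        "group_size": o.group_size, "unit_id": o.unit_id,
    } for o in observations]
    path = Path(path)
    pd.DataFrame(rows, columns=OBS_COLUMNS).to_csv(path, index=False)
    return path


def read_observations(path) -> list[Observation]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(OBS_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"observation CSV missing columns {sorted(missing)}")
    out = []
    for rec in df.to_dict("records"):
        out.append(Observation(
            obs_id=str(rec["obs_id"]), square_id=str(rec["square_id"]),
            location=(float(rec["x"]), float(rec["y"])),
            year=int(rec["year"]), season=str(rec["season"]),
            unit_kind=str(rec["unit_kind"]),
            group_size=int(rec["group_size"]),
            unit_id=str(rec.get("unit_id") or rec["obs_id"]),
        ))
    return out


# ---------------------------------------------------------------------------
# grid maps: Esri ASCII grid + JSON sidecar


def write_grid_map(pmap: GridPatchMap, path) -> Path:
    """Write one grid map as <path>.asc plus <path>.json metadata."""
    path = Path(path)
    asc = path.with_suffix(".asc")
    x0, y0, _, _ = pmap.square.bounds
    nrows, ncols = pmap.cells.shape
    lines = [
        f"ncols {ncols}", f"nrows {nrows}",
        f"xllcorner {x0!r}", f"yllcorner {y0!r}",
        f"cellsize {pmap.cell_size!r}", "NODATA_value -1",
    ]
    # ASCII grids store the northern row first; internal row 0 is southern
    for row in pmap.cells[::-1]:
        lines.append(" ".join(str(int(v)) for v in row))
    asc.write_text("\n".join(lines) + "\n")
    meta = {
        "square_id": pmap.square_id, "year": pmap.year, "scale": pmap.scale,
        "side_length": pmap.square.side_length,
        "centroid": list(pmap.square.centroid),
        "legend": {str(i): c for i, c in enumerate(pmap.legend)},
    }
    path.with_suffix(".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return asc


def read_grid_map(path) -> GridPatchMap:
    """Read a map written by :func:`write_grid_map` (pass either suffix)."""
    path = Path(path)
    asc = path.with_suffix(".asc")
    meta = json.loads(path.with_suffix(".json").read_text())
    header: dict[str, str] = {}
    rows: list[list[int]] = []
    for line in asc.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if len(parts) == 2 and not parts[0].lstrip("-").isdigit():
            header[parts[0].lower()] = parts[1]
        else:
            rows.append([int(v) for v in parts])
    cells = np.array(rows, dtype=np.int16)[::-1]  # back to south-first
    legend = [meta["legend"][str(i)] for i in range(len(meta["legend"]))]
    square = SurveySquare(square_id=meta["square_id"],
                          centroid=tuple(meta["centroid"]),
                          side_length=float(meta["side_length"]))
    return GridPatchMap(square, int(meta["year"]), meta["scale"], cells,
                        legend, float(header["cellsize"]))


def write_grid_maps(maps_by_year: Mapping[int, Mapping[str, GridPatchMap]],
                    outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for year in sorted(maps_by_year):
        for sid in sorted(maps_by_year[year]):
            written.append(write_grid_map(maps_by_year[year][sid],
                                          outdir / f"{sid}_{year}"))
    return written


def read_grid_maps(mapdir) -> dict[int, dict[str, GridPatchMap]]:
    """Load every <square>_<year>.asc map under a directory, keyed by year."""
    out: dict[int, dict[str, GridPatchMap]] = {}
    for asc in sorted(Path(mapdir).glob("*.asc")):
        pmap = read_grid_map(asc)
        out.setdefault(pmap.year, {})[pmap.square_id] = pmap
    if not out:
        raise FileNotFoundError(f"no .asc maps under {mapdir}")
    return out


# ---------------------------------------------------------------------------
# polygon maps: GeoJSON


def write_geojson_maps(maps: Sequence[PolygonPatchMap], path) -> Path:
    features = []
    squares = {}
    for pmap in maps:
        squares[pmap.square_id] = {
            "centroid": list(pmap.square.centroid),
            "side_length": pmap.square.side_length,
        }
        for poly, code in pmap.features:
            features.append({
                "type": "Feature",
                "geometry": shapely_mapping(poly),
                "properties": {"square_id": pmap.square_id,
                               "year": pmap.year, "scale": pmap.scale,
                               "habitat": code},
            })
    doc = {"type": "FeatureCollection", "features": features,
           "squares": squares}
    path = Path(path)
    path.write_text(json.dumps(doc, sort_keys=True) + "\n")
    return path


def read_geojson_maps(path) -> dict[int, dict[str, PolygonPatchMap]]:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    square_meta = doc.get("squares", {})
    grouped: dict[tuple[str, int, str], list] = {}
    for feat in doc["features"]:
        props = feat["properties"]
        key = (props["square_id"], int(props["year"]), props["scale"])
        grouped.setdefault(key, []).append(
            (shapely_shape(feat["geometry"]), props["habitat"]))
    out: dict[int, dict[str, PolygonPatchMap]] = {}
    for (sid, year, scale), feats in grouped.items():
        meta = square_meta.get(sid)
        if meta:
            square = SurveySquare(sid, tuple(meta["centroid"]),
                                  float(meta["side_length"]))
        else:  # fall back to the bounding box of the features
            from shapely.ops import unary_union

            minx, miny, maxx, maxy = unary_union(
                [p for p, _ in feats]).bounds
            side = max(maxx - minx, maxy - miny)
            square = SurveySquare(sid, ((minx + maxx) / 2, (miny + maxy) / 2),
                                  side)
        out.setdefault(year, {})[sid] = PolygonPatchMap(square, year, scale,
                                                        feats)
    return out


def read_maps(path) -> dict[int, dict[str, PatchMap]]:
    """Dispatch on suffix: a directory of .asc grids or a .geojson file."""
    p = Path(path)
    if p.is_dir():
        return read_grid_maps(p)
    if p.suffix in (".geojson", ".json"):
        return read_geojson_maps(p)
    raise ValueError(f"cannot infer map format from {path}")
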