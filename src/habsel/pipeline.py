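"""End-to-end analysis runs: simulate/load -> electivity -> bootstrap ->
landscape metrics -> report bundle.

`analyze` is the in-memory engine; `run_analysis` wraps it with file IO, a
config object, logging and a metadata sidecar so that a config hash plus a
seed fully determine every numeric output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .electivity import AvailabilityFrame, electivity_table
from .landscape import (
    FINE_SCALE_VOCABULARY,
    ROUGH_SCALE_VOCABULARY,
    CompositionProfile,
    Observation,
    PatchMap,
    plot_composition,
    reference_plot,
    vocabulary_codes,
)
from .metrics import (
    SCOPES,
    change_summary,
    diversity_table,
    seasonal_distance_summary,
    trend_correlation,
)
from .resampling import BootstrapSpec, bootstrap_all_habitats

logger = logging.getLogger("habsel")

__all__ = ["AnalysisConfig", "ReportBundle", "build_availability",
           "validate_inputs", "analyze", "run_analysis"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything a reproducible run needs.

    availability_mode: "averaged" compares every unit against one frame
    averaged over all squares (rough-scale convention); "per_square"
    compares each unit against its own square (fine-scale convention).
    availability_source: "square_map" (default) builds availability from
    each whole square map, which guarantees every used type is available;
    "reference_plot" uses the circular plot at each square centre (the
    field-protocol convention) but can raise an unsupported-use error when
    a used type is absent from every centre plot.
    """

    observations: str
    maps: str
    scale: str = "rough"
    availability_mode: str = "averaged"  # or "per_square"
    availability_source: str = "square_map"  # or "reference_plot"
    level: str = "individual"  # "square" | "individual" | "territory"
    radius: float = 100.0
    n_resamples: int = 1500
    confidence_level: float = 0.95
    min_units: int = 7
    seed: int = 0
    outdir: str = "habsel_out"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.availability_mode not in ("averaged", "per_square"):
            raise ValueError("availability_mode must be averaged|per_square")
        if self.availability_source not in ("reference_plot", "square_map"):
            raise ValueError(
                "availability_source must be reference_plot|square_map")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text))
        return cls(**data)

    def spec(self) -> BootstrapSpec:
        return BootstrapSpec(n_resamples=self.n_resamples,
                             level=self.confidence_level, seed=self.seed,
                             min_units=self.min_units)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All tables of one run plus the metadata needed to trace them."""

    electivity_long: pd.DataFrame
    electivity_summary: pd.DataFrame
    change_tables: pd.DataFrame
    diversity: pd.DataFrame
    distance_summary: pd.DataFrame
    metadata: dict
    paths: dict[str, Path] = field(default_factory=dict)


def build_availability(
    maps: Mapping[str, PatchMap],
    mode: str = "averaged",
    source: str = "reference_plot",
    radius: float = 100.0,
):
    """Availability frame(s) from one year's maps.

    Returns a single :class:`AvailabilityFrame` in averaged mode, or a dict
    square_id -> frame in per-square mode.
    """
    comps: dict[str, dict[str, float]] = {}
    for sid in sorted(maps):
        pmap = maps[sid]
        if source == "reference_plot":
            plot = reference_plot(pmap.square, radius)
            comps[sid] = plot_composition(pmap, plot).as_dict()
        else:
            comps[sid] = pmap.composition()
    if mode == "per_square":
        frames = {}
        for sid, c in comps.items():
            if sum(1 for v in c.values() if v > 0) < 2:
                logger.warning("square %s offers a single habitat type; "
                               "electivity is undefined there and the "
                               "square is skipped", sid)
                continue
            frames[sid] = AvailabilityFrame(proportions=c, mode="per_square",
                                            source=sid)
        if not frames:
            raise ValueError("no square offers at least 2 habitat types")
        return frames
    codes = sorted(set().union(*comps.values()))
    mean = {c: float(np.mean([comp.get(c, 0.0) for comp in comps.values()]))
            for c in codes}
    total = sum(mean.values())
    mean = {c: v / total for c, v in mean.items()}
    return AvailabilityFrame(proportions=mean, mode="averaged_over_squares",
                             source="all_squares")


def validate_inputs(
    observations_path,
    maps_by_year: Mapping[int, Mapping[str, PatchMap]],
    vocab=None,
    boundary_tolerance: float = 0.0,
) -> pd.DataFrame:
    """Report-only schema check of an observation CSV against the maps.

    Flags missing columns, unknown squares, out-of-square locations,
    coveys with group_size <= 2, unknown seasons/unit kinds and unknown
    habitat codes in the maps.  Returns a DataFrame (file, row, rule,
    detail); empty means clean.
    """
    problems = []
    path = Path(observations_path)
    df = pd.read_csv(path)
    required = {"obs_id", "square_id", "x", "y", "year", "season",
                "unit_kind", "group_size"}
    for col in sorted(required - set(df.columns)):
        problems.append({"file": path.name, "row": -1,
                         "rule": "missing_column", "detail": col})
    known_squares = {sid: m for maps in maps_by_year.values()
                     for sid, m in maps.items()}
    if not (required - set(df.columns)):
        for i, rec in enumerate(df.to_dict("records")):
            sid = str(rec["square_id"])
            if sid not in known_squares:
                problems.append({"file": path.name, "row": i,
                                 "rule": "unknown_square", "detail": sid})
            else:
                sq = known_squares[sid].square
                if not sq.contains(float(rec["x"]), float(rec["y"]),
                                   tolerance=boundary_tolerance):
                    problems.append({"file": path.name, "row": i,
                                     "rule": "location_outside_square",
                                     "detail": sid})
            if rec["unit_kind"] == "covey" and int(rec["group_size"]) <= 2:
                problems.append({
                    "file": path.name, "row": i, "rule": "covey_too_small",
                    "detail": f"a covey has more than 2 individuals, got "
                              f"{rec['group_size']}"})
            if rec["season"] not in ("winter", "spring"):
                problems.append({"file": path.name, "row": i,
                                 "rule": "unknown_season",
                                 "detail": str(rec["season"])})
            if rec["unit_kind"] not in ("individual", "pair", "covey",
                                        "territory"):
                problems.append({"file": path.name, "row": i,
                                 "rule": "unknown_unit_kind",
                                 "detail": str(rec["unit_kind"])})
    if vocab is not None:
        allowed = set(vocabulary_codes(vocab))
        for year, maps in sorted(maps_by_year.items()):
            for sid in sorted(maps):
                pmap = maps[sid]
                codes = set(getattr(pmap, "legend", ()))
                if not codes:
                    codes = {c for _, c in pmap.features}  # polygons
                for code in sorted(codes - allowed):
                    problems.append({"file": f"map:{sid}_{year}", "row": -1,
                                     "rule": "unknown_habitat_code",
                                     "detail": code})
    return pd.DataFrame(problems,
                        columns=["file", "row", "rule", "detail"])


def analyze(
    maps_by_year: Mapping[int, Mapping[str, PatchMap]],
    observations: Sequence[Observation],
    level: str = "individual",
    availability_mode: str = "averaged",
    availability_source: str = "square_map",
    radius: float = 100.0,
    spec: BootstrapSpec | None = None,
    analysis_year: int | None = None,
) -> dict[str, pd.DataFrame]:
    """In-memory pipeline over loaded maps and observations.

    Electivity and distance summaries run on ``analysis_year`` (default:
    the latest mapped year), per season; change and diversity tables span
    all years.  Returns a dict of tidy DataFrames.
    """
    if not observations:
        raise ValueError("empty observation set")
    if spec is None:
        spec = BootstrapSpec()
    year = analysis_year if analysis_year is not None else max(maps_by_year)
    maps = maps_by_year[year]
    mode_name = ("per_square" if availability_mode == "per_square"
                 else "averaged")
    avail = build_availability(maps, mode=mode_name,
                               source=availability_source, radius=radius)

    year_obs = [o for o in observations if o.year == year]
    long_parts, summary_parts = [], []
    for season in sorted({o.season for o in year_obs}):
        season_obs = [o for o in year_obs if o.season == season]
        if level == "territory" and season != "spring":
            continue
        table = electivity_table(season_obs, maps, avail, level=level,
                                 radius=radius)
        table.insert(0, "season", season)
        summary = bootstrap_all_habitats(table, spec)
        summary.insert(0, "season", season)
        long_parts.append(table)
        summary_parts.append(summary)
        logger.info("electivity %s/%s: %d units, %d rows", year, season,
                    table["unit_id"].nunique(), len(table))
    if not long_parts:
        raise ValueError(f"no analysable units at level {level!r} in {year}")

    change_parts = []
    for scope in SCOPES:
        change_parts.append(change_summary(maps_by_year, observations,
                                           scope=scope, radius=radius))
    diversity_parts = []
    for y in sorted(maps_by_year):
        d = diversity_table(maps_by_year[y],
                            [o for o in observations if o.year == y],
                            radius=radius)
        d.insert(0, "year", y)
        diversity_parts.append(d)
    distances = seasonal_distance_summary(
        year_obs, maps,
        spec=BootstrapSpec(n_resamples=1000, seed=spec.seed, min_units=2))
    infra = pd.concat(change_parts, ignore_index=True)
    avail_rows = infra[infra["scope"] == "availability"]
    trend = (trend_correlation(avail_rows["year"],
                               avail_rows["total_infrastructure_ha"])
             if len(avail_rows) >= 3 else float("nan"))
    return {
        "electivity_long": pd.concat(long_parts, ignore_index=True),
        "electivity_summary": pd.concat(summary_parts, ignore_index=True),
        "change_tables": infra,
        "diversity": pd.concat(diversity_parts, ignore_index=True),
        "distance_summary": distances,
        "infrastructure_trend_r": trend,
    }


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """File-level pipeline: load, analyse, write the report bundle."""
    maps_by_year = hio.read_maps(config.maps)
    observations = hio.read_observations(config.observations)
    logger.info("loaded %d observations, %d map-years",
                len(observations), len(maps_by_year))
    vocab = (ROUGH_SCALE_VOCABULARY if config.scale == "rough"
             else FINE_SCALE_VOCABULARY)
    violations = validate_inputs(config.observations, maps_by_year, vocab)
    if len(violations):
        logger.warning("input validation: %d problem(s); run `habsel "
                       "validate` for the full report", len(violations))
    tables = analyze(
        maps_by_year, observations, level=config.level,
        availability_mode=config.availability_mode,
        availability_source=config.availability_source,
        radius=config.radius, spec=config.spec())
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trend = tables.pop("infrastructure_trend_r")
    paths = {}
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        paths[name] = p
    metadata = {
        "run_id": f"{config.digest()}-{config.seed}",
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_observations": len(observations),
        "n_validation_problems": int(len(violations)),
        "infrastructure_trend_r": (None if np.isnan(trend) else trend),
        "row_counts": {k: int(len(v)) for k, v in tables.items()},
        "python": sys.version.split()[0],
    }
    meta_path = outdir / "run_metadata.json"
    meta_path.write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
    paths["metadata"] = meta_path
    return ReportBundle(metadata=metadata, paths=paths, **tables)
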