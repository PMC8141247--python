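"""Readers, writers, and the end-to-end pipeline.

Formats are deliberately plain: GeoJSON for geometry (region polygons
with severity-count properties, facility points with beds, road
linestrings with a ``road_class`` property), long-format CSV for the
travel-time matrix (``origin_id, destination_id, minutes`` — easy to
stream, diff, and validate partially), CSV for scores and tables, JSON
for the configuration echo and the run manifest. Coordinates are planar
metres throughout; no CRS metadata is read or written.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, mapping, shape

from . import __version__
from .accessibility import (
    DEFAULT_DECAY,
    DEFAULT_SEVERITY,
    DEFAULT_THRESHOLD_MIN,
    METHODS,
    SEVERITY_CATEGORIES,
    AccessResult,
    DecayScheme,
    Facility,
    Region,
    SeverityWeights,
    run_configuration,
)
from .evaluation import compare_methods, overlay_mean, summarize
from .synthetic_city import CityParams, SyntheticCity, generate_city
from .travel import (
    SpeedModel,
    RoadSegment,
    TravelTimeMatrix,
    build_network,
    closest_facility_distance,
    travel_time_matrix,
)

__all__ = [
    "read_regions",
    "read_facilities",
    "read_roads",
    "read_matrix",
    "write_matrix",
    "write_regions",
    "write_facilities",
    "write_roads",
    "write_scores",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id {i!r}")
        seen.add(i)


# ---------------------------------------------------------------- readers

def _load_features(path: str | Path) -> list[dict]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    return doc["features"]


def read_regions(path: str | Path) -> tuple[list[Region], dict[str, Polygon]]:
    """Read demand regions from GeoJSON polygons (or points).

    Each feature needs an ``id`` property plus the four severity counts
    (``mild``, ``moderate``, ``severe``, ``very_severe``). Polygon
    features use their geometric centroid unless an explicit
    ``centroid_x``/``centroid_y`` pair (a demand-weighted centroid) is
    present. Returns the regions plus any polygons found.
    """
    regions: list[Region] = []
    polygons: dict[str, Polygon] = {}
    for feat in _load_features(path):
        props = feat.get("properties") or {}
        rid = props.get("id")
        if rid is None:
            raise ValueError(f"{path}: region feature without an 'id' property")
        counts = []
        for cat in SEVERITY_CATEGORIES:
            if cat not in props:
                raise ValueError(f"{path}: region {rid!r} missing count {cat!r}")
            v = int(props[cat])
            if v < 0:
                raise ValueError(f"{path}: region {rid!r} has negative count for {cat!r}")
            counts.append(v)
        geom = shape(feat["geometry"])
        if "centroid_x" in props and "centroid_y" in props:
            centroid = (float(props["centroid_x"]), float(props["centroid_y"]))
        else:
            centroid = (geom.centroid.x, geom.centroid.y)
        if isinstance(geom, Polygon):
            polygons[str(rid)] = geom
        regions.append(
            Region(id=str(rid), centroid=centroid, severity_counts=tuple(counts))
        )
    _check_unique([r.id for r in regions], "region")
    return regions, polygons


def read_facilities(path: str | Path) -> list[Facility]:
    """Read hospital point features (``id`` and positive ``beds`` required)."""
    facilities = []
    for feat in _load_features(path):
        props = feat.get("properties") or {}
        fid = props.get("id")
        if fid is None or "beds" not in props:
            raise ValueError(f"{path}: facility feature missing 'id' or 'beds'")
        geom = shape(feat["geometry"])
        if not isinstance(geom, Point):
            raise ValueError(f"{path}: facility {fid!r} is not a point")
        facilities.append(
            Facility(id=str(fid), location=(geom.x, geom.y), beds=int(props["beds"]))
        )
    _check_unique([f.id for f in facilities], "facility")
    return facilities


def read_roads(path: str | Path) -> list[RoadSegment]:
    """Read road linestrings carrying a ``road_class`` property."""
    roads = []
    for k, feat in enumerate(_load_features(path)):
        props = feat.get("properties") or {}
        if "road_class" not in props:
            raise ValueError(f"{path}: road feature #{k} missing 'road_class'")
        geom = shape(feat["geometry"])
        if not isinstance(geom, LineString):
            raise ValueError(f"{path}: road feature #{k} is not a LineString")
        roads.append(
            RoadSegment(
                geometry=tuple((x, y) for x, y in geom.coords),
                road_class=str(props["road_class"]),
            )
        )
    return roads


def read_matrix(path: str | Path) -> TravelTimeMatrix:
    """Read a long-format travel-time CSV and require complete coverage.

    Columns: ``origin_id, destination_id, minutes``. Every origin must
    pair with every destination exactly once; the first missing pair is
    named in the error. The string ``inf`` marks unreachable pairs.
    """
    df = pd.read_csv(path, dtype={"origin_id": str, "destination_id": str})
    required = {"origin_id", "destination_id", "minutes"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: matrix CSV needs columns {sorted(required)}")
    origins = tuple(dict.fromkeys(df["origin_id"]))
    dests = tuple(dict.fromkeys(df["destination_id"]))
    pivot = df.pivot_table(
        index="origin_id", columns="destination_id", values="minutes", aggfunc="first"
    )
    if df.duplicated(["origin_id", "destination_id"]).any():
        dup = df[df.duplicated(["origin_id", "destination_id"])].iloc[0]
        raise ValueError(
            f"{path}: duplicate entry for pair "
            f"({dup['origin_id']!r}, {dup['destination_id']!r})"
        )
    pivot = pivot.reindex(index=origins, columns=dests)
    if pivot.isna().any().any():
        i, j = np.argwhere(pivot.isna().values)[0]
        raise ValueError(f"{path}: missing pair ({origins[i]!r}, {dests[j]!r})")
    return TravelTimeMatrix(origins, dests, pivot.values.astype(float))


# ---------------------------------------------------------------- writers

def _write_features(path: str | Path, features: list[dict]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def write_regions(
    path: str | Path,
    regions: Sequence[Region],
    polygons: Mapping[str, Polygon] | None = None,
) -> None:
    features = []
    for r in regions:
        geom = (
            polygons[r.id]
            if polygons is not None and r.id in polygons
            else Point(r.centroid)
        )
        props = {"id": r.id, "centroid_x": r.centroid[0], "centroid_y": r.centroid[1]}
        props.update(dict(zip(SEVERITY_CATEGORIES, (int(c) for c in r.severity_counts))))
        features.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
        )
    _write_features(path, features)


def write_facilities(path: str | Path, facilities: Sequence[Facility]) -> None:
    _write_features(
        path,
        [
            {
                "type": "Feature",
                "geometry": mapping(Point(f.location)),
                "properties": {"id": f.id, "beds": f.beds},
            }
            for f in facilities
        ],
    )


def write_roads(path: str | Path, roads: Sequence[RoadSegment]) -> None:
    _write_features(
        path,
        [
            {
                "type": "Feature",
                "geometry": mapping(LineString(seg.geometry)),
                "properties": {"road_class": seg.road_class},
            }
            for seg in roads
        ],
    )


def write_matrix(path: str | Path, ttm: TravelTimeMatrix) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows = [
        (o, d, ttm.times[i, j])
        for i, o in enumerate(ttm.origin_ids)
        for j, d in enumerate(ttm.destination_ids)
    ]
    pd.DataFrame(rows, columns=["origin_id", "destination_id", "minutes"]).to_csv(
        path, index=False
    )


def write_scores(path: str | Path, result: AccessResult) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "region_id": result.region_ids,
            "method": result.method,
            "score": result.scores,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------- pipeline

@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either point at input files (``regions_path`` + ``facilities_path``
    plus ``roads_path`` or a precomputed ``matrix_path``) or leave them
    unset to generate a synthetic city from ``city_params``. All
    randomness flows from the single seed inside ``city_params``.
    """

    out_dir: str
    regions_path: str | None = None
    facilities_path: str | None = None
    roads_path: str | None = None
    matrix_path: str | None = None
    methods: tuple[str, ...] = METHODS
    threshold_min: float = DEFAULT_THRESHOLD_MIN
    decay: DecayScheme = DEFAULT_DECAY
    severity: SeverityWeights = DEFAULT_SEVERITY
    speeds: SpeedModel = field(default_factory=SpeedModel)
    high_threshold: float = 0.57
    city_params: CityParams = field(default_factory=CityParams)

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("method list must be non-empty")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")
        for p in (self.regions_path, self.facilities_path, self.roads_path, self.matrix_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides win over file values."""
        with open(path) as fh:
            raw = json.load(fh)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "city_params" in raw and isinstance(raw["city_params"], dict):
            cp = dict(raw["city_params"])
            for key in ("severity_mix", "type_mix", "road_class_shares", "bed_range"):
                if key in cp:
                    cp[key] = tuple(cp[key])
            raw["city_params"] = CityParams(**cp)
        if "decay" in raw and isinstance(raw["decay"], dict):
            raw["decay"] = DecayScheme(
                tuple(raw["decay"]["zone_breaks"]), tuple(raw["decay"]["zone_weights"])
            )
        if "severity" in raw and isinstance(raw["severity"], (list, tuple)):
            raw["severity"] = SeverityWeights(tuple(raw["severity"]))
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)


def _run_method(
    config: RunConfig,
    method: str,
    regions: Sequence[Region],
    facilities: Sequence[Facility],
    times: np.ndarray,
) -> AccessResult:
    kwargs: dict = {}
    if method.endswith("e2sfca"):
        kwargs["scheme"] = config.decay
    else:
        kwargs["threshold"] = config.threshold_min
    if method.startswith("sev_"):
        kwargs["severity"] = config.severity
    return run_configuration(regions, facilities, times, method, **kwargs)


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Run generate/load -> travel times -> four scores -> evaluation.

    Writes every artefact (matrix, per-method scores, comparison table,
    summaries, overlay, manifest) under ``config.out_dir`` and returns
    the in-memory results. Re-running with the same config and seed
    reproduces all numeric outputs. Any stage failure aborts with the
    stage name; artefacts written by earlier stages are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "inputs"
        city: SyntheticCity | None = None
        if config.regions_path is None:
            logger.info("no input layers given: generating a synthetic city "
                        "(seed=%d)", config.city_params.seed)
            city = generate_city(config.city_params)
            regions, facilities, roads = city.regions, city.facilities, city.roads
            polygons = city.region_polygons
            write_regions(out / "regions.geojson", regions, polygons)
            write_facilities(out / "facilities.geojson", facilities)
            write_roads(out / "roads.geojson", roads)
        else:
            if config.facilities_path is None:
                raise ValueError("facilities_path required with regions_path")
            regions, polygons = read_regions(config.regions_path)
            facilities = read_facilities(config.facilities_path)
            roads = read_roads(config.roads_path) if config.roads_path else None

        stage = "traveltime"
        if config.matrix_path is not None:
            ttm = read_matrix(config.matrix_path)
            if set(ttm.origin_ids) != {r.id for r in regions} or set(
                ttm.destination_ids
            ) != {f.id for f in facilities}:
                raise ValueError("matrix ids do not match region/facility layers")
        else:
            if roads is None:
                raise ValueError("either roads_path or matrix_path is required")
            graph = build_network(roads, config.speeds)
            ttm = travel_time_matrix(
                graph,
                {r.id: r.centroid for r in regions},
                {f.id: f.location for f in facilities},
            )
        write_matrix(out / "travel_times.csv", ttm)
        region_index = {r.id: r for r in regions}
        facility_index = {f.id: f for f in facilities}
        regions = [region_index[rid] for rid in ttm.origin_ids]
        facilities = [facility_index[fid] for fid in ttm.destination_ids]

        stage = "access"
        results = [
            _run_method(config, m, regions, facilities, ttm.times)
            for m in config.methods
        ]
        for res in results:
            write_scores(out / f"scores_{res.method}.csv", res)
        wide = pd.DataFrame({"region_id": results[0].region_ids})
        for res in results:
            wide[res.method] = res.scores
        wide.to_csv(out / "scores_all.csv", index=False)

        stage = "evaluate"
        cfd = closest_facility_distance(ttm)
        pd.DataFrame(
            {"region_id": list(cfd), "closest_facility_min": list(cfd.values())}
        ).to_csv(out / "closest_facility.csv", index=False)
        comparison = compare_methods(results, cfd)
        comparison.to_csv(out / "comparison.csv")
        overlay = overlay_mean(results)
        write_scores(out / "scores_overlay.csv", overlay)
        summary_rows = []
        for res in [*results, overlay]:
            s = summarize(res.scores, config.high_threshold)
            summary_rows.append({"method": res.method, **asdict(s)})
        summary = pd.DataFrame(summary_rows).set_index("method")
        summary.to_csv(out / "summary.csv")

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "methods": list(config.methods),
            "threshold_min": config.threshold_min,
            "decay": {
                "zone_breaks": list(config.decay.zone_breaks),
                "zone_weights": list(config.decay.zone_weights),
            },
            "severity_weights": list(config.severity.weights),
            "speeds_kmh": dict(config.speeds.speeds_kmh),
            "high_threshold": config.high_threshold,
            "synthetic": city is not None,
            "seed": config.city_params.seed,
            "n_regions": len(regions),
            "n_facilities": len(facilities),
        }
        if city is not None:
            manifest["city_params"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config.city_params).items()
            }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "ttm": ttm,
        "results": results,
        "cfd": cfd,
        "comparison": comparison,
        "overlay": overlay,
        "summary": summary,
        "out_dir": str(out),
    }
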