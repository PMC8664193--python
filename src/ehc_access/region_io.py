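"""Reading and writing study regions as GeoJSON + CSV file sets.

A region directory holds::

    network.geojson    LineString per edge; properties length_m, speed_kmh,
                       node_a, node_b (junction ids are preserved verbatim)
    stations.geojson   Point per ambulance station; property facility_id
    hospitals.geojson  Point per emergency department; property facility_id
    areas.geojson      Polygon per analysis area; property area_id
    covariates.csv     area_id, older_share, high_edu_share, median_income,
                       area_type, region, has_station (+ municipality_id,
                       population, reportable)
    popgrid.csv        x, y, count
    truth.json         generating parameters (synthetic regions only)

The writers serialize floats with full ``repr`` precision, so a write/read
round trip reproduces every numeric field exactly.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape

from .region import AreaUnit, SyntheticRegion
from .road_network import (
    AMBULANCE_STATION,
    EMERGENCY_DEPARTMENT,
    Facility,
    build_network,
)

NETWORK_FILE = "network.geojson"
STATIONS_FILE = "stations.geojson"
HOSPITALS_FILE = "hospitals.geojson"
AREAS_FILE = "areas.geojson"
COVARIATES_FILE = "covariates.csv"
POPGRID_FILE = "popgrid.csv"
TRUTH_FILE = "truth.json"


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def _dump(obj: dict, path: Path) -> None:
    try:
        with open(path, "w") as fh:
            json.dump(obj, fh, separators=(",", ":"))
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"failed to write {path}: {exc}") from exc


def write_region(region: SyntheticRegion, directory: str | os.PathLike) -> list[Path]:
    """Write a region to ``directory``; returns the written paths."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    edge_feats = []
    for rec in sorted(region.network.edge_records(), key=lambda r: (r["a"], r["b"])):
        pa = region.network.position(rec["a"])
        pb = region.network.position(rec["b"])
        edge_feats.append({
            "type": "Feature",
            "geometry": {"type": "LineString", "coordinates": [list(pa), list(pb)]},
            "properties": {
                "node_a": rec["a"], "node_b": rec["b"],
                "length_m": rec["length_m"], "speed_kmh": rec["speed_kmh"],
            },
        })
    _dump(_feature_collection(edge_feats), out / NETWORK_FILE)
    written.append(out / NETWORK_FILE)

    for fname, facs in ((STATIONS_FILE, region.stations), (HOSPITALS_FILE, region.hospitals)):
        feats = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": list(f.location)},
                "properties": {"facility_id": f.facility_id},
            }
            for f in facs
        ]
        _dump(_feature_collection(feats), out / fname)
        written.append(out / fname)

    area_feats = [
        {
            "type": "Feature",
            "geometry": shapely.geometry.mapping(a.polygon),
            "properties": {"area_id": a.area_id, "reportable": a.reportable},
        }
        for a in region.areas
    ]
    _dump(_feature_collection(area_feats), out / AREAS_FILE)
    written.append(out / AREAS_FILE)

    cov = region.covariate_frame()
    cov.to_csv(out / COVARIATES_FILE, index=False)
    written.append(out / COVARIATES_FILE)

    grid = pd.DataFrame(region.population_grid, columns=["x", "y", "count"])
    grid.to_csv(out / POPGRID_FILE, index=False)
    written.append(out / POPGRID_FILE)

    _dump(region.truth, out / TRUTH_FILE)
    written.append(out / TRUTH_FILE)
    return written


def _load_features(path: Path) -> list[dict]:
    if not path.exists():
        raise FileNotFoundError(f"missing region file: {path}")
    with open(path) as fh:
        return json.load(fh)["features"]


def _load_facilities(path: Path, kind: str) -> list[Facility]:
    feats = _load_features(path)
    if not feats:
        raise ValueError(f"no facilities in {path}")
    return [
        Facility(
            facility_id=str(f["properties"]["facility_id"]),
            kind=kind,
            location=tuple(f["geometry"]["coordinates"]),
        )
        for f in feats
    ]


def read_region(directory: str | os.PathLike) -> SyntheticRegion:
    """Read a region directory back into a :class:`SyntheticRegion`."""
    src = Path(directory)
    network = build_network(_load_features(src / NETWORK_FILE))
    stations = _load_facilities(src / STATIONS_FILE, AMBULANCE_STATION)
    hospitals = _load_facilities(src / HOSPITALS_FILE, EMERGENCY_DEPARTMENT)

    cov = pd.read_csv(src / COVARIATES_FILE, float_precision="round_trip")
    cov = cov.set_index("area_id", drop=False)
    areas: list[AreaUnit] = []
    for feat in _load_features(src / AREAS_FILE):
        area_id = str(feat["properties"]["area_id"])
        row = cov.loc[area_id]
        areas.append(
            AreaUnit(
                area_id=area_id,
                polygon=shape(feat["geometry"]),
                area_type=row["area_type"],
                region=row["region"],
                older_share=float(row["older_share"]),
                high_edu_share=float(row["high_edu_share"]),
                median_income=float(row["median_income"]),
                has_station=int(row["has_station"]),
                municipality_id=int(row.get("municipality_id", 0)),
                population=float(row.get("population", 0.0)),
                reportable=bool(feat["properties"].get("reportable", True)),
            )
        )

    grid = pd.read_csv(src / POPGRID_FILE, float_precision="round_trip")
    population_grid = grid[["x", "y", "count"]].to_numpy(dtype=float)

    truth: dict = {}
    truth_path = src / TRUTH_FILE
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)

    return SyntheticRegion(
        network=network,
        stations=stations,
        hospitals=hospitals,
        areas=sorted(areas, key=lambda a: a.area_id),
        population_grid=population_grid,
        truth=truth,
    )
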