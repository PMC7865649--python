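"""Readers and writers for the pipeline's file formats.

All tables are UTF-8 CSV with a header row. Coordinates may be decimal
degrees or DMS strings (auto-detected per cell). Map handoff formats are
GeoJSON (plain JSON, written with the stdlib) and KML (small flat XML).
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Sequence

import pandas as pd

from .geodesy import GeoPoint, parse_coordinate
from .localization import DetectionSet, LocalizationResult, Station
from .synthetic import TrueCall
from .tracking import CallRecord, IndividualCluster, IntervalCounts, MovementPath

__all__ = [
    "InputFormatError",
    "read_stations",
    "write_stations",
    "read_detections",
    "write_detections",
    "read_references",
    "write_results",
    "read_results",
    "write_truth",
    "write_clusters",
    "write_interval_counts",
    "results_to_geojson",
    "results_to_kml",
    "paths_to_geojson",
]


class InputFormatError(ValueError):
    """An input file is missing, malformed, or lacks required columns."""


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except Exception as exc:  # pandas raises several parser error types
        raise InputFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def read_stations(path: str | Path) -> list[Station]:
    """Stations CSV: columns id, lat, lon (decimal degrees or DMS strings)."""
    df = _read_csv(path, ["id", "lat", "lon"])
    stations = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            lat = parse_coordinate(row.lat)
            lon = parse_coordinate(row.lon)
            stations.append(Station(id=str(row.id), position=GeoPoint(lat, lon)))
        except (ValueError, TypeError) as exc:
            raise InputFormatError(f"{path}: line {row_no}: {exc}") from exc
    ids = [s.id for s in stations]
    if len(set(ids)) != len(ids):
        raise InputFormatError(f"{path}: duplicate station ids {ids}")
    return stations


def write_stations(stations: Sequence[Station], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [s.id for s in stations],
            "lat": [s.position.lat for s in stations],
            "lon": [s.position.lon for s in stations],
        }
    ).to_csv(path, index=False)


def read_detections(path: str | Path) -> list[DetectionSet]:
    """Detections CSV (long format): columns call_id, station_id, time_s."""
    df = _read_csv(path, ["call_id", "station_id", "time_s"])
    sets: list[DetectionSet] = []
    if df.empty:
        return sets
    try:
        df = df.assign(time_s=pd.to_numeric(df["time_s"]))
    except (ValueError, TypeError) as exc:
        bad = df[pd.to_numeric(df["time_s"], errors="coerce").isna()]
        line = int(bad.index[0]) + 2 if len(bad) else "?"
        raise InputFormatError(
            f"{path}: line {line}: non-numeric time_s value"
        ) from exc
    for call_id, grp in df.groupby("call_id", sort=False):
        dup = grp["station_id"].duplicated()
        if dup.any():
            raise InputFormatError(
                f"{path}: call {call_id!r} has duplicate station "
                f"{grp['station_id'][dup].iloc[0]!r}"
            )
        sets.append(
            DetectionSet(
                call_id=str(call_id),
                detections=dict(zip(grp["station_id"], grp["time_s"])),
            )
        )
    return sets


def write_detections(sets: Sequence[DetectionSet], path: str | Path) -> None:
    rows = [
        {"call_id": ds.call_id, "station_id": sid, "time_s": t}
        for ds in sets
        for sid, t in ds.detections.items()
    ]
    pd.DataFrame(rows, columns=["call_id", "station_id", "time_s"]).to_csv(
        path, index=False
    )


def read_references(path: str | Path) -> dict[str, GeoPoint]:
    """Reference points CSV: columns id, lat, lon."""
    df = _read_csv(path, ["id", "lat", "lon"])
    refs: dict[str, GeoPoint] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            refs[str(row.id)] = GeoPoint(
                parse_coordinate(row.lat), parse_coordinate(row.lon)
            )
        except (ValueError, TypeError) as exc:
            raise InputFormatError(f"{path}: line {row_no}: {exc}") from exc
    return refs


def write_results(results: Sequence[LocalizationResult], path: str | Path) -> None:
    pd.DataFrame(
        {
            "call_id": [r.call_id for r in results],
            "lat": [r.position.lat for r in results],
            "lon": [r.position.lon for r in results],
            "rmse_m": [r.rmse_m for r in results],
            "first_station": [r.first_station for r in results],
            "n_stations_used": [len(r.stations_used) for r in results],
        }
    ).to_csv(path, index=False)


def read_results(path: str | Path, time_by_call: dict[str, float] | None = None
                 ) -> list[CallRecord]:
    """Load a results CSV as CallRecords for the tracking layer.

    If the CSV has a time_s column it is used; otherwise detection times can
    be supplied via ``time_by_call`` (first-detection time per call).
    """
    df = _read_csv(path, ["call_id", "lat", "lon", "rmse_m"])
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        cid = str(row.call_id)
        if "time_s" in df.columns:
            t = float(row.time_s)
        elif time_by_call is not None and cid in time_by_call:
            t = time_by_call[cid]
        else:
            raise InputFormatError(
                f"{path}: line {row_no}: no time_s column and no supplied "
                f"time for call {cid!r}"
            )
        records.append(
            CallRecord(
                call_id=cid,
                position=GeoPoint(float(row.lat), float(row.lon)),
                time_s=t,
                rmse_m=float(row.rmse_m),
            )
        )
    return records


def write_truth(calls: Sequence[TrueCall], path: str | Path) -> None:
    pd.DataFrame(
        {
            "call_id": [c.call_id for c in calls],
            "individual_id": [c.individual_id for c in calls],
            "lat": [c.position.lat for c in calls],
            "lon": [c.position.lon for c in calls],
            "t": [c.emission_time_s for c in calls],
        }
    ).to_csv(path, index=False)


def write_clusters(clusters: Sequence[IndividualCluster], path: str | Path) -> None:
    rows = [
        {"cluster_id": c.cluster_id, "call_id": cid}
        for c in clusters
        for cid in c.call_ids
    ]
    pd.DataFrame(rows, columns=["cluster_id", "call_id"]).to_csv(path, index=False)


def write_interval_counts(ic: IntervalCounts, path: str | Path) -> None:
    start = [ic.session_start + k * ic.interval_s for k in range(len(ic.counts))]
    pd.DataFrame(
        {"interval_start_s": start, "count": list(ic.counts)}
    ).to_csv(path, index=False)


def _feature(geom: dict, props: dict) -> dict:
    return {"type": "Feature", "geometry": geom, "properties": props}


def results_to_geojson(
    results: Sequence[LocalizationResult], path: str | Path
) -> None:
    """Point FeatureCollection of retrieved call positions (lon, lat order)."""
    features = [
        _feature(
            {"type": "Point", "coordinates": [r.position.lon, r.position.lat]},
            {
                "call_id": r.call_id,
                "rmse_m": r.rmse_m,
                "first_station": r.first_station,
            },
        )
        for r in results
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=2)
    )


def paths_to_geojson(paths: Sequence[MovementPath], path: str | Path) -> None:
    """LineString FeatureCollection of per-individual movement paths."""
    features = []
    for p in paths:
        if len(p.positions) < 2:
            continue
        features.append(
            _feature(
                {
                    "type": "LineString",
                    "coordinates": [[q.lon, q.lat] for q in p.positions],
                },
                {
                    "cluster_id": p.cluster_id,
                    "net_displacement_m": p.net_displacement_m,
                    "path_length_m": p.path_length_m,
                    "bearing_deg": p.bearing_deg,
                },
            )
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=2)
    )


def results_to_kml(results: Sequence[LocalizationResult], path: str | Path) -> None:
    """Minimal KML document of placemarks, for satellite-imagery overlay."""
    kml = ET.Element("kml", xmlns="http://www.opengis.net/kml/2.2")
    doc = ET.SubElement(kml, "Document")
    ET.SubElement(doc, "name").text = "Localized calls"
    for r in results:
        pm = ET.SubElement(doc, "Placemark")
        ET.SubElement(pm, "name").text = r.call_id
        ET.SubElement(pm, "description").text = (
            f"RMSE {r.rmse_m:.2f} m; first detector {r.first_station}"
        )
        point = ET.SubElement(pm, "Point")
        ET.SubElement(point, "coordinates").text = (
            f"{r.position.lon:.8f},{r.position.lat:.8f},0"
        )
    ET.ElementTree(kml).write(path, encoding="unicode", xml_declaration=True)
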