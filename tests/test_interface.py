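"""File formats and the command-line pipeline (localize/simulate/validate/track)."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
import pytest
from click.testing import CliRunner

from deertrack.cli import main
from deertrack.geodesy import GeoPoint, flat_earth_distance, offset_point
from deertrack.io import (
    InputFormatError,
    read_detections,
    read_results,
    read_stations,
    results_to_geojson,
    write_detections,
    write_results,
    write_stations,
)
from deertrack.localization import build_grid, localize
from deertrack.synthetic import forward_detections, utokyo_fixture


@pytest.fixture()
def runner():
    return CliRunner()


def _all_output(result) -> str:
    out = result.output
    try:
        out += result.stderr
    except (ValueError, AttributeError):
        pass
    return out


def _write_utokyo_inputs(tmp: Path, sources: dict[str, GeoPoint]) -> tuple[Path, Path]:
    fix = utokyo_fixture()
    stations_csv = tmp / "stations.csv"
    write_stations(list(fix.stations), stations_csv)
    dsets = [
        forward_detections(p, list(fix.stations), 340.0, call_id=cid)
        for cid, p in sources.items()
    ]
    detections_csv = tmp / "detections.csv"
    write_detections(dsets, detections_csv)
    return stations_csv, detections_csv


class TestCsvRoundTrips:
    def test_stations_roundtrip_and_dms_autodetect(self, tmp_path):
        csv = tmp_path / "stations.csv"
        csv.write_text(
            "id,lat,lon\n"
            "Rec1,35°39′38.12″ N,139°40′54.13″ E\n"
            "Rec2,35.6600528,139.6821028\n"
        )
        stations = read_stations(csv)
        assert stations[0].position.lat == pytest.approx(35 + 39 / 60 + 38.12 / 3600)
        assert stations[1].position.lon == pytest.approx(139.6821028)
        out = tmp_path / "back.csv"
        write_stations(stations, out)
        again = read_stations(out)
        assert [s.id for s in again] == ["Rec1", "Rec2"]
        assert again[0].position.lat == pytest.approx(
            stations[0].position.lat, abs=1e-12
        )

    def test_detections_roundtrip(self, tmp_path):
        fix = utokyo_fixture()
        src = fix.references["C"]
        ds = forward_detections(src, list(fix.stations), 340.0, call_id="C")
        p = tmp_path / "det.csv"
        write_detections([ds], p)
        back = read_detections(p)
        assert len(back) == 1
        assert back[0].detections == pytest.approx(ds.detections)

    def test_results_roundtrip_with_times(self, tmp_path, utokyo,
                                          utokyo_grid_small):
        src = offset_point(utokyo_grid_small.center, 4.0, -3.0)
        ds = forward_detections(src, list(utokyo.stations), 340.0, call_id="x")
        res = localize(ds, list(utokyo.stations), 340.0, utokyo_grid_small)
        p = tmp_path / "results.csv"
        write_results([res], p)
        df = pd.read_csv(p)
        assert list(df.columns) == [
            "call_id", "lat", "lon", "rmse_m", "first_station", "n_stations_used",
        ]
        records = read_results(p, time_by_call={"x": 12.0})
        assert records[0].time_s == 12.0

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("foo,bar\n1,2\n")
        with pytest.raises(InputFormatError, match="missing required column"):
            read_stations(p)

    def test_bad_coordinate_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("id,lat,lon\nRec1,35.66,139.68\nRec2,oops,139.68\n")
        with pytest.raises(InputFormatError, match="line 3"):
            read_stations(p)

    def test_geojson_is_valid_and_lonlat_ordered(self, tmp_path, utokyo,
                                                 utokyo_grid_small):
        src = offset_point(utokyo_grid_small.center, 4.0, -3.0)
        ds = forward_detections(src, list(utokyo.stations), 340.0, call_id="x")
        res = localize(ds, list(utokyo.stations), 340.0, utokyo_grid_small)
        p = tmp_path / "r.geojson"
        results_to_geojson([res], p)
        gj = json.loads(p.read_text())
        assert gj["type"] == "FeatureCollection"
        lon, lat = gj["features"][0]["geometry"]["coordinates"]
        assert lon == pytest.approx(res.position.lon)
        assert lat == pytest.approx(res.position.lat)


class TestLocalizeCommand:
    def test_single_call_end_to_end(self, runner, tmp_path):
        fix = utokyo_fixture()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid = build_grid(list(fix.stations), spacing_m=0.5, extent_m=400.0)
        src = offset_point(grid.center, 10.0, 6.0)  # on-lattice source
        st_csv, det_csv = _write_utokyo_inputs(tmp_path, {"E1": src})
        out = tmp_path / "out"
        result = runner.invoke(main, [
            "localize", "--stations", str(st_csv), "--detections", str(det_csv),
            "--out-dir", str(out), "--speed", "340", "--extent", "400",
            "--geojson", "--kml",
        ])
        assert result.exit_code == 0, _all_output(result)
        df = pd.read_csv(out / "results.csv")
        assert len(df) == 1 and df.loc[0, "call_id"] == "E1"
        got = GeoPoint(df.loc[0, "lat"], df.loc[0, "lon"])
        assert flat_earth_distance(got, src) <= 1e-6
        assert (out / "results.geojson").exists()
        assert (out / "results.kml").exists()
        snap = json.loads((out / "localize_config.json").read_text())
        assert snap["speed_mps"] == 340.0 and snap["extent_m"] == 400.0

    def test_temperature_sets_speed(self, runner, tmp_path):
        fix = utokyo_fixture()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid = build_grid(list(fix.stations), spacing_m=0.5, extent_m=400.0)
        src = offset_point(grid.center, -8.0, 4.0)
        st_csv, det_csv = _write_utokyo_inputs(tmp_path, {"c": src})
        out = tmp_path / "out"
        result = runner.invoke(main, [
            "localize", "--stations", str(st_csv), "--detections", str(det_csv),
            "--out-dir", str(out), "--temperature", "18", "--extent", "400",
        ])
        assert result.exit_code == 0, _all_output(result)
        snap = json.loads((out / "localize_config.json").read_text())
        assert snap["speed_mps"] == pytest.approx(331.2 + 0.606 * 18)

    def test_empty_detections_warns_but_succeeds(self, runner, tmp_path):
        st_csv, _ = _write_utokyo_inputs(tmp_path, {})
        det_csv = tmp_path / "empty.csv"
        det_csv.write_text("call_id,station_id,time_s\n")
        out = tmp_path / "out"
        result = runner.invoke(main, [
            "localize", "--stations", str(st_csv), "--detections", str(det_csv),
            "--out-dir", str(out), "--speed", "340", "--extent", "400",
        ])
        assert result.exit_code == 0, _all_output(result)
        assert pd.read_csv(out / "results.csv").empty

    def test_corrupt_input_exits_2(self, runner, tmp_path):
        st_csv = tmp_path / "stations.csv"
        st_csv.write_text("id,lat,lon\nRec1,35.66,139.68\nRec2,bogus,139.68\n")
        det_csv = tmp_path / "det.csv"
        det_csv.write_text("call_id,station_id,time_s\nc,Rec1,0.0\n")
        result = runner.invoke(main, [
            "localize", "--stations", str(st_csv), "--detections", str(det_csv),
            "--speed", "340",
        ])
        assert result.exit_code == 2

    def test_rerun_is_idempotent(self, runner, tmp_path):
        fix = utokyo_fixture()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid = build_grid(list(fix.stations), spacing_m=0.5, extent_m=400.0)
        src = offset_point(grid.center, 22.0, -14.0)
        st_csv, det_csv = _write_utokyo_inputs(tmp_path, {"c": src})
        outputs = []
        for name in ("a", "b"):
            out = tmp_path / name
            result = runner.invoke(main, [
                "localize", "--stations", str(st_csv),
                "--detections", str(det_csv), "--out-dir", str(out),
                "--speed", "340", "--extent", "400",
            ])
            assert result.exit_code == 0
            outputs.append((out / "results.csv").read_bytes())
        assert outputs[0] == outputs[1]


class TestSimulateCommand:
    def test_seeded_runs_are_byte_identical(self, runner, tmp_path):
        files = []
        for name in ("a", "b"):
            out = tmp_path / name
            result = runner.invoke(main, [
                "simulate", "--seed", "5", "--out-dir", str(out),
            ])
            assert result.exit_code == 0, _all_output(result)
            files.append((out / "detections.csv").read_bytes())
            assert (out / "truth.csv").exists()
            assert (out / "stations.csv").exists()
        assert files[0] == files[1]

    def test_zero_individuals_empty_truth(self, runner, tmp_path):
        out = tmp_path / "sim"
        result = runner.invoke(main, [
            "simulate", "--n-individuals", "0", "--out-dir", str(out),
        ])
        assert result.exit_code == 0
        assert pd.read_csv(out / "truth.csv").empty

    def test_config_file_and_roundtrip_through_localize(self, runner, tmp_path):
        cfg = tmp_path / "scenario.yaml"
        cfg.write_text(
            "seed: 9\nn_individuals: 2\nduration_s: 1200\n"
            "timing_noise_sd_s: 0.0\nmovement_step_sd_m: 0.0\n"
        )
        sim = tmp_path / "sim"
        result = runner.invoke(main, ["simulate", "--config", str(cfg),
                                      "--out-dir", str(sim)])
        assert result.exit_code == 0, _all_output(result)
        out = tmp_path / "loc"
        result = runner.invoke(main, [
            "localize", "--stations", str(sim / "stations.csv"),
            "--detections", str(sim / "detections.csv"),
            "--out-dir", str(out), "--speed", "340",
            "--extent", "2400", "--spacing", "4",
        ])
        assert result.exit_code == 0, _all_output(result)
        n_loc = len(pd.read_csv(out / "results.csv"))
        n_localizable = sum(
            ds.localizable for ds in read_detections(sim / "detections.csv")
        )
        assert n_loc == n_localizable

    def test_bad_config_exits_2(self, runner, tmp_path):
        cfg = tmp_path / "scenario.yaml"
        cfg.write_text("no_such_field: 1\n")
        result = runner.invoke(main, ["simulate", "--config", str(cfg)])
        assert result.exit_code == 2


class TestValidateCommand:
    def test_known_offset_gives_five_meter_error(self, runner, tmp_path):
        fix = utokyo_fixture()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid = build_grid(list(fix.stations), spacing_m=0.5, extent_m=400.0)
        src = offset_point(grid.center, 10.0, 6.0)  # on-lattice, exact retrieval
        ref = offset_point(src, 0.0, 5.0)  # surveyed point 5 m north
        st_csv, det_csv = _write_utokyo_inputs(tmp_path, {"P": src})
        ref_csv = tmp_path / "refs.csv"
        ref_csv.write_text(f"id,lat,lon\nP,{ref.lat!r},{ref.lon!r}\n")
        out = tmp_path / "val"
        result = runner.invoke(main, [
            "validate", "--stations", str(st_csv), "--detections", str(det_csv),
            "--references", str(ref_csv), "--out-dir", str(out),
            "--speed", "340", "--extent", "400",
        ])
        assert result.exit_code == 0, _all_output(result)
        summary = json.loads((out / "summary.json").read_text())
        assert summary["mean_error_m"] == pytest.approx(5.0, abs=1e-6)
        assert summary["rmse_m"] == pytest.approx(5.0, abs=1e-6)

    def test_noise_free_points_recovered_subcell(self, runner, tmp_path):
        fix = utokyo_fixture()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid = build_grid(list(fix.stations), spacing_m=0.5, extent_m=400.0)
        sources = {
            "P1": offset_point(grid.center, 6.2, -4.1),
            "P2": offset_point(grid.center, -11.7, 8.3),
        }
        st_csv, det_csv = _write_utokyo_inputs(tmp_path, sources)
        ref_csv = tmp_path / "refs.csv"
        lines = ["id,lat,lon"] + [
            f"{k},{p.lat!r},{p.lon!r}" for k, p in sources.items()
        ]
        ref_csv.write_text("\n".join(lines) + "\n")
        out = tmp_path / "val"
        result = runner.invoke(main, [
            "validate", "--stations", str(st_csv), "--detections", str(det_csv),
            "--references", str(ref_csv), "--out-dir", str(out),
            "--speed", "340", "--extent", "400",
        ])
        assert result.exit_code == 0, _all_output(result)
        summary = json.loads((out / "summary.json").read_text())
        assert summary["n_points"] == 2
        assert summary["mean_error_m"] <= 0.36

    def test_unmatched_reference_excluded(self, runner, tmp_path):
        fix = utokyo_fixture()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid = build_grid(list(fix.stations), spacing_m=0.5, extent_m=400.0)
        src = offset_point(grid.center, 10.0, 6.0)
        st_csv, det_csv = _write_utokyo_inputs(tmp_path, {"P": src})
        ref_csv = tmp_path / "refs.csv"
        ref_csv.write_text(
            f"id,lat,lon\nQ,{src.lat!r},{src.lon!r}\n"
        )
        out = tmp_path / "val"
        result = runner.invoke(main, [
            "validate", "--stations", str(st_csv), "--detections", str(det_csv),
            "--references", str(ref_csv), "--out-dir", str(out),
            "--speed", "340", "--extent", "400",
        ])
        assert result.exit_code == 0
        summary = json.loads((out / "summary.json").read_text())
        assert summary["n_points"] == 0


class TestTrackCommand:
    def test_track_end_to_end(self, runner, tmp_path):
        # two callers ~200 m apart, one of them calling three times
        rows = [
            ("a1", 36.9400, 139.2200, 0.0, 0.1),
            ("a2", 36.9401, 139.2200, 1200.0, 0.1),
            ("a3", 36.9401, 139.2201, 2400.0, 0.1),
            ("b1", 36.9420, 139.2200, 600.0, 0.1),
        ]
        res_csv = tmp_path / "results.csv"
        res_csv.write_text(
            "call_id,lat,lon,rmse_m,first_station,n_stations_used,time_s\n"
            + "\n".join(
                f"{cid},{lat!r},{lon!r},{r},Rec1,3,{t}"
                for cid, lat, lon, t, r in rows
            )
            + "\n"
        )
        out = tmp_path / "tracks"
        result = runner.invoke(main, [
            "track", "--results", str(res_csv), "--out-dir", str(out),
            "--linkage", "50", "--interval", "600",
            "--session-start", "0", "--session-end", "3000",
        ])
        assert result.exit_code == 0, _all_output(result)
        clusters = pd.read_csv(out / "clusters.csv")
        assert clusters["cluster_id"].nunique() == 2
        assert len(clusters) == 4
        counts = pd.read_csv(out / "interval_counts.csv")
        assert counts["count"].sum() == 4
        gj = json.loads((out / "paths.geojson").read_text())
        assert len(gj["features"]) == 1  # only the 3-call cluster moves
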