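import json

import numpy as np
import pytest
import tifffile
import yaml
from click.testing import CliRunner

import ciliatransport as ct
from ciliatransport import io as ctio
from ciliatransport.cli import main as cli_main


class TestMovieIO:
    def test_round_trip_bit_identical(self, tmp_path, quiet_preset):
        movie, _, _ = ct.simulate_transport_movie(quiet_preset)
        path = tmp_path / "movie.tif"
        ctio.write_movie(movie, path)
        back = ctio.read_movie(path, movie.pixel_size_um, movie.frame_interval_s)
        assert back.frames.dtype == movie.frames.dtype
        assert np.array_equal(back.frames, movie.frames)

    def test_rgb_tiff_rejected(self, tmp_path):
        path = tmp_path / "rgb.tif"
        tifffile.imwrite(path, np.zeros((4, 4, 3), dtype=np.uint8), photometric="rgb")
        with pytest.raises(ValueError, match="grayscale"):
            ctio.read_movie(path, 0.1)

    def test_unreadable_file_rejected(self, tmp_path):
        path = tmp_path / "junk.tif"
        path.write_bytes(b"this is not a tiff at all")
        with pytest.raises(ValueError, match="unreadable|page"):
            ctio.read_movie(path, 0.1)

    def test_calibration_from_arguments_not_tags(self, tmp_path, quiet_preset):
        movie, _, _ = ct.simulate_transport_movie(quiet_preset)
        path = tmp_path / "movie.tif"
        ctio.write_movie(movie, path)
        back = ctio.read_movie(path, pixel_size_um=0.2, frame_interval_s=1.0)
        assert back.pixel_size_um == 0.2
        assert back.frame_interval_s == 1.0


class TestPathIO:
    @pytest.mark.parametrize("suffix", [".csv", ".json"])
    def test_round_trip_with_junction(self, tmp_path, suffix):
        path = ct.DendritePath([[4.0, 2.0], [4.0, 30.0], [10.0, 30.0]],
                               junction_arclength_um=1.6)
        f = tmp_path / f"path{suffix}"
        ctio.write_path(path, f)
        back = ctio.read_path(f)
        assert np.allclose(back.vertices, path.vertices)
        assert back.junction_arclength_um == pytest.approx(1.6)


class TestEventsIO:
    def test_events_csv_round_trip(self, tmp_path):
        events = [
            ct.TransportEvent(0, "anterograde", 1.2, 4.0, 3, 19),
            ct.TransportEvent(1, "retrograde", 0.7, 5.5, 20, 41),
        ]
        f = tmp_path / "events.csv"
        ctio.write_events_csv(events, f)
        assert ctio.read_events_csv(f) == events


class TestRunPipeline:
    def _config(self, tmp_path, seed=5):
        return ct.PipelineConfig(
            preset="WT", seed=seed, output_dir=str(tmp_path / f"run{seed}"),
        )

    def test_missing_path_file_fails_before_computation(self, tmp_path):
        config = ct.PipelineConfig(movie_path="nope.tif", path_file=None)
        with pytest.raises(ValueError):
            config.validate()

    def test_preset_run_writes_all_outputs(self, tmp_path, monkeypatch):
        # shrink the run so the interface test stays fast
        monkeypatch.setitem(ct.PACKAGED_PRESETS["WT"], "duration_min", 0.5)
        config = self._config(tmp_path)
        report = ct.run_pipeline(config)
        out = tmp_path / "run5"
        for name in ("drift.csv", "kymograph.tif", "events.csv", "stats.json",
                     "run_log.json", "ground_truth.csv"):
            assert (out / name).exists(), name
        assert report["anterograde"]["n"] >= 0
        log = json.loads((out / "run_log.json").read_text())
        assert log["seed"] == 5

    def test_same_config_and_seed_reproduces_outputs(self, tmp_path, monkeypatch):
        monkeypatch.setitem(ct.PACKAGED_PRESETS["WT"], "duration_min", 0.5)
        c1 = ct.PipelineConfig(preset="WT", seed=9, output_dir=str(tmp_path / "a"))
        c2 = ct.PipelineConfig(preset="WT", seed=9, output_dir=str(tmp_path / "b"))
        ct.run_pipeline(c1)
        ct.run_pipeline(c2)
        assert (tmp_path / "a/events.csv").read_bytes() == \
            (tmp_path / "b/events.csv").read_bytes()
        assert (tmp_path / "a/kymograph.tif").read_bytes() == \
            (tmp_path / "b/kymograph.tif").read_bytes()


class TestCli:
    def test_simulate_kymo_detect_stats_chain(self, tmp_path):
        runner = CliRunner()
        preset_file = tmp_path / "mini.yaml"
        preset_file.write_text(yaml.safe_dump({
            "name": "mini", "duration_min": 0.5, "rate_antero": 4.0,
            "v_antero_mean": 1.0, "v_antero_sd": 0.05, "path_length_um": 8.0,
            "frame_shape": [48, 160], "seed": 3,
        }))
        stem = tmp_path / "sim"
        r = runner.invoke(cli_main, ["simulate", str(preset_file), "--out", str(stem)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, [
            "kymo", str(stem) + ".tif", "--path-file", str(stem) + "_path.csv",
            "--out", str(tmp_path / "k.tif"),
        ])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, [
            "detect", str(tmp_path / "k.tif"), "--out", str(tmp_path / "events.csv"),
        ])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, [
            "stats", str(tmp_path / "events.csv"), "--total-time-min", "0.5",
            "--out", str(tmp_path / "stats.json"),
        ])
        assert r.exit_code == 0, r.output
        report = json.loads((tmp_path / "stats.json").read_text())
        assert "anterograde" in report

    def test_quantify_pair_reports_ratio(self, tmp_path):
        a = ct.load_preset("stack_wt").replace(seed=1)
        b = ct.load_preset("stack_chb3").replace(seed=2)
        sa, sb, _ = ct.simulate_cilium_stack(a, b)
        ctio.write_stack(sa, tmp_path / "wt.tif")
        ctio.write_stack(sb, tmp_path / "mut.tif")
        runner = CliRunner()
        r = runner.invoke(cli_main, [
            "quantify", str(tmp_path / "wt.tif"), str(tmp_path / "mut.tif"),
            "--threshold", "28", "--out", str(tmp_path / "fluor.csv"),
        ])
        assert r.exit_code == 0, r.output
        assert "ratio" in r.output

    def test_unknown_preset_fails_cleanly(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["simulate", "nosuch", "--out", str(tmp_path / "x")])
        assert r.exit_code != 0
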