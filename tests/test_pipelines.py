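import numpy as np
import pytest

from myohisto.imgio import MultichannelImage, write_image
from myohisto.pipelines import (
    PipelineConfig,
    default_config,
    load_config,
    run_batch,
    run_cd68,
    run_collagen,
    run_ebd,
    run_emyhc,
)
from myohisto.synth import (
    SceneParams,
    generate_scene,
    render_brightfield_collagen,
    render_fluorescence,
)


def fluor_scene(assay, **kwargs):
    params = SceneParams(**kwargs)
    truth = generate_scene(params)
    return truth, render_fluorescence(truth, assay, params)


def blank_rgb(h=64, w=64):
    return MultichannelImage(np.zeros((h, w, 3)), ("red", "green", "blue"))


class TestEbdPipeline:
    def test_recovers_exact_positive_count_on_clean_scene(self):
        truth, img = fluor_scene(
            "ebd", n_fibers=100, marker_fraction=0.07,
            noise_sd=0.0, blur_sigma=0.0, seed=21,
        )
        res = run_ebd(img, default_config("ebd"))
        assert res.counts == {
            "total_cells": 100, "not_ebd_cells": 93, "ebd_pos_cells": 7,
        }
        assert res.percent["pct_ebd_pos"] == pytest.approx(7.0)
        assert not res.warnings

    def test_dye_free_scene_reports_zero_positives(self):
        truth, img = fluor_scene(
            "ebd", n_fibers=100, marker_fraction=0.0,
            noise_sd=0.03, blur_sigma=1.5, seed=22,
        )
        res = run_ebd(img, default_config("ebd"))
        assert res.counts["ebd_pos_cells"] == 0
        assert res.counts["total_cells"] == res.counts["not_ebd_cells"]

    def test_blank_image_warns_and_omits_percent(self):
        # at the 512-px frame scale the all-bright inverted frame becomes a
        # single frame-sized object, far beyond max_diameter, so nothing
        # survives the size filter
        res = run_ebd(blank_rgb(512, 512), default_config("ebd"))
        assert res.counts["total_cells"] == 0
        assert res.percent == {}
        assert res.warnings

    def test_count_conservation_without_warnings(self):
        for seed in (23, 24, 25):
            truth, img = fluor_scene(
                "ebd", n_fibers=64, height=416, width=416,
                marker_fraction=0.1, noise_sd=0.02, blur_sigma=1.0, seed=seed,
            )
            res = run_ebd(img, default_config("ebd"))
            if not res.warnings:
                assert (
                    res.counts["not_ebd_cells"] + res.counts["ebd_pos_cells"]
                    == res.counts["total_cells"]
                )

    def test_positive_count_monotone_in_rendered_positives(self):
        counts = []
        for frac in (0.0, 0.05, 0.10, 0.15):
            _, img = fluor_scene(
                "ebd", n_fibers=100, marker_fraction=frac,
                noise_sd=0.0, blur_sigma=0.0, seed=26,
            )
            counts.append(run_ebd(img, default_config("ebd")).counts["ebd_pos_cells"])
        assert counts == sorted(counts)


class TestEmyhcPipeline:
    def test_recovers_count_percentage_and_sizes(self):
        truth, img = fluor_scene(
            "emyhc", n_fibers=50, marker_fraction=0.14,
            marker_size_bias="small", noise_sd=0.0, blur_sigma=0.0, seed=27,
        )
        res = run_emyhc(img, default_config("emyhc"))
        assert res.counts == {"total_cells": 50, "emyhc_pos_cells": 7}
        assert res.percent["pct_emyhc_pos"] == pytest.approx(14.0)
        true_areas = np.sort(truth.fiber_areas[truth.marker_flags])
        got = np.sort(res.sizes)
        np.testing.assert_allclose(got, true_areas, rtol=0.15)

    def test_positive_fibers_measure_smaller_than_negatives(self):
        truth, img = fluor_scene(
            "emyhc", n_fibers=50, marker_fraction=0.14,
            marker_size_bias="small", noise_sd=0.02, blur_sigma=1.0, seed=28,
        )
        res = run_emyhc(img, default_config("emyhc"))
        neg_median = np.median(truth.fiber_areas[~truth.marker_flags])
        assert np.median(res.sizes) < neg_median

    def test_markerless_scene_gives_empty_size_list(self):
        _, img = fluor_scene(
            "emyhc", n_fibers=50, marker_fraction=0.0,
            noise_sd=0.02, blur_sigma=1.0, seed=29,
        )
        res = run_emyhc(img, default_config("emyhc"))
        assert res.counts["emyhc_pos_cells"] == 0
        assert res.sizes == []


class TestCd68Pipeline:
    def test_percent_area_tracks_painted_mask(self):
        params = SceneParams(n_fibers=100, aggregate_count=16,
                             noise_sd=0.0, blur_sigma=0.0, seed=30)
        truth = generate_scene(params)
        img = render_fluorescence(truth, "cd68", params)
        res = run_cd68(img, default_config("cd68"))
        assert res.percent["pct_area"] == pytest.approx(
            truth.summary["marker_pct_area"], abs=0.3
        )

    def test_zero_signal_gives_zero_area(self):
        res = run_cd68(blank_rgb(), default_config("cd68"))
        assert res.percent["pct_area"] == 0.0

    def test_full_frame_signal_gives_hundred_percent(self):
        img = MultichannelImage(
            np.dstack([np.zeros((64, 64)), np.full((64, 64), 0.85),
                       np.zeros((64, 64))]),
            ("red", "green", "blue"),
        )
        res = run_cd68(img, default_config("cd68"))
        assert res.percent["pct_area"] == 100.0


class TestCollagenPipeline:
    def test_percent_area_tracks_painted_collagen(self):
        params = SceneParams(n_fibers=40, collagen_fraction=0.10,
                             noise_sd=0.0, blur_sigma=0.0, seed=31)
        truth = generate_scene(params)
        img = render_brightfield_collagen(truth, params)
        res = run_collagen(img, default_config("collagen"))
        assert res.percent["pct_area"] == pytest.approx(
            truth.summary["marker_pct_area"], abs=1.0
        )

    def test_collagen_free_scene_near_zero(self):
        params = SceneParams(n_fibers=40, collagen_fraction=0.0,
                             noise_sd=0.0, blur_sigma=0.0, seed=32)
        truth = generate_scene(params)
        img = render_brightfield_collagen(truth, params)
        res = run_collagen(img, default_config("collagen"))
        assert res.percent["pct_area"] <= 0.5

    def test_uniform_midgray_filtered_out_by_diameter(self):
        img = MultichannelImage(np.full((512, 512, 3), 0.5),
                                ("red", "green", "blue"))
        res = run_collagen(img, default_config("collagen"))
        assert res.percent["pct_area"] == 0.0


class TestBatchAndConfig:
    @staticmethod
    def _write_scenes(tmp_path, n, **kwargs):
        paths = []
        for i in range(n):
            params = SceneParams(seed=40 + i, **kwargs)
            truth = generate_scene(params)
            img = render_fluorescence(truth, "ebd", params)
            p = tmp_path / f"scene_{i}.tif"
            write_image(img, p)
            paths.append(p)
        return paths

    def test_batch_writes_one_row_per_image(self, tmp_path):
        paths = self._write_scenes(tmp_path, 3, n_fibers=25, height=256,
                                   width=256, marker_fraction=0.08)
        out = tmp_path / "out.csv"
        results = run_batch(paths, default_config("ebd"), out)
        assert len(results) == 3
        assert len(out.read_text().strip().splitlines()) == 4

    def test_corrupt_image_becomes_warning_row(self, tmp_path):
        paths = self._write_scenes(tmp_path, 2, n_fibers=25, height=256,
                                   width=256, marker_fraction=0.08)
        bad = tmp_path / "corrupt.tif"
        bad.write_bytes(b"not a tiff at all")
        results = run_batch(paths + [bad], default_config("ebd"),
                            tmp_path / "out.csv")
        assert [r.failed for r in results] == [False, False, True]
        assert "error" in results[-1].warnings[0]

    def test_all_corrupt_raises(self, tmp_path):
        bad = tmp_path / "corrupt.tif"
        bad.write_bytes(b"junk")
        with pytest.raises(RuntimeError):
            run_batch([bad], default_config("ebd"), tmp_path / "out.csv")

    def test_identical_runs_produce_byte_identical_csv(self, tmp_path):
        paths = self._write_scenes(tmp_path, 2, n_fibers=25, height=256,
                                   width=256, marker_fraction=0.08,
                                   noise_sd=0.02)
        out1, out2 = tmp_path / "a.csv", tmp_path / "b.csv"
        run_batch(paths, default_config("ebd"), out1)
        run_batch(paths, default_config("ebd"), out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_emyhc_batch_writes_object_sizes_companion(self, tmp_path):
        params = SceneParams(seed=50, n_fibers=25, height=256, width=256,
                             marker_fraction=0.12, marker_size_bias="small")
        truth = generate_scene(params)
        img = render_fluorescence(truth, "emyhc", params)
        p = tmp_path / "scene.tif"
        write_image(img, p)
        run_batch([p], default_config("emyhc"), tmp_path / "res.csv")
        companion = tmp_path / "res_objects.csv"
        assert companion.exists()
        lines = companion.read_text().strip().splitlines()
        assert lines[0] == "image_id,label,area_px"
        assert len(lines) == 1 + truth.marker_flags.sum()

    def test_yaml_config_overrides_defaults(self, tmp_path):
        cfg_file = tmp_path / "cfg.yaml"
        cfg_file.write_text(
            "assay: ebd\n"
            "square_exponent: 3\n"
            "cell_params:\n"
            "  min_diameter: 14\n"
            "  threshold:\n"
            "    n_sd: 2.5\n"
        )
        cfg = load_config(cfg_file)
        assert cfg.square_exponent == 3.0
        assert cfg.cell_params.min_diameter == 14
        assert cfg.cell_params.threshold.n_sd == 2.5
        # untouched keys keep their defaults
        assert cfg.cell_params.max_diameter == default_config("ebd").cell_params.max_diameter

    def test_missing_channel_role_rejected(self):
        base = default_config("ebd")
        with pytest.raises(ValueError, match="missing"):
            PipelineConfig(assay="ebd", cell_params=base.cell_params,
                           marker_params=base.marker_params,
                           channel_roles={"laminin": "green"})

    def test_image_without_required_channel_rejected(self):
        cfg = default_config("ebd")
        gray_only = MultichannelImage(np.zeros((8, 8, 1)), ("gray",))
        with pytest.raises(ValueError, match="absent"):
            run_ebd(gray_only, cfg)
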