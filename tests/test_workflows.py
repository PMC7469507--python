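import csv

import numpy as np
import pytest
import imageio.v3 as iio

import adipoquant as aq
from conftest import center_seed


@pytest.fixture(scope="module")
def workspace(tmp_path_factory):
    """Synthetic image on disk plus annotation files for all three methods."""
    work = tmp_path_factory.mktemp("run")
    spec = aq.SyntheticSpec(
        n_cells=5, gap_probability=0.0, noise_sd=0.02, speckle_count=15, rng_seed=9
    )
    img, truth = aq.generate(spec)
    iio.imwrite(work / "image.png", (img.values * 255).round().astype(np.uint8))
    aq.write_seeds(
        [(c.label, center_seed(c)) for c in truth.cells], work / "seeds.csv"
    )
    aq.write_vertices(
        [aq.ht_polygon_for_cell(c, 32) for c in truth.cells], work / "verts.csv"
    )
    aq.write_ellipses([aq.ea_for_cell(c) for c in truth.cells], work / "ells.csv")
    return work, spec, truth


def _cfg(work, method, ann, out, **kw):
    return aq.RunConfig(
        image_path=str(work / "image.png"),
        method=method,
        annotations_path=str(work / ann),
        microns_per_pixel=1.0,
        out_dir=str(work / out),
        **kw,
    )


class TestReaders:
    def test_seed_roundtrip(self, workspace):
        work, _, truth = workspace
        seeds = aq.read_seeds(work / "seeds.csv")
        assert len(seeds) == len(truth.cells)
        assert all(isinstance(s, aq.SeedPoint) for _, s in seeds)

    def test_vertex_roundtrip_preserves_order(self, workspace):
        work, _, truth = workspace
        polys = {p.label: p for p in aq.read_vertices(work / "verts.csv")}
        orig = aq.ht_polygon_for_cell(truth.cells[0], 32)
        got = polys[orig.label]
        assert got.vertices == orig.vertices  # repr round-trip is exact

    def test_ellipse_roundtrip_full_precision(self, workspace):
        work, _, truth = workspace
        ells = {e.label: e for e in aq.read_ellipses(work / "ells.csv")}
        orig = aq.ea_for_cell(truth.cells[0])
        assert ells[orig.label].semi_major == orig.semi_major

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("cell_id,row,col\nok,1,2\nbad,x,3\n")
        with pytest.raises(ValueError, match="line 3"):
            aq.read_seeds(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("cell_id,r,c\nok,1,2\n")
        with pytest.raises(ValueError, match="header"):
            aq.read_seeds(p)


class TestRunMeasure:
    def test_tm_end_to_end(self, workspace):
        work, _, truth = workspace
        res = aq.run_measure(_cfg(work, "tm", "seeds.csv", "tm_out", write_xlsx=True))
        assert res.success and len(res.measurements) == 5
        with open(res.results_csv) as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == 5 and all(r["flags"] == "" for r in rows)
        assert {r["method"] for r in rows} == {"TM"}
        # every declared output exists
        out = res.results_csv.parent
        for name in ("results.csv", "results.xlsx", "overlay.png", "run_log.json",
                     "histogram.csv", "histogram.png"):
            assert (out / name).exists()

    def test_measured_areas_match_truth(self, workspace):
        work, _, truth = workspace
        res = aq.run_measure(_cfg(work, "tm", "seeds.csv", "tm_out2"))
        truth_by_label = {c.label: c.true_area_px for c in truth.cells}
        for m in res.measurements:
            assert m.area_px == pytest.approx(truth_by_label[m.cell_id], rel=0.05)

    def test_partial_failure_keeps_other_cells(self, workspace, tmp_path):
        work, _, truth = workspace
        seeds = aq.read_seeds(work / "seeds.csv")
        bad = tmp_path / "seeds_bad.csv"
        with open(bad, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["cell_id", "row", "col"])
            w.writerow([seeds[0][0], seeds[0][1].row, seeds[0][1].col])
            w.writerow(["off_image", 9000, 9000])
        cfg = aq.RunConfig(
            image_path=str(work / "image.png"),
            method="tm",
            annotations_path=str(bad),
            microns_per_pixel=1.0,
            out_dir=str(tmp_path / "out"),
        )
        res = aq.run_measure(cfg)
        assert not res.success
        assert len(res.measurements) == 1 and len(res.errors) == 1
        assert res.errors[0]["cell_id"] == "off_image"
        with open(res.results_csv) as fh:
            assert len(list(csv.DictReader(fh))) == 1  # complete rows only

    def test_rerun_is_byte_identical(self, workspace):
        work, _, _ = workspace
        r1 = aq.run_measure(_cfg(work, "tm", "seeds.csv", "det1"))
        r2 = aq.run_measure(_cfg(work, "tm", "seeds.csv", "det2"))
        assert r1.results_csv.read_bytes() == r2.results_csv.read_bytes()

    def test_ht_and_ea_runs(self, workspace):
        work, _, truth = workspace
        for method, ann in (("ht", "verts.csv"), ("ea", "ells.csv")):
            res = aq.run_measure(_cfg(work, method, ann, f"{method}_out"))
            assert res.success and len(res.measurements) == len(truth.cells)

    def test_run_log_records_parameters(self, workspace):
        import json

        work, _, _ = workspace
        res = aq.run_measure(_cfg(work, "tm", "seeds.csv", "logchk"))
        log = json.loads(res.run_log.read_text())
        tp = log["config"]["transform_params"]
        assert tp == {
            "low_level_in": 0.9,
            "shadows": 0.15,
            "binary_threshold": 0.8,
            "despeckle_radius": 5,
            "despeckle_passes": 5,
        }
        assert set(log["per_cell_seconds"]) == {f"cell_0{i}" for i in range(1, 6)}


class TestRunCompare:
    def test_identical_results_give_unit_concordance(self, workspace, tmp_path):
        work, _, _ = workspace
        res = aq.run_measure(_cfg(work, "tm", "seeds.csv", "cmp_tm"))
        # relabel a copy as HT so both "methods" carry identical areas
        dup = tmp_path / "ht_results.csv"
        text = res.results_csv.read_text().replace(",TM,", ",HT,")
        dup.write_text(text)
        cmp = aq.run_compare([res.results_csv, dup], tmp_path / "cmp", scatter=False)
        row = cmp.concordance_table.iloc[0]
        assert row["slope"] == pytest.approx(1.0)
        assert row["r_squared"] == pytest.approx(1.0)

    def test_three_methods_give_three_pairs(self, workspace, tmp_path):
        work, _, _ = workspace
        paths = []
        for method, ann in (("tm", "seeds.csv"), ("ht", "verts.csv"), ("ea", "ells.csv")):
            paths.append(
                aq.run_measure(_cfg(work, method, ann, f"cmp3_{method}")).results_csv
            )
        cmp = aq.run_compare(paths, tmp_path / "cmp3")
        assert len(cmp.concordance_table) == 3
        pairs = set(map(tuple, cmp.concordance_table[["x_method", "y_method"]].values))
        assert pairs == {("HT", "TM"), ("HT", "EA"), ("TM", "EA")}
        assert cmp.concordance_csv.exists() and cmp.repeatability_csv.exists()

    def test_single_method_rejected(self, workspace, tmp_path):
        work, _, _ = workspace
        res = aq.run_measure(_cfg(work, "tm", "seeds.csv", "cmp1"))
        with pytest.raises(ValueError, match="two methods"):
            aq.run_compare([res.results_csv], tmp_path / "cmp1o")
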