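import hashlib
import re

import numpy as np
import pytest

from scopeqc.core import DatasetError, parse_config
from scopeqc.fixtures import DEMO_CONFIG, write_demo_dataset
from scopeqc.reporting import (
    MeasurementRow,
    ReportEntry,
    _ENTRY_RE,
    read_measurements,
    rebuild_reports,
    run_suite,
    update_html_report,
    write_measurements,
)


def rows_for(ts, n=3):
    # values exact in binary and within 6 significant digits
    return [MeasurementRow(ts, "Sys", "10x", "psf", f"param{i}",
                           0.25 * (i + 1), "um") for i in range(n)]


class TestTsv:
    def test_three_rows_four_lines(self, tmp_path):
        path = tmp_path / "measurements.tsv"
        write_measurements(rows_for("2024-01-01T00:00:00"), path)
        assert len(path.read_text().splitlines()) == 4

    def test_append_does_not_duplicate_header(self, tmp_path):
        path = tmp_path / "measurements.tsv"
        write_measurements(rows_for("t1"), path)
        write_measurements(rows_for("t2"), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 7
        assert sum(1 for ln in lines if ln.startswith("timestamp")) == 1

    def test_round_trip_exact(self, tmp_path):
        path = tmp_path / "measurements.tsv"
        rows = rows_for("2024-01-01T00:00:00")
        write_measurements(rows, path)
        loaded = read_measurements(path)
        assert loaded == rows

    def test_six_significant_digits(self, tmp_path):
        path = tmp_path / "m.tsv"
        value = 0.22360679774997896
        write_measurements(
            [MeasurementRow("t", "s", "o", "bead", "d", value, "um")], path)
        assert "0.223607" in path.read_text()
        loaded = read_measurements(path)[0]
        assert loaded.value == pytest.approx(value, rel=1e-6)

    def test_empty_rows_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_measurements([], tmp_path / "m.tsv")

    def test_nonfinite_value_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            MeasurementRow("t", "s", "o", "a", "p", float("nan"), "u")

    def test_empty_field_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            MeasurementRow("t", "", "o", "a", "p", 1.0, "u")


class TestHtmlReport:
    def test_first_run_creates_report(self, tmp_path):
        page = update_html_report(tmp_path, "Sys", "10x",
                                  ReportEntry("t1", rows_for("t1")))
        text = page.read_text()
        assert len(_ENTRY_RE.findall(text)) == 1
        assert (tmp_path / "Sys" / "index.html").exists()

    def test_second_run_preserves_first_entry_bytes(self, tmp_path):
        page = update_html_report(tmp_path, "Sys", "10x",
                                  ReportEntry("t1", rows_for("t1")))
        first_block = _ENTRY_RE.search(page.read_text()).group(0)
        digest = hashlib.sha256(first_block.encode()).hexdigest()
        update_html_report(tmp_path, "Sys", "10x",
                           ReportEntry("t2", rows_for("t2")))
        blocks = [m.group(0) for m in _ENTRY_RE.finditer(page.read_text())]
        assert len(blocks) == 2
        assert hashlib.sha256(blocks[0].encode()).hexdigest() == digest

    def test_immutability_across_three_runs(self, tmp_path):
        page = None
        digests = []
        for k in range(3):
            page = update_html_report(tmp_path, "Sys", "10x",
                                      ReportEntry(f"t{k}", rows_for(f"t{k}")))
            blocks = [m.group(0) for m in _ENTRY_RE.finditer(page.read_text())]
            for i, block in enumerate(blocks[:len(digests)]):
                assert hashlib.sha256(block.encode()).hexdigest() == digests[i]
            digests = [hashlib.sha256(b.encode()).hexdigest() for b in blocks]
        assert len(digests) == 3

    def test_two_objectives_one_index(self, tmp_path):
        update_html_report(tmp_path, "Sys", "10x",
                           ReportEntry("t1", rows_for("t1")))
        update_html_report(tmp_path, "Sys", "63x",
                           ReportEntry("t1", rows_for("t1")))
        index = (tmp_path / "Sys" / "index.html").read_text()
        assert "10x.html" in index and "63x.html" in index
        # navigation on each page lists both objectives
        assert "63x.html" in (tmp_path / "Sys" / "10x.html").read_text()

    def test_out_of_order_timestamp_rejected(self, tmp_path):
        update_html_report(tmp_path, "Sys", "10x",
                           ReportEntry("t2", rows_for("t2")))
        with pytest.raises(ValueError, match="not later"):
            update_html_report(tmp_path, "Sys", "10x",
                               ReportEntry("t1", rows_for("t1")))

    def test_corrupt_report_backed_up_and_rebuilt(self, tmp_path, caplog):
        tsv = tmp_path / "measurements.tsv"
        write_measurements(rows_for("t1"), tsv)
        update_html_report(tmp_path, "Sys", "10x",
                           ReportEntry("t1", rows_for("t1")), tsv_path=tsv)
        page = tmp_path / "Sys" / "10x.html"
        page.write_text("<html>mangled by hand, markers gone</html>")
        update_html_report(tmp_path, "Sys", "10x",
                           ReportEntry("t2", rows_for("t2")), tsv_path=tsv)
        backups = list((tmp_path / "Sys").glob("*.corrupt-*"))
        assert len(backups) == 1
        blocks = _ENTRY_RE.findall(page.read_text())
        assert len(blocks) == 2  # t1 rebuilt from TSV + new t2

    def test_rebuild_from_tsv_matches_tables(self, tmp_path):
        tsv = tmp_path / "measurements.tsv"
        write_measurements(rows_for("t1"), tsv)
        write_measurements(rows_for("t2"), tsv)
        pages = rebuild_reports(tmp_path / "html", tsv)
        assert len(pages) == 1
        text = pages[0].read_text()
        assert len(_ENTRY_RE.findall(text)) == 2
        for row in read_measurements(tsv):
            assert row.parameter in text


@pytest.fixture(scope="module")
def demo(tmp_path_factory):
    root = tmp_path_factory.mktemp("demo")
    obj_dir = write_demo_dataset(root, seed=11)
    return root, obj_dir


class TestRunSuite:
    def test_full_dataset_all_assays(self, demo, tmp_path):
        root, obj_dir = demo
        cfg = parse_config(DEMO_CONFIG)
        summary = run_suite(cfg, obj_dir, tmp_path / "out", objective="10x",
                            html_dir=tmp_path / "html")
        assert not summary.failures
        assert {"laser", "axial405", "bead", "psf", "field405", "scanpmt1",
                "grid", "stage", "stageacc", "zgalvo"} <= set(summary.ran)
        assays_with_rows = {r.assay for r in summary.rows}
        for keyword in summary.ran:
            assert keyword in assays_with_rows
        assert summary.exit_status == 0
        assert (tmp_path / "out" / "measurements.tsv").exists()
        assert summary.html_page.exists()

    def test_single_recording_runs_one_assay(self, demo, tmp_path):
        root, obj_dir = demo
        only = tmp_path / "only"
        only.mkdir()
        for name in ("field488.tif", "field488.meta.yaml"):
            (only / name).write_bytes((obj_dir / name).read_bytes())
        cfg = parse_config(DEMO_CONFIG)
        summary = run_suite(cfg, only, tmp_path / "out", objective="10x")
        assert summary.ran == ["field488"]
        assert {r.assay for r in summary.rows} == {"field488"}

    def test_corrupt_recording_isolated(self, demo, tmp_path):
        root, obj_dir = demo
        broken = tmp_path / "broken"
        broken.mkdir()
        for path in obj_dir.iterdir():
            (broken / path.name).write_bytes(path.read_bytes())
        (broken / "bead.tif").write_bytes(b"not a tiff at all")
        cfg = parse_config(DEMO_CONFIG)
        summary = run_suite(cfg, broken, tmp_path / "out", objective="10x")
        assert "bead" in summary.failures
        assert "psf" in summary.ran  # others completed
        assert summary.exit_status == 0

    def test_empty_directory_hard_error(self, tmp_path):
        cfg = parse_config(DEMO_CONFIG)
        empty = tmp_path / "empty"
        empty.mkdir()
        with pytest.raises(DatasetError, match="no recognised"):
            run_suite(cfg, empty, tmp_path / "out", objective="10x")

    def test_html_tables_match_tsv(self, demo, tmp_path):
        root, obj_dir = demo
        cfg = parse_config(DEMO_CONFIG)
        summary = run_suite(cfg, obj_dir, tmp_path / "out", objective="10x",
                            html_dir=tmp_path / "html")
        html = summary.html_page.read_text()
        for row in read_measurements(tmp_path / "out" / "measurements.tsv"):
            assert row.parameter in html
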