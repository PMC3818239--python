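import logging

import numpy as np
import pytest
import tifffile
import yaml

from scopeqc.core import (
    ConfigError,
    DatasetError,
    ImageStack,
    SidecarError,
    discover_dataset,
    parse_config,
    read_stack,
    write_stack,
)

from conftest import make_stack


class TestParseConfig:
    def test_basic_parse(self, simple_config_text):
        cfg = parse_config(simple_config_text)
        assert cfg.system_name == "TestScope"
        assert cfg.objectives == ["10x", "20x", "63x"]
        assert cfg.lasers_by_assay["field"] == [405.0, 488.0, 561.0, 633.0]

    def test_empty_file_is_error(self):
        with pytest.raises(ConfigError):
            parse_config("")

    def test_missing_objectives_is_error(self):
        with pytest.raises(ConfigError, match="objectives"):
            parse_config("system=S\n")

    def test_duplicate_objectives_named_in_error(self):
        with pytest.raises(ConfigError, match="20x"):
            parse_config("system=S\nobjectives=10x,20x,20x\n")

    def test_unknown_key_warns_but_parses(self, caplog):
        with caplog.at_level(logging.WARNING, logger="scopeqc.core"):
            cfg = parse_config("system=S\nobjectives=10x\nbogus=1\n")
        assert cfg.objectives == ["10x"]
        assert any("bogus" in rec.message for rec in caplog.records)

    def test_laser_out_of_range(self):
        with pytest.raises(ConfigError, match="350-700"):
            parse_config("system=S\nobjectives=10x\nlasers.field=800\n")

    def test_comments_and_blank_lines_ignored(self):
        cfg = parse_config("\n# c\nsystem=S # trailing\nobjectives=10x\n\n")
        assert cfg.system_name == "S"


def _touch_tiff(path):
    tifffile.imwrite(path, np.zeros((4, 4), dtype=np.uint16))


class TestDiscoverDataset:
    def test_three_keywords(self, tmp_path):
        for name in ("bead.tif", "psf.tif", "field405.tif"):
            _touch_tiff(tmp_path / name)
        ds = discover_dataset(tmp_path, "10x")
        assert sorted(ds.recordings) == ["bead", "field405", "psf"]
        assert all(len(v) == 1 for v in ds.recordings.values())

    def test_whitespace_in_name_is_hard_error(self, tmp_path):
        _touch_tiff(tmp_path / "my bead.tif")
        with pytest.raises(DatasetError, match="my bead"):
            discover_dataset(tmp_path, "10x")

    def test_stage_grouping_ordered(self, tmp_path):
        # created out of order on purpose
        for name in ("stage3.tif", "stage1.tif", "stage2.tif"):
            _touch_tiff(tmp_path / name)
        ds = discover_dataset(tmp_path, "10x")
        assert list(ds.recordings) == ["stage"]
        assert [p.name for p in ds.recordings["stage"]] == [
            "stage1.tif", "stage2.tif", "stage3.tif"]

    def test_stageacc_not_claimed_by_stage(self, tmp_path):
        _touch_tiff(tmp_path / "stageacc1.tif")
        _touch_tiff(tmp_path / "stage1.tif")
        ds = discover_dataset(tmp_path, "10x")
        assert sorted(ds.recordings) == ["stage", "stageacc"]

    def test_case_insensitive_match(self, tmp_path):
        _touch_tiff(tmp_path / "BEAD.TIF")
        ds = discover_dataset(tmp_path, "10x")
        assert "bead" in ds.recordings

    def test_unrecognised_file_skipped(self, tmp_path):
        _touch_tiff(tmp_path / "bead.tif")
        _touch_tiff(tmp_path / "mystery.tif")
        ds = discover_dataset(tmp_path, "10x")
        assert [p.name for p in ds.skipped] == ["mystery.tif"]

    def test_duplicate_keyword_is_error(self, tmp_path):
        _touch_tiff(tmp_path / "bead.tif")
        _touch_tiff(tmp_path / "bead_copy.tif")
        with pytest.raises(DatasetError, match="bead"):
            discover_dataset(tmp_path, "10x")

    def test_idempotent(self, tmp_path):
        for name in ("bead.tif", "psf.tif", "stage2.tif", "stage1.tif"):
            _touch_tiff(tmp_path / name)
        first = discover_dataset(tmp_path, "10x")
        second = discover_dataset(tmp_path, "10x")
        assert first.recordings == second.recordings


class TestStackIO:
    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(7)
        stack = make_stack(
            rng.integers(0, 4000, size=(3, 2, 4, 8, 9)).astype(np.uint16),
            pixel_size_xy=0.05, z_step=0.2, frame_interval=1.5,
            channel_wavelengths=[488.0, 561.0],
            stage_positions=[(0.0, 0.0), (1.0, 2.0), (3.0, 4.0)],
            bit_depth=12,
        )
        path = tmp_path / "bead.tif"
        write_stack(stack, path)
        loaded = read_stack(path)
        np.testing.assert_array_equal(loaded.pixels, stack.pixels)
        assert loaded.pixel_size_xy == stack.pixel_size_xy
        assert loaded.z_step == stack.z_step
        assert loaded.frame_interval == stack.frame_interval
        assert loaded.channel_wavelengths == stack.channel_wavelengths
        assert loaded.stage_positions == stack.stage_positions
        assert loaded.bit_depth == 12

    def test_json_sidecar_round_trip(self, tmp_path):
        stack = make_stack(np.ones((2, 1, 1, 4, 4), dtype=np.uint16),
                           wavelength_axis=[488.0, 490.0])
        path = tmp_path / "scanpmt1.tif"
        write_stack(stack, path, sidecar_format="json")
        loaded = read_stack(path)
        assert loaded.wavelength_axis == [488.0, 490.0]

    def test_t_extent_from_sidecar(self, tmp_path):
        stack = make_stack(np.zeros((100, 1, 1, 4, 4), dtype=np.uint16))
        path = tmp_path / "laser.tif"
        write_stack(stack, path)
        assert read_stack(path).size_t == 100

    def test_missing_sidecar_names_required_fields(self, tmp_path):
        _touch_tiff(tmp_path / "bead.tif")
        with pytest.raises(SidecarError, match="pixel_size_xy_um"):
            read_stack(tmp_path / "bead.tif")

    def test_channel_count_mismatch(self, tmp_path):
        tifffile.imwrite(tmp_path / "bead.tif",
                         np.zeros((3, 4, 4), dtype=np.uint16))
        meta = dict(size_c=3, channel_wavelengths_nm=[405, 488, 561, 633])
        (tmp_path / "bead.meta.yaml").write_text(yaml.safe_dump(meta))
        with pytest.raises(SidecarError, match="4 channel"):
            read_stack(tmp_path / "bead.tif")

    def test_page_count_mismatch(self, tmp_path):
        tifffile.imwrite(tmp_path / "laser.tif",
                         np.zeros((3, 4, 4), dtype=np.uint16))
        (tmp_path / "laser.meta.yaml").write_text(yaml.safe_dump(
            dict(size_t=5)))
        with pytest.raises(SidecarError, match="5 pages"):
            read_stack(tmp_path / "laser.tif")

    def test_sidecar_wins_over_embedded_metadata(self, tmp_path, caplog):
        # embedded resolution says 1 µm/px, sidecar says 0.25 µm/px
        tifffile.imwrite(tmp_path / "field488.tif",
                         np.zeros((8, 8), dtype=np.uint16),
                         resolution=(1e4, 1e4), resolutionunit="CENTIMETER")
        (tmp_path / "field488.meta.yaml").write_text(yaml.safe_dump(
            dict(pixel_size_xy_um=0.25)))
        with caplog.at_level(logging.WARNING, logger="scopeqc.core"):
            loaded = read_stack(tmp_path / "field488.tif")
        assert loaded.pixel_size_xy == 0.25
        assert any("sidecar wins" in rec.message for rec in caplog.records)


class TestImageStackInvariants:
    def test_wavelength_axis_length_enforced(self):
        with pytest.raises(ValueError):
            make_stack(np.zeros((3, 1, 1, 2, 2)), wavelength_axis=[1.0, 2.0])

    def test_stage_positions_length_enforced(self):
        with pytest.raises(ValueError):
            make_stack(np.zeros((3, 1, 1, 2, 2)),
                       stage_positions=[(0.0, 0.0)])

    def test_requires_5d(self):
        with pytest.raises(ValueError):
            ImageStack(pixels=np.zeros((2, 2)))
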