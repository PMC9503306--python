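"""Geometry invariants and raster/report round trips."""

import numpy as np
import pytest

from ccfd import (
    BinaryMask,
    EnFaceImage,
    FDReport,
    ScanGeometry,
    ValidationError,
    read_enface,
    read_report,
    write_mask,
    write_report,
)
from ccfd.io import read_mask, write_enface

from conftest import random_image


class TestScanGeometry:
    def test_pixel_pitch_of_standard_field(self):
        geom = ScanGeometry(6.0, 6.0, 500, 500)
        assert geom.pixel_width_um == pytest.approx(12.0)
        assert geom.pixel_area_um2 == pytest.approx(144.0)
        assert geom.field_area_mm2 == 36.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(field_width_mm=0.0, field_height_mm=6.0, grid_cols=10, grid_rows=10),
            dict(field_width_mm=6.0, field_height_mm=-1.0, grid_cols=10, grid_rows=10),
            dict(field_width_mm=6.0, field_height_mm=6.0, grid_cols=1, grid_rows=10),
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            ScanGeometry(**kwargs)


class TestEnFaceImage:
    def test_dimension_mismatch_rejected(self, geom_small):
        with pytest.raises(ValidationError):
            EnFaceImage(np.zeros((10, 10), np.uint8), 8, geom_small, "flow")

    def test_out_of_range_intensity_rejected(self, geom_small):
        px = np.full(geom_small.shape, 300, np.int32)
        with pytest.raises(ValidationError):
            EnFaceImage(px, 8, geom_small, "flow")

    def test_all_zero_16bit_degenerate(self, geom_small):
        img = EnFaceImage(np.zeros(geom_small.shape, np.uint16), 16, geom_small, "flow")
        assert img.pixels.min() == img.pixels.max() == 0
        assert img.max_value == 65535


class TestRasterRoundTrip:
    @pytest.mark.parametrize("bit_depth", [8, 16])
    @pytest.mark.parametrize("suffix", ["tiff", "png"])
    def test_image_round_trip_preserves_pixels(self, tmp_path, rng, geom_small,
                                               bit_depth, suffix):
        img = random_image(rng, geom_small, bit_depth)
        path = tmp_path / f"img.{suffix}"
        write_enface(img, path)
        back = read_enface(path, geom_small, "flow")
        assert back.bit_depth == bit_depth
        np.testing.assert_array_equal(back.pixels, img.pixels)
        assert back.geometry.pixel_area_um2 == img.geometry.pixel_area_um2

    def test_geometry_mismatch_raises(self, tmp_path, rng, geom_small):
        img = random_image(rng, geom_small)
        path = tmp_path / "img.png"
        write_enface(img, path)
        wrong = ScanGeometry(6.0, 6.0, 512, 512)
        with pytest.raises(ValidationError):
            read_enface(path, wrong, "flow")

    def test_rgb_input_rejected(self, tmp_path, geom_small):
        import imageio.v3 as iio

        path = tmp_path / "rgb.png"
        iio.imwrite(path, np.zeros((24, 24, 3), np.uint8))
        with pytest.raises(ValidationError):
            read_enface(path, geom_small, "flow")

    def test_missing_file_raises_io_error(self, tmp_path, geom_small):
        with pytest.raises((OSError, FileNotFoundError)):
            read_enface(tmp_path / "nope.tiff", geom_small, "flow")


class TestMaskRoundTrip:
    def test_all_deficit_mask_is_black(self, tmp_path):
        geom = ScanGeometry(1.0, 1.0, 4, 4)
        mask = BinaryMask(np.ones((4, 4), bool), geom)
        path = tmp_path / "mask.png"
        write_mask(mask, path)
        import imageio.v3 as iio

        assert (iio.imread(path) == 0).all()

    def test_checkerboard_round_trip(self, tmp_path, geom_small):
        px = np.indices(geom_small.shape).sum(axis=0) % 2 == 0
        mask = BinaryMask(px, geom_small, radius_px=4)
        path = tmp_path / "mask.png"
        write_mask(mask, path)
        back = read_mask(path, geom_small, radius_px=4)
        np.testing.assert_array_equal(back.pixels, mask.pixels)

    def test_write_read_write_is_idempotent(self, tmp_path, rng, geom_small):
        mask = BinaryMask(rng.random(geom_small.shape) < 0.3, geom_small)
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        write_mask(mask, p1)
        write_mask(read_mask(p1, geom_small), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestReportCSV:
    def _report(self, geom, percent=48.96):
        n_px = round(percent / 100 * geom.grid_rows * geom.grid_cols)
        return FDReport(
            fd_percent=100.0 * n_px / (geom.grid_rows * geom.grid_cols),
            fd_count=3,
            fd_mean_size_um2=n_px * geom.pixel_area_um2 / 3,
            fd_total_area_mm2=n_px * geom.pixel_area_um2 / 1e6,
            radius_px=4,
            geometry=geom,
        )

    def test_empty_report_is_header_only(self, tmp_path):
        path = tmp_path / "r.csv"
        write_report([], path)
        df = read_report(path)
        assert len(df) == 0
        assert list(df.columns) == [
            "eye_id", "group", "radius_px", "fd_percent", "fd_count",
            "fd_mean_size_um2", "fd_total_area_mm2",
        ]

    def test_two_eyes_two_radii_gives_four_rows(self, tmp_path, geom_500):
        rep = self._report(geom_500)
        rows = [("e1", "1a", rep), ("e1", "1a", rep), ("e2", "2", rep), ("e2", "2", rep)]
        path = tmp_path / "r.csv"
        write_report(rows, path, header_comment="sigma=2.0")
        df = read_report(path)
        assert len(df) == 4

    def test_fd_percent_parses_back_exactly(self, tmp_path, geom_500):
        rep = self._report(geom_500, percent=48.96)
        path = tmp_path / "r.csv"
        write_report([("e1", "1b", rep)], path)
        df = read_report(path)
        assert df.loc[0, "fd_percent"] == pytest.approx(rep.fd_percent)
        assert f"{df.loc[0, 'fd_percent']:.2f}" == "48.96"
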