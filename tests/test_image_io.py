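import math

import numpy as np
import pytest

from xmir.image_io import (
    DatasetManifest,
    ImageRecord,
    ManifestRow,
    RigidTransform,
    apply_rigid_transform,
    crop_center,
    load_manifest,
    log_preprocess,
    read_image,
    write_image,
    write_manifest,
)


class TestImageRecord:
    def test_rejects_out_of_range_and_nonfinite_pixels(self):
        with pytest.raises(ValueError):
            ImageRecord("x", "A", np.array([[0.0, 1.5]]))
        with pytest.raises(ValueError):
            ImageRecord("x", "A", np.array([[np.nan, 0.5]]))

    def test_shape_properties(self):
        rec = ImageRecord("x", "A", np.zeros((3, 5)))
        assert (rec.height, rec.width) == (3, 5)

    def test_gray_averages_rgb(self):
        px = np.zeros((2, 2, 3))
        px[..., 0] = 0.9
        rec = ImageRecord("x", "A", px)
        assert np.allclose(rec.gray(), 0.3)


class TestReadWrite:
    @pytest.mark.parametrize(
        "bit_depth,value,expected",
        [(8, 255, 1.0), (8, 0, 0.0), (16, 65535, 1.0)],
    )
    def test_integer_rescale_by_dtype_range(self, tmp_path, bit_depth, value, expected):
        px = np.full((4, 4), value / (255 if bit_depth == 8 else 65535), dtype=float)
        path = tmp_path / "img.png"
        write_image(ImageRecord("x", "A", px), path, bit_depth=bit_depth)
        rec = read_image(path, "A")
        assert np.allclose(rec.pixels, expected)

    def test_png_roundtrip_within_bit_depth(self, tmp_path, smooth_image):
        path = tmp_path / "img.png"
        write_image(smooth_image, path, bit_depth=16)
        rec = read_image(path, "A")
        assert np.abs(rec.pixels - smooth_image.pixels).max() <= 1.0 / 65535

    def test_tiff_roundtrip(self, tmp_path, smooth_image):
        path = tmp_path / "img.tif"
        write_image(smooth_image, path, bit_depth=16)
        rec = read_image(path, "A")
        assert np.abs(rec.pixels - smooth_image.pixels).max() <= 1.0 / 65535

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(IOError, match="no_such"):
            read_image(tmp_path / "no_such.png", "A")


class TestLogPreprocess:
    def test_endpoints_fixed(self):
        rec = ImageRecord("x", "A", np.array([[0.0, 1.0]]))
        out = log_preprocess(rec)
        assert out.pixels[0, 0] == 0.0
        assert out.pixels[0, 1] == pytest.approx(1.0)

    def test_midpoint_matches_formula(self):
        rec = ImageRecord("x", "A", np.full((2, 2), 0.5))
        out = log_preprocess(rec, c=255.0)
        assert out.pixels[0, 0] == pytest.approx(
            math.log(128.5) / math.log(256.0), abs=1e-12
        )

    def test_monotone_and_range_preserving(self):
        x = np.linspace(0, 1, 11)
        out = log_preprocess(ImageRecord("x", "A", x[None, :])).pixels[0]
        assert np.all(np.diff(out) > 0)
        assert out.min() >= 0 and out.max() <= 1


class TestRigidTransform:
    def test_identity_leaves_pixels_unchanged(self, smooth_image):
        out = apply_rigid_transform(smooth_image, RigidTransform(0, 0, 0))
        assert np.allclose(out.pixels, smooth_image.pixels)

    def test_quarter_turn_on_2x2_grid(self):
        rec = ImageRecord("x", "A", np.array([[1, 2], [3, 4]]) / 4.0)
        out = apply_rigid_transform(rec, RigidTransform(90, 0, 0))
        assert np.allclose(out.pixels * 4, [[2, 4], [1, 3]])

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_quarter_turns_permute_pixels_exactly(self, k):
        rng = np.random.default_rng(0)
        rec = ImageRecord("x", "A", rng.random((11, 11)))
        out = apply_rigid_transform(rec, RigidTransform(90.0 * k, 0, 0))
        assert np.array_equal(out.pixels, np.rot90(rec.pixels, k))

    def test_integer_translation_shifts_exactly(self):
        rng = np.random.default_rng(1)
        rec = ImageRecord("x", "A", rng.random((8, 8)))
        out = apply_rigid_transform(rec, RigidTransform(0, 2, -1))
        # content moves +2 columns, -1 rows; vacated area filled with 0
        assert np.array_equal(out.pixels[0:7, 2:], rec.pixels[1:8, :6])
        assert np.all(out.pixels[:, :2] == 0)

    def test_inverse_recovers_interior(self, smooth_image):
        t = RigidTransform(17.0, 5.5, -3.25)
        back = apply_rigid_transform(
            apply_rigid_transform(smooth_image, t), t.inverse()
        )
        inner = (slice(32, 96),) * 2
        assert np.abs(back.pixels[inner] - smooth_image.pixels[inner]).max() < 0.05

    def test_out_of_canvas_filled_with_zero(self, smooth_image):
        out = apply_rigid_transform(smooth_image, RigidTransform(0, 200, 0))
        assert np.all(out.pixels[:, :50] == 0)


class TestCropCenter:
    def test_centered_window_indices(self):
        px = np.zeros((834, 834))
        px[289, 289] = 1.0  # expected top-left corner of the 256 window
        px[544, 544] = 0.5  # expected bottom-right corner
        out = crop_center(ImageRecord("x", "A", px), 256)
        assert out.pixels.shape == (256, 256)
        assert out.pixels[0, 0] == 1.0
        assert out.pixels[255, 255] == 0.5

    def test_small_odd_case(self):
        px = np.arange(25, dtype=float).reshape(5, 5) / 24
        out = crop_center(ImageRecord("x", "A", px), 3)
        assert np.allclose(out.pixels, px[1:4, 1:4])

    def test_full_size_is_identity(self, smooth_image):
        out = crop_center(smooth_image, 128)
        assert np.array_equal(out.pixels, smooth_image.pixels)

    def test_oversized_crop_rejected(self, smooth_image):
        with pytest.raises(ValueError):
            crop_center(smooth_image, 300)

    def test_crop_commutes_with_identity_transform(self, smooth_image):
        direct = crop_center(smooth_image, 64)
        via = crop_center(
            apply_rigid_transform(smooth_image, RigidTransform(0, 0, 0)), 64
        )
        assert np.allclose(direct.pixels, via.pixels)


class TestManifest:
    def _rows(self):
        return [
            ManifestRow("p0", "A", "images/p0_A.png", "train"),
            ManifestRow("p0", "B", "images/p0_B.png", "train"),
            ManifestRow(
                "p1", "A", "images/p1_A.png", "test",
                transform=RigidTransform(12.5, -3.0, 44.0),
            ),
        ]

    def test_roundtrip_preserves_rows(self, tmp_path):
        manifest = DatasetManifest(rows=self._rows())
        path = tmp_path / "manifest.csv"
        write_manifest(manifest, path)
        loaded = load_manifest(path)
        assert loaded.rows == self._rows()

    def test_duplicate_pair_modality_rejected(self):
        rows = self._rows() + [ManifestRow("p0", "A", "other.png", "train")]
        with pytest.raises(ValueError, match="duplicate"):
            DatasetManifest(rows=rows)

    def test_unknown_split_rejected(self):
        with pytest.raises(ValueError, match="split"):
            DatasetManifest(rows=[ManifestRow("p0", "A", "x.png", "holdout")])

    def test_empty_transform_columns_mean_no_transform(self, tmp_path):
        path = tmp_path / "manifest.csv"
        path.write_text(
            "pair_id,modality,path,split,angle_deg,tx,ty\n"
            "p0,A,images/p0_A.png,train,,,\n"
        )
        loaded = load_manifest(path)
        assert loaded.rows[0].transform is None

    def test_select_filters_by_modality_and_split(self):
        manifest = DatasetManifest(rows=self._rows())
        assert len(manifest.select(modality="A")) == 2
        assert len(manifest.select(modality="A", split="test")) == 1
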