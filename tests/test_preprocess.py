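"""Tests of the fixed preprocessing chain and its inverse mapping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reflexseg.preprocess import (DEFAULT_CROP_RIGHT, DEFAULT_CROP_TOP,
                                  EyeHalf, ModelInput, PreprocessConfig,
                                  PreprocessError, RawPhotograph,
                                  crop_top_right, load_image, load_mask,
                                  map_mask_to_original, preprocess_mask,
                                  preprocess_pipeline, resize_and_pad,
                                  save_mask, save_record, load_record,
                                  split_halves)


def make_photo(width, height, seed=0):
    rng = np.random.default_rng(seed)
    return RawPhotograph(rng.integers(0, 256, (height, width, 3),
                                      dtype=np.uint8))


class TestRawPhotograph:
    def test_rejects_bad_shapes_and_ranges(self):
        with pytest.raises(PreprocessError):
            RawPhotograph(np.zeros((4, 4), np.uint8))
        with pytest.raises(PreprocessError):
            RawPhotograph(np.full((4, 4, 3), 300))


class TestSplitHalves:
    def test_clinical_dimensions(self):
        left, right = split_halves(make_photo(1200, 797))
        assert left.pixels.shape == (797, 600, 3)
        assert right.pixels.shape == (797, 600, 3)
        assert left.origin_x == 0 and right.origin_x == 600

    def test_smallest_even_width(self):
        left, right = split_halves(make_photo(2, 2))
        assert left.pixels.shape == (2, 1, 3)
        assert right.pixels.shape == (2, 1, 3)

    def test_odd_width_drops_centre_column(self):
        photo = make_photo(5, 4)
        left, right = split_halves(photo)
        # explicit column-index slicing oracle: left cols [0,1], right [3,4]
        np.testing.assert_array_equal(left.pixels, photo.pixels[:, 0:2])
        np.testing.assert_array_equal(right.pixels, photo.pixels[:, 3:5])
        assert right.origin_x == 3

    def test_width_one_rejected(self):
        with pytest.raises(PreprocessError):
            split_halves(make_photo(1, 4))

    def test_halves_cover_disjoint_columns(self):
        photo = make_photo(10, 6)
        left, right = split_halves(photo)
        np.testing.assert_array_equal(
            np.concatenate([left.pixels, right.pixels], axis=1), photo.pixels)


class TestCropTopRight:
    def test_paper_crop_values(self):
        half, _ = split_halves(make_photo(1200, 797))
        cropped = crop_top_right(half, 200, 450)
        assert cropped.pixels.shape == (597, 150, 3)

    def test_zero_crop_is_identity(self):
        half, _ = split_halves(make_photo(20, 10))
        out = crop_top_right(half, 0, 0)
        np.testing.assert_array_equal(out.pixels, half.pixels)

    def test_pixel_correspondence(self):
        half, _ = split_halves(make_photo(20, 16))
        out = crop_top_right(half, 3, 2)
        np.testing.assert_array_equal(out.pixels, half.pixels[3:, :8])

    @pytest.mark.parametrize("top,right", [(10, 0), (0, 10), (16, 10)])
    def test_crop_consuming_axis_rejected(self, top, right):
        half = EyeHalf(np.zeros((10, 10, 3), np.uint8), "left", 0)
        with pytest.raises(PreprocessError, match="consumes"):
            crop_top_right(half, top, right)


class TestResizeAndPad:
    def test_clinical_crop_geometry(self):
        # 597 tall x 150 wide -> scale 512/597, content 512 x 129
        img = make_photo(150, 597).pixels
        out, geom = resize_and_pad(img)
        assert out.shape == (512, 512, 3)
        assert geom["content_height"] == 512
        assert geom["content_width"] == 129  # round(150 * 512 / 597)
        assert geom["pad_right"] == 383 and geom["pad_bottom"] == 0

    def test_identity_scale(self):
        img = make_photo(512, 512).pixels
        out, geom = resize_and_pad(img)
        assert geom["scale"] == 1.0
        assert geom["pad_right"] == geom["pad_bottom"] == 0
        np.testing.assert_allclose(out, img / 255.0, atol=1e-6)

    def test_exact_integer_upscale(self):
        img = make_photo(256, 128).pixels  # 128 tall x 256 wide
        out, geom = resize_and_pad(img)
        assert geom["scale"] == 2.0
        assert geom["content_width"] == 512
        assert geom["content_height"] == 256
        assert geom["pad_bottom"] == 256 and geom["pad_right"] == 0

    def test_padding_is_exactly_zero(self):
        img = np.full((100, 30, 3), 255, np.uint8)
        out, geom = resize_and_pad(img)
        assert (out[:, geom["content_width"]:, :] == 0).all()
        assert (out[geom["content_height"]:, :, :] == 0).all()

    def test_intensities_in_unit_interval(self):
        out, _ = resize_and_pad(make_photo(77, 33).pixels)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(PreprocessError):
            resize_and_pad(np.zeros((0, 3, 3)))

    @given(st.integers(20, 300), st.integers(20, 300))
    def test_aspect_ratio_preserved(self, w, h):
        img = np.zeros((h, w, 3), np.uint8)
        _, geom = resize_and_pad(img)
        got = geom["content_width"] / geom["content_height"]
        # rounding the short side by +-0.5 px bounds the relative error
        short = min(geom["content_width"], geom["content_height"])
        assert abs(got - w / h) / (w / h) <= 1.0 / short


class TestPipeline:
    def test_clinical_left_eye_end_to_end(self):
        photo = make_photo(1200, 797)
        model_in, record = preprocess_pipeline(photo, "left")
        assert model_in.pixels.shape == (512, 512, 3)
        assert model_in.pixels.min() >= 0 and model_in.pixels.max() <= 1
        assert record.scale == pytest.approx(512 / 597)
        assert record.side == "left" and not record.mirrored

    def test_bit_identical_determinism(self):
        photo = make_photo(1200, 797, seed=5)
        a, _ = preprocess_pipeline(photo, "left")
        b, _ = preprocess_pipeline(photo, "left")
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_right_eye_is_mirrored_by_default(self):
        photo = make_photo(1200, 797, seed=6)
        _, record = preprocess_pipeline(photo, "right")
        assert record.mirrored and record.origin_x == 600
        cfg = PreprocessConfig(mirror_right_eye=False)
        _, record2 = preprocess_pipeline(photo, "right", cfg)
        assert not record2.mirrored

    def test_mirrored_right_equals_left_of_flipped_photo(self):
        photo = make_photo(1200, 797, seed=7)
        flipped = RawPhotograph(photo.pixels[:, ::-1])
        right_in, _ = preprocess_pipeline(photo, "right")
        left_of_flipped, _ = preprocess_pipeline(flipped, "left")
        np.testing.assert_array_equal(right_in.pixels, left_of_flipped.pixels)

    def test_mask_dims_track_image_dims(self):
        # carrying an indicator mask through the chain lands where the
        # bright pixel block lands in the image
        photo_px = np.zeros((797, 1200, 3), np.uint8)
        photo_px[300:320, 50:70] = 255
        mask = np.zeros((797, 1200), np.uint8)
        mask[300:320, 50:70] = 1
        model_in, record = preprocess_pipeline(RawPhotograph(photo_px), "left")
        mask512 = preprocess_mask(mask, record)
        assert mask512.shape == (512, 512)
        img_bright = model_in.pixels[..., 0] > 0.5
        overlap = (mask512 & img_bright).sum()
        assert overlap / mask512.sum() > 0.8


class TestInverseMapping:
    def test_all_zero_mask_is_fixed_point(self):
        _, record = preprocess_pipeline(make_photo(1200, 797), "left")
        out = map_mask_to_original(np.zeros((512, 512), np.uint8), record)
        assert out.shape == (797, 1200) and out.sum() == 0

    def test_padded_region_maps_nowhere(self):
        _, record = preprocess_pipeline(make_photo(1200, 797), "left")
        mask = np.zeros((512, 512), np.uint8)
        mask[10, record.content_width + 5] = 1  # inside right padding
        out = map_mask_to_original(mask, record)
        assert out.sum() == 0

    @pytest.mark.parametrize("side", ["left", "right"])
    def test_blob_round_trip_iou(self, side):
        photo = make_photo(1200, 797, seed=8)
        _, record = preprocess_pipeline(photo, side)
        raw_mask = np.zeros((797, 1200), np.uint8)
        # an 8x8 blob inside the cropped field of view of the chosen half
        r0, c0 = (400, 80) if side == "left" else (400, 1100)
        raw_mask[r0:r0 + 8, c0:c0 + 8] = 1
        mask512 = preprocess_mask(raw_mask, record)
        assert mask512.sum() > 0
        back = map_mask_to_original(mask512, record)
        inter = (back & raw_mask).sum()
        union = (back | raw_mask).sum()
        assert inter / union >= 0.5

    def test_component_count_preserved_for_wide_blobs(self):
        from scipy.ndimage import label
        photo = make_photo(1200, 797, seed=9)
        _, record = preprocess_pipeline(photo, "left")
        raw_mask = np.zeros((797, 1200), np.uint8)
        raw_mask[300:310, 30:40] = 1
        raw_mask[500:508, 90:98] = 1
        back = map_mask_to_original(preprocess_mask(raw_mask, record), record)
        assert label(back)[1] == label(raw_mask)[1] == 2

    def test_wrong_mask_shape_rejected(self):
        _, record = preprocess_pipeline(make_photo(1200, 797), "left")
        with pytest.raises(PreprocessError):
            map_mask_to_original(np.zeros((256, 256), np.uint8), record)

    def test_scaled_square_maps_back_to_source_location(self):
        # forward-transform oracle: place a square in the raw frame, push it
        # through the chain, invert, and compare against the original square
        photo = make_photo(1200, 797, seed=10)
        _, record = preprocess_pipeline(photo, "left")
        raw = np.zeros((797, 1200), np.uint8)
        raw[420:430, 60:70] = 1
        back = map_mask_to_original(preprocess_mask(raw, record), record)
        ys, xs = np.nonzero(back)
        assert abs(ys.mean() - 424.5) < 2 and abs(xs.mean() - 64.5) < 2


class TestIOAndRecords:
    def test_image_and_mask_readers(self, tmp_path):
        from PIL import Image
        arr = np.random.default_rng(0).integers(
            0, 256, (10, 12, 3), dtype=np.uint8)
        Image.fromarray(arr).save(tmp_path / "img.png")
        photo = load_image(tmp_path / "img.png")
        np.testing.assert_array_equal(photo.pixels, arr)

        mask = (arr[..., 0] > 127).astype(np.uint8)
        save_mask(mask, tmp_path / "mask.png")
        np.testing.assert_array_equal(load_mask(tmp_path / "mask.png"), mask)

    def test_record_round_trip(self, tmp_path):
        _, record = preprocess_pipeline(make_photo(1200, 797), "right")
        save_record(record, tmp_path / "rec.json")
        assert load_record(tmp_path / "rec.json") == record

    def test_config_from_yaml(self, tmp_path):
        (tmp_path / "cfg.yaml").write_text(
            "crop_top: 100\ncrop_right: 200\nmirror_right_eye: false\n")
        cfg = PreprocessConfig.from_file(tmp_path / "cfg.yaml")
        assert cfg == PreprocessConfig(crop_top=100, crop_right=200,
                                       mirror_right_eye=False)

    def test_model_input_validation(self):
        with pytest.raises(PreprocessError):
            ModelInput(np.full((512, 512, 3), 2.0))
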