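"""Box geometry, crop/restore transforms, normalization and PNG round trips."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cscseg.geometry import (CropRecord, DetBox, box_to_window, crop,
                             make_crop_record, normalize_input, read_mask,
                             read_png, resize, restore, scale_box, tight_box,
                             write_mask, write_png)
from cscseg.evaluation import iou


class TestScaleBox:
    @pytest.mark.parametrize("box,factor,expected", [
        ((200, 150, 100, 80), 1.2, (200, 150, 120, 96)),
        ((50, 50, 10, 20), 2.0, (50, 50, 20, 40)),
    ])
    def test_expands_about_center(self, box, factor, expected):
        cx, cy, w, h = box
        out = scale_box(DetBox(cx=cx, cy=cy, w=w, h=h, confidence=0.7), factor)
        assert (out.cx, out.cy, out.w, out.h) == pytest.approx(expected)
        assert out.confidence == 0.7

    def test_identity(self):
        b = DetBox(cx=5, cy=5, w=3, h=4)
        assert scale_box(b, 1.0) == b

    def test_rejects_nonpositive_factor(self):
        with pytest.raises(ValueError):
            scale_box(DetBox(cx=0, cy=0, w=1, h=1), 0.0)

    @given(st.floats(0.1, 4), st.floats(0.1, 4))
    def test_multiplicative(self, a, c):
        b = DetBox(cx=10.0, cy=-3.0, w=7.0, h=2.5)
        lhs = scale_box(scale_box(b, a), c)
        rhs = scale_box(b, a * c)
        assert lhs.w == pytest.approx(rhs.w, rel=1e-9)
        assert lhs.h == pytest.approx(rhs.h, rel=1e-9)
        assert (lhs.cx, lhs.cy) == (rhs.cx, rhs.cy)


class TestBoxToWindow:
    def test_clips_at_border(self):
        w = box_to_window(DetBox(cx=10, cy=10, w=40, h=40), (100, 100))
        assert w == (0, 30, 0, 30)

    def test_interior_box(self):
        w = box_to_window(DetBox(cx=50, cy=50, w=10, h=10), (100, 100))
        assert w == (45, 55, 45, 55)

    def test_fully_outside_is_detection_failure(self):
        assert box_to_window(DetBox(cx=-100, cy=-100, w=10, h=10), (100, 100)) is None

    @given(st.floats(-50, 150), st.floats(-50, 150),
           st.floats(0.5, 80), st.floats(0.5, 80))
    def test_window_inside_canvas_or_failure(self, cx, cy, w, h):
        win = box_to_window(DetBox(cx=cx, cy=cy, w=w, h=h), (100, 80))
        if win is not None:
            x0, x1, y0, y1 = win
            assert 0 <= x0 < x1 <= 100 and 0 <= y0 < y1 <= 80

    def test_outward_rounding_never_shrinks(self):
        # a fractional box must be covered entirely by its window
        win = box_to_window(DetBox(cx=10.3, cy=10.7, w=3.1, h=2.3), (100, 100))
        x0, x1, y0, y1 = win
        assert x0 <= 10.3 - 3.1 / 2 and x1 >= 10.3 + 3.1 / 2
        assert y0 <= 10.7 - 2.3 / 2 and y1 >= 10.7 + 2.3 / 2


class TestMakeCropRecord:
    def test_expansion_arithmetic(self):
        rec = make_crop_record(DetBox(cx=320, cy=240, w=100, h=100), (640, 480))
        assert rec.window == (260, 380, 180, 300)
        assert rec.crop_output_size == (256, 256)

    def test_corner_box_clipped(self):
        rec = make_crop_record(DetBox(cx=5, cy=5, w=40, h=40), (640, 480))
        x0, x1, y0, y1 = rec.window
        assert x0 == 0 and y0 == 0 and x1 > 0 and y1 > 0

    def test_expanded_window_contains_unexpanded(self):
        b = DetBox(cx=320, cy=240, w=100, h=80)
        small = make_crop_record(b, (640, 480), expand=1.0)
        big = make_crop_record(b, (640, 480), expand=1.2)
        assert big.window[0] <= small.window[0] and big.window[1] >= small.window[1]
        assert big.window[2] <= small.window[2] and big.window[3] >= small.window[3]


class TestCropRestore:
    def test_whole_image_window(self, rng):
        img = rng.integers(0, 256, (480, 640), dtype=np.uint8)
        rec = CropRecord((0, 640, 0, 480), (640, 480), (256, 256))
        out = crop(img, rec)
        assert out.shape == (256, 256) and out.dtype == np.uint8

    def test_mask_crop_stays_binary(self, rng):
        m = (rng.random((480, 640)) > 0.5).astype(np.uint8)
        rec = CropRecord((100, 300, 50, 250), (640, 480), (256, 256))
        out = crop(m, rec, mask=True)
        assert set(np.unique(out)) <= {0, 1}

    def test_size_mismatch_rejected(self, rng):
        rec = CropRecord((0, 10, 0, 10), (20, 20), (10, 10))
        with pytest.raises(ValueError):
            crop(np.zeros((30, 30), dtype=np.uint8), rec)

    def test_round_trip_exact_without_resize(self, rng):
        # window size equals output size: crop-restore-crop is pixel-exact
        img = rng.random((480, 640)).astype(np.float32)
        rec = CropRecord((100, 164, 50, 114), (640, 480), (64, 64))
        c1 = resize(img[50:114, 100:164], (64, 64))
        restored = restore(c1, rec)
        assert np.array_equal(restored[50:114, 100:164], c1)
        assert restored.sum() == pytest.approx(c1.sum(), rel=1e-5)

    def test_restore_zero_and_one(self):
        rec = CropRecord((10, 74, 20, 84), (100, 100), (64, 64))
        z = restore(np.zeros((64, 64), dtype=np.float32), rec)
        assert not z.any()
        o = restore(np.ones((64, 64), dtype=np.float32), rec)
        assert o[20:84, 10:74].min() == 1.0
        o[20:84, 10:74] = 0
        assert not o.any()

    def test_round_trip_blob_iou(self, rng):
        # with resizing, a smooth blob survives crop->restore with IoU > 0.95
        yy, xx = np.mgrid[0:480, 0:640]
        for k in range(5):
            cx, cy = rng.integers(200, 440), rng.integers(150, 330)
            a, b = rng.integers(25, 60), rng.integers(25, 60)
            blob = (((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1).astype(np.uint8)
            rec = make_crop_record(tight_box(blob), (640, 480), 1.2, (256, 256))
            back = restore(crop(blob, rec, mask=True).astype(np.float32), rec)
            assert iou((back > 0.5).astype(np.uint8), blob) > 0.95


class TestNormalize:
    def test_endpoints_exact(self):
        img = np.array([[0, 255]], dtype=np.uint8)
        out = normalize_input(img)
        assert out[0, 0] == -1.0 and out[0, 1] == 1.0

    def test_midpoint(self):
        assert abs(normalize_input(np.array([[128]], dtype=np.uint8))[0, 0]) < 0.005

    @given(st.integers(0, 254))
    def test_affine_monotone(self, v):
        a = normalize_input(np.array([[v]], dtype=np.uint8))[0, 0]
        b = normalize_input(np.array([[v + 1]], dtype=np.uint8))[0, 0]
        assert b > a
        assert b - a == pytest.approx(1 / 127.5, rel=1e-5)


class TestPngIO:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        img = rng.integers(0, 256, (480, 640), dtype=np.uint8)
        p = tmp_path / "frame.png"
        write_png(p, img)
        assert np.array_equal(read_png(p), img)

    def test_mask_coding(self, tmp_path, rng):
        m = (rng.random((32, 32)) > 0.5).astype(np.uint8)
        p = tmp_path / "mask.png"
        write_mask(p, m)
        assert np.array_equal(read_mask(p), m)
        assert set(np.unique(read_png(p))) <= {0, 255}

    def test_rgb_read_as_luminance(self, tmp_path):
        from PIL import Image
        arr = np.zeros((8, 8, 3), dtype=np.uint8)
        arr[..., 0] = 255  # pure red
        p = tmp_path / "rgb.png"
        Image.fromarray(arr).save(p)
        g = read_png(p)
        assert g.shape == (8, 8)
        assert 60 <= g[0, 0] <= 90  # luminance of red

    def test_corrupt_file_raises_with_path(self, tmp_path):
        p = tmp_path / "bad.png"
        p.write_bytes(b"not a png")
        with pytest.raises(OSError, match="bad.png"):
            read_png(p)
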