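import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from flygroom.features import (
    ComMap,
    FeatureConfig,
    crop_rois,
    extract_stream,
    fuse_channels,
    locate_roi,
    motion_energy,
    temporal_com,
)


def com_oracle(series, index_base=0):
    """O(w^2) direct-DFT spectral center of mass of one pixel series."""
    w = len(series)
    mags = []
    for k in range(w):
        z = sum(series[t] * np.exp(-2j * np.pi * k * t / w) for t in range(w))
        mags.append(abs(z))
    den = sum(mags)
    if den == 0:
        return 0.0
    return sum((k + index_base) * m for k, m in enumerate(mags)) / den


class TestMotionEnergy:
    def test_constant_stack_is_zero(self):
        stack = np.ones((7, 10, 10)) * 0.4
        assert (motion_energy(stack) == 0).all()

    def test_alternating_pixel_accumulates_unit_steps(self):
        stack = np.zeros((7, 5, 5))
        stack[1::2, 2, 3] = 1.0  # 0,1,0,1,0,1,0
        D = motion_energy(stack)
        assert D[2, 3] == pytest.approx(6.0)
        D[2, 3] = 0
        assert (D == 0).all()

    def test_matches_double_loop_oracle(self, rng):
        stack = rng.random((7, 10, 10))
        D = motion_energy(stack)
        for r in range(10):
            for c in range(10):
                ref = sum(
                    abs(stack[i, r, c] - stack[i - 1, r, c]) for i in range(1, 7)
                )
                assert D[r, c] == pytest.approx(ref, abs=1e-12)

    def test_invariant_under_constant_offset(self, rng):
        stack = rng.random((7, 8, 8))
        offset = rng.random((8, 8))
        np.testing.assert_allclose(
            motion_energy(stack), motion_energy(stack + offset), atol=1e-12
        )

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            motion_energy(np.zeros((1, 4, 4)))


class TestLocateRoi:
    def test_all_zero_ties_break_to_origin(self):
        assert locate_roi(np.zeros((50, 50))) == (0, 0)

    def test_unique_maximum(self):
        D = np.zeros((500, 500))
        D[200, 300] = 3.0
        assert locate_roi(D) == (200, 300)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            D = rng.random((30, 40))
            best, arg = -1.0, None
            for r in range(30):
                for c in range(40):
                    if D[r, c] > best:
                        best, arg = D[r, c], (r, c)
            assert locate_roi(D) == arg


class TestCropRois:
    def test_interior_center_half_open_box(self, rng):
        stack = rng.random((7, 500, 500))
        body = rng.integers(0, 256, (500, 500)).astype(np.uint8)
        troi, sroi = crop_rois(stack, body, (250, 250), 100)
        np.testing.assert_array_equal(troi, stack[:, 200:300, 200:300])
        np.testing.assert_array_equal(sroi, body[200:300, 200:300])

    def test_border_center_clamps_inside(self, rng):
        stack = rng.random((7, 500, 500))
        body = np.zeros((500, 500), np.uint8)
        troi, _ = crop_rois(stack, body, (10, 250), 100)
        np.testing.assert_array_equal(troi, stack[:, 0:100, 200:300])
        troi, _ = crop_rois(stack, body, (495, 495), 100)
        np.testing.assert_array_equal(troi, stack[:, 400:500, 400:500])

    def test_both_rois_cover_identical_pixels(self):
        # coordinate-coded image: value = row * 1000 + col
        rr, cc = np.mgrid[0:300, 0:300]
        coded = (rr * 1000 + cc).astype(float)
        stack = np.stack([coded] * 7)
        troi, sroi = crop_rois(stack, coded, (37, 250), 100)
        np.testing.assert_array_equal(troi[0], sroi)

    def test_oversized_roi_rejected(self):
        with pytest.raises(ValueError):
            crop_rois(np.zeros((7, 50, 50)), np.zeros((50, 50)), (25, 25), 100)


class TestTemporalCom:
    def test_constant_positive_pixel_is_pure_dc(self):
        troi = np.full((7, 4, 4), 0.6)
        com = temporal_com(troi)
        assert com.raw == pytest.approx(np.zeros((4, 4)))

    def test_all_zero_pixel_uses_zero_denominator_rule(self):
        com = temporal_com(np.zeros((7, 3, 3)))
        assert (com.raw == 0).all() and (com.normalized == 0).all()

    def test_matches_direct_dft_oracle(self, rng):
        troi = rng.random((7, 6, 6))
        com = temporal_com(troi)
        for r in range(6):
            for c in range(6):
                assert com.raw[r, c] == pytest.approx(
                    com_oracle(troi[:, r, c]), abs=1e-9
                )

    def test_one_based_index_variant_saturates_static_pixels(self):
        troi = np.full((7, 2, 2), 0.5)
        com = temporal_com(troi, index_base=1)
        # all mass at DC, weighted 1 -> m = 1 -> saturated after clipping
        assert com.normalized == pytest.approx(np.ones((2, 2)))

    @given(
        arrays(
            np.float64,
            (7, 3, 3),
            elements=st.floats(0, 1, allow_nan=False, width=32),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_normalized_always_in_unit_interval(self, troi):
        com = temporal_com(troi)
        assert (com.raw >= 0).all()
        assert (com.normalized >= 0).all() and (com.normalized <= 1).all()
        np.testing.assert_array_equal(com.normalized, np.clip(com.raw, 0, 1))


class TestFuseChannels:
    def test_motionless_empty_window_is_black(self):
        troi = np.zeros((7, 10, 10))
        img = fuse_channels(temporal_com(troi), np.zeros((10, 10)), troi)
        assert (img == 0).all()

    def test_static_body_green_caps_at_142(self):
        troi = np.full((7, 10, 10), 0.3)
        sroi = np.full((10, 10), 255.0)
        img = fuse_channels(temporal_com(troi), sroi, troi)
        assert (img[..., 0] == 0).all()
        assert (img[..., 1] == 142).all()  # round(255 / 1.8)
        assert (img[..., 2] == round(0.3 * 255)).all()

    def test_blue_is_second_frame(self, rng):
        troi = rng.random((7, 8, 8))
        img = fuse_channels(temporal_com(troi), np.zeros((8, 8)), troi)
        np.testing.assert_array_equal(img[..., 2], np.rint(255 * troi[1]))

    def test_shape_mismatch_rejected(self):
        troi = np.zeros((7, 10, 10))
        with pytest.raises(ValueError):
            fuse_channels(temporal_com(troi), np.zeros((9, 9)), troi)


class TestExtractStream:
    def make_frames(self, n, rng):
        return [rng.integers(0, 256, (40, 40, 3), dtype=np.uint8) for _ in range(n)]

    def test_window_count_is_n_minus_w_plus_one(self, rng):
        cfg = FeatureConfig(size=40, roi=20)
        frames = self.make_frames(20, rng)
        out = list(extract_stream(frames, cfg))
        assert len(out) == 20 - 7 + 1
        assert [fi.window_index for fi in out] == list(range(1, 15))

    def test_exactly_one_window(self, rng):
        out = list(extract_stream(self.make_frames(7, rng), FeatureConfig(size=40, roi=20)))
        assert len(out) == 1 and out[0].window_index == 1

    def test_short_stream_warns_and_yields_nothing(self, rng):
        with pytest.warns(UserWarning, match="shorter than one window"):
            out = list(extract_stream(self.make_frames(3, rng), FeatureConfig(size=40, roi=20)))
        assert out == []

    def test_bit_identical_reruns(self, rng):
        frames = self.make_frames(12, rng)
        cfg = FeatureConfig(size=40, roi=20)
        a = [fi.pixels for fi in extract_stream(frames, cfg)]
        b = [fi.pixels for fi in extract_stream(frames, cfg)]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_channels_within_bounds(self, head_scene_frames):
        _, frames, _ = head_scene_frames
        for fi in extract_stream(frames[:10], FeatureConfig()):
            assert fi.pixels.dtype == np.uint8
            assert fi.pixels[..., 1].max() <= 142
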