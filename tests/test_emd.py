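"""Reichardt-correlator core: luminance, acuity filtering, EMD responses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dazzle.emd import MotionField, ViewerModel, acuity_filter, emd_pair, process_clip, to_luminance
from dazzle.stimuli import GratingSpec, render_grating


def michelson_contrast(image: np.ndarray) -> float:
    lo, hi = image.min(), image.max()
    return (hi - lo) / (hi + lo) if hi + lo > 0 else 0.0


@pytest.fixture(scope="module")
def viewer():
    # default geometry: 2.5 cpd at 30 cm, 10 px/cm rendering
    return ViewerModel.from_geometry(2.5, scale=10.0, viewing_distance=30.0)


class TestLuminance:
    @pytest.mark.parametrize(
        "frame,expected",
        [
            (np.full((4, 4), 255, dtype=np.uint8), 1.0),
            (np.zeros((4, 4), dtype=np.uint8), 0.0),
            (np.full((4, 4), 128, dtype=np.uint8), 128 / 255),
        ],
    )
    def test_integer_frames_rescaled_by_bit_depth(self, frame, expected):
        assert np.allclose(to_luminance(frame), expected)

    def test_rgb_reduced_with_rec709_weights(self):
        frame = np.zeros((2, 2, 3), dtype=np.uint8)
        frame[..., 1] = 255  # pure green
        assert np.allclose(to_luminance(frame), 0.7152)

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            to_luminance(np.zeros((0, 0)))


class TestViewerModel:
    def test_sampling_base_from_default_geometry(self, viewer):
        # 10 px/cm at 30 cm -> 5.236 px/deg; half the resolvable period is 1 px
        assert viewer.pixels_per_degree == pytest.approx(10 * 30 * np.pi / 180)
        assert viewer.delta == 1
        assert viewer.sigma == 0.5

    def test_subnyquist_sampling_rejected(self):
        with pytest.raises(ValueError, match="pixels_per_degree"):
            ViewerModel(acuity=10.0, pixels_per_degree=5.0)

    def test_delta_scales_with_sampling_density(self):
        fine = ViewerModel.from_geometry(2.5, scale=40.0)
        assert fine.delta == pytest.approx(round(fine.pixels_per_degree / 5.0))


class TestAcuityFilter:
    def test_uniform_image_unchanged(self, viewer):
        img = np.full((16, 16), 0.37)
        assert np.allclose(acuity_filter(img, viewer), img)

    def test_halfacuity_grating_keeps_most_contrast(self, viewer):
        # 1.25 cpd at 30 cm -> bar width ~0.21 cm
        bar = 30 * np.tan(np.radians(1.0)) / (2 * 1.25)
        img = render_grating(GratingSpec(bar_width=bar), 200, 8, scale=10.0)
        filtered = acuity_filter(img, viewer)
        core = filtered[:, 50:150]
        assert michelson_contrast(core) > 0.5 * michelson_contrast(img)

    def test_double_acuity_grating_indiscriminable(self, viewer):
        # 5 cpd at 30 cm -> bar width ~0.052 cm: the finest test grating
        bar = 30 * np.tan(np.radians(1.0)) / (2 * 5.0)
        with pytest.warns(UserWarning):
            img = render_grating(GratingSpec(bar_width=bar), 200, 8, scale=10.0)
        filtered = acuity_filter(img, viewer)
        core = filtered[:, 50:150]
        assert michelson_contrast(core) < 0.05 * 1.0  # relative to unit input contrast


class TestEmdPair:
    def test_identical_frames_give_zero_field(self, rng):
        frame = rng.random((12, 12))
        field = emd_pair(frame, frame, 1)
        assert np.all(field.h == 0) and np.all(field.v == 0)

    def test_period4_shift_hand_example(self):
        # [1,1,0,0] shifted right by one px; correlator gives (+1,+1,0,0)
        prev = np.tile([1.0, 1.0, 0.0, 0.0], (4, 3))
        curr = np.roll(prev, 1, axis=1)
        field = emd_pair(prev, curr, 1)
        assert np.array_equal(field.h[0, :4], [1.0, 1.0, 0.0, 0.0])
        assert field.h[field.valid].mean() == pytest.approx(0.5, abs=0.05)
        nz = field.valid & (field.magnitude > 0)
        assert np.allclose(field.direction[nz], 90.0)

    def test_horizontal_grating_translated_horizontally_is_silent(self):
        img = render_grating(GratingSpec(bar_width=0.4, orientation="horizontal"), 40, 40, scale=10.0)
        shifted = np.roll(img, 3, axis=1)  # constant along x: roll is identity
        field = emd_pair(img, shifted, 1)
        assert np.all(field.h == 0) and np.all(field.v == 0)

    @settings(max_examples=25, deadline=None)
    @given(
        prev=arrays(float, (6, 6), elements=st.floats(0, 1)),
        curr=arrays(float, (6, 6), elements=st.floats(0, 1)),
    )
    def test_antisymmetry_under_frame_swap(self, prev, curr):
        fwd = emd_pair(prev, curr, 1)
        rev = emd_pair(curr, prev, 1)
        assert np.array_equal(fwd.h, -rev.h)
        assert np.array_equal(fwd.v, -rev.v)

    @settings(max_examples=25, deadline=None)
    @given(
        prev=arrays(float, (6, 8), elements=st.floats(0, 1)),
        curr=arrays(float, (6, 8), elements=st.floats(0, 1)),
    )
    def test_mirror_symmetry_negates_horizontal_response(self, prev, curr):
        d = 1
        fwd = emd_pair(prev, curr, d)
        mir = emd_pair(np.fliplr(prev), np.fliplr(curr), d)
        # mirroring shifts the correlator's anchor: H'(x) = -H(W-1-x-d)
        w = prev.shape[1]
        for x in range(w - d):
            assert mir.h[:, x] == pytest.approx(-fwd.h[:, w - 1 - x - d])
            assert mir.v[:, x] == pytest.approx(fwd.v[:, w - 1 - x])

    def test_nyquist_grating_mean_response_is_zero(self):
        # period exactly 2*delta, shifted by delta: direction is ambiguous,
        # so the response averages to zero over complete periods
        d = 2
        prev = np.tile(np.repeat([1.0, 0.0], d), (8, 4))
        curr = np.roll(prev, d, axis=1)
        field = emd_pair(prev, curr, d)
        assert field.h[0, :12].mean() == pytest.approx(0.0, abs=1e-12)

    def test_border_pixels_marked_invalid(self):
        field = emd_pair(np.ones((5, 7)), np.ones((5, 7)), 2)
        assert not field.valid[:, -2:].any()
        assert not field.valid[-2:, :].any()
        assert field.valid[:3, :5].all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            emd_pair(np.ones((4, 4)), np.ones((4, 5)), 1)


class TestProcessClip:
    def test_two_identical_frames_one_zero_field(self, viewer):
        frames = np.tile(np.linspace(0, 1, 32), (2, 32, 1))
        fields = process_clip(frames, viewer)
        assert len(fields) == 1
        assert np.all(fields[0].h == 0) and np.all(fields[0].v == 0)

    def test_single_frame_rejected(self, viewer):
        with pytest.raises(ValueError, match="2 frames"):
            process_clip(np.zeros((1, 8, 8)), viewer)

    def test_reversed_order_negates_fields(self, viewer, rng):
        frames = rng.random((4, 16, 16))
        fwd = process_clip(frames, viewer)
        rev = process_clip(frames[::-1], viewer)
        for f, r in zip(fwd, rev[::-1]):
            assert np.allclose(f.h, -r.h) and np.allclose(f.v, -r.v)

    def test_fast_clip_warns_about_temporal_resolution(self, fixtures):
        slow_viewer = ViewerModel.from_geometry(2.5, scale=10.0, temporal_resolution=10.0)
        with pytest.warns(UserWarning, match="temporal"):
            process_clip(fixtures["pan_right"], slow_viewer)

    def test_resolvable_pan_is_overwhelmingly_rightward(self, fixtures, viewer):
        fields = process_clip(fixtures["pan_right"], viewer)
        field = fields[0]
        nz = field.valid & (field.magnitude > 1e-12)
        offsets = (field.direction[nz] - 90.0 + 180.0) % 360.0 - 180.0
        assert np.mean(np.abs(offsets) <= 10.0) > 0.9

    def test_static_scene_silent_through_full_arm(self, fixtures, viewer):
        fields = process_clip(fixtures["static"], viewer)
        for f in fields:
            assert np.all(f.h == 0) and np.all(f.v == 0)
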