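"""Stimulus generation: gratings, fish sprite, clips and tracks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dazzle.stimuli import (
    ClipSpec,
    FishSprite,
    GratingSpec,
    SubPixelBarWarning,
    TrackSpec,
    compose_clip,
    render_fish,
    render_grating,
    simulate_track,
)


class TestRenderGrating:
    def test_vertical_bars_alternate_along_x_with_period_2w(self):
        img = render_grating(GratingSpec(bar_width=1.0), 40, 8, scale=10.0)
        row = img[0]
        expected = np.tile(np.r_[np.zeros(10), np.ones(10)], 2)
        assert np.array_equal(row, expected)
        assert np.array_equal(img, np.broadcast_to(row, img.shape))

    def test_horizontal_orientation_varies_along_y(self):
        img = render_grating(GratingSpec(bar_width=0.5, orientation="horizontal"), 8, 30, scale=10.0)
        col = img[:, 0]
        expected = np.tile(np.r_[np.zeros(5), np.ones(5)], 3)
        assert np.array_equal(col, expected)
        assert np.all(img == img[:, :1])

    def test_two_distinct_values_when_edges_on_pixel_boundaries(self):
        img = render_grating(GratingSpec(bar_width=0.3, dark_level=0.1, light_level=0.8), 60, 4, scale=10.0)
        assert set(np.unique(img)) == {0.1, 0.8}

    def test_subpixel_bars_warn_and_average_to_mean_grey(self):
        with pytest.warns(SubPixelBarWarning):
            img = render_grating(GratingSpec(bar_width=0.05), 32, 4, scale=10.0)
        # period is exactly 1 px so every pixel integrates half dark, half light
        assert np.allclose(img, 0.5)

    @pytest.mark.parametrize("bar_width,scale", [(1.0, 10.0), (0.5, 10.0), (0.25, 8.0), (2.0, 5.0)])
    def test_fourier_peak_at_design_frequency(self, bar_width, scale):
        n = 512
        img = render_grating(GratingSpec(bar_width=bar_width), n, 1, scale=scale)
        spectrum = np.abs(np.fft.rfft(img[0] - img[0].mean()))
        freqs = np.fft.rfftfreq(n)
        expected = 1.0 / (2.0 * bar_width * scale)
        assert abs(freqs[np.argmax(spectrum)] - expected) <= freqs[1]

    def test_phase_shifts_pattern_toward_positive_x(self):
        base = render_grating(GratingSpec(bar_width=0.5), 40, 1, scale=10.0)
        shifted = render_grating(GratingSpec(bar_width=0.5, phase=0.3), 40, 1, scale=10.0)
        assert np.allclose(shifted[0, 3:], base[0, :-3])

    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(ValueError, match="dimensions"):
            render_grating(GratingSpec(bar_width=1.0), 0, 10, scale=10.0)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            GratingSpec(bar_width=-1.0)
        with pytest.raises(ValueError):
            GratingSpec(bar_width=1.0, dark_level=0.9, light_level=0.2)


class TestRenderFish:
    def test_no_stripes_gives_uniform_ellipse(self):
        image, mask = render_fish(FishSprite(n_stripes=0), scale=10.0)
        assert set(np.unique(image[mask > 0])) == {0.95}
        assert set(np.unique(mask)) == {0.0, 1.0}

    def test_three_stripes_are_five_px_wide_bands(self):
        sprite = FishSprite(body_length=6.0, body_height=3.0, stripe_width=0.5, n_stripes=3)
        image, mask = render_fish(sprite, scale=10.0)
        assert image.shape == (30, 60)
        mid_row = image[15]
        dark_cols = np.where((mid_row == 0.0) & (mask[15] > 0))[0]
        # three separated bands of exactly 5 columns
        runs = np.split(dark_cols, np.where(np.diff(dark_cols) > 1)[0] + 1)
        assert len(runs) == 3
        assert all(len(r) == 5 for r in runs)

    def test_dark_fraction_tracks_stripe_coverage(self):
        sprite = FishSprite(body_length=6.0, body_height=3.0, stripe_width=0.5, n_stripes=3)
        image, mask = render_fish(sprite, scale=40.0)
        inside = mask > 0
        frac = np.mean(image[inside] == sprite.stripe_level)
        # interior stripes cross taller chords of the ellipse, so the pixel
        # fraction sits somewhat above the length fraction 3 * 0.5 / 6
        nominal = sprite.n_stripes * sprite.stripe_width / sprite.body_length
        assert nominal * 0.8 < frac < nominal * 1.4

    def test_stripes_exceeding_body_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            FishSprite(body_length=2.0, stripe_width=1.0, n_stripes=3)


class TestComposeClip:
    def _spec(self, **kwargs):
        base = dict(
            grating=GratingSpec(bar_width=0.5),
            frame_rate=30.0,
            n_frames=5,
            scale=10.0,
            width_px=120,
            height_px=80,
        )
        base.update(kwargs)
        return ClipSpec(**base)

    def test_static_scene_has_identical_frames(self):
        clip = compose_clip(self._spec(camera_speed=0.0))
        assert np.array_equal(clip.frames[0], clip.frames[-1])

    def test_background_shift_arithmetic(self):
        spec = self._spec(camera_speed=17.0)
        assert spec.background_shift_px == pytest.approx(17.0 * 10.0 / 30.0)

    def test_background_pans_by_camera_shift(self):
        clip = compose_clip(self._spec(camera_speed=9.0))  # 3 px / frame exactly
        assert np.allclose(clip.frames[1][:, 3:], clip.frames[0][:, :-3])

    def test_fish_centroid_advances_at_fish_speed(self):
        spec = self._spec(
            fish=FishSprite(body_length=3.0, body_height=1.5),
            fish_speed=9.0,
            fish_start=(3.0, 4.0),
            n_frames=4,
        )
        clip = compose_clip(spec)
        # centroid oracle: the body level 0.95 appears nowhere in the binary
        # background, so body pixels identify the fish directly
        xs = []
        for t in range(4):
            ys, xcols = np.nonzero(clip.frames[t] == 0.95)
            xs.append(xcols.mean())
        steps = np.diff(xs)
        assert np.allclose(steps, 9.0 * 10.0 / 30.0, atol=0.5)

    def test_background_identical_outside_fish_mask(self):
        spec = self._spec(fish=FishSprite(body_length=3.0, body_height=1.5), fish_start=(3.0, 4.0))
        with_fish = compose_clip(spec)
        without = compose_clip(self._spec())
        frame_w, frame_wo = with_fish.frames[0], without.frames[0]
        touched = frame_w != frame_wo
        # changed pixels are confined to the sprite bounding box
        ys, xcols = np.nonzero(touched)
        assert np.ptp(ys) + 1 <= 15 and np.ptp(xcols) + 1 <= 30

    def test_fish_exiting_frame_names_the_frame(self):
        spec = self._spec(
            fish=FishSprite(body_length=3.0, body_height=1.5),
            fish_speed=60.0,
            fish_start=(9.0, 4.0),
            n_frames=10,
        )
        with pytest.raises(ValueError, match="frame [0-9]"):
            compose_clip(spec)


class TestSimulateTrack:
    def test_degenerate_walk_is_stationary(self):
        spec = TrackSpec(preferred_distance=13.5, duration=10.0, attraction_strength=0.0,
                         step_sd=0.0, start=(11.0, 13.5), seed=1)
        track = simulate_track(spec)
        assert np.allclose(track.y_cm, 13.5)
        assert np.allclose(track.x_cm, 11.0)

    def test_same_seed_reproduces_track_exactly(self):
        spec = TrackSpec(preferred_distance=17.0, duration=30.0, seed=42)
        a, b = simulate_track(spec), simulate_track(spec)
        assert np.array_equal(a.x_px, b.x_px)
        assert np.array_equal(a.y_px, b.y_px)

    def test_positions_stay_inside_arena(self):
        spec = TrackSpec(preferred_distance=1.0, duration=60.0, step_sd=3.0, seed=7)
        track = simulate_track(spec)
        assert track.y_cm.min() >= 0.0 and track.y_cm.max() <= spec.arena_length
        assert track.x_cm.min() >= 0.0 and track.x_cm.max() <= spec.arena_width

    def test_long_run_mean_converges_to_preferred_distance(self):
        # Monte-Carlo oracle: OU stationary sd and autocorrelation give the
        # standard error of the time-mean over n steps.
        spec = TrackSpec(preferred_distance=13.5, duration=2e5 / 15.0, attraction_strength=0.5,
                         step_sd=0.8, seed=3)
        track = simulate_track(spec)
        n = track.y_cm.size
        rho = 1.0 - spec.attraction_strength / spec.frame_rate
        sd_stat = spec.step_sd / np.sqrt(1.0 - rho**2)
        se = sd_stat * np.sqrt((1.0 + rho) / (1.0 - rho) / n)
        assert abs(track.y_cm.mean() - 13.5) < 3.0 * se

    @given(seed=st.integers(0, 2**20))
    @settings(max_examples=20, deadline=None)
    def test_track_bounded_for_any_seed(self, seed):
        spec = TrackSpec(preferred_distance=30.0, duration=4.0, step_sd=5.0, seed=seed)
        track = simulate_track(spec)
        assert (track.y_cm >= 0).all() and (track.y_cm <= 35.0).all()
        assert (track.x_cm >= 0).all() and (track.x_cm <= 22.0).all()

    def test_preferred_distance_outside_arena_rejected(self):
        with pytest.raises(ValueError):
            TrackSpec(preferred_distance=40.0)
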