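"""Synthetic visual stimuli and behavioural tracks.

This module renders the inputs that the motion model and the trajectory
pipeline analyse: square-wave gratings of alternating dark/light bars, a
stylised striped fish sprite (an ellipse with dark transverse bars), composed
"virtual predator" video clips in which the background pans while the fish
translates, and mean-reverting random-walk tracks emulating a fish holding a
preferred distance from a grating wall in an open-field arena.

All geometry is expressed in centimetres and converted to pixels through an
explicit ``scale`` (px/cm).  The pixel grid is 0-based with x rightward and
y downward; a pixel ``i`` covers the half-open interval ``[i, i+1)/scale`` cm.
Sub-pixel bar edges are resolved by exact area-weighted averaging so that very
fine gratings blur toward their mean luminance instead of aliasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GratingSpec",
    "FishSprite",
    "ClipSpec",
    "TrackSpec",
    "Clip",
    "SubPixelBarWarning",
    "render_grating",
    "render_fish",
    "compose_clip",
    "simulate_track",
    "simulate_track_batch",
    "simulate_motion_observations",
]

#: Default rendering scale (px per cm) used throughout the package.
DEFAULT_SCALE = 10.0


class SubPixelBarWarning(UserWarning):
    """Raised when grating bars are narrower than half a pixel."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GratingSpec:
    """Square-wave grating: alternating dark and light bars of equal width.

    One full spatial period is ``2 * bar_width`` (one dark plus one light
    bar).  ``orientation`` is the orientation of the bars themselves:
    vertical bars vary along x, horizontal bars vary along y.  ``phase``
    shifts the pattern along the varying axis, in cm; increasing phase moves
    the pattern toward +x (vertical bars) or +y (horizontal bars).
    """

    bar_width: float
    orientation: str = "vertical"
    dark_level: float = 0.0
    light_level: float = 1.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.bar_width <= 0:
            raise ValueError(f"bar_width must be > 0, got {self.bar_width}")
        if self.orientation not in ("vertical", "horizontal"):
            raise ValueError(f"orientation must be 'vertical' or 'horizontal', got {self.orientation!r}")
        if not (self.dark_level < self.light_level):
            raise ValueError("dark_level must be strictly less than light_level")

    @property
    def period(self) -> float:
        """Spatial period in cm (one dark + one light bar)."""
        return 2.0 * self.bar_width


@dataclass(frozen=True)
class FishSprite:
    """Stylised striped fish: an ellipse with evenly spaced dark transverse bars.

    Defaults emulate a ~10 cm humbug-class reef fish with three dark
    ~0.5 cm stripes perpendicular to the body axis on a light body.
    """

    body_length: float = 10.0
    body_height: float = 5.0
    stripe_width: float = 0.5
    n_stripes: int = 3
    body_level: float = 0.95
    stripe_level: float = 0.0

    def __post_init__(self) -> None:
        if self.body_length <= 0 or self.body_height <= 0:
            raise ValueError("body dimensions must be positive")
        if self.n_stripes < 0:
            raise ValueError("n_stripes must be >= 0")
        if self.stripe_width < 0:
            raise ValueError("stripe_width must be >= 0")
        if self.n_stripes and self.stripe_width * self.n_stripes > self.body_length:
            raise ValueError(
                f"stripes ({self.n_stripes} x {self.stripe_width} cm) exceed body length "
                f"{self.body_length} cm"
            )


@dataclass(frozen=True)
class ClipSpec:
    """A composed predator-view clip: panning grating, optionally a moving fish.

    ``camera_speed`` translates the background pattern (cm/s, signed, +x);
    ``fish_speed`` is the fish's image-plane speed (cm/s, signed, +x).  The
    per-frame background shift in px is ``camera_speed * scale / frame_rate``.
    ``fish_start`` is the fish centre at frame 0 in cm; when ``None`` the fish
    starts centred vertically at one quarter of the frame width.
    """

    grating: GratingSpec
    fish: FishSprite | None = None
    frame_rate: float = 30.0
    n_frames: int = 30
    scale: float = DEFAULT_SCALE
    width_px: int = 720
    height_px: int = 660
    fish_speed: float = 0.0
    camera_speed: float = 0.0
    fish_start: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("frame dimensions must be positive")

    @property
    def background_shift_px(self) -> float:
        """Background translation per frame, in px."""
        return self.camera_speed * self.scale / self.frame_rate


@dataclass
class Clip:
    """Rendered frame sequence plus the metadata needed downstream.

    ``frames`` is an (n_frames, height, width) float array in [0, 1].
    ``fish_centers_px`` holds the (x, y) fish centroid per frame in px, or
    ``None`` for background-only clips.
    """

    frames: np.ndarray
    spec: ClipSpec
    fish_centers_px: np.ndarray | None = None

    @property
    def frame_rate(self) -> float:
        return self.spec.frame_rate

    @property
    def scale(self) -> float:
        return self.spec.scale

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class TrackSpec:
    """Mean-reverting random walk emulating open-field behaviour.

    The axis perpendicular to the grating (y, the grating sits at y = 0)
    follows ``y[t+1] = y[t] + a * (preferred_distance - y[t]) * dt + eps`` with
    ``eps ~ N(0, step_sd^2)``; the parallel axis (x) is an unbiased walk with
    the same step noise.  Positions reflect off the arena walls.  Defaults
    match a 5-min, 15 fps trial in a 22 x 35 cm arena.
    """

    preferred_distance: float = 17.5
    arena_length: float = 35.0
    arena_width: float = 22.0
    duration: float = 300.0
    frame_rate: float = 15.0
    attraction_strength: float = 0.5
    step_sd: float = 0.8
    start: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.preferred_distance <= self.arena_length):
            raise ValueError("preferred_distance must lie within [0, arena_length]")
        if self.arena_length <= 0 or self.arena_width <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be positive")
        if self.attraction_strength < 0 or self.step_sd < 0:
            raise ValueError("attraction_strength and step_sd must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _light_cumulative(x: np.ndarray, bar_width: float) -> np.ndarray:
    # Cumulative length of light bar in [0, x) for the canonical wave:
    # dark on [0, w), light on [w, 2w), repeating.
    p = 2.0 * bar_width
    n, r = np.divmod(x, p)
    return n * bar_width + np.clip(r - bar_width, 0.0, bar_width)


def _square_wave_profile(
    n_px: int, spec: GratingSpec, scale: float, mode: str, extra_phase: float = 0.0
) -> np.ndarray:
    """1-D intensity profile along the varying axis."""
    phase = spec.phase + extra_phase
    if mode == "area":
        edges = np.arange(n_px + 1, dtype=float) / scale - phase
        frac = np.diff(_light_cumulative(edges, spec.bar_width)) * scale
        # snap float jitter so aligned edges yield bit-exact two-level output
        frac = np.clip(np.round(frac, 12), 0.0, 1.0)
    elif mode == "nearest":
        centers = (np.arange(n_px, dtype=float) + 0.5) / scale - phase
        frac = (np.mod(centers, spec.period) >= spec.bar_width).astype(float)
    else:
        raise ValueError(f"unknown rendering mode {mode!r}")
    return spec.dark_level + (spec.light_level - spec.dark_level) * frac


def render_grating(
    spec: GratingSpec,
    width_px: int,
    height_px: int,
    scale: float = DEFAULT_SCALE,
    mode: str = "area",
    _extra_phase: float = 0.0,
) -> np.ndarray:
    """Render a square-wave grating to a (height_px, width_px) float image.

    Parameters
    ----------
    spec
        Grating definition (bar width in cm, orientation, levels, phase).
    width_px, height_px
        Output image size in px; must be positive.
    scale
        Rendering scale in px per cm.
    mode
        ``"area"`` (default) resolves sub-pixel bar edges by exact
        area-weighted averaging; ``"nearest"`` samples at pixel centres for
        bit-exact two-level output when edges fall on pixel boundaries.

    Warns with :class:`SubPixelBarWarning` when a bar maps to less than one
    pixel (``scale * bar_width < 1``).
    """
    if width_px <= 0 or height_px <= 0:
        raise ValueError(f"image dimensions must be positive, got {width_px} x {height_px}")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if scale * spec.bar_width < 1.0:
        warnings.warn(
            f"bars of {spec.bar_width} cm at {scale} px/cm are narrower than one pixel "
            f"({scale * spec.bar_width:.3g} px); the rendered grating approaches uniform grey",
            SubPixelBarWarning,
            stacklevel=2,
        )
    if spec.orientation == "vertical":
        profile = _square_wave_profile(width_px, spec, scale, mode, _extra_phase)
        return np.broadcast_to(profile[None, :], (height_px, width_px)).copy()
    profile = _square_wave_profile(height_px, spec, scale, mode, _extra_phase)
    return np.broadcast_to(profile[:, None], (height_px, width_px)).copy()


def render_fish(sprite: FishSprite, scale: float = DEFAULT_SCALE) -> tuple[np.ndarray, np.ndarray]:
    """Render the fish sprite; returns ``(intensity, opacity_mask)``.

    The body is an axis-aligned ellipse of ``body_length x body_height`` cm at
    ``body_level`` intensity; ``n_stripes`` vertical (transverse) bars of
    ``stripe_width`` cm at ``stripe_level`` are centred at even interior
    positions ``body_length * (k+1) / (n+1)``.  The opacity mask is 1 inside
    the ellipse outline and 0 outside.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    w = max(int(round(sprite.body_length * scale)), 1)
    h = max(int(round(sprite.body_height * scale)), 1)
    x = (np.arange(w) + 0.5) / scale  # cm, pixel centres
    y = (np.arange(h) + 0.5) / scale
    cx, cy = sprite.body_length / 2.0, sprite.body_height / 2.0
    a, b = sprite.body_length / 2.0, sprite.body_height / 2.0
    xx, yy = np.meshgrid(x, y)
    mask = (((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0).astype(float)

    image = np.full((h, w), sprite.body_level, dtype=float)
    stripe_px = int(round(sprite.stripe_width * scale))
    for k in range(sprite.n_stripes):
        center = sprite.body_length * (k + 1) / (sprite.n_stripes + 1)
        left = int(round(center * scale - stripe_px / 2.0))
        image[:, max(left, 0):max(left, 0) + stripe_px] = sprite.stripe_level
    image *= mask
    return image, mask


def compose_clip(spec: ClipSpec, mode: str = "area") -> Clip:
    """Compose a clip: panning grating background with an optional moving fish.

    Each frame is the grating translated by the cumulative camera shift with
    the fish sprite alpha-composited at its cumulative position.  Raises if
    the fish leaves the frame, naming the offending frame index.
    """
    frames = np.empty((spec.n_frames, spec.height_px, spec.width_px), dtype=float)
    fish_centers = None

    sprite_img = sprite_mask = None
    if spec.fish is not None:
        sprite_img, sprite_mask = render_fish(spec.fish, spec.scale)
        fish_centers = np.empty((spec.n_frames, 2), dtype=float)
        if spec.fish_start is None:
            x0 = spec.width_px / spec.scale / 4.0
            y0 = spec.height_px / spec.scale / 2.0
        else:
            x0, y0 = spec.fish_start

    for t in range(spec.n_frames):
        camera_shift = spec.camera_speed * t / spec.frame_rate  # cm
        bg = render_grating(
            spec.grating, spec.width_px, spec.height_px, spec.scale, mode=mode,
            _extra_phase=camera_shift,
        )
        if spec.fish is not None:
            fx = x0 + spec.fish_speed * t / spec.frame_rate
            fy = y0
            sh, sw = sprite_img.shape
            left = int(round(fx * spec.scale - sw / 2.0))
            top = int(round(fy * spec.scale - sh / 2.0))
            if left < 0 or top < 0 or left + sw > spec.width_px or top + sh > spec.height_px:
                raise ValueError(
                    f"fish exits the frame at frame {t}: sprite bbox "
                    f"({left},{top})-({left + sw},{top + sh}) vs frame "
                    f"{spec.width_px} x {spec.height_px}"
                )
            region = bg[top:top + sh, left:left + sw]
            bg[top:top + sh, left:left + sw] = (
                sprite_mask * sprite_img + (1.0 - sprite_mask) * region
            )
            fish_centers[t] = (left + sw / 2.0, top + sh / 2.0)
        frames[t] = bg

    return Clip(frames=frames, spec=spec, fish_centers_px=fish_centers)


# ---------------------------------------------------------------------------
# behavioural tracks
# ---------------------------------------------------------------------------


def _reflect(values: np.ndarray, upper: float) -> np.ndarray:
    """Reflect values into [0, upper] (triangle fold with period 2*upper)."""
    r = np.mod(values, 2.0 * upper)
    return np.where(r > upper, 2.0 * upper - r, r)


def simulate_track_batch(
    spec: TrackSpec,
    preferred_distances: np.ndarray,
    step_sds: np.ndarray | float | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate several tracks at once under a shared spec.

    ``preferred_distances`` (length m) gives each track its own attractor on
    the grating-perpendicular axis (e.g. per-fish preferences); ``step_sds``
    optionally varies the step noise per track.  Returns ``(x, y)`` arrays of
    shape (m, n_frames) in cm.  Used by the single-track front end and by the
    statistical calibration simulations.
    """
    pref = np.atleast_1d(np.asarray(preferred_distances, dtype=float))
    if np.any(pref < 0) or np.any(pref > spec.arena_length):
        raise ValueError("preferred distances must lie within [0, arena_length]")
    m = pref.size
    sds = np.broadcast_to(
        np.asarray(spec.step_sd if step_sds is None else step_sds, dtype=float), (m,)
    )
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_frames
    dt = 1.0 / spec.frame_rate
    a = spec.attraction_strength

    if spec.start is None:
        start_x, start_y = spec.arena_width / 2.0, spec.arena_length / 2.0
    else:
        start_x, start_y = spec.start

    x = np.empty((m, n))
    y = np.empty((m, n))
    x[:, 0] = start_x
    y[:, 0] = start_y
    # Draw all noise up front: (2, m, n-1) keeps the stream layout stable.
    noise = rng.standard_normal((2, m, n - 1))
    for t in range(1, n):
        y_step = a * (pref - y[:, t - 1]) * dt + sds * noise[0, :, t - 1]
        x_step = sds * noise[1, :, t - 1]
        y[:, t] = _reflect(y[:, t - 1] + y_step, spec.arena_length)
        x[:, t] = _reflect(x[:, t - 1] + x_step, spec.arena_width)
    return x, y


def simulate_track(spec: TrackSpec, cm_per_px: float = 0.02763):
    """Simulate one open-field track; returns a :class:`dazzle.behaviour.TrackedPath`.

    Positions are emitted in px (converted with ``cm_per_px``) at the spec's
    frame rate with confidence 1.0; identical spec + seed yields an identical
    track.
    """
    from .behaviour import TrackedPath  # local import avoids a cycle at import time

    x, y = simulate_track_batch(spec, np.array([spec.preferred_distance]))
    frames = np.arange(spec.n_frames)
    return TrackedPath(
        frames=frames,
        x_px=x[0] / cm_per_px,
        y_px=y[0] / cm_per_px,
        confidence=np.ones(spec.n_frames),
        frame_rate=spec.frame_rate,
        cm_per_px=cm_per_px,
    )


# ---------------------------------------------------------------------------
# synthetic motion observations (for statistical calibration)
# ---------------------------------------------------------------------------


def simulate_motion_observations(
    seed: int,
    n_bins: int = 8,
    n_fish: int = 3,
    n_trials: int = 3,
    grating_sizes: tuple[float, ...] = (0.25,),
    orientations: tuple[str, ...] = ("horizontal", "vertical"),
    baseline: float = 2.0,
    group_sd: float = 0.3,
    noise_sd: float = 0.25,
    effects: dict | None = None,
):
    """Simulate a tidy motion-strength table on the model's own scale.

    The response is generated on the square-root scale (where the motion model
    is linear and Gaussian): sqrt-strength = baseline + fish-in-trial effect +
    condition effect + noise, then squared.  ``effects`` maps
    ``(direction_bin, grating_size, orientation)`` to an additive shift on the
    sqrt scale; absent keys mean no effect (the null).  Mirrors the paper's
    design of individual fish observed across repeated trials per condition.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    bins = (np.arange(n_bins) * (360 // n_bins)).astype(int) if 360 % n_bins == 0 else np.arange(n_bins) * 5
    effects = effects or {}
    rows = []
    for trial in range(n_trials):
        for fish in range(n_fish):
            b_group = rng.normal(0.0, group_sd)
            for size in grating_sizes:
                for orient in orientations:
                    eps = rng.normal(0.0, noise_sd, size=n_bins)
                    for j, d in enumerate(bins):
                        shift = effects.get((int(d), size, orient), 0.0)
                        s = baseline + b_group + shift + eps[j]
                        rows.append(
                            (abs(s) ** 2, int(d), size, orient, f"f{fish}", f"t{trial}")
                        )
    return pd.DataFrame(
        rows,
        columns=["strength", "direction_bin", "grating_size", "orientation", "fish_id", "trial_id"],
    )
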