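"""Two-dimensional Reichardt-correlator motion detection (the "2DMD" core).

Two orthogonal arrays of elementary motion detectors (EMDs) are applied to
consecutive, acuity-filtered luminance frames.  Each EMD multiplies the
intensity at one sampling point in the previous frame with the intensity at a
point ``delta`` px away in the current frame and subtracts the mirror
product::

    H(x, y) = prev(x, y) * curr(x + d, y) - prev(x + d, y) * curr(x, y)
    V(x, y) = prev(x, y) * curr(x, y + d) - prev(x, y + d) * curr(x, y)

Positive H encodes rightward motion and positive V downward motion.  The
temporal filter is a pure one-frame delay (temporal filter = 1), so a clip at
the viewer's temporal resolution is compared frame against next frame.

The sampling base ``delta`` is matched to the viewer's spatial resolving
power: ``delta = round(pixels_per_degree / (2 * acuity))``, i.e. half the
period, in px, of the finest grating the viewer resolves.  Frames are
low-pass filtered with a Gaussian of sigma = delta / 2 before correlation so
that spatial frequencies beyond the viewer's acuity do not contribute motion
energy.

Direction convention (matching the downstream colour wheel): 0 deg = image-up,
90 deg = rightward (the normalised direction of prey travel), 180 deg = down,
270 deg = leftward; angles increase clockwise from image-up.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .stimuli import Clip

__all__ = ["ViewerModel", "MotionField", "to_luminance", "acuity_filter", "emd_pair", "process_clip"]

#: Rec. 709 luma weights for RGB -> luminance reduction.
_REC709 = np.array([0.2126, 0.7152, 0.0722])


@dataclass(frozen=True)
class ViewerModel:
    """The virtual predator's eye.

    Parameters
    ----------
    acuity
        Peak spatial resolving power in cycles/deg.
    pixels_per_degree
        Image sampling density in px/deg; must be at least ``2 * acuity`` so
        the acuity limit is representable on the pixel grid.
    viewing_distance
        Distance from eye to scene in cm (bookkeeping; it enters only through
        ``pixels_per_degree`` when built via :meth:`from_geometry`).
    temporal_resolution
        Flicker-fusion limit in Hz; clips faster than this trigger a warning.
    """

    acuity: float
    pixels_per_degree: float
    viewing_distance: float = 30.0
    temporal_resolution: float = 30.0

    def __post_init__(self) -> None:
        if self.acuity <= 0:
            raise ValueError("acuity must be > 0")
        if self.pixels_per_degree < 2.0 * self.acuity:
            raise ValueError(
                f"pixels_per_degree ({self.pixels_per_degree:.3g}) must be >= 2 * acuity "
                f"({2 * self.acuity:.3g}) for the acuity limit to be representable"
            )

    @classmethod
    def from_geometry(
        cls,
        acuity: float,
        scale: float,
        viewing_distance: float = 30.0,
        temporal_resolution: float = 30.0,
    ) -> "ViewerModel":
        """Build a viewer from rendering scale (px/cm) and viewing distance (cm).

        Uses the small-angle relation ``pixels_per_degree = scale *
        viewing_distance * pi / 180``.
        """
        ppd = scale * viewing_distance * math.pi / 180.0
        return cls(
            acuity=acuity,
            pixels_per_degree=ppd,
            viewing_distance=viewing_distance,
            temporal_resolution=temporal_resolution,
        )

    @property
    def delta(self) -> int:
        """EMD sampling base in px: half the just-resolvable period, >= 1."""
        return max(1, int(round(self.pixels_per_degree / (2.0 * self.acuity))))

    @property
    def sigma(self) -> float:
        """Gaussian pre-filter sigma in px (delta / 2)."""
        return self.delta / 2.0


@dataclass
class MotionField:
    """Per-pixel EMD responses for one frame pair.

    ``h`` and ``v`` are signed horizontal/vertical responses; ``valid`` marks
    pixels whose ``delta``-offset partner lies inside the frame (pixels within
    ``delta`` of the right or bottom border are invalid and must be excluded
    from all summaries).
    """

    h: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    delta: int = 1

    def __post_init__(self) -> None:
        if not (self.h.shape == self.v.shape == self.valid.shape):
            raise ValueError("h, v and valid must share a shape")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.h, self.v)

    @property
    def direction(self) -> np.ndarray:
        """Direction in degrees: 0 = up, 90 = right, 180 = down, 270 = left."""
        return np.degrees(np.arctan2(self.h, -self.v)) % 360.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.h.shape


def to_luminance(frame: np.ndarray) -> np.ndarray:
    """Reduce a frame to achromatic intensity in [0, 1].

    Three-channel input is reduced with the Rec. 709 luma weights.  Integer
    input is rescaled by its bit-depth maximum (global scaling, not per-frame
    min/max); float input is assumed to already lie in [0, 1].
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    if np.issubdtype(frame.dtype, np.integer):
        scale = float(np.iinfo(frame.dtype).max)
    else:
        scale = 1.0
    if frame.ndim == 3:
        if frame.shape[2] < 3:
            raise ValueError(f"expected 1 or 3 channels, got shape {frame.shape}")
        frame = frame[..., :3] @ _REC709
    elif frame.ndim != 2:
        raise ValueError(f"expected a 2-D or 3-D frame, got ndim={frame.ndim}")
    return frame.astype(float) / scale


def acuity_filter(image: np.ndarray, viewer: ViewerModel) -> np.ndarray:
    """Acuity-matched Gaussian low-pass (sigma = viewer.delta / 2 px).

    Attenuates spatial frequencies beyond the viewer's resolving power so
    that, at matched geometry, gratings finer than the acuity limit lose
    nearly all of their Michelson contrast before reaching the correlator.
    """
    return gaussian_filter(np.asarray(image, dtype=float), viewer.sigma, mode="nearest")


def emd_pair(prev: np.ndarray, curr: np.ndarray, delta: int = 1) -> MotionField:
    """Correlate one frame pair with orthogonal EMD arrays of sampling base ``delta``.

    Inputs must be luminance-converted (and normally acuity-filtered) images
    of identical shape.  Returns a dense :class:`MotionField`; border pixels
    lacking a ``delta``-offset partner are flagged invalid rather than zeroed.
    """
    prev = np.asarray(prev, dtype=float)
    curr = np.asarray(curr, dtype=float)
    if prev.shape != curr.shape:
        raise ValueError(f"frame shapes differ: {prev.shape} vs {curr.shape}")
    if delta < 1:
        raise ValueError("delta must be >= 1")
    ny, nx = prev.shape
    if nx <= delta or ny <= delta:
        raise ValueError(f"frames of shape {prev.shape} too small for delta={delta}")

    h = np.zeros_like(prev)
    v = np.zeros_like(prev)
    h[:, :-delta] = prev[:, :-delta] * curr[:, delta:] - prev[:, delta:] * curr[:, :-delta]
    v[:-delta, :] = prev[:-delta, :] * curr[delta:, :] - prev[delta:, :] * curr[:-delta, :]
    valid = np.zeros(prev.shape, dtype=bool)
    valid[:-delta, :-delta] = True
    return MotionField(h=h, v=v, valid=valid, delta=delta)


def process_clip(clip, viewer: ViewerModel) -> list[MotionField]:
    """Run the full 2DMD pipeline over a clip.

    Converts each frame to luminance, applies the acuity filter, and
    correlates each consecutive frame pair with the viewer's sampling base
    (one-frame temporal delay).  Accepts a :class:`~dazzle.stimuli.Clip` or a
    plain frame sequence; yields ``n_frames - 1`` motion fields.
    """
    if isinstance(clip, Clip):
        frames = clip.frames
        if clip.frame_rate > viewer.temporal_resolution:
            warnings.warn(
                f"clip frame rate {clip.frame_rate} Hz exceeds the viewer's temporal "
                f"resolution {viewer.temporal_resolution} Hz; the one-frame delay then "
                "under-represents the viewer's integration time",
                UserWarning,
                stacklevel=2,
            )
    else:
        frames = np.asarray(clip)
    if len(frames) < 2:
        raise ValueError("a clip needs at least 2 frames")

    filtered = [acuity_filter(to_luminance(f), viewer) for f in frames]
    return [
        emd_pair(filtered[i], filtered[i + 1], viewer.delta)
        for i in range(len(filtered) - 1)
    ]
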