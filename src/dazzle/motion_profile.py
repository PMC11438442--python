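"""Directional summaries of motion fields.

Turns per-pixel EMD responses into the pipeline's summary statistics: a
region-of-interest crop, normalisation of travel direction (so every analysis
reads as left-to-right prey travel), the 72-bin directional profile (mean
motion strength in 5-degree-wide direction bins), background subtraction with
a zero floor, total motion, and a colour direction map for inspection.

Bin ``k`` covers the half-open interval ``[5k - 2.5, 5k + 2.5)`` degrees
(mod 360), i.e. bins are centred on the round angles 0, 5, ..., 355.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .emd import MotionField

__all__ = [
    "DirectionalProfile",
    "BIN_CENTERS",
    "extract_roi",
    "normalise_direction",
    "directional_profile",
    "subtract_background",
    "total_motion",
    "direction_map",
]

N_BINS = 72
BIN_WIDTH = 360.0 / N_BINS
#: Bin centres in degrees: 0, 5, ..., 355.
BIN_CENTERS = np.arange(N_BINS) * BIN_WIDTH


@dataclass
class DirectionalProfile:
    """Mean motion strength per 5-degree direction bin.

    ``strengths[k]`` is the mean magnitude over all contributing pixel-frames
    whose direction falls in bin ``k``; ``n_pixels[k]`` counts those
    contributions (0 for an empty bin, whose strength is 0).  ``subject``
    records what the profile describes: ``"fish"``, ``"background"`` or
    ``"fish_minus_background"``.
    """

    strengths: np.ndarray
    n_pixels: np.ndarray
    subject: str = "fish"
    roi: tuple[int, int, int] | None = None  # (origin_x, origin_y, size)
    bin_centers: np.ndarray = field(default_factory=lambda: BIN_CENTERS.copy())

    def __post_init__(self) -> None:
        self.strengths = np.asarray(self.strengths, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels, dtype=int)
        if self.strengths.shape != (N_BINS,) or self.n_pixels.shape != (N_BINS,):
            raise ValueError(f"profiles have {N_BINS} bins")
        if np.any(self.strengths < 0):
            raise ValueError("strengths must be non-negative")

    def sector_fraction(self, center_deg: float, half_width_deg: float) -> float:
        """Fraction of total motion energy (strength x count) within
        ``center_deg +/- half_width_deg``."""
        energy = self.strengths * self.n_pixels
        total = energy.sum()
        if total == 0:
            return 0.0
        offset = (self.bin_centers - center_deg + 180.0) % 360.0 - 180.0
        return float(energy[np.abs(offset) <= half_width_deg].sum() / total)


def _as_fields(fields) -> list[MotionField]:
    if isinstance(fields, MotionField):
        return [fields]
    return list(fields)


def extract_roi(
    fields: Sequence[MotionField] | MotionField,
    origin: tuple[int, int],
    size: int,
    frame_range: tuple[int, int] | None = None,
) -> list[MotionField]:
    """Crop motion fields to a ``size x size`` window at ``origin`` (x, y).

    ``frame_range`` optionally trims to the sub-sequence ``[start, stop)`` of
    fields (e.g. the frames during which the prey is inside the window).
    Raises when the window exceeds the field extent, naming the overflow axis.
    """
    fields = _as_fields(fields)
    if frame_range is not None:
        fields = fields[frame_range[0]:frame_range[1]]
    if not fields:
        raise ValueError("no fields left after frame trimming")
    x0, y0 = origin
    if size <= 0:
        raise ValueError("ROI size must be positive")
    out = []
    for f in fields:
        ny, nx = f.shape
        if x0 < 0 or x0 + size > nx:
            raise ValueError(f"ROI x-range [{x0}, {x0 + size}) exceeds field width {nx}")
        if y0 < 0 or y0 + size > ny:
            raise ValueError(f"ROI y-range [{y0}, {y0 + size}) exceeds field height {ny}")
        out.append(
            MotionField(
                h=f.h[y0:y0 + size, x0:x0 + size],
                v=f.v[y0:y0 + size, x0:x0 + size],
                valid=f.valid[y0:y0 + size, x0:x0 + size],
                delta=f.delta,
            )
        )
    return out


def normalise_direction(
    fields: Sequence[MotionField] | MotionField, travel_direction: str
) -> list[MotionField]:
    """Mirror fields so the prey always reads as travelling left-to-right.

    For leftward travel each field is flipped horizontally and its horizontal
    response negated (a true mirror); applying the operation twice is the
    identity.  Rightward clips pass through unchanged.
    """
    fields = _as_fields(fields)
    if travel_direction == "right":
        return fields
    if travel_direction != "left":
        raise ValueError(f"travel_direction must be 'left' or 'right', got {travel_direction!r}")
    return [
        MotionField(
            h=-np.flip(f.h, axis=1),
            v=np.flip(f.v, axis=1),
            valid=np.flip(f.valid, axis=1),
            delta=f.delta,
        )
        for f in fields
    ]


def directional_profile(
    fields: Sequence[MotionField] | MotionField,
    subject: str = "fish",
    include_zero: bool = False,
) -> DirectionalProfile:
    """Accumulate valid pixel-frames into the 72-bin directional profile.

    Every valid pixel with magnitude > 0 contributes its magnitude to the
    5-degree bin containing its direction; ``strengths`` is the mean per bin.
    Zero-magnitude pixels have no direction and are excluded by default
    (``include_zero=True`` assigns them to the bin of their computed 0-degree
    direction instead).  Raises when no valid pixels exist at all.
    """
    fields = _as_fields(fields)
    sums = np.zeros(N_BINS)
    counts = np.zeros(N_BINS, dtype=int)
    any_valid = False
    for f in fields:
        mask = f.valid
        if not mask.any():
            continue
        any_valid = True
        mag = f.magnitude[mask]
        direction = f.direction[mask]
        if not include_zero:
            nz = mag > 0
            mag, direction = mag[nz], direction[nz]
        idx = (np.floor((direction + BIN_WIDTH / 2.0) / BIN_WIDTH).astype(int)) % N_BINS
        sums += np.bincount(idx, weights=mag, minlength=N_BINS)
        counts += np.bincount(idx, minlength=N_BINS)
    if not any_valid:
        raise ValueError("all pixels invalid: nothing to profile")
    strengths = np.divide(sums, counts, out=np.zeros(N_BINS), where=counts > 0)
    return DirectionalProfile(strengths=strengths, n_pixels=counts, subject=subject)


def subtract_background(
    fish: DirectionalProfile, background: DirectionalProfile
) -> DirectionalProfile:
    """Bin-wise ``max(fish - background, 0)``.

    Where background motion exceeds the prey's motion the cue is treated as
    zero (the floor rule); bin counts are carried over from the fish profile.
    """
    if not np.allclose(fish.bin_centers, background.bin_centers):
        raise ValueError("profiles have mismatching bin structures")
    strengths = np.maximum(fish.strengths - background.strengths, 0.0)
    return DirectionalProfile(
        strengths=strengths,
        n_pixels=fish.n_pixels.copy(),
        subject="fish_minus_background",
        roi=fish.roi,
    )


def total_motion(profile: DirectionalProfile, weighting: str = "pixel") -> float:
    """Total mean strength of motion.

    ``weighting="pixel"`` (default) is the pixel-weighted mean magnitude over
    all contributing pixel-frames, ``sum(strengths * n_pixels) / sum(n_pixels)``;
    ``weighting="bin"`` averages the 72 bin strengths directly.  Returns 0 for
    an all-empty profile.
    """
    if weighting == "pixel":
        n = profile.n_pixels.sum()
        if n == 0:
            return 0.0
        return float((profile.strengths * profile.n_pixels).sum() / n)
    if weighting == "bin":
        return float(profile.strengths.mean())
    raise ValueError(f"weighting must be 'pixel' or 'bin', got {weighting!r}")


# Colour-wheel anchors: direction (deg) -> hue (deg).  90 = travel direction
# (blue), 270 = opposite (red), 0 = up (yellow), 180 = down (dark pink).
_ANCHOR_DIRS = np.array([0.0, 90.0, 180.0, 270.0, 360.0])
_ANCHOR_HUES = np.array([60.0, 240.0, 320.0, 360.0, 420.0])


def direction_map(field: MotionField, vmax: float | None = None) -> np.ndarray:
    """Render a motion field as an RGB image.

    Hue encodes direction (blue = travel direction 90 deg, red = opposite
    270 deg, yellow = up, dark pink = down); value scales with magnitude
    relative to ``vmax`` (the field maximum by default); black marks invalid
    or zero-magnitude pixels.
    """
    mag = field.magnitude
    if vmax is None:
        vmax = float(mag[field.valid].max()) if field.valid.any() else 0.0
    hue = np.interp(field.direction, _ANCHOR_DIRS, _ANCHOR_HUES) % 360.0
    value = np.zeros_like(mag) if vmax == 0 else np.clip(mag / vmax, 0.0, 1.0)
    value[~field.valid] = 0.0
    value[mag == 0] = 0.0
    hsv = np.stack([hue / 360.0, np.ones_like(hue), value], axis=-1)
    return hsv_to_rgb(hsv)
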