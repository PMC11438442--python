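"""Behavioural-trajectory pipeline.

Ingests tracked head coordinates (e.g. markerless-tracking output as
``frame,x_px,y_px,confidence`` CSV), filters by confidence, converts pixels
to centimetres, bins the track into 15-s (225-frame at 15 fps) windows, and
computes the two open-field summaries analysed downstream: perpendicular
distance from the grating wall and summed path length per window.

Points below the confidence cutoff are flagged and linearly interpolated
from flanking valid points rather than dropped, which preserves the fixed
225-frame bin structure.  The arena's grating sits at y = 0 with the
perpendicular axis spanning [0, 35] cm by default; distances are reported as
magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrackedPath",
    "load_track",
    "distance_to_grating",
    "distance_moved",
    "normalise_distance",
    "summarise_track",
    "summarise_tracks",
]

#: Default pixel-to-centimetre conversion (cm per px).
DEFAULT_CM_PER_PX = 0.02763
#: Frames per summary bin (15 s at 15 fps).
DEFAULT_BIN_FRAMES = 225
#: Arena extent along the grating-perpendicular axis, cm.
DEFAULT_ARENA_LENGTH = 35.0

REQUIRED_COLUMNS = ("frame", "x_px", "y_px", "confidence")


@dataclass
class TrackedPath:
    """Time-stamped head coordinates with per-point confidence.

    ``x_px``/``y_px`` are raw positions; ``valid`` marks points at or above
    the confidence cutoff.  ``x_cm``/``y_cm`` expose centimetre coordinates
    with sub-cutoff points linearly interpolated (never silently dropped).
    """

    frames: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    confidence: np.ndarray
    frame_rate: float = 15.0
    cm_per_px: float = DEFAULT_CM_PER_PX
    p_cutoff: float = 0.0
    fish_id: str | None = None
    round_id: str | None = None
    grating_size: float | None = None
    orientation: str | None = None

    def __post_init__(self) -> None:
        for name in ("frames", "x_px", "y_px", "confidence"):
            setattr(self, name, np.asarray(getattr(self, name)))
        n = self.frames.size
        if not (self.x_px.size == self.y_px.size == self.confidence.size == n):
            raise ValueError("frames, x_px, y_px and confidence must have equal length")
        if n == 0:
            raise ValueError("empty track")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if self.cm_per_px <= 0 or self.frame_rate <= 0:
            raise ValueError("cm_per_px and frame_rate must be positive")
        if not self.valid.any():
            raise ValueError("no points at or above the confidence cutoff")

    @property
    def valid(self) -> np.ndarray:
        return self.confidence >= self.p_cutoff

    @property
    def px_per_cm(self) -> float:
        return 1.0 / self.cm_per_px

    @property
    def duration(self) -> float:
        """Track duration in seconds (one position per video frame)."""
        return self.frames.size / self.frame_rate

    def _interpolated(self, values: np.ndarray) -> np.ndarray:
        if self.valid.all():
            return values.astype(float)
        idx = np.arange(values.size)
        return np.interp(idx, idx[self.valid], values[self.valid].astype(float))

    @property
    def x_cm(self) -> np.ndarray:
        return self._interpolated(self.x_px) * self.cm_per_px

    @property
    def y_cm(self) -> np.ndarray:
        return self._interpolated(self.y_px) * self.cm_per_px


def load_track(
    source,
    p_cutoff: float = 0.9,
    frame_rate: float = 15.0,
    cm_per_px: float = DEFAULT_CM_PER_PX,
    **labels,
) -> TrackedPath:
    """Load a tracked path from a CSV file (or DataFrame) and apply the cutoff.

    The table must carry columns ``frame, x_px, y_px, confidence``; optional
    ``fish_id, round_id, grating_size_cm, orientation`` columns (or keyword
    labels) annotate the track for batch analyses.  Points with confidence
    below ``p_cutoff`` are flagged invalid and interpolated in the cm-domain
    accessors.
    """
    if isinstance(source, (str, Path)):
        table = pd.read_csv(source)
    else:
        table = pd.DataFrame(source)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"track table is missing required columns: {missing}")

    meta = {}
    for col, attr in (("fish_id", "fish_id"), ("round", "round_id"), ("round_id", "round_id"),
                      ("grating_size_cm", "grating_size"), ("orientation", "orientation")):
        if col in table.columns:
            vals = table[col].unique()
            if len(vals) > 1:
                raise ValueError(f"column {col!r} is not constant within one track")
            meta[attr] = vals[0]
    meta.update(labels)

    return TrackedPath(
        frames=table["frame"].to_numpy(),
        x_px=table["x_px"].to_numpy(dtype=float),
        y_px=table["y_px"].to_numpy(dtype=float),
        confidence=table["confidence"].to_numpy(dtype=float),
        frame_rate=frame_rate,
        cm_per_px=cm_per_px,
        p_cutoff=p_cutoff,
        **meta,
    )


def _n_bins(path: TrackedPath, bin_frames: int) -> int:
    n = path.frames.size // bin_frames
    if n == 0:
        raise ValueError(
            f"track of {path.frames.size} points is shorter than one bin ({bin_frames} frames)"
        )
    return n


def distance_to_grating(
    path: TrackedPath,
    grating_y: float = 0.0,
    bin_frames: int = DEFAULT_BIN_FRAMES,
    stat: str = "last",
) -> np.ndarray:
    """Perpendicular distance (cm) from the grating, one sample per bin.

    ``stat="last"`` (default) samples the position at each bin's closing
    frame; ``stat="mean"`` averages the distance over the bin.  A standard
    5-min, 15 fps trial yields 20 samples.
    """
    nb = _n_bins(path, bin_frames)
    d = np.abs(path.y_cm - grating_y)
    if stat == "last":
        return d[bin_frames - 1::bin_frames][:nb].copy()
    if stat == "mean":
        return d[: nb * bin_frames].reshape(nb, bin_frames).mean(axis=1)
    raise ValueError(f"stat must be 'last' or 'mean', got {stat!r}")


def distance_moved(path: TrackedPath, bin_frames: int = DEFAULT_BIN_FRAMES) -> np.ndarray:
    """Summed Euclidean path length (cm) within each bin.

    The step between frames ``i`` and ``i+1`` is assigned to bin
    ``i // bin_frames``; the final bin therefore sums one step fewer than the
    others (there is no step out of the last frame).
    """
    nb = _n_bins(path, bin_frames)
    steps = np.hypot(np.diff(path.x_cm), np.diff(path.y_cm))
    bins = np.arange(steps.size) // bin_frames
    keep = bins < nb
    return np.bincount(bins[keep], weights=steps[keep], minlength=nb)


def normalise_distance(
    d, arena_length: float = DEFAULT_ARENA_LENGTH, n_obs: int | None = None
):
    """Map distances in [0, arena_length] to the open interval (0, 1).

    Divides by ``arena_length`` and applies the boundary squeeze
    ``(y * (n - 1) + 0.5) / n`` with ``n`` the number of observations in the
    dataset (``n_obs``; defaults to the input length), so exact 0 and 1 never
    reach a beta likelihood.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(d > arena_length):
        bad = d[(d < 0) | (d > arena_length)]
        raise ValueError(f"distances outside [0, {arena_length}]: {bad[:5]}")
    n = int(n_obs) if n_obs is not None else d.size
    if n < 2:
        raise ValueError("boundary squeeze needs at least 2 observations")
    y = d / arena_length
    return (y * (n - 1) + 0.5) / n


def summarise_track(
    path: TrackedPath,
    grating_y: float = 0.0,
    bin_frames: int = DEFAULT_BIN_FRAMES,
    arena_length: float = DEFAULT_ARENA_LENGTH,
    stat: str = "last",
    n_obs: int | None = None,
) -> pd.DataFrame:
    """Per-bin tidy summary of one track.

    Columns: ``fish_id, round_id, grating_size_cm, orientation, bin_index,
    distance_cm, moved_cm, normalised_distance``.
    """
    dist = distance_to_grating(path, grating_y, bin_frames, stat=stat)
    moved = distance_moved(path, bin_frames)
    return pd.DataFrame(
        {
            "fish_id": path.fish_id,
            "round_id": path.round_id,
            "grating_size_cm": path.grating_size,
            "orientation": path.orientation,
            "bin_index": np.arange(dist.size),
            "distance_cm": dist,
            "moved_cm": moved,
            "normalised_distance": normalise_distance(
                np.clip(dist, 0.0, arena_length), arena_length,
                n_obs=n_obs if n_obs is not None else dist.size,
            ),
        }
    )


def summarise_tracks(paths, **kwargs) -> pd.DataFrame:
    """Summarise a collection of tracks into one tidy table.

    The boundary squeeze for ``normalised_distance`` uses the total number of
    observations across all tracks, as required for a shared beta likelihood.
    """
    paths = list(paths)
    bin_frames = kwargs.get("bin_frames", DEFAULT_BIN_FRAMES)
    total_obs = sum(p.frames.size // bin_frames for p in paths)
    frames = [summarise_track(p, n_obs=total_obs, **kwargs) for p in paths]
    return pd.concat(frames, ignore_index=True)
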