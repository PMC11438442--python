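"""Readers and writers for the pipeline's on-disk formats.

* Clips: directories of 16-bit grayscale PNGs named ``frame_%06d.png`` with a
  ``metadata.json`` sidecar recording frame rate, scale and the generating
  specs.
* Tracks: CSV with header ``frame,x_px,y_px,confidence`` (plus optional label
  columns).
* Directional profiles: CSV with ``bin_center_deg,strength,n_pixels`` columns
  and ``#``-prefixed metadata header lines.
* Motion fields: NPZ stacks of the H, V and valid planes plus parameters.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .behaviour import TrackedPath
from .emd import MotionField
from .motion_profile import N_BINS, DirectionalProfile
from .stimuli import Clip, ClipSpec, FishSprite, GratingSpec

__all__ = [
    "write_clip",
    "read_clip",
    "write_track",
    "read_track",
    "write_profile",
    "read_profile",
    "write_fields",
    "read_fields",
]

_FRAME_NAME = "frame_{:06d}.png"


def _spec_to_dict(spec) -> dict:
    d = dataclasses.asdict(spec)
    return {k: v for k, v in d.items() if not isinstance(v, dict) or v}


def write_clip(clip: Clip, directory) -> Path:
    """Write a clip as 16-bit grayscale PNG frames plus a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(clip.frames):
        data = np.clip(frame, 0.0, 1.0)
        iio.imwrite(directory / _FRAME_NAME.format(i), np.round(data * 65535).astype(np.uint16))
    spec = clip.spec
    meta = {
        "frame_rate": spec.frame_rate,
        "scale": spec.scale,
        "n_frames": int(len(clip)),
        "grating": _spec_to_dict(spec.grating),
        "fish": _spec_to_dict(spec.fish) if spec.fish is not None else None,
        "clip": {
            k: getattr(spec, k)
            for k in ("width_px", "height_px", "fish_speed", "camera_speed", "fish_start")
        },
        "fish_centers_px": None
        if clip.fish_centers_px is None
        else clip.fish_centers_px.tolist(),
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return directory


def read_clip(directory) -> Clip:
    """Read a PNG frame directory written by :func:`write_clip`."""
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    frames = []
    for i in range(meta["n_frames"]):
        img = iio.imread(directory / _FRAME_NAME.format(i))
        frames.append(img.astype(float) / np.iinfo(img.dtype).max)
    grating = GratingSpec(**meta["grating"])
    fish = FishSprite(**meta["fish"]) if meta["fish"] is not None else None
    clip_kwargs = dict(meta["clip"])
    if clip_kwargs.get("fish_start") is not None:
        clip_kwargs["fish_start"] = tuple(clip_kwargs["fish_start"])
    spec = ClipSpec(
        grating=grating,
        fish=fish,
        frame_rate=meta["frame_rate"],
        n_frames=meta["n_frames"],
        scale=meta["scale"],
        **clip_kwargs,
    )
    centers = meta.get("fish_centers_px")
    return Clip(
        frames=np.stack(frames),
        spec=spec,
        fish_centers_px=None if centers is None else np.asarray(centers, dtype=float),
    )


def write_track(path: TrackedPath, filename) -> Path:
    """Write a track as ``frame,x_px,y_px,confidence`` CSV (plus label columns)."""
    filename = Path(filename)
    filename.parent.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(
        {
            "frame": path.frames,
            "x_px": path.x_px,
            "y_px": path.y_px,
            "confidence": path.confidence,
        }
    )
    for col, value in (
        ("fish_id", path.fish_id),
        ("round_id", path.round_id),
        ("grating_size_cm", path.grating_size),
        ("orientation", path.orientation),
    ):
        if value is not None:
            table[col] = value
    table.to_csv(filename, index=False)
    return filename


def read_track(filename, **kwargs) -> TrackedPath:
    """Read a track CSV (thin alias of :func:`dazzle.behaviour.load_track`)."""
    from .behaviour import load_track

    return load_track(filename, **kwargs)


def write_profile(profile: DirectionalProfile, filename, **metadata) -> Path:
    """Write a directional profile as CSV with ``#`` metadata header lines."""
    filename = Path(filename)
    filename.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# subject: {profile.subject}"]
    if profile.roi is not None:
        lines.append(f"# roi: {profile.roi[0]},{profile.roi[1]},{profile.roi[2]}")
    for key, value in sorted(metadata.items()):
        lines.append(f"# {key}: {value}")
    body = pd.DataFrame(
        {
            "bin_center_deg": profile.bin_centers,
            "strength": profile.strengths,
            "n_pixels": profile.n_pixels,
        }
    ).to_csv(index=False)
    filename.write_text("\n".join(lines) + "\n" + body)
    return filename


def read_profile(filename) -> DirectionalProfile:
    """Read a profile CSV written by :func:`write_profile`."""
    filename = Path(filename)
    subject = "fish"
    roi = None
    with open(filename) as fh:
        offset = 0
        for line in fh:
            if not line.startswith("#"):
                break
            offset += 1
            key, _, value = line[1:].partition(":")
            key, value = key.strip(), value.strip()
            if key == "subject":
                subject = value
            elif key == "roi":
                roi = tuple(int(v) for v in value.split(","))
    table = pd.read_csv(filename, skiprows=offset)
    if len(table) != N_BINS:
        raise ValueError(f"expected {N_BINS} bins in {filename}, found {len(table)}")
    return DirectionalProfile(
        strengths=table["strength"].to_numpy(),
        n_pixels=table["n_pixels"].to_numpy(),
        subject=subject,
        roi=roi,
    )


def write_fields(fields, filename, **metadata) -> Path:
    """Persist a motion-field sequence as an NPZ stack of H/V/valid planes."""
    filename = Path(filename)
    filename.parent.mkdir(parents=True, exist_ok=True)
    fields = list(fields)
    np.savez_compressed(
        filename,
        h=np.stack([f.h for f in fields]),
        v=np.stack([f.v for f in fields]),
        valid=np.stack([f.valid for f in fields]),
        delta=np.array([fields[0].delta]),
        metadata=json.dumps(metadata),
    )
    return filename


def read_fields(filename) -> list[MotionField]:
    """Load a motion-field sequence written by :func:`write_fields`."""
    with np.load(filename, allow_pickle=False) as data:
        delta = int(data["delta"][0])
        return [
            MotionField(h=h, v=v, valid=m, delta=delta)
            for h, v, m in zip(data["h"], data["v"], data["valid"])
        ]
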