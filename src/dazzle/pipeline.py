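"""End-to-end reproducible pipeline and deterministic fixtures.

``run_pipeline`` executes both analysis arms from one config and seed:

* motion arm — synthesise fish and background-only clips per grating
  condition, run the correlator, extract ROI profiles, subtract background
  motion, and fit the motion mixed model;
* behaviour arm — simulate open-field tracks per condition, summarise them
  into per-bin distances, and fit the distance and movement models.

Every intermediate artifact is written under a run directory together with a
JSON manifest of content hashes and a log of parameters and seeds, so a
persisted config re-run with the same seed reproduces the manifest exactly.

``make_fixtures`` builds the small deterministic clips and tracks used by the
test suite to cover documented edge cases.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .calibration import simulate_behaviour_dataset
from .config import PipelineConfig
from .emd import ViewerModel, process_clip
from .motion_profile import (
    directional_profile,
    extract_roi,
    normalise_direction,
    subtract_background,
    total_motion,
)
from .stats import fit_distance_model, fit_motion_model, fit_movement_model
from .stimuli import Clip, ClipSpec, FishSprite, GratingSpec, TrackSpec, simulate_track

__all__ = ["run_pipeline", "make_fixtures", "analyse_condition_clip"]


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def make_condition_clips(
    config: PipelineConfig,
    grating_size: float,
    orientation: str,
    phase: float = 0.0,
    fish_start_x: float | None = None,
) -> tuple[Clip, Clip]:
    """Compose the fish clip and its background-only twin for one condition."""
    grating = GratingSpec(bar_width=grating_size, orientation=orientation, phase=phase)
    fish = FishSprite()
    height_cm = config.clip_height_px / config.scale
    start_x = fish_start_x if fish_start_x is not None else config.clip_width_px / config.scale / 4.0
    common = dict(
        frame_rate=config.clip_frame_rate,
        n_frames=config.clip_n_frames,
        scale=config.scale,
        width_px=config.clip_width_px,
        height_px=config.clip_height_px,
        camera_speed=config.camera_speed,
    )
    fish_spec = ClipSpec(
        grating=grating,
        fish=fish,
        fish_speed=config.fish_speed,
        fish_start=(start_x, height_cm / 2.0),
        **common,
    )
    bg_spec = ClipSpec(grating=grating, fish=None, **common)
    from .stimuli import compose_clip

    return compose_clip(fish_spec), compose_clip(bg_spec)


def analyse_condition_clip(
    fish_clip: Clip,
    background_clip: Clip,
    viewer: ViewerModel,
    roi_size: int,
    travel_direction: str = "right",
):
    """Run the motion arm for one clip pair.

    Returns ``(fish_profile, background_profile, subtracted_profile)`` over a
    centred ``roi_size`` ROI; fields are mirrored first when the prey travels
    leftward so that 90 degrees always reads as the direction of travel.
    """
    fields_fish = normalise_direction(process_clip(fish_clip, viewer), travel_direction)
    fields_bg = normalise_direction(process_clip(background_clip, viewer), travel_direction)
    ny, nx = fields_fish[0].shape
    if roi_size > min(nx, ny):
        raise ValueError(f"ROI size {roi_size} exceeds clip extent {nx} x {ny}")
    origin = ((nx - roi_size) // 2, (ny - roi_size) // 2)
    roi_fish = extract_roi(fields_fish, origin, roi_size)
    roi_bg = extract_roi(fields_bg, origin, roi_size)
    prof_fish = directional_profile(roi_fish, subject="fish")
    prof_bg = directional_profile(roi_bg, subject="background")
    prof_fish.roi = prof_bg.roi = (origin[0], origin[1], roi_size)
    return prof_fish, prof_bg, subtract_background(prof_fish, prof_bg)


def _motion_arm(config: PipelineConfig, run_dir: Path, rng, log: list) -> dict:
    viewer = ViewerModel.from_geometry(
        config.viewer_acuity, config.scale, config.viewing_distance, config.temporal_resolution
    )
    log.append(f"viewer: acuity={viewer.acuity} cpd, delta={viewer.delta} px, sigma={viewer.sigma} px")
    motion_dir = run_dir / "motion"
    motion_dir.mkdir(parents=True)
    rows = []
    for size in config.motion_grating_sizes:
        for orientation in config.orientations:
            cond = f"{orientation}_{size:g}cm"
            for fish_i in range(config.motion_n_fish):
                for trial in range(config.motion_n_trials):
                    # per-recording staging variation: grating phase and
                    # fish entry point differ between replicate videos
                    phase = float(rng.uniform(0.0, 2.0 * size))
                    start_x = config.clip_width_px / config.scale / 4.0 + float(
                        rng.uniform(-1.0, 1.0)
                    )
                    # keep the sprite inside the frame for the whole clip
                    half = FishSprite().body_length / 2.0
                    travel = config.fish_speed * (config.clip_n_frames - 1) / config.clip_frame_rate
                    lo = half + 0.1
                    hi = config.clip_width_px / config.scale - half - max(travel, 0.0) - 0.1
                    start_x = float(np.clip(start_x, lo, min(hi, max(lo, hi))))
                    fish_clip, bg_clip = make_condition_clips(
                        config, size, orientation, phase=phase, fish_start_x=start_x
                    )
                    prof_fish, prof_bg, prof_sub = analyse_condition_clip(
                        fish_clip, bg_clip, viewer, config.roi_size
                    )
                    if fish_i == 0 and trial == 0:
                        dio.write_profile(
                            prof_sub, motion_dir / f"profile_{cond}.csv",
                            grating_size=size, orientation=orientation,
                            delta=viewer.delta, sigma=viewer.sigma,
                        )
                    for d, s in zip(prof_sub.bin_centers, prof_sub.strengths):
                        rows.append(
                            {
                                "strength": s,
                                "direction_bin": int(d),
                                "grating_size": size,
                                "orientation": orientation,
                                "fish_id": f"f{fish_i}",
                                "trial_id": f"t{trial}",
                                "total_motion": total_motion(prof_sub),
                            }
                        )
    table = pd.DataFrame(rows)
    table.to_csv(motion_dir / "motion_observations.csv", index=False)
    fit = fit_motion_model(table, alpha=config.alpha)
    fit.contrasts.to_csv(motion_dir / "motion_contrasts.csv", index=False)
    log.append(
        f"motion LRT: X2={fit.lrt['statistic']:.2f}, df={fit.lrt['df']}, p={fit.lrt['p']:.3g}"
    )
    return {"table": table, "fit": fit, "dir": motion_dir}


def _behaviour_arm(config: PipelineConfig, run_dir: Path, rng, log: list) -> dict:
    behaviour_dir = run_dir / "behaviour"
    behaviour_dir.mkdir(parents=True)
    conditions = {
        (o, s): None for o in config.orientations for s in config.grating_sizes
    }
    from .config import DEFAULT_PREFERRED_DISTANCES, DEFAULT_STEP_SDS

    conditions = {k: DEFAULT_PREFERRED_DISTANCES.get(k, 17.5) for k in conditions}
    step_sds = {k: DEFAULT_STEP_SDS.get(k, 0.8) for k in conditions}
    summary = simulate_behaviour_dataset(
        seed=int(rng.integers(2**31 - 1)),
        conditions=conditions,
        step_sds=step_sds,
        n_fish=config.n_fish,
        n_rounds=config.n_rounds,
        duration=config.trial_duration,
        frame_rate=config.behaviour_frame_rate,
        fish_distance_sd=config.fish_distance_sd,
        attraction_strength=config.attraction_strength,
        arena_length=config.arena_length,
        arena_width=config.arena_width,
    )
    summary.to_csv(behaviour_dir / "behaviour_summary.csv", index=False)
    dist_fit = fit_distance_model(summary, alpha=config.alpha, arena_length=config.arena_length)
    dist_fit.marginal_means.to_csv(behaviour_dir / "distance_marginal_means.csv", index=False)
    dist_fit.contrasts.to_csv(behaviour_dir / "distance_contrasts.csv", index=False)
    dist_fit.aic_table.to_csv(behaviour_dir / "distance_aic.csv", index=False)
    move_fit = fit_movement_model(summary, alpha=config.alpha)
    move_fit.contrasts.to_csv(behaviour_dir / "movement_contrasts.csv", index=False)
    log.append(
        f"distance LRT (time): X2={dist_fit.lrt['statistic']:.2f}, p={dist_fit.lrt['p']:.3g}; "
        f"overdispersion={dist_fit.overdispersion:.2f}"
    )
    return {"summary": summary, "distance": dist_fit, "movement": move_fit, "dir": behaviour_dir}


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute both arms under ``out_dir`` and return the run directory.

    Writes every intermediate table, a ``manifest.json`` with SHA-256 content
    hashes of all artifacts, the effective config as TOML, and a plain-text
    log.  Identical config + seed produce identical manifests.
    """
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed: {config.seed}"]
    rng = np.random.default_rng(config.seed)
    config.to_toml(run_dir / "config.toml")

    try:
        _motion_arm(config, run_dir, rng, log)
        _behaviour_arm(config, run_dir, rng, log)
    except Exception as exc:  # halt with stage context
        (run_dir / "log.txt").write_text("\n".join(log) + f"\nFAILED: {exc}\n")
        raise

    (run_dir / "log.txt").write_text("\n".join(log) + "\n")
    manifest = {
        str(p.relative_to(run_dir)): _hash_file(p)
        for p in sorted(run_dir.rglob("*"))
        if p.is_file() and p.name not in ("manifest.json", "log.txt")
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return run_dir


def make_fixtures(seed: int = 0) -> dict:
    """Small deterministic clips and tracks covering documented edge cases.

    Returns a dict with:

    * ``static`` — a static scene (all-zero motion through the whole arm);
    * ``pan_right`` — a resolvable vertical grating panning rightward
      (profile peak at 90 degrees);
    * ``subacuity`` — a grating finer than the viewer's acuity (background
      profile below the discriminability threshold);
    * ``nyquist`` — a grating at exactly twice the sampling base, shifted by
      the sampling base per frame (direction-ambiguous edge case);
    * ``still_track`` — a zero-noise, zero-attraction stationary track;
    * ``boundary_track`` — a track hugging the grating wall.
    """
    viewer = ViewerModel.from_geometry(2.5, scale=10.0)
    small = dict(frame_rate=30.0, n_frames=6, scale=10.0, width_px=64, height_px=64)

    static = ClipSpec(grating=GratingSpec(bar_width=0.4), camera_speed=0.0, **small)
    # coarse, clearly-resolvable grating at ~0.15 period/frame: the pan reads
    # almost purely rightward at every responsive pixel
    pan_right = ClipSpec(grating=GratingSpec(bar_width=1.0), camera_speed=9.0, **small)
    # bar width chosen so one period is exactly 2 * delta px and the per-frame
    # shift is exactly delta px: the aliasing knife-edge
    delta = viewer.delta
    nyq_bar = delta / 10.0
    nyq_speed = delta * 30.0 / 10.0
    nyquist = ClipSpec(grating=GratingSpec(bar_width=nyq_bar), camera_speed=nyq_speed, **small)
    import warnings as _warnings

    from .stimuli import compose_clip

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        subacuity = ClipSpec(grating=GratingSpec(bar_width=0.05), camera_speed=17.0, **small)
        clips = {
            "static": compose_clip(static),
            "pan_right": compose_clip(pan_right),
            "nyquist": compose_clip(nyquist),
            "subacuity": compose_clip(subacuity),
        }

    still = simulate_track(
        TrackSpec(preferred_distance=13.5, duration=20.0, attraction_strength=0.0,
                  step_sd=0.0, start=(11.0, 13.5), seed=seed)
    )
    boundary = simulate_track(
        TrackSpec(preferred_distance=0.0, duration=20.0, attraction_strength=3.0,
                  step_sd=0.5, seed=seed + 1)
    )
    return {"viewer": viewer, **clips, "still_track": still, "boundary_track": boundary}
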