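"""Simulation-based generation and calibration of the statistical layer.

Provides (a) a behaviour-dataset simulator that turns per-condition track
parameters into the tidy per-bin table the models consume, (b) a null
false-positive-rate check for the per-direction motion contrasts, and (c) a
parameter-recovery / interval-coverage check for the beta mixed regression.
These run both in the test suite and in the acceptance script; problem sizes
are arguments so callers can scale replication to their time budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behaviour import TrackedPath, summarise_tracks
from .config import DEFAULT_PREFERRED_DISTANCES, DEFAULT_STEP_SDS
from .stats import fit_distance_model, fit_motion_model
from .stimuli import TrackSpec, simulate_motion_observations, simulate_track_batch

__all__ = [
    "simulate_behaviour_dataset",
    "motion_null_false_positive_rate",
    "beta_recovery",
]


def simulate_behaviour_dataset(
    seed: int,
    conditions: dict | None = None,
    step_sds: dict | None = None,
    n_fish: int = 10,
    n_rounds: int = 2,
    duration: float = 300.0,
    frame_rate: float = 15.0,
    fish_distance_sd: float = 2.0,
    attraction_strength: float = 0.5,
    arena_length: float = 35.0,
    arena_width: float = 22.0,
) -> pd.DataFrame:
    """Simulate the full behavioural experiment and summarise it per bin.

    ``conditions`` maps ``(orientation, bar_width_cm)`` to the condition-mean
    preferred distance (cm); each fish draws a persistent deviation from a
    ``N(0, fish_distance_sd^2)`` around that mean, clipped to the arena.
    Every fish is tracked once per condition per round, exactly as in the
    open-field design.  Returns the tidy per-bin summary table.
    """
    conditions = DEFAULT_PREFERRED_DISTANCES if conditions is None else conditions
    step_sds = DEFAULT_STEP_SDS if step_sds is None else step_sds
    rng = np.random.default_rng(seed)

    # Persistent per-fish distance preference offsets.
    fish_offsets = rng.normal(0.0, fish_distance_sd, size=n_fish)

    tracks: list[TrackedPath] = []
    for (orientation, size), mean_distance in sorted(conditions.items()):
        sd = step_sds.get((orientation, size), 0.8)
        for rnd in range(n_rounds):
            prefs = np.clip(mean_distance + fish_offsets, 1.0, arena_length - 1.0)
            spec = TrackSpec(
                preferred_distance=float(np.clip(mean_distance, 0, arena_length)),
                arena_length=arena_length,
                arena_width=arena_width,
                duration=duration,
                frame_rate=frame_rate,
                attraction_strength=attraction_strength,
                step_sd=sd,
            )
            x, y = simulate_track_batch(
                spec, prefs, step_sds=sd, seed=int(rng.integers(2**31 - 1))
            )
            for i in range(n_fish):
                n = x.shape[1]
                tracks.append(
                    TrackedPath(
                        frames=np.arange(n),
                        x_px=x[i] / 0.02763,
                        y_px=y[i] / 0.02763,
                        confidence=np.ones(n),
                        frame_rate=frame_rate,
                        fish_id=f"f{i}",
                        round_id=f"r{rnd}",
                        grating_size=size,
                        orientation=orientation,
                    )
                )
    return summarise_tracks(tracks, arena_length=arena_length)


def motion_null_false_positive_rate(
    seed: int,
    n_sims: int = 500,
    alpha: float = 0.05,
    n_bins: int = 8,
    n_fish: int = 3,
    n_trials: int = 3,
) -> dict:
    """Per-direction contrast false-positive rate under the null.

    Simulates ``n_sims`` motion tables with no condition effect (fish and
    trial heterogeneity only), fits the motion mixed model to each, and
    counts per-direction horizontal-vs-vertical contrasts with adjusted
    p < alpha.  Returns the rate, its Monte-Carlo standard error computed
    over simulations (contrasts within one fit are correlated), and counts.
    """
    rng = np.random.default_rng(seed)
    per_sim_rates = []
    failures = 0
    for _ in range(n_sims):
        table = simulate_motion_observations(
            seed=int(rng.integers(2**31 - 1)),
            n_bins=n_bins,
            n_fish=n_fish,
            n_trials=n_trials,
        )
        try:
            fit = fit_motion_model(table, alpha=alpha)
        except Exception:
            failures += 1
            continue
        per_sim_rates.append(float((fit.contrasts["p_adj"] < alpha).mean()))
    rates = np.asarray(per_sim_rates)
    return {
        "rate": float(rates.mean()),
        "mc_se": float(rates.std(ddof=1) / np.sqrt(rates.size)),
        "n_sims": int(rates.size),
        "n_tests": int(rates.size * n_bins),
        "failures": failures,
    }


@dataclass
class BetaRecoveryReport:
    """Interval-coverage and estimate summary over recovery simulations."""

    coverage: float
    n_intervals: int
    mean_estimates: dict
    contrast_power: float
    n_sims: int


def beta_recovery(
    seed: int,
    n_sims: int = 200,
    mean_vertical: float = 13.5,
    mean_horizontal: float = 17.7,
    grating_size: float = 0.5,
    n_fish: int = 6,
    n_rounds: int = 2,
    duration: float = 150.0,
    fish_distance_sd: float = 2.0,
    alpha: float = 0.05,
) -> BetaRecoveryReport:
    """Parameter recovery for the beta mixed regression on simulated tracks.

    Each simulation generates tracks for one grating size with
    orientation-dependent preferred distances, fits the distance model, and
    checks whether each generating condition mean lies inside the fitted 95%
    interval of the corresponding population marginal mean.  Also reports the
    rate at which the orientation contrast is flagged (power).
    """
    rng = np.random.default_rng(seed)
    conditions = {
        ("vertical", grating_size): mean_vertical,
        ("horizontal", grating_size): mean_horizontal,
    }
    covered = 0
    n_intervals = 0
    flagged = 0
    est_v, est_h = [], []
    n_ok = 0
    for _ in range(n_sims):
        table = simulate_behaviour_dataset(
            seed=int(rng.integers(2**31 - 1)),
            conditions=conditions,
            step_sds={k: 0.8 for k in conditions},
            n_fish=n_fish,
            n_rounds=n_rounds,
            duration=duration,
            fish_distance_sd=fish_distance_sd,
        )
        try:
            fit = fit_distance_model(table, alpha=alpha, candidate_time_model=False)
        except Exception:
            continue
        n_ok += 1
        mm = fit.marginal_means.set_index("orientation")
        for orientation, truth in (("vertical", mean_vertical), ("horizontal", mean_horizontal)):
            row = mm.loc[orientation]
            n_intervals += 1
            if row["ci_low_cm"] <= truth <= row["ci_high_cm"]:
                covered += 1
        est_v.append(float(mm.loc["vertical", "mean_cm"]))
        est_h.append(float(mm.loc["horizontal", "mean_cm"]))
        ori = fit.contrasts[fit.contrasts["family"] == "orientation_within_size"]
        if (ori["p_adj"] < alpha).any():
            flagged += 1
    return BetaRecoveryReport(
        coverage=covered / n_intervals if n_intervals else float("nan"),
        n_intervals=n_intervals,
        mean_estimates={
            "vertical": float(np.mean(est_v)) if est_v else float("nan"),
            "horizontal": float(np.mean(est_h)) if est_h else float("nan"),
        },
        contrast_power=flagged / n_ok if n_ok else float("nan"),
        n_sims=n_ok,
    )
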