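"""Open-field behaviour: simulated trials, per-bin summaries, mixed models.

Simulates the full behavioural experiment (every fish tested against every
grating condition in two rounds), summarises each 5-min track into 15-s bins
of distance-from-grating and distance-moved, then fits the beta mixed
regression for distance and the log-linear mixed model for movement.
"""

import warnings

from dazzle.calibration import simulate_behaviour_dataset
from dazzle.stats import fit_distance_model, fit_movement_model

warnings.simplefilter("ignore")

table = simulate_behaviour_dataset(seed=7)
print(f"simulated {table[['fish_id', 'round_id']].drop_duplicates().shape[0]} fish-rounds, "
      f"{len(table)} 15-s bins\n")

dist = fit_distance_model(table)
print("distance model (beta mixed regression, logit link):")
print(f"  time-interaction LRT: X2 = {dist.lrt['statistic']:.2f}, p = {dist.lrt['p']:.3f}")
print(f"  overdispersion ratio: {dist.overdispersion:.2f}")
qr = dist.final.quantile_residuals()
print(f"  quantile residuals: mean {qr.mean():+.2f}, sd {qr.std():.2f} (should be ~0, ~1)")
print("\nmarginal mean distance from the grating (cm):")
mm = dist.marginal_means.pivot(index="grating_size_cm", columns="orientation", values="mean_cm")
print(mm.round(2).to_string())

ori = dist.contrasts[dist.contrasts["family"] == "orientation_within_size"]
flagged = ori[ori["p_adj"] < 0.05]
print(f"\norientation differences flagged at alpha=0.05 for bar widths: "
      f"{sorted(flagged['grating_size_cm'])}")

move = fit_movement_model(table)
mo = move.contrasts[move.contrasts["family"] == "orientation_within_size"]
print("\nmovement model (LMM on log distance moved): orientation contrasts")
print(mo[["grating_size_cm", "estimate", "p_adj", "eta_squared"]].round(4).to_string(index=False))
print(
    "\nNegative estimates mean more movement against vertical gratings of that\n"
    "size; fish move most at the finest vertical grating and least when the\n"
    "background matches their own stripe period."
)
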