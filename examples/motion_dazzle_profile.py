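"""Motion-dazzle analysis of a synthetic striped fish on a grating.

Composes a clip of the striped fish sprite translating over a panning
square-wave grating, runs the Reichardt-correlator model at the virtual
predator's acuity, and prints the background-subtracted directional profile
summary.  Energy at 90 deg is motion in the direction of travel; energy at
270 deg is the illusory opposing motion that defines motion dazzle.
"""

import warnings

from dazzle.config import PipelineConfig
from dazzle.emd import ViewerModel
from dazzle.motion_profile import total_motion
from dazzle.pipeline import analyse_condition_clip, make_condition_clips

warnings.simplefilter("ignore")  # the finest grating is deliberately sub-pixel

config = PipelineConfig()
viewer = ViewerModel.from_geometry(
    config.viewer_acuity, config.scale, config.viewing_distance
)
print(
    f"viewer: {viewer.acuity} cycles/deg at {viewer.viewing_distance} cm "
    f"-> sampling base {viewer.delta} px, pre-filter sigma {viewer.sigma} px\n"
)

for bar_cm in (0.05, 0.25, 1.0):
    fish_clip, bg_clip = make_condition_clips(config, bar_cm, "vertical")
    fish, bg, sub = analyse_condition_clip(fish_clip, bg_clip, viewer, config.roi_size)
    print(f"vertical grating, {bar_cm} cm bars:")
    print(f"  background peak strength: {bg.strengths.max():.2e} "
          f"(fish peak {fish.strengths.max():.2e})")
    print(f"  background energy within +/-45 deg of pan: {bg.sector_fraction(90, 45):.0%}")
    print(f"  fish-minus-background energy at 90/270 deg sectors: "
          f"{sub.sector_fraction(90, 45):.0%} / {sub.sector_fraction(270, 45):.0%}")
    print(f"  total mean motion (arbitrary units): {total_motion(sub):.2e}\n")

print(
    "The 0.05 cm grating is invisible to the viewer (background ~ 0) and the\n"
    "fish profile is bimodal: the internal stripes alone generate opposing\n"
    "motion cues.  The 0.25 cm grating drives strong one-directional\n"
    "background motion instead."
)
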