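# dazzle

Motion-dazzle analysis of striped prey on square-wave grating backgrounds.

High-contrast body stripes can generate misleading motion cues — apparent
motion opposite to an animal's direction of travel — in the eye of a pursuing
predator ("motion dazzle"). This package models that effect for a small
striped reef fish (a humbug-damselfish-like prey) viewed against
black-and-white square-wave gratings of varying bar width and orientation,
and analyses the fish's own behavioural response to those backgrounds. It is
written for visual ecologists and behavioural biologists who want the whole
analysis to run from synthetic, fully parameterised stimuli with no external
data.

## What it computes

**Retinal motion model (2-D elementary motion detectors).** Each frame pair
of a clip is converted to luminance, low-pass filtered to the viewer's
spatial resolving power, and passed through two orthogonal arrays of
Reichardt correlators with sampling base Δ (px) and a one-frame temporal
delay:

    H(x, y) = I_t(x, y) · I_{t+1}(x+Δ, y) − I_t(x+Δ, y) · I_{t+1}(x, y)
    V(x, y) = I_t(x, y) · I_{t+1}(x, y+Δ) − I_t(x, y+Δ) · I_{t+1}(x, y)

Per-pixel vectors (H, V) are summarised as the mean motion strength in 72
five-degree direction bins over a region of interest (0° = up, 90° = the
prey's direction of travel); background-only motion is subtracted bin-wise
with a floor at zero.

**Visual acuity.** Anatomical spatial resolving power from peak retinal cell
density D (cells/mm²) and focal length f (mm) under hexagonal packing:
SRP = f·tan 1° / (2s) cycles/deg with row spacing s = √(√3 / 2D). Behavioural
acuity is taken as half the anatomical value, and the maximum distance at
which a grating cycle of size c stays resolvable is d = c / (2·tan(θ/2)) with
θ = 1/acuity degrees.

**Behaviour.** Tracked head coordinates (frame, x\_px, y\_px, confidence) are
confidence-filtered at p ≥ 0.9, converted at 0.02763 cm/px, and binned into
15-s (225-frame) windows of distance-from-grating and distance-moved.
Distance (normalised to (0,1) over the 35-cm arena) is modelled by a beta
mixed regression with nested fish and round-within-fish intercepts; movement
by a linear mixed model on log distance; both with likelihood-ratio
interaction tests, AIC model comparison and Tukey-adjusted pairwise
contrasts.

A synthetic-stimulus module generates all inputs: bit-exact gratings, a
striped elliptical fish sprite, composed predator-view clips, and
mean-reverting random-walk arena tracks.

## Worked example

```sh
python examples/motion_dazzle_profile.py
```

prints, for a virtual predator with 2.5 cycles/deg acuity at 30 cm:

```
vertical grating, 0.05 cm bars:
  background peak strength: 0.00e+00 (fish peak 3.24e-01)
  background energy within +/-45 deg of pan: 0%
  fish-minus-background energy at 90/270 deg sectors: 56% / 29%

vertical grating, 0.25 cm bars:
  background peak strength: 3.18e-01 (fish peak 3.38e-01)
  background energy within +/-45 deg of pan: 95%
```

The 0.05 cm grating is below the viewer's acuity, so the background
generates no motion at all, while the fish's internal stripes put substantial
energy both with (90°) and against (270°) its direction of travel — the
motion-dazzle signature. The 0.25 cm grating is resolvable and drives strong
background motion in a single direction instead.

The other examples cover the acuity toolkit (`acuity_estimates.py`, which
prints the 2.65 cycles/deg anatomical estimate and per-grating resolvable
distances), the behavioural arm (`open_field_behaviour.py`, which recovers
per-condition mean distances such as 13.1 cm at the 0.5 cm vertical grating
versus 17.0 cm at its horizontal counterpart), and the end-to-end pipeline
(`full_pipeline.py`, writing a hash-manifested run directory). A thin
`dazzle` CLI exposes the same stages as subcommands (`synth`, `motion`,
`acuity`, `behaviour`, `stats`, `run`).

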