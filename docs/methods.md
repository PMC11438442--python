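# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what its synthetic-data tests do and do not show
about real data.

## Stimuli

Gratings are ideal square waves: alternating dark/light bars of equal width,
one period = 2 × bar width. Rendering integrates the wave exactly over each
pixel's footprint (area-weighted anti-aliasing), so bar edges that fall on
pixel boundaries give bit-exact two-level images while sub-pixel bars blur
toward mean grey — the finest study grating (0.05 cm bars at the default
10 px/cm) has a one-pixel period and renders as uniform 0.5, which is
physically the right limit for a viewer whose optics cannot resolve it. A
nearest-neighbour mode exists for pixel-exact tests. Fractions are snapped at
1e-12 to keep aligned edges exactly two-valued.

The prey sprite is a stylised ellipse (default 10 × 5 cm, light body 0.95)
with three dark transverse bars of 0.5 cm, centred at even interior
positions and rasterised to whole pixels. Shape detail beyond "striped
ellipse" does not enter the model, which sees only luminance.

Clips compose a phase-shifted grating (background pan, default 17 cm/s — the
middle of the 15–20 cm/s band a towed camera moves at) with the sprite
alpha-composited at integer pixel positions; the sprite's image-plane speed
defaults to 15 cm/s. Defaults: 30 fps, 15 frames, 720 × 660 px frames,
600 px region of interest. Frame count is the main runtime lever and 14
frame pairs are ample for these deterministic stimuli.

Open-field tracks are discrete mean-reverting random walks on the axis
perpendicular to the grating (attractor = preferred distance, rate 0.5 s⁻¹,
i.e. ~2 s relaxation) with an unbiased bounded walk along the other axis;
step noise defaults to 0.8 cm/frame at 15 fps, positions reflect off the
22 × 35 cm arena walls. The stationary sd of ~3 cm and 15-s sampling (which
renders successive bin samples nearly independent) make the binned distances
approximately beta-compatible after normalisation. Per-condition attractors
and step noises encode the study's reported condition means (13.5 / 17.7 cm
at the 0.5 cm gratings, 16.88 / 18.20 cm at 0.05 cm) and orderings (equal
orientations at 0.1 / 0.25 / 1 cm; most movement at fine vertical gratings,
least at the fine horizontal one); per-fish preference offsets are N(0, 2 cm²)
and persist across rounds.

What the generator does *not* emulate: body undulation and turning, depth,
water optics, tracking noise structure (confidences are 1.0 except where a
test injects drop-outs), and non-stationary behaviour within a trial.
Passing tests therefore demonstrate correctness of the pipeline and
calibration of the statistics under the stated model, not biological realism
of any particular fish.

## Viewer and correlator

The viewer is summarised by acuity (cycles/deg), viewing distance, and
pixels-per-degree = scale × distance × π/180 (small-angle; exact tangents
would differ by <0.01% here). The correlator's sampling base is
Δ = round(ppd / (2 × acuity)) px — half the period of the finest resolvable
grating — with Δ ≥ 1 and a hard error when the pixel grid cannot represent
the acuity (ppd < 2 × acuity). The default geometry (2.5 cycles/deg at
30 cm, 10 px/cm) gives Δ = 1: the model of a predator at about a metre.

Spatial pre-filtering is a single Gaussian with σ = Δ/2 px. At matched
geometry this passes most contrast at half the acuity (>50%) and, together
with area-averaged rendering, annihilates gratings at twice the acuity
(<5% residual contrast). The temporal filter is a pure one-frame delay —
frame rate equals the viewer's assumed temporal resolution — and a warning
is raised when a clip is faster than that.

Responses are computed densely at every pixel; pixels within Δ of the right
or bottom border lack a correlation partner and are flagged invalid rather
than zeroed, because zeros would bias bin means. There is no output
nonlinearity and no temporal integration beyond the delay. Direction is
atan2(H, −V), clockwise from image-up, so 90° is always the (normalised)
direction of prey travel; leftward-travel clips are mirrored (horizontal
flip + H negation), which maps direction θ to −θ mod 360°.

A known property of this raw-luminance Reichardt form: on a panning periodic
pattern the mean-luminance (DC) term makes the pixel-level sign wobble near
luminance troughs, so pixel-count unidirectionality is only near-total for
coarse patterns at small per-frame shifts; energy-weighted summaries are
robust, and the qualitative checks use the study's own staging. A uniformly
panning periodic background yields strictly one-signed net motion — the
opposing-direction background energy seen in real footage reflects
non-uniform camera motion, which the constant-velocity synthetic pan
deliberately omits.

## Profiles

Bin k covers [5k − 2.5°, 5k + 2.5°); zero-magnitude pixels carry no
direction and are excluded from bin means by default (a flag includes them).
Background subtraction is bin-wise on profiles, floored at zero. "Total
motion" defaults to the pixel-weighted mean over contributing pixel-frames;
a bin-averaged variant is provided. The ROI is a centred square window
(default 600 px); for synthetic clips the sprite's known trajectory
guarantees it stays inside.

## Acuity formulas

Hexagonal packing: nearest-neighbour spacing √(2/(√3·D)), row spacing
√(√3/(2·D)); the Nyquist pair of rows per cycle with retinal magnification
f·tan 1° gives SRP = f·tan 1°/(2·row spacing). With the bundled fixture
(D = 28,983 cells/mm², f = 1.660 mm — the focal length is not an observed
value but is derived by inverting the formula against the species' reported
2.65 cycles/deg) the round trip is exact. The behavioural/anatomical factor
defaults to 0.5; 2.65 × 0.5 = 1.325, whereas the study quotes "around 1.1"
— the exact factor its authors used is unstated, so resolvable-distance
functions take acuity as an explicit argument and the examples use 1.1 where
they mirror the published distances (~6.3 cm for the 0.1 cm cycle, ~31.5 cm
for the 0.5 cm cycle; both tan-based, within 2% and 5% of the published
"~6.25" and "~30"). All geometry is tan-based, not small-angle.

## Behaviour pipeline

Sub-cutoff points are linearly interpolated rather than dropped, preserving
the 225-frame bin structure (deletion would desynchronise bins). Per-bin
distance is sampled at the bin's closing frame (a bin-mean option exists);
per-bin movement sums the steps whose leading frame falls in the bin, so the
final bin of an n-point track sums n−1 mod 225 steps. Normalisation divides
by the 35-cm arena and applies the standard boundary squeeze
(y(n−1)+0.5)/n with n = total observations, inverted linearly when marginal
means are reported back in cm.

## Statistics

Motion strength is square-root transformed and fitted with statsmodels
MixedLM: direction × size × orientation fixed effects (single-level factors
are dropped automatically), REML for contrasts, ML for likelihood-ratio
tests of the highest-order interaction, and a random intercept per
fish-within-trial recording cell — with only three trials a trial-level
variance is not estimable, so the top level of the nesting is absorbed into
the cell intercept.

The distance model is a beta mixed regression written for this package:
logit link, constant precision φ, and nested random intercepts for fish and
round-within-fish. The marginal likelihood integrates the intercepts by a
joint Laplace approximation around each fish's posterior mode (damped Newton
on the 1+R-dimensional mode problem per fish, warm-started between
likelihood evaluations); maximisation is L-BFGS-B on (β, log φ, log σ_fish,
log σ_round:fish) with the covariance taken from the numerical observed
information. The fish-level intercept is retained (not collapsed into
fish-round cells) because individual preferences persist across rounds; this
is what makes the fixed-effect standard errors honest, and the
implementation is validated in the test suite against glmmTMB reference
values frozen from an identical fit (log-likelihood, coefficients, SEs and
variance components agree to four decimals). Marginal means are
population-averaged over the combined intercept distribution by
Gauss–Hermite quadrature (appropriate there, as the integrand is centred),
with delta-method SEs over the full parameter covariance and t intervals on
fish-count degrees of freedom. Overdispersion is reported as a Pearson-style
ratio. Candidate fixed structures (with and without a time interaction;
time entering as a standardised linear covariate) are compared by AIC and
likelihood ratio; contrasts and marginal means are reported from the
orientation × size model, preferring the smaller candidate when AICs are
within 2. As a generic residual check the fit exposes normal quantile (PIT)
residuals conditional on the estimated intercept modes, which should be
approximately standard normal under a well-specified model.

Movement is log(moved + offset) in the same LMM machinery, offset = half the
smallest positive observation when zeros occur; contrasts carry an
approximate eta-squared (t²/(t²+df)).

Pairwise comparisons are built from fixed-effect cell contrasts. Families of
all pairs among k means use the studentized-range ("Tukey") p-value with
residual degrees of freedom; orientation contrasts within a direction bin or
grating size are one-comparison families and pass through unadjusted
(the by-group pairwise-comparison convention); Sidak/Bonferroni are
available for arbitrary families. Calibration simulations show the
per-direction contrasts hold the nominal α within Monte-Carlo error (500
null simulations of a 3-fish × 3-trial design) and the beta model's 95%
intervals cover generating condition means in ≈95% of 200 track-level
simulations (6 fish, 2 rounds, 2.5-min tracks — scaled from the full design
so the whole calibration runs in minutes; the full-size design is used for
the single-fit analyses).

## Degenerate inputs and tie-breaks

Empty direction bins report strength 0 with zero count; an all-invalid field
refuses to profile. Bars narrower than one pixel warn. A fish sprite leaving
the frame aborts clip composition with the frame index. Zero-noise,
zero-attraction tracks are exactly stationary; reflection at arena walls is
a triangle fold, preserving determinism under a fixed seed. σ parameters in
the beta model are bounded below at e⁻⁶ to keep the Laplace factorisation
finite at the zero-variance boundary; a singular numerical Hessian falls
back to a ridged pseudo-inverse and the fit is flagged.

## Limitations

The correlator is a deliberately minimal retinal front end — no
motion-energy opponency, no multi-scale pyramids, no higher-order feature
tracking — so its outputs are comparable across conditions but are not
predictions of any specific predator's percept. The supplementary-data
loaders sniff column headers and may need explicit renames for arbitrary
deposited layouts. The beta model fits a single dispersion for all
conditions; dispersion covariates are out of scope.
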