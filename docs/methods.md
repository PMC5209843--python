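# Methods

## The measurement problem

A seedling's cotyledon or first-leaf tips oscillate vertically with the
circadian clock. Under constant light, the free-running period of that
oscillation (normally near 24 h in *Arabidopsis*) is the phenotype of
interest: clock mutants shorten or lengthen it by tenths of an hour to
hours. The raw data are time-lapse photographs of vertical plates, one
frame every 10 minutes for several days, with up to 25 seedlings per plate
in separate chambers. The pipeline reduces each plant to two scalar time
series (left and right tip height in pixels) and each series to one period
estimate with a reliability measure.

## Stage 1: tip positions from images

**Fiducial marks.** Each plate carries four red dots: two at opposite outer
plate corners and two at the anti-diagonal corners (top-right and
bottom-left) of the top-left reference chamber — the minimal information
that fixes both the plate span and the chamber size. Mark pixels are
selected by a radial HSV filter: hue within 15° of red (0°, wrapping),
saturation ≥ 0.4 and value ≥ 0.3 (the floors exclude grey/dark pixels that
share the hue angle; hue itself is brightness-invariant, which makes the
detection robust to lighting drift). The binary mask is cleaned by one
erosion + dilation with a 3×3 square, 8-connected components are labelled,
and blobs smaller than 0.5% of the image are discarded. Exactly four blobs
must remain; otherwise a `MarkDetectionError` asks the operator for a
manual marks file (four "x y" lines). The grid is tiled from the plate
origin using the reference chamber's width/height; if the tiled grid
exceeds the plate span by more than 10% the marks are inconsistent
(`LayoutError`).

**Segmentation.** Each chamber crop is downscaled to 70% linear size
(noise suppression), converted to Rec. 601 luminance, normalised to a fixed
mean level of 0.5 (per frame, so lighting drift between frames does not
change the operating point), then sheared eight times: each pass maps
[0, mean] linearly onto the full range (values above the mean saturate
white) and applies a further 10% linear stretch about mid-grey. Because
most of a chamber is background, the mean sits just below the background
level, so the dark plant is driven to black while the paper background
saturates to white. The image is binarised at its mean (foreground =
darker). Detection is contrast-based rather than colour-based on purpose:
it works for plants of any chlorophyll content. Pixels passing the red
fiducial filter are replaced by background white *before* contrasting —
registration discs centred on chamber corners necessarily intrude into the
corner of a chamber crop and would otherwise masquerade as dark blobs.

**Metric blob filter.** Contrasting surfaces clutter (speckles, droplets)
and can split one plant into several blobs. Each 8-connected blob gets a
plant-likeness score

    score = 1 − 0.5·(d/d_max) − 0.3·(1 − a/a_max) − 0.2·e

with d the centroid distance to the chamber centre (d_max = half the larger
chamber dimension, so border-hugging blobs score ratio ≈ 0.9–1.4), a the
blob area (a_max = largest blob present) and e = 1 − minor/major axis ratio
(elongation penalty). The best-scoring blob seeds the plant; other blobs
join the union if their score reaches 0.35 and their centroid lies within
half a chamber diagonal of the seed. Split cotyledons re-join this way;
small distant clutter is dropped. All weights are configurable.

**Tip tracing.** With x_min (x_max) the leftmost (rightmost) foreground
column of the united mask, the left (right) tip row is the mean row of
foreground pixels within a border band of b = 4 pixels (configurable 3–5)
of that column — the pixels of the binarised silhouette that cut across its
outline. Rows are rescaled to full resolution (÷0.7) and emitted as
`image_height − row`, so upward movement increases the value. Only the
vertical coordinate is kept; the period is invariant to the sign convention
and to the constant chamber offset. Frames with an empty mask are recorded
as missing; chambers with detection rate < 0.8 are flagged unusable.
Timestamps come from lexicographic frame order × the sampling interval
(EXIF is ignored; deterministic).

## Stage 2: period estimation

**Model.** After removing the growth trend, a tip trace is modelled as a
sum of at most four cosine terms, each with amplitude Aₖ (px), period Tₖ
(h) and phase φₖ (h, first peak after t = 0). Internally each term is
parameterised as aₖcos(2πt/Tₖ) + bₖsin(2πt/Tₖ), which is linear in (a, b)
and free of phase wrap-around.

**Detrending.** Default: ordinary least-squares line over the non-missing
samples (residuals have zero mean and zero linear trend). A one-pass
centred moving-average mode (`--detrend moving-average --window-h 24`) is
available for parity experiments; the linear mode is the default because it
is parameter-free and exactly invertible.

**Affine correction inside the fit.** On a finite window, sampled cosines
are not exactly orthogonal to lines, so subtracting the OLS line leaks a
small affine component back into the series (for five 24 h cycles at 10-min
sampling the leak is at the 10⁻³ level of the amplitude — enough to bias a
cosine-only fit by ~3×10⁻⁵ relative in period and, on noisy data, to spawn
degenerate long-period terms with runaway amplitude). The NLLS model
therefore carries an intercept + slope correction (c₀, c₁) fitted jointly
with the cosines; it is folded back into the reported trend and is never a
rhythm candidate. This is the same joint trend-plus-cosines treatment
classical FFT–NLLS uses.

**FFT seeding.** The mean-removed series (missing samples linearly
interpolated *for this step only*) is zero-padded to 8× its length; local
maxima of the power spectrum inside the circadian window (default 15–35 h,
wide enough for any plausible plant period) become candidates
(A from 2|X|/n, φ from the bin phase), strongest first. Maxima below 0.1%
of the dominant spectral power are side-lobe ripple of the rectangular
window, not candidates — without that floor a strong out-of-window rhythm
would always offer a spurious in-window "peak". No taper is applied: the
nonlinear refinement removes any need for it.

**Gauss–Newton with safeguards.** The SSE is minimised over all (aₖ, bₖ,
Tₖ, c₀, c₁) by Gauss–Newton. Each step is halved (up to 20 times) until the
SSE decreases; free periods are projected into [dt/2, 4·span] (periods
beyond a few observation spans are unidentifiable trend surrogates).
Convergence: relative SSE change < 10⁻⁸, or no improving step exists and
the GN model predicts no meaningful decrease, or 100 iterations. A
`ConvergenceError` is raised only when nothing ever improved *and* a
meaningful decrease was predicted — the signature of a pathological seed.

**Term selection.** Greedy forward selection: fit the strongest in-window
candidate first; then repeatedly take the strongest peak of the residual
spectrum at *any* resolvable period (so harmonics, e.g. a 12 h component,
can be absorbed) and refit all terms jointly. A candidate is kept only if
the joint refit reduces the current residual sum of squares by at least 10%
(`--term-var-threshold`); otherwise the term is mostly noise variance and
selection stops. Selection also stops at four terms or when the residual
falls below 10⁻¹⁰ of the signal energy (exact fit).

**Support-plane relative errors.** For n samples and p free parameters, the
confidence region is SSE ≤ SSE_min·(1 + p/(n−p)·F(p, n−p; 1−α)), α = 0.05.
For each period Tₖ the displacement Δ at which the re-optimised SSE (all
other parameters refit by warm-started Gauss–Newton) crosses that target is
found by bracketing + Brent bisection in both directions; the relative
error is max(Δ⁺, Δ⁻)/Tₖ. If the target is not reached within 50%
displacement the parameter is unidentifiable and the component is marked
unreliable (relative error ∞). On noiseless data SSE_min ≈ 0 makes the
interval collapse, so relative errors go to ~10⁻⁸.

**Period call.** Among components with period inside the window and
relative error ≤ 0.15 (the reliability ceiling that operationalises "no
period could be determined"), the one with the *least relative error* — the
term with the most impact on the fit — is the plant's leaf-movement period;
ties break towards the larger amplitude. No qualifying component ⇒
"arrhythmic" (a value, not an error). Per plant the left leaf's period is
used, the right leaf only when the left is arrhythmic, and never an
average: averaging a reliable period with a noisy one only degrades it.

**Group comparison.** Per-group mean/SD and a two-sample, two-sided,
equal-variance Student's t test (pooled variance; the classical test, not
Welch). Zero pooled variance is handled explicitly: equal means ⇒ t = 0,
p = 1; unequal ⇒ exact separation, p = 0.

## The synthetic generator

`simulate_series` produces y(t) = A·cos(2π(t−φ)/T) + m·t + ε with ε i.i.d.
uniform on ±(noise_frac·A) — uniform, not Gaussian, matching the "evenly
distributed noise" the validation design calls for; fractions above 1 are
still fractions of A (200% ⇒ ±2A). Defaults are the study conditions:
amplitude 10 px (the period estimate is amplitude-invariant, so the pixel
scale is immaterial), 10-min sampling, 120 h duration (five circadian
cycles), 15% noise. `render_plate_series` draws white plates with the four
red discs and per-chamber stem + two-ellipse silhouettes whose outermost
tip rows follow a programmed motion; mark radius defaults to 26 px on a
600×600 frame so the discs clear the 0.5% size filter. The renderer is a
geometric fixture, not a photorealistic one: it exercises hue filtering,
grid derivation, contrast segmentation, clutter rejection and tip tracing,
but it does not emulate specular droplets, soft shadows, leaf torsion or
plants touching chamber walls — passing on renders therefore validates the
pipeline's logic and numerics, not its robustness to every laboratory
artefact.

## Problem sizes used in the tests

Simulated-series checks use 721 samples (120 h at 10 min) and 20 seeds per
condition. The imaging end-to-end check renders 72 frames at a 100-min
interval so the same 120 h span (and a resolvable 24 h rhythm) fits in a
compact stack; the 10-min interval remains the default everywhere else.
The group-power check uses cohorts of n = 40 (periods 24.7 h vs 23.1 h,
±15% noise) over 10 replicate runs.

## Known limitations

- At 200% noise (±2A uniform) the period of a 120 h / 721-sample series is
  still statistically identifiable — the support-plane relative error stays
  near 0.02, far below the 0.15 ceiling — so the pipeline keeps returning
  confident ~24 h estimates where a less efficient estimator would fail;
  the dispersion across seeds (SD ≈ 0.2 h) does grow exactly as expected.
- The support-plane search treats parameters one at a time (all others
  re-optimised), the usual approximation; a fully joint region would be
  wider for strongly correlated parameters.
- Tip tracing assumes leaves orthogonal to the camera and reports vertical
  motion only; 3-D reconstruction and horizontal output are out of scope.
- The left/right tip pairing assumes one plant per chamber; two plants in a
  chamber would be fused by the metric filter into nonsense.
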