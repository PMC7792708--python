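# Methods

This note documents the models, measurement conventions, numerical choices
and known limitations of the `epimap` pipeline. Units throughout: time in
ms, space in µm (pixel pitch), speeds in cm/s (1 cm/s = 10 µm/ms),
fluorescence in arbitrary camera counts.

## Acquisition model and pacing protocol

A recording is a (T, H, W) stack of fluorescence counts with a frame rate
(default 490.2 Hz, i.e. 2.04 ms frames) and a pixel pitch (default 118 µm).
The dynamic pacing protocol is a staircase of pacing cycle lengths with a
fixed pulse count per step; the default is 30 pulses at each of 250, 200,
175, 150, 125, 97, 80, 70 and 60 ms. Stimulus times are the cumulative sum
of the intervals, with the first pulse at t = 0. The analysis uses the last
five beats of each PCL (at reduced scale: the last five of however many were
delivered; at least six are needed so that every averaged beat has a
preceding diastolic interval).

## The synthetic movie generator

The generator is first-class code: it defines the study conditions under
which the pipeline is validated.

**Beat trains.** Every pixel carries an iterated restitution map
`APD₆₀(n) = APD_ss · (1 − b · exp(−DI(n−1)/τ))`, where DI(n−1) is the time
from 60 % repolarization of beat n−1 to the activation of beat n. The first
beat uses DI = PCL_first − APD_ss as a neutral, near-steady-state start. By
construction every captured beat satisfies APD₆₀ + DI = inter-stimulus
interval exactly, which the pipeline's identity tests rely on. A stimulus
fails to capture when its prospective DI falls below `min_di` (default
12 ms) or when the pixel lies in a planted 2:1-block region during a
blocked PCL; skipped stimuli leave the previous AP in place so the DI keeps
accumulating (a blocked pixel sees a doubled local cycle length).

**Defaults.** APD_ss defaults to 58 ms (a healthy rat LV epicardium value;
cohort simulations use per-group means). The restitution shape parameters
b = 0.6 and τ = 40 ms are typical rat-ventricle dynamic-restitution values;
they are truth parameters of the generator, chosen once, and the fitting
stage estimates them freely.

**Waveform.** Each optical AP is: a linear upstroke of 2 ms (activation —
the 50 %-amplitude point — at its midpoint); a 3 ms near-peak shoulder; an
exponential decay whose time constant is solved per beat,
τ_r = (APD₆₀ − d/2 − plateau)/ln 2.5, so the 40 %-amplitude crossing lands
at AT + APD₆₀ analytically; then a linear terminal phase (0.8·(APD₆₀ − d/2),
truncated 1 ms before the next upstroke) back to baseline. The shoulder
matters: the optical point-spread of a band-limited acquisition chain (a
40 Hz low-pass at 490 fps spreads the upstroke over ~10 ms) clips a
cornered peak and would bias every measured amplitude and APD; a brief
near-peak shoulder is both what real optical APs look like and what keeps
the rendered waveform's amplitude recoverable after filtering.

**Wave geometry.** Planar fronts (normalized direction, constant speed) or
focal sources (radial distance over speed) set per-pixel activation
offsets. Kinematic only — there is no reaction–diffusion or ionic model,
so wavefront curvature does not interact with APD.

**Artifacts.** Applied after ground truth is recorded, in this order: dead
pixels (signal removed), multiplicative photobleaching `exp(−t/τ_bleach)`,
additive linear drift, additive Gaussian noise, clipping at the saturation
level (default 16383, a 14-bit sensor). One seeded generator with spawned
sub-streams per artifact makes movies bit-reproducible.

**What the generator does not emulate.** Mechanical motion (the pipeline
targets excitation–contraction-uncoupled preparations; a registration hook
exists but none is bundled), pacing stimulus artifacts, dye internalization
dynamics, spatially correlated noise, and front–APD coupling. Passing tests
therefore demonstrate correctness of the measurement chain under the stated
signal model, not robustness to every experimental pathology.

## Signal conditioning

Fixed order: ROI polygon → bad-pixel exclusion → linear detrend → zero-phase
Butterworth low-pass → background subtraction → 1–100 normalization → 5×5
masked spatial mean. Each excluded pixel keeps the single reason that first
removed it, and no stage reinstates a pixel.

- **ROI**: pixel centers inside the polygon (matplotlib path test).
- **Exclusion**: any sample at/above the saturation level; temporal variance
  below a threshold — 4× the median variance of a user-marked off-tissue
  region when given, an absolute value when configured, else 5 % of the
  median in-ROI variance (adaptive to illumination).
- **Low-pass**: Butterworth, order 4 (order is a free choice; 4 gives a
  sharp band edge without ringing), cutoff 40 Hz (configurable 40–45),
  applied forward–backward so timing markers acquire no phase delay.
- **Background**: per-pixel 5th percentile of the detrended trace — a
  robust diastolic floor.
- **Normalization**: per pixel over the whole recording, min → 1,
  max → 100; constant traces are excluded, not mapped. (Per-PCL-segment
  normalization is a config switch; whole-recording is the default.)
- **Spatial mean**: 5×5 average over *included* neighbours only, no
  padding; excluded pixels pass through. This avoids bleeding background
  into tissue but makes border pixels asymmetric — see Limitations.

## Beat measurement

Within each analyzed beat window (shifted 15 ms, at most PCL/4, before the
stimulus — the zero-phase filter spreads the upstroke symmetrically, so the
upstroke base precedes the stimulus):

- **Peak** = earliest maximal sample in the window.
- **Base** = the maximal discrete second-derivative sample before the peak
  (the inflection at the upstroke base). The base *value* is read at the
  sub-sample inflection location (quadratic vertex of the second
  derivative, linear interpolation of the trace): at ~2 ms sampling the
  trace rises steeply at the base, and whole-sample reads would jitter
  base, amplitude and thresholds with the sampling phase.
- **AT** = linear-interpolated 50 %-amplitude crossing on the rising limb.
- **APD₆₀** = first interpolated downward crossing of 40 % amplitude after
  the peak, minus AT; no crossing before the window end invalidates the
  beat (no_repolarization).
- **DI** = next *detected* AT minus AT minus APD₆₀ (for a 2:1 pixel the
  next detected AT is two windows on).
- **AT outliers**: per paced beat, ATs with |z| strictly above 2.5 sample
  standard deviations of the grid-wide AT distribution are removed in one
  pass and excluded from every downstream quantity. Boundary values are
  retained. APDs are not separately z-filtered.
- **Per-pixel means**: APD₆₀ (and CV) over the last four beats; DI over the
  four DIs preceding those beats; `beats_used` counts valid APs among the
  last four.
- **Capture**: a PCL is analyzed only if the ROI-mean trace yields a median
  inter-activation interval within 10 % of the PCL and ≥ 90 % of expected
  activations.
- **Conduction loss**: percent change, 250 → 150 ms, in the number of
  pixels with `beats_used = 4`.

## Conduction velocity

Least-squares plane t = a·x + b·y + c over a 7×7 window (half-width 3,
configurable). A first unrestricted fit gives the local gradient; neighbours
are then re-admitted only if their AT lies within
`α · (halfwidth · pitch · |∇t| + 2σ̂)` of the center's AT, with α = 2 and σ̂
the MAD-based scale of the first-pass residuals. The gradient term excludes
across-wavefront discontinuities (tens of ms); the noise term stops the
window from truncating legitimate scatter, which would bias speeds high (a
pure gradient-scaled window attenuated noisy-field gradients by ~20 %). At
least 10 admitted points are required; gradients below 1e-12 ms/µm are
reported as flat. Velocity = ∇t/|∇t|² (direction of travel, speed 1/|∇t|).
On an exactly planar AT field the recovery is exact to machine precision
for any window size.

## Restitution fitting

Global restitution points are means of the per-pixel mean maps over defined
pixels, one point per captured PCL (fits use PCLs in the 97–250 ms span).
The three-parameter fit is bounded nonlinear least squares
(APD_ss ∈ (0, 2·max APD], b ∈ [0, 1.5], τ ∈ (0, 1000] ms; start at
max APD, 0.5, 50 ms; up to 5 jittered restarts). Two-stage cohort scheme:
stage 1 pools all points of a group (raw pooling, hearts implicitly
weighted by their number of captured PCLs); stage 2 refits APD_ss per heart
with (b, τ) frozen — a closed form, Σ(APD·s)/Σ(s²) with
s = 1 − b·exp(−DI/τ). The restitution vector angle is the four-quadrant
angle of (ΔDI, ΔAPD) from the 175 ms to the 150 ms point, counterclockwise
from the +DI axis, in [0, 360); both axes are in ms so the angle is
computed on equal-unit axes.

## Dispersion statistics

Per pixel at one PCL: radial distance and angle of (DI mean, APD₆₀ mean)
about the global mean restitution point (same angle convention). Pixels at
zero distance have no angle and are excluded from the segment fraction's
denominator; the fraction counts angles inside [130°, 140°] ∪ [310°, 320°]
(boundaries inclusive) among pixels with defined angles. The mean point is
used as-is, not projected onto the PCL = APD + DI line. The 2-D histogram
uses 1 ms bins and is display-only.

## Cohort statistics

Brown–Forsythe: one-way ANOVA on absolute deviations from group medians
(scipy's median-centered Levene). Fisher's LSD planned contrasts: single
pooled variance over all groups, MSE = Σ(nᵢ−1)sᵢ²/Σ(nᵢ−1),
t = Δmean/√(MSE·(1/n₁+1/n₂)), df = Σ(nᵢ−1), two-sided, uncorrected for
multiplicity; computable directly from printed (mean, SD, n) summaries.
When the equal-variance test rejects, contrasts are reported N/A and the
Brown–Forsythe p stands alone. SDs use the n−1 convention. No normality
test is bundled.

Median-centered Brown–Forsythe is conservative in small samples (empirical
level ≈ 0.03 at n = 10–30 per group, ≈ 0.048 at n = 50), so the suite's
type-I calibration simulation uses 3 × n = 50, where the F reference is
accurate.

## Problem sizes and numerical checks

Tests and the acceptance script run reduced-scale versions of the study
conditions, chosen as the smallest sizes at which each property is
informative: 64×64 grids with 6 pulses/PCL for movie-level identities and
conduction loss, 32×32 for parameter recovery, 8×8 with the full 30
pulses/PCL for steady-state identities, 200–1000 Monte-Carlo replicates for
stochastic recoveries. The per-beat identity APD₆₀ + DI = inter-AT interval
is algebraically exact; the *per-pixel mean* identity carries a
(apd_last − apd_first)/4 pairing term — the restitution transient plus
sampling-phase jitter, ~0.07 ms at 6 beats/PCL, < 1e-6 ms at 30 — which is
why ground-truth identities are asserted at full pulse counts and
movie-level identities against the frame interval.

## Known limitations

- Border pixels (within the spatial-filter plus plane-fit half-widths, ~5
  px) have biased ATs from asymmetric neighbourhood averaging; CV
  summaries should be taken over interior pixels, as the cohort scripts do.
- The 5×5 filter bleeds neighbouring APs up to 2 px into a conduction-block
  region, so skipped beats near a block border can be detected as
  low-amplitude APs; planted-block recovery is accurate up to that border
  band.
- Measured APD₆₀ carries a small systematic offset (≈ +0.4 ms at default
  settings) from band-limiting the waveform; it cancels in the
  APD + DI identity and in contrasts between conditions measured the same
  way.
- Capture inference uses the ROI-mean trace; regional (subtotal) capture
  loss does not flag the PCL, by design — it surfaces in `beats_used` maps
  and the conduction-loss metric instead.
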