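# Methods

This note documents the models, estimators and numerical choices behind
patchkit, and what the synthetic-data generator does and does not emulate.

## Trajectory model and units

A track is the centroid time series of one diffraction-limited endocytic
patch: times (s), positions (nm), background-subtracted intensity (a.u.).
Positions are converted from camera pixels to nanometres once, at load
(65 nm/px for live imaging, 160 nm/px for reconstructed STORM images), and
every downstream computation works in nanometres. Tracks must be sampled
uniformly to within half a frame interval; non-uniform trajectories are
rejected at load rather than resampled, because the acquisitions this
pipeline targets are continuous fixed-rate streams and a gap usually means
a tracking failure. Tracks shorter than 3 frames or with a non-positive
intensity peak are likewise dropped, with the reason logged and reported.

## Inflection detection

The motion signature of a coat-protein track is flat (stationary assembly,
localization noise only), then a linear ramp (invagination at roughly
constant speed), then diffusive wander (released vesicle). The detection
problem is hard in a way worth stating: at 9 Hz and 23.8–51.8 nm/s the
per-frame displacement gain is 2.6–5.8 nm against ~15 nm localization noise
per coordinate, so no rule that inspects frames locally can localize the
kink — an estimator must pool many frames on both sides.

The default estimator therefore fits the shape globally and refines
locally:

1. **Coarse segmentation.** Exhaustive least-squares changepoint fitting of
   the distance-from-origin series (after a 3-frame centered moving
   average) into four segments: a constant, then three free lines, O(n²)
   via prefix-sum tables. Four segments matter: the post-scission wander
   carries the dominant variance, and with fewer segments the optimum
   spends its changepoints subdividing the wander while the weak ramp
   merges into the flat phase. On exact ties the latest first-changepoint
   wins, because in noise-free data a line fits the flat phase as well as a
   constant does and the changepoint would otherwise collapse leftward.
2. **Candidate adjudication and 2D refinement.** The first two fitted
   changepoints are both treated as kink candidates. Each is refined by a
   continuous flat→drift (hinge) fit on the 2D positions in a local window
   (40 frames back, 25 forward — the forward span stays inside the 4–5 s
   directed phase). A candidate is accepted only if the hinge explains at
   least 5% of the stationary-model variance *and* the refined kink's
   post-arm genuinely drifts (a line beats a constant by >15% of variance);
   if the accepted kink's *pre*-arm drifts, it sits on the drift→diffusion
   transition and the window is stepped back and refit (at most 6 steps).

   Refining on the 2D positions rather than on the distance series is
   deliberate: distance-from-origin shares the noisy first-frame position
   across every sample, which injects a random flat/ramp level offset of
   the order of the localization noise and de-localizes the kink by several
   frames.

The published regression-residual rule — subtract the OLS line from the
displacement series and take the argmin, earliest tie first — is available
as `method="residual"` (on either displacement kind). It is retained for
comparability but is not the default: on simulated tracks at realistic
noise its kink localization is an order of magnitude worse, because the
residual surface is nearly flat over tens of frames on the stationary side.

On simulated fission-like events (51.8 nm/s, 9 Hz, 15 nm noise) the default
estimator hits the true inflection within ±2 frames in ~95% of events and
is unbiased; at 23.8 nm/s its error SD is ~3 frames, close to the
information-theoretic limit at that signal-to-noise ratio.

## Alignment, averaging and scission inference

Tracks are aligned at their reference (inflection for coat/NPF markers,
rising half-max intensity for actin markers), intensity is rescaled to each
track's own maximum, and displacement is measured from the interpolated
position *at the reference time* — measuring from the first frame would let
pre-reference jitter offset the origin. Series are linearly interpolated
(never extrapolated) onto a grid at the smallest frame interval present;
bins covered by fewer than `n_min = 3` tracks are masked. The across-track
SD uses ddof = 1.

An optional registration pass (`refine_references`) re-times each track by
matching its displacement curve to the ensemble mean within ±4 s,
recentered on the median shift so only relative offsets move. It is off by
default: it repairs gross outliers when the template is sharp, but at low
displacement signal-to-noise it matches noise and degrades the alignment
(both behaviours were measured on simulation).

Scission is the first bin more than 2 s after the reference where the
displacement SD exceeds `k = 2` times the baseline median (window
[0, 2 s], the early directed phase where regular movement keeps the SD
small) for `m = 3` consecutive bins. The constants are configurable; the
defaults were chosen so the simulated diffusive phase at the default
diffusion coefficient triggers within a few bins while a continued-drift
control never does. Raising `k` can only delay (or lose) the detection —
the rule is monotone by construction.

Invagination speed is the OLS slope of mean displacement over
(0, t_scission]. The ensemble mean of a displacement *magnitude* sits on a
Rice-distribution noise floor (~25–30 nm at default noise) that drags a raw
slope below the true speed by up to ~20% at the slower preset, so by
default the pre-reference mean displacement — a pure noise floor, the patch
being stationary there — is subtracted in quadrature before the fit
(`debias=False` restores the raw slope). With the correction both presets
are recovered within a few percent at n = 50 tracks.

Patch lifetime is the time between the first and last crossings of 10% of
peak intensity, linearly interpolated at both ends. Two-channel alignment
shifts *both* channels of an event by the reference channel's alignment
time and averages both on one shared grid; signal onset within an ensemble
is the first bin whose mean exceeds the pre-event baseline by 3 baseline
SDs.

The crowding filter removes every track that ever comes within 325 nm
(5 live-imaging pixels, about the diffraction-limited spot radius used by
the tracker) of another concurrent track; both members of a close pair go,
since neither is cleanly measurable while they overlap.

## Molecule counting

Counting is ratiometric against a 120-copy sfGFP nanocage standard:
count = 120 × (patch intensity rate) / (standard intensity rate) ×
brightness correction, with intensities normalized per unit exposure.
Brightness factors: GFP = sfGFP = 1.0, mEGFP = 1.14 (mEGFP is 14% brighter
than GFP); mCherry is deliberately absent from the table so any attempt to
count through it fails loudly. sfGFP = GFP is an assumption exposed as a
config key. Exposure-linearity QC passes when the standard's mean intensity
vs exposure has R² ≥ 0.99 and an intercept within 3 SE of zero; Gaussian
fits of standard intensity histograms are maximum-likelihood with a
normality flag for multimodal samples.

The ratio-chain resolver treats the measured pairwise ratio table as a
graph (ratios taken as already brightness-corrected molecule ratios; raw
intensity ratios should pass through `brightness_correct_ratio` exactly
once). Counts propagate from anchors along breadth-first shortest paths;
when several anchors reach a node the geometric mean is reported — ratios
are multiplicative, so averaging belongs in log space — and the max/min
path disagreement is recorded, warning above 20%. Repeated measurements of
the same pair are combined the same way (geometric mean, disagreement
warning) rather than silently overwriting each other. Cycle products are
checked direction-independently (max(p, 1/p) − 1 > 20% warns). The pooled
budding-yeast type-I myosins are a composite node whose count is the sum of
its members; composites resolve once all members are known and then
propagate outward, but are never split back into members. Counts are
reported as floats and rounded only for display.

## STORM lengths

Structures arrive as pre-cropped localization lists in pixels (160 nm/px).
`rotate_cloud("auto")` aligns the principal axis of the xy covariance with
the x-axis (rotation about the centroid; an explicit angle is also
accepted). `structure_length` is the largest pairwise Euclidean distance
among point pairs whose |Δy| ≤ 0.01 px; because a real cloud may contain no
such pair, the threshold doubles (logged) until one qualifies.
`longest_axis` drops the y constraint. z coordinates are carried but
ignored unless `use_z=True`. The strict |Δy| window is not just fidelity to
the rule — it also suppresses the upward bias of the max-span statistic
(extreme points pushed outward by localization noise), which is why
simulated rods are recovered within ~5% across 120–350 nm at 10 nm noise
while a loosened window overestimates short rods by >10%.

## Synthetic-data generator

The generator emulates exactly the features the detectors rely on:

* **Motion** — stationary (localization noise only, default 15 nm per
  coordinate), then constant-velocity drift in a random direction
  (presets 23.8 and 51.8 nm/s; default fission-like, since the stage
  pipeline exists to define fission-yeast internalization stages), then 2D
  Brownian steps with per-axis variance 2·D·Δt (default
  D = 4000 nm²/s, a ~100 nm vesicle in cytoplasm by a Stokes–Einstein
  estimate with effective viscosity ~1 Pa·s). Stationary durations draw
  uniformly from 30–120 s, as observed for coat proteins, and are snapped
  to the frame grid so ground truth coincides with a frame.
* **Intensity** — piecewise-linear rise from 0 to the peak, reaching the
  peak exactly at the motion inflection (coat proteins peak when
  invagination starts), then linear decay (default 10 s to zero; the decay
  continues through scission — defocus losses are not modeled separately),
  with multiplicative Gaussian noise (CV 0.1) floored at −3 noise SD.
  A logistic rise is available behind a flag.
* **Event-to-event variability** — speed, directed duration and peak
  intensity jitter multiplicatively with CV 0.05 by default (Gaussian
  factors; the underlying distributions are unknown, so this is an
  assumption). Start positions scatter over a 5 µm field so the crowding
  filter is exercised realistically.
* **Calibration intensities** — Gaussian, truncated at zero.
* **STORM clouds** — uniform points on a rotated length × width rectangle
  plus isotropic localization noise, endpoints included so a noise-free
  rod has exactly its nominal extent.

Every generator is a pure function of its parameters and seed; a track set
derives per-event seeds deterministically from one master seed.

What the generator does **not** emulate: photobleaching, defocus intensity
loss after scission, camera noise beyond multiplicative Gaussian, spot
merging/splitting in crowded fields, anisotropic localization error, or
z motion. Passing recovery tests therefore demonstrate that the estimators
are correct and well-calibrated for the assumed motion/intensity structure
— not that they are robust to every artefact of real movies.

## Problem sizes used in tests and the acceptance script

Recovery studies use 50-track ensembles per condition (matching typical
per-experiment event counts), 200 events for the inflection hit-rate study,
25 clouds per rod length, and 10⁴ draws for distribution-fit checks. These
sizes keep every study's sampling error well inside the tolerances being
asserted.

## Known limitations

* The inflection detector assumes one stationary→directed transition per
  track; tracks with multiple excursions will align on the strongest one.
* Scission inference needs ≥3 tracks covering the post-reference window;
  it reports the SD-jump onset, which lags true scission by up to ~2 bins.
* The speed fit assumes an approximately linear mean-displacement ramp;
  strongly curved ramps (accelerating invaginations) would be summarized by
  an average slope.
* The ratio-chain resolver propagates no measurement uncertainty; path
  disagreement and cycle checks are the only error signals.
* STORM length rules measure in the rotated xy plane; out-of-plane tilt
  shortens structures and is not corrected.
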