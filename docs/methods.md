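# Methods

This note documents the models, conventions and design choices behind
`gazemorph`, in the spirit of a package methods appendix.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate and time conventions

All geometry is in degrees of visual angle (dva) in a screen-centered
frame: x rightward, y upward, image center at the origin.  "Left eye" /
"right eye" are observer-referenced (the eye on the observer's left/right
of the screen).  Time is integer milliseconds at a nominal 1,000 Hz; trial
time 0 is image onset and the 1-s pre-stimulus central fixation occupies
[−1000, 0) ms.  Gaze is stored to 4 decimals, which makes file round trips
exact and pipeline digests reproducible.  Missing samples (blinks, tracker
dropout) are stored as NaN and never interpolated: fabricating gaze would
bias heatmaps and dwell times.

## Trial inclusion and blink bridging

A trial is kept when its cumulative on-image viewing strictly exceeds 7 s.
Off-image or missing runs strictly shorter than 500 ms are treated as
natural blinks: they do not break viewing continuity and their duration
counts toward the inclusion total, but their samples are never used in any
heatmap or statistic.  Counting bridged time toward inclusion is one
reading of the rule "interruptions below blink scale are ignored"; the
alternative (count only literal on-image samples) differs by at most a few
hundred ms per trial and is recovered by setting `max_gap_ms = 0`.

## Saccade detection

The velocity criterion is referenced to each trial's own pre-stimulus
fixation: with m and s the median and standard deviation of eye *speed*
in that window, samples with speed above `m + 6s` seed candidate events,
which are extended in both directions to the nearest samples below
`m + 2s`.  Reading the thresholds as offsets above the median (rather than
multiples of it) is the only interpretation that sits above fixational
noise; speed (not a velocity component) is used because the criterion must
be direction-free.

The speed estimator is a central difference of 5-ms moving-averaged
positions, one-sided at the ends; any window touching a missing sample is
undefined (NaN) and events cannot extend across it.  Remaining guards are
standard at 1 kHz: events shorter than 8 ms are dropped and events
separated by at most 10 ms are merged.  A degenerate fixation window (zero
speed variance, e.g. a synthetic noise-free trace) falls back to an
absolute 30 dva/s floor with a warning.  Amplitude is the Euclidean
start-to-end displacement of the raw positions; peak velocity is the
maximum defined speed inside the event.

## Main sequence

The amplitude/peak-velocity law is modeled through the origin, `PV = βA`,
with the closed-form least-squares slope `β = ΣA·PV / ΣA²` (the estimator
class also verifies this against generic least squares in the tests).  R²
is computed about the mean of PV rather than about zero; for a
through-origin model this is the conservative convention (uncentered R²
would be substantially higher for any positively sloped cloud) and it is
the documented, configurable choice.  Saccade groups are compared by
permuting saccade labels and recomputing Δβ.

## Fixation heatmaps

Display heatmaps accumulate one count per 1-ms sample — total mass is
dwell time in ms — after removing samples inside saccades with amplitude
above 1 dva (the exclusion removes samples, not trials).  The native grid
is 20 px/deg (a choice; only the analysis resolution is prescribed) and
smoothing uses a unit-sum Gaussian kernel of SD 0.25 dva with zero
padding, so mass is conserved for interior sources.  Analysis heatmaps are
produced by exact block-sum down-sampling to 5 px/deg — 140 × 105 pixels
for the 28 × 21 dva image — followed by a Gaussian of SD 2.5 px.  Heatmap
distance is the plain Euclidean norm over the flattened grid.  Trials are
averaged without per-trial mass normalization by default (raw dwell mass),
with unit-mass weighting available through the averaging weights.

## Morphing onto the mean face

The mean face shape is the pointwise mean of the 26 corresponding
landmarks.  The Delaunay triangulation is computed **once on the mean
shape** and its vertex-index topology is transferred to every face:
per-face triangulations could differ combinatorially, which would destroy
the triangle correspondence the warp needs.  Each triangle pair defines a
homogeneous affine `T_i` solved exactly from the three vertex
correspondences; a point is warped by the map of the source triangle that
contains it (barycentric containment with a 1e-9 tolerance).  Because the
transferred topology need not be a valid triangulation of a jittered face,
source triangles can overlap; containment is therefore resolved
deterministically in triangle-index order, which also fixes the boundary
tie-break (lowest index wins).  Points outside the source hull have no
defining triangle: they are flagged `in_mesh = False` and passed through
unwarped, and off-face dwell is analyzed separately.  Gaze is warped
sample-by-sample and heatmaps in the mean-face frame are rebuilt from the
warped samples (warp-then-bin); warping binned images instead would
distort mass by the per-triangle Jacobians.

Mirrored stimuli are handled by mirroring the landmark set about the image
midline and swapping left/right semantic labels so the canonical point
order — and with it the cross-image correspondence — is preserved;
applying the mirror twice is the exact identity.

## Looking-time statistics

Eye ROIs are squares centered on the mean-shape eye centers with side 1.6×
the inter-corner eye width (the study gives no dimensions; this default is
configurable).  Dwell inside a closed rectangle sums each sample's
interval to the next sample (the last sample contributes the nominal 1 ms),
restricted to in-mesh samples.  A right-hemisphere injection makes the
observer-right eye ipsilateral.  Baseline normalization subtracts, from
each injection trial's observer-referenced right-minus-left dwell, the mean
bias over all baseline trials within ±31 days of that injection session,
then re-expresses the result ipsi-minus-contra.

Permutation inference uses trial-level exchangeability, two-sided add-one
Monte Carlo p-values `(1 + hits)/(1 + n)` at 10,000 resamples by default,
and exact enumeration (p = hits/total, no add-one needed) when the split or
sign-flip space is small.  Benjamini–Hochberg correction (via statsmodels)
is applied across the looking-time comparison family assembled in one
analysis table.  Note BH adjustment is *not* idempotent in general
(e.g. [0, 1, 0.5] → [0, 1, 0.75] → [0, 1, 1]); adjusted values dominate raw
ones and are monotone in the sorted order, which is what the property tests
assert.

CIs are percentile bootstraps over trials.  For baseline-normalized
effects the interval resamples **both** pools — injection trials and the
baseline trials whose mean is subtracted — because the subtracted bias is
itself an estimate; resampling only the injection trials demonstrably
under-covers.  The bootstrap approximates the per-session ±31-day window
means by the pooled baseline mean, which is accurate here because baseline
sessions are interleaved throughout the calendar.

The pattern change index for trial i is
`(d(hᵢ, H̿) − d(hᵢ, h̄)) / d(hᵢ, H̿)`, with h̄ the same-stimulus mean over
the trial's injection condition and H̿ the same-stimulus grand mean over
the condition plus baseline trials, both at analysis resolution.  It is 1
when the trial matches its condition mean exactly but not the grand mean,
0 when both distances are equal (including the degenerate all-zero case),
negative when the trial is farther from its condition mean, and undefined
(trial excluded) when `d(hᵢ, H̿) = 0` with `d(hᵢ, h̄) > 0`.  The expected
natural variation is estimated within baseline data by a random split-half
per stimulus: one half plays the condition role while the grand mean uses
all baseline trials of that stimulus.

Face-detection metrics: a face is "found" when gaze enters the face
polygon; latency is the end of the first saccade landing inside it, 0 by
convention when gaze is already on the face at image onset, and the first
in-polygon sample time if gaze drifts in without a qualifying saccade.

## Synthetic experiments

The generator emulates the statistical structure of the study's free
viewing, not its imagery: 28 × 21 dva stimuli shown 10 s at 1,000 Hz after
a 1-s central fixation; 26-landmark face layouts (template + per-image
position offset up to ±7 dva and landmark jitter SD 0.3 dva) each with a
mirrored twin; a session calendar interleaving baseline sessions with the
8 injection conditions so every injection session has baselines within
±31 days.

Scanpaths alternate fixations and saccades.  Fixation targets are drawn
over ROIs (left eye, right eye, nose, mouth, other-face, off-face) to
produce the Yarbus-T concentration; fixation durations are log-normal
(median 320 ms, σ_log 0.4, clipped to 80–1500 ms — a generator convention,
not a claim about the data).  Saccade speed follows a raised-cosine
profile whose peak obeys `PV = βA(1 + ε)` with β = 30 dva/s per dva and
multiplicative noise ε of SD 0.15; the profile is integrated to position
and additive gaze noise of SD 0.02 dva is superimposed.  The noise
defaults keep every generated saccade reliably above the detection
threshold, which makes the generator-truth event-count comparison a test
of the detector rather than of the noise floor; they also yield a cleaner
main sequence (R² ≈ 0.9 at these settings, computed by the suite) than
degraded real recordings.  Successive targets are at least 1.5 dva apart
for the same reason.  Blinks are sub-500-ms missing-sample gaps placed
away from true saccades.

Lateralized biases are programmed in seconds and realized as ROI
time-share tilts: a target observer-referenced dwell difference Δ converts
to a share tilt of Δ/(2 × trial length) between the two eyes (baseline
bias default 1.1 s; face-patch 10 µL ipsilateral effect default 1.4 s,
control 10 µL 0.25 s, 5 µL conditions 0).  Successive fixation ROIs are
drawn from a no-repeat chain with transition probability
`q(j→k) = p_k/(1−p_j)`, whose stationary visit distribution is
∝ `p_k(1−p_k)`; the chain parameters are obtained by fixed-point inversion
so realized time shares equal the programmed ones.  (Naive i.i.d. ROI
choice with a minimum-separation retry rule makes dwell superlinear in the
ROI probability and measurably inflates programmed effects; the chain
removes that distortion.)  Eye-targeted fixations are scattered with a
clipped Gaussian kept well inside the eye ROI so programmed eye dwell is
counted there even after piecewise-affine distortion of jittered faces.
The off-face share is small (≈3%) consistent with faces dominating looking
time in face trials.

Ground truth recorded per trial — the emitted saccade events, eye-ROI and
face-polygon dwell counted directly off the emitted samples, the
programmed dwell difference, and β — is exact by construction and serves
as the oracle for every downstream test.

What the generator does **not** emulate: image content and low-level
saliency, smooth pursuit and microsaccades, pupil dynamics, calibration
drift, session-level slow fluctuations of the baseline bias, and
inter-animal differences.  Passing tests therefore demonstrate that the
pipeline recovers the statistical structure it claims to measure, not that
it is robust to every artifact of real recordings.

## Problem sizes and determinism

The test suite and acceptance script use deliberately scaled experiment
sizes chosen as the package's own verification budget: unit tests run
single conditions of tens of trials; effect recovery uses 100 injection
trials per condition at the study's 1.4-s and 1.0-s magnitudes; the
permutation-calibration check draws 1,000 replicate null splits from a
64-trial full-pipeline baseline pool (1,000 rather than a few hundred so
the ±0.02 calibration band is checked with a standard error of ~0.007);
the acceptance script runs the full 8-condition design at 14 trials per
session.  All randomness flows from explicit seeds through
`numpy.random.SeedSequence` spawning, every stochastic statistic records
its resample count, and rerunning any entry point with the same seed
reproduces outputs byte for byte.

## Known limitations

* The dwell accounting convention (each sample owns the interval to the
  next retained sample) attributes excluded-saccade and gap time to the
  preceding fixation's ROI; alternatives (capping intervals at the nominal
  period) change absolute dwell by the total excluded time but affect
  ipsi/contra *differences* only through share weighting.
* With few unique images, per-image geometry idiosyncrasies (landmark
  jitter interacting with the warp) add an image-set random effect to
  dwell differences; estimates over small image sets wobble accordingly.
* The pattern-change baseline band uses a single random split-half rather
  than averaging over many splits.
* Exact permutation enumeration is capped (20,000 splits / 2^20 sign
  patterns) before switching to Monte Carlo.
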