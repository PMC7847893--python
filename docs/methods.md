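# Methods

This note documents the models, parameter choices and numerical
conventions behind `zfplate`, and what the synthetic-data tests do and
do not establish about real recordings.

## Conventions

Pixels are 0-based, origin top-left; ROI rectangles are half-open in
both axes.  Frame indices are 0-based; all times are seconds from run
start.  Centroids are ROI-relative `(x, y)` floats with NaN marking
frames where no fish was found.  Motion value `i` is the delta-pixel
count between frames `i` and `i+1`, so a motion trace is one sample
shorter than its centroid trace.

The acquisition system's native file layouts are not published; the
`formats` module defines canonical CSV dialects (a `#`-comment header
carrying `fps`/`t0`/`plate_format`, then plain columns) chosen for
diffability and portability.  Readers are tolerant of surrounding
whitespace; writers emit one canonical form, and write∘read is the
identity on it.

## Tracking

Each 1-s clip's background is the per-pixel **mode** across its frames
(optionally stride-sampled), with ties broken toward the lowest
intensity.  The model assumes the fish occupies any given pixel in
fewer than half the frames of the clip; a fish that never moves during
a clip *is* the background and is reported as missing, which downstream
layers treat as a value, not an error.  Fish darker or brighter than
background are both handled via the absolute difference.

Segmentation thresholds the absolute difference at
`intensity_diff_threshold` (default 12 of 255; strict `>`), keeps
8-connected components of at least `min_blob_area` (default 4 px²), and
selects the largest component, ties broken by the smaller `(row, col)`
bounding-box corner.  The centroid is the unweighted mean of member
pixels.  Delta pixels use the same strict threshold on consecutive-frame
differences.  Both defaults are config-exposed: they depend on optics,
illumination and sensor noise, and should be recalibrated per rig.
Tracking is a deterministic function of the input bytes.

## Bouts and slow-speed metrics

A bout is a maximal run of motion frames strictly above
`motion_on_threshold` (default 2 delta pixels at 30 fps); runs separated
by fewer than `merge_gap_frames` (3) are fused, then runs shorter than
`min_bout_frames` (2) are dropped.  Distance/velocity metrics come from
the centroid trace with interior missing frames linearly interpolated —
interpolation happens only here, never at the tracking layer, so raw
traces stay honest.  A bout over motion frames `[s, e)` is measured on
centroid frames `s..e` inclusive; by the triangle inequality its
straight-line displacement never exceeds its path distance.

The "well-center" region for the thigmotaxis metric is the concentric
rectangle holding 50% of well area (an area-balanced null: a uniformly
distributed fish scores 0.5).  Sleep bouts are quiescent intervals of at
least 60 s, the standard larval criterion; waking activity is active
time per awake minute.  Time binning uses fixed-width bins assigned by
frame start time; bin sums conserve the grand total exactly (the last
bin may be partial), and bin means are time-weighted.

## Stimulus responses

Responses are scored inside a window after stimulus onset (the last
delay in the command string positions the strong stimulus inside the
clip; no delay means onset at frame 0).  Acoustic startles are scored
over 100 frames (~350 ms) — they are short-latency events — while
dark-flash responses may occur anywhere in the 1-s clip, so the visual
window is the whole clip.  The two trigger rules use the standard
operating thresholds: centroid movement > 0.9 px per frame sustained
for ≥ 2 frame steps, or delta pixels > 3.0 for ≥ 3 consecutive frames
(strict `>` on thresholds, `≥` on run lengths).  Latency is the first
frame of the earliest qualifying run under either rule; kinematic
metrics are accumulated from that frame to the window end.

Heading-angle sums skip steps under 0.25 px as positional noise and wrap
each successive turn to (−180°, 180°].  Note the polyline geometry: an
n-point semicircle sums to 180·(n−2)/(n−1) degrees, converging to 180°
only with dense sampling.

C-bend and O-bend filters are screening heuristics, not kinematic
measurements (body-curvature angles would need tail segmentation beyond
this data's resolution).  Defaults — C-bend: cumulative delta pixels
≥ 75 and mean velocity ≥ 40 px/s; O-bend: latency within 43–285 frames
(~150–1000 ms) and |heading sum| ≥ 90° — were calibrated on the
simulator such that escape-scale bursts pass the C filter and
spontaneous routine swims trigger the O filter in < 1% of stimulus-free
clips.  All cutoffs are config values and should be re-tuned per rig;
comparisons are inclusive at the cutoff.

## Assays

**Arousal threshold.**  The response curve (response fraction per
stimulus power) is fitted by bounded least squares with a 4-parameter
logistic in log₁₀ intensity; the threshold is the EC50, the intensity at
the floor/ceiling midpoint.  Floor and ceiling are bounded to [0, 1] and
the slope to [0.05, 20].  Five multi-starts (one data-driven, four
seeded random) dodge local minima; because starts and bounds are
expressed relative to the data's log-range, the fit is exactly
scale-equivariant.  Degenerate data — dynamic range under 0.1, as for a
flat curve — return an unsuccessful fit with a diagnostic message and a
NaN threshold, never a silent number.  At 12 intensities × 40 Bernoulli
trials the median recovered EC50 is within 15% of truth.

**Curve comparison.**  Extra sum-of-squares F test: the null model fits
one 4PL to the pooled points (4 parameters), the alternative fits each
curve separately (8); `F = ((RSS₀ − RSS₁)/4)/(RSS₁/(n − 8))` with the
F(4, n−8) reference distribution.  Fitting response *fractions* rather
than trial-level outcomes matches standard curve-comparison practice;
its size is close to nominal in simulation (see the acceptance suite).

**Prepulse inhibition.**  `%PPI = 100·(1 − p_PPI/p_control)`; NaN when
the control rate is zero.  Prepulse responders are excluded before any
rate is computed.  The exclusion quote-level unit is ambiguous between
fish and trial; the default excludes per-trial (only PPI trials whose
own prepulse elicited a response), which preserves power, with
`exclude="unit"` removing every trial of any prepulse-responding fish.
Magnitude metrics are averaged over responding trials.

**Habituation.**  Trials split into consecutive blocks (default 10);
the index is `1 − p_last/p_first`, NaN when the first block has no
responses.

## Group comparison

Metrics are computed independently within each (possibly overlapping)
section: time sections get bout/sleep/position metrics from slow-speed
traces, event sections get response metrics from the high-speed clips
whose events they contain.  Each metric is compared across groups with
the tie-corrected Kruskal–Wallis test (chi-square approximation; for
groups of ~6 the approximation is accurate to roughly 0.07 mid-range
and better in the tail).  Raw p-values are reported and counted at
p < 0.05 — screening practice — with an optional Benjamini–Hochberg
column that does not change the count.

SSMD uses unbiased sample variances; two zero-variance samples with
equal means give 0, with unequal means signed infinity.  The run-level
summary drops non-finite SSMDs, then takes a Gaussian KDE with Scott's
rule bandwidth on a 512-point grid spanning the data range ± 3
bandwidths; the peak is the grid argmax.  Metrics constant across all
fish carry no information and are skipped.

The baseline mixed model is `value ~ group + time_bin` (fixed) with a
per-fish random intercept, fitted by REML via statsmodels; the original
screen's exact specification is not published, so this formula is this
package's documented choice.  With one time bin it collapses to a group
comparison of means.

## Synthetic data

The simulator emulates the statistical structure the analyses assume,
with exact ground truth:

- **Spontaneous swimming**: a renewal process — exponential inter-bout
  intervals at 15 bouts/min by day and 3 by night, lognormal bout
  durations (median 0.3 s, σ_log 0.35), a correlated random walk within
  bouts (25 px/s, per-frame turns N(0, 25°)) reflecting off well walls.
  Bout boundaries are frame-accurate, with a minimum 5-frame gap and
  3-frame duration so the default detector recovers them exactly.
  Active frames draw Poisson(20) delta pixels (floored at 3); quiescent
  frames are 0.
- **Responses**: Bernoulli trials with logistic probability in log₁₀
  stimulus power (floor 0.02, ceiling 0.95, slope 1.5), EC50 13.17 by
  day and 31.43 by night — the day/night arousal asymmetry.  Stimulus
  power is 1000 × the amplitude field, so the a0.0005–a1 battery spans
  0.5–1000.  Lognormal latencies (acoustic median 15 ms, visual 250 ms),
  a 0.5 multiplicative prepulse-inhibition factor on two-delay acoustic
  commands, exponential habituation with a 20-trial time constant.
- **Rendering**: a dark ellipse (4 × 2 px axes, intensity 80) oriented
  along its motion over a flat background (200) with Gaussian sensor
  noise (σ 2) applied to the whole frame — noise on the fish too is what
  keeps any single intensity from dominating a pixel's histogram.
- **Plates**: column-interleaved two-group layouts, an events file, a
  sections file and a JSON manifest recording every ground truth; the
  entire dataset is a pure function of the spec's mandatory seed.

What passing synthetic tests shows: the algorithms implement their
definitions correctly and recover known structure at realistic signal
levels.  What they do not show: robustness to real-world nuisances the
simulator omits — uneven illumination, reflections at well walls,
debris, partial occlusion, multiple animals per well, camera rolling
shutter, or drift in stimulus delivery.  Threshold defaults carried to
a real rig need recalibration.

## Problem sizes

Defaults are sized so the whole suite runs quickly on one core: 12–96
simulated wells, runs of 1–30 simulated minutes, 48 × 48 px wells,
1-s clips at 285 fps.  Statistical checks use 100–500 replicates
(seeded), which bounds Monte-Carlo error at the few-percent level used
in the assertions.

## Known limitations

- Centroid-only kinematics: no tail or eye segmentation, so C-/O-bend
  classification is heuristic filtering of bulk responses.
- Per-clip mode background assumes the fish moves within each clip.
- One animal per ROI; multi-animal arenas are out of scope.
- The Kruskal–Wallis p-value is asymptotic; for very small groups an
  exact permutation test would be preferable.
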