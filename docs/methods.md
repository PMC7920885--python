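# Methods

`handmotion` quantifies open-surgery technical skill from overhead video of
an operator wearing two differently colored gloves (green = dominant hand,
orange = non-dominant hand), together with an observer-annotated event
timeline of the procedure. This note describes each stage's model, the
parameters that matter, the numerical choices, and what the synthetic test
harness does and does not establish.

## Glove tracking

Each video frame is segmented in HSV space: a glove is the set of pixels
whose hue (degrees, wrap-around supported), saturation and value fall
inside that glove's configured box. HSV rather than RGB distance makes the
segmentation tolerant of the brightness variation typical of operating
lights. Among the in-range pixels the largest 8-connected component is
selected — small same-colored specks elsewhere in the scene cannot steal a
detection — and the hand position is defined as the **center of the
component's minimal axis-aligned bounding box**. Using the bbox center
(rather than the pixel-mass centroid) is a fixed, documented convention;
the two differ by well under a pixel for compact blobs.

Detection is purely per-frame: no motion model, no smoothing, no carried
state. This is what produces the observed lock-on/re-acquire behavior —
when a glove leaves the field the track simply reports invalid frames, and
the first frame in which the color reappears is detected as if nothing had
happened. A component must contain at least `min_pixels` pixels to count
(default 30 at a 1920x1080 frame, scaled proportionally to frame area
otherwise). The two glove color boxes, and any distractor colors in a
synthetic scene, are required to be pairwise disjoint in HSV space; an
overlapping configuration is rejected up front.

Pixel coordinates use the image convention (origin top-left, x right,
y down); frame indices are 0-based. The HSV conversion is a vectorized
reimplementation verified against `skimage.color.rgb2hsv` to 1e-5 in a
unit test; it exists because the conversion dominates whole-video tracking
time.

## Kinematics at 1 Hz

Per-frame centroids are collapsed to one position per second (mean of the
valid centroids inside each whole second, marked invalid when fewer than
half of the second's frames have a valid detection) and then differenced:

* speed(k) = |p(k+1) − p(k)| in pixels/s,
* acceleration(k) = speed(k+1) − speed(k) in pixels/s per s,
* directional change θ(k) = unsigned angle in [0°, 180°] between the
  displacement vectors p(k)→p(k+1) and p(k+1)→p(k+2).

Averaging within the second before differencing suppresses detector pixel
noise that frame-rate differencing at 50 fps would amplify by the frame
rate. Three numerical conventions worth noting:

* **No interpolation across gaps.** Idle (out-of-frame) time is signal in
  this domain, not noise; every kinematic sample touching an invalid
  position is itself invalid.
* **Zero displacement has no direction.** θ for a second with zero motion
  is invalid rather than 0°, so stillness cannot masquerade as directional
  stability.
* All series are NaN-padded to the common 1 Hz grid (length =
  ⌊duration⌋ s) with explicit validity masks; speed has one fewer defined
  sample than there are positions, acceleration and θ one fewer than
  speed.

Speed and acceleration are translation- and rotation-invariant and scale
linearly with a rescaling of coordinates; θ is invariant to all three.
These invariances are property-tested to 1e-9.

## Joint entropy

For each feature the dominant-hand series X and non-dominant series Y are
discretized on a shared binning and the plug-in Shannon joint entropy

    H(X,Y) = − Σ_{x,y} p̂(x,y) log₂ p̂(x,y)

is computed from the joint histogram (empty cells contribute nothing;
p̂ = counts/n). Lower joint entropy corresponds to more regular,
predictable bimanual motion; the estimator is the bare maximum-likelihood
formula with no bias correction, whose bias is O(cells/n) and is checked
against the analytic value on uniform data (10,000 uniform pairs on 4×4
bins give 4.00 ± 0.02 bits).

Binning is the one genuinely free choice, and it is recorded in full
(edges, counts, sample sizes) in every result:

* speed and acceleration: 32 equal-width bins per hand spanning the pooled
  1st–99th percentile range of the two hands, tails clipped into the end
  bins. Joint support is therefore at most 10 bits, the same order as the
  7–9 bits such analyses report for real procedures.
* directional change: 8 fixed bins of 22.5° over [0°, 180°] (≤ 6 bits
  joint).

The percentile range is computed per procedure; no cross-operator
calibration is applied, so entropies are comparable only between runs that
used an identical binning policy — the policy is embedded in the output
for exactly this reason. Pairs are filtered pairwise per feature (a pair
is used when both samples are valid; each feature keeps its own maximal
pair set), and a feature with zero valid pairs is reported as *undefined*,
never as 0 bits, mirroring how a recording without colored gloves must be
handled.

## Procedure-timing metrics

A procedure timeline is a timestamped event stream: milestones
(`skin_incision`, `pectoralis_minor_divided`, `vessel_loop_passed`),
hand/instrument contact intervals, instrument in/out-of-incision
intervals, instrument pickups, and blunt/sharp dissection intervals.
After structural validation (matched interval events, per-instrument
in/out alternation, incision preceding all activity, disjoint dissection
modes) the eight observational metrics are computed:

1. total time = vessel-loop milestone − skin incision; a procedure with no
   vessel-loop milestone is **censored** at the time limit (default
   1200 s): reported as "> 1200", flagged, excluded from group means,
   never silently averaged;
2. idle time = measure of the union of instrument out-of-incision
   intervals, clipped to the procedure window;
3. active time = measure of the union of contact and dissection intervals
   (simultaneous bimanual activity is not double-counted);
4. time from incision to pectoralis-minor division;
5. instrument changes = transitions between *distinct* instruments in
   pickup order (re-picking the same instrument is not a change);
6–7. blunt and sharp dissection time;
8. per-instrument in-incision durations;

plus active/idle ratio, sharp/blunt ratio and idle as % of active
(undefined ratios are reported as undefined, not 0). Active and idle
derive from different event families, so active + idle need not equal
total — real per-operator panels show the same non-additivity.

All interval arithmetic is carried out in integer milliseconds (event
times are quantized to a 1 ms grid, intervals half-open [start, end)), so
sums are exact for ms-resolution annotations and the synthetic round trip
below is an equality, not an approximation.

## The synthetic harness

Because surgical recordings cannot ship with a package, every stage is
exercised against generated data with known ground truth.

**Motion model.** Each hand carries a velocity that relaxes toward
`base_speed` (default 100 px/s) along a heading re-drawn at
Poisson-distributed events (`direction_change_rate`, default 0.2 /s),
perturbed each frame by an isotropic Gaussian velocity kick of scale
`jitter_sd` — an Ornstein–Uhlenbeck-style process integrated at the frame
rate (default 50 fps) with a 0.1 s relaxation time. Positions are kept in
frame by reflecting walls, each hand confined to its own half of the
frame (dominant left, non-dominant right, separated by more than a blob
diameter) so the blobs never occlude each other. Idle is modeled as the
hand leaving the frame: the idle budget (`idle_fraction`, default 0.2) is
carved into a few contiguous bouts (~15 s average) whose total matches the
requested fraction to within one frame. All randomness flows from a
single seed; a fixed seed gives bit-identical output.

`jitter_sd` is the skill knob: presets use 2 px/s (expert), 10 px/s
(resident) and 20 px/s (novice) with **all other parameters equal**, so
entropy contrasts between levels are attributable to motion roughness
alone. The short relaxation time matters here: purposeful motion stays
tightly concentrated around `base_speed`, so the per-second speed
distribution is a sharp peak plus a turn-induced tail whose extent fixes
the percentile binning range, and increasing jitter broadens the peak
across more bins. This yields a monotone jitter→entropy response
(Spearman ρ > 0.9 along a jitter ladder) and reproduces the qualitative
ordering experts < residents < non-surgeon novices in ≥ 9/10 seeds at
600 s per operator. With a long relaxation time the response flattens,
because percentile-ranged equal-width binning is scale-invariant and a
noise-dominated speed distribution has a nearly shape-invariant histogram.

**Rendering.** Scenes are drawn as solid filled circles (radius 10 px by
default) on a gray background in a 640×480 frame — tracking is
color-based, so shape and texture are irrelevant. Distractor blobs in
non-glove colors follow deterministic circular paths and are drawn beneath
the gloves. Video is written as zlib-compressed multi-page TIFF with a
per-frame ground-truth CSV sidecar.

**Timelines.** `generate_timeline` builds a valid event stream whose
computed metrics equal the requested targets exactly: idle intervals are
realized as out-of-incision bouts of a primary instrument, active time as
a single contact interval containing the dissection intervals, and
pickups cycle through distinct instruments. Round-trip equality is
property-tested over random valid targets, censored cases included.

**What the harness does not show.** The generator is a test harness, not
a validated model of surgeon hand motion: no published distributional
description of real intraoperative hand kinematics exists to calibrate
it. It omits occlusion by instruments or the operator's body, lighting
variation and shadows, glove-color degradation (blood), camera shake,
hand crossing, and any correlation between the two hands' motion.
Passing tests therefore establish the *correctness of the measurement
chain* (tracking recovers known positions to sub-pixel accuracy, entropy
matches enumeration oracles, metrics invert their generator exactly) and
the *qualitative direction* of the skill–entropy relationship under the
stated motion model — not absolute entropy values for real procedures,
which additionally depend on camera geometry and binning policy.

## Problem sizes and defaults

| Parameter | Default | Why |
|---|---|---|
| frame rate | 50 fps | consumer-camera recording rate the pipeline targets |
| kinematic resolution | 1 s | within-second averaging suppresses detector noise |
| speed/acceleration bins | 32 over pooled P1–P99 | ≤ 10 bits joint support, order of reported values |
| direction bins | 8 × 22.5° | fixed physical range [0°, 180°] |
| `min_pixels` | 30 at 1080p, area-scaled | rejects specks without dropping a real glove |
| time limit | 1200 s | 20-minute procedure cap; censoring threshold |
| base_speed / relaxation | 100 px/s, 0.1 s | concentrated purposeful-motion speed peak |
| jitter presets | 2 / 10 / 20 px/s | expert / resident / novice contrast |
| acceptance video | 60 s, 640×480, 50 fps, 2 distractors | full tracking chain at a tractable render size |
| skill-ordering runs | 10 seeds × 3 levels × 600 s | estimator noise well below the level gaps |

## Known limitations

* Entropies are in camera-pixel units' bins: comparisons across rigs
  require the same camera distance/angle and binning policy.
* The plug-in estimator is biased upward for sparse histograms; with the
  default 32² cells and ≥ 300 valid seconds the bias is material (~1 bit)
  but common to all operators under the same policy, so orderings stand.
* Fine-motor (finger/carpal) kinematics are out of scope; the tracker
  reports one point per hand.
* Event timelines come from human annotation (or the generator); the
  package does not infer procedure events from video.
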