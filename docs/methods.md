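# Methods

## Scope and data model

The package quantifies crawling behavior of *C. elegans* on linear NaCl
gradients (and on/off bacterial food) from centroid trajectories, and
analyzes two kinds of physiological readouts: fluorescence calcium traces
and luminescence concentration–response series. All positional analysis
runs on a uniform 2 frames/s grid (dt = 0.5 s), matching the acquisition
rate of the assay it models; imported trajectories with jittered timestamps
are snapped to that grid with a warning. Coordinates are arena millimeters;
the gradient is a `GradientSpec` — an affine map from the coordinate along a
unit axis (default +y) to concentration, clamped at the plate edges. The
standard plate is 0–100 mM over 120 mm with release at the 60 mm midpoint
(~50 mM). Reported positions are axis coordinates relative to the release
point; add `release_mm` to convert to plate-edge coordinates.

## Tracking

Worms are dark blobs on a bright arena. Detection: per-pixel mean of the
whole stack as background (a rolling alternative was considered and
rejected — the assays are short and illumination static), foreground =
background − frame clipped at zero (a polarity flag covers bright worms),
Gaussian smoothing, fixed intensity threshold, 8-connected components,
single-animal area gate, intensity-weighted centroids. Linking is greedy
mutual-nearest-neighbor between adjacent frames under a displacement cap.
Tracks end rather than guess: a missing detection (no gap bridging), two
tracks claiming one detection (collision — both end), two detections
equidistant from a track (ambiguity), or a centroid entering the border
margin (default 2× the blob-radius estimate from the median detection
area). Downstream index code tolerates one animal contributing several
track fragments, so ending early is cheap and linking errors are expensive
— hence the conservative rules. Tracks shorter than 5 min are discarded;
survivors are converted to mm, smoothed with a centered 1.5 s (3-sample)
moving average whose half-window shrinks symmetrically at the ends (an
affine path is reproduced exactly, so constant-velocity speed is exact),
and speed is |Δxy|/dt with the first interval duplicated to sample 0.

## Behavioral-state segmentation

Explicit thresholds on the smoothed path, all configurable
(`SegmentationParams`):

- **pause** — in the 10 s window centered on the sample (truncated at track
  ends), strictly more than half of the samples have speed < 0.01 mm/s.
  Exactly half is not a pause.
- **turn core** — the vertex angle at the sample, between the first points
  ≥ 0.3 mm behind and ahead along the path, is strictly < 80° (a straight
  path gives ≈180°). Samples whose ±0.3 mm arcs run off the track end, or
  whose chord collapses to zero length (a path looping onto itself), are
  not evaluable and never cores. The alternative reading of the angle — the
  complement, between the incoming and outgoing chords — is available via
  `angle_convention="complement"`.
- **turn** — cores plus a forward-only extension over contiguous samples
  with speed < 0.1 mm/s (a post-turn stationary sample belongs to the turn,
  which also fixes the pause/turn overlap: precedence is
  turn/pirouette > pause > run).
- **pirouette** — successive turns with gaps strictly < 3.8 s chain into one
  reorientation event spanning first start to last end; the gap samples are
  relabeled pirouette.

Arc lookup uses the exact sample at which the cumulative path length
crosses 0.3 mm (no interpolation), keeping labels sample-aligned. Every
rule has a brute-force oracle in the test suite (direct re-evaluation of
every window, arc and angle per sample, plain loops); pipeline and oracle
must agree on 100% of samples across randomized tracks.

Runs are the maximal unlabeled intervals; their direction is the sign of
net axis displacement (exactly zero → "tie", counted in neither direction).

## Navigation indices

Per animal, over an analysis window (default 0–600 s with ≥ 300 s of track
presence required; a 0–300 s preset exists for single-worm stage-tracking
assays). Tracks failing the presence requirement are dropped, which also
keeps one track per animal; surviving same-id fragments keep the longest.

- **chemotactic** = mean signed axis velocity / mean speed, both means over
  the same displacement intervals, so the ratio is bounded by ±1 by
  construction and the 6-min-up/4-min-down worked case gives exactly +0.2.
- **BRW** = fractional difference of mean run durations by direction. Runs
  clipped by the window contribute their in-window duration. An empty
  direction contributes mean 0 (a one-sided animal scores ±1); an animal
  with no runs is undefined.
- **klinotaxis** = fractional difference of counts of post-reorientation
  runs classified up/down by their first 5 s of net axis displacement; runs
  shorter than 5 s (another behavior started) are discarded; undefined when
  nothing qualifies.

All three negate exactly under reversal of the gradient axis, which the
tests assert to 1e−12. Population aggregation is a separate explicit step
(the acceptance script uses means; the report writer emits medians,
quartiles and Tukey 1.5×IQR whiskers, with linear-interpolation quartiles
so small-sample values are reproducible).

## Foraging

On food: speed and angular speed (|wrapped heading change|/dt, headings
from successive displacements) are averaged over non-overlapping 10 s bins
aligned to track start (incomplete trailing bin dropped); roaming iff
speed strictly exceeds angular_speed × (1/450) (mm/s)/(deg/s) — on-line
and undefined-heading (static) bins are dwelling. The 450 constant's units
are a convention choice exposed in config. Off food: segmentation state
fractions (summing to 1) plus mean speed including pause samples.

## Physiology

ΔF/F0 (%): a per-sample background stream is reduced to its median before
subtraction; F0 is the mean corrected fluorescence over the 10 s
pre-stimulus window; F0 ≤ 0 is a hard error. ΔR/R uses R = YFP/CFP — the
standard orientation for yellow-cameleon indicators; the reciprocal is one
flag away since the field's phrasing is often ambiguous.

Concentration–response: wells are normalized to the total calcium response,
ligand/(ligand + lysis) (the alternative reading, ligand/lysis alone,
differs only by a monotone transform and was not adopted), then expressed
as percent of the series maximum. The fit is a variable-slope
four-parameter logistic on log10 concentration with all replicate wells as
observations (replicate-mean fitting is a flag); initialization is
bottom = min, top = max, hill = 1, logEC50 at the half-range crossing by
linear interpolation. Constant series are flagged before fitting (no
inflection); a non-positive Hill slope at the optimum flags the result.
EC50 standard errors come from the asymptotic covariance by the delta
method.

## Synthetic data

The locomotion simulator is the package's ground-truth source, not a
fixture: a continuous run/turn/pause state machine sampled at 2 Hz.

- Run speed ~ truncated normal (0.12 ± 0.03 mm/s), per-step wrapped-Gaussian
  heading jitter (10°).
- **Biased random walk** enters as run-termination modulation: per-step
  termination probability λ0·dt·(1 − β·cosφ) clamped to [0, 1], φ the angle
  to the up-gradient axis — runs pointed up last longer when β > 0. Speed
  itself is unmodulated, matching the behavioral observation that
  experience changes run *duration*.
- **Klinotaxis** enters at reorientation: the new heading falls in the
  up-gradient half-circle with probability (1 + κ)/2, uniform within the
  chosen half — the simplest mechanism the klinotaxis index detects while
  leaving run durations untouched.
- Reorientations are single 2 s low-speed (0.04 mm/s) turn cores or, with
  probability 0.3, pirouette bursts of 2–4 cores separated by 0.5–3.5 s
  gaps. Poisson pauses (rate 0.01 /s, mean 4 s) freeze the worm with ~µm
  jitter. Boundaries reflect by default; a truncate mode ends tracks at the
  edge for tracker tests. Defaults are order-of-magnitude choices typical
  of young-adult crawling; no empirical duration distributions are claimed.
- Seeds: one master seed; worm *i* uses `SeedSequence((seed, i))`, so
  populations are reproducible under reordering and all generators are pure
  functions of (params, seed).

The renderer draws dark Gaussian blobs (σ = 2 px at 4 px/mm) on a bright
uint8 background with optional Gaussian noise; overlapping worms merge —
deliberately, as a tracker test case. `grid_population` confines worms to
padded grid cells for guaranteed-collision-free fidelity tests.

Calcium traces are F = bg + baseline·(1 + A/100·k(t)) with k either a
plateau step or a rise–decay double exponential normalized to unit peak on
the sampled grid, so the noiseless peak ΔF/F0 equals A exactly; the FRET
variant scales two channels by independent percentages (±10% gives a
+22.2% ratio step). Dose–response tables draw the normalized response from
the four-parameter logistic plus Gaussian noise and emit a consistent
ligand/lysis luminescence pair, so normalization reproduces the noisy value
exactly and the noiseless fit must recover all four parameters.

### What the generators do and do not emulate

They reproduce the statistical structure the analysis rules key on — state
durations, heading statistics, gradient biases, blob appearance, response
shapes — but not worm posture (centroid only, as the analysis is
centroid-based), lawn boundaries, collisions between real animals' bodies,
photobleaching, or motion artifacts in traces. Passing tests therefore
validate the computations, not the biology of any particular recording.

### Known estimator interactions

The two biases are not perfectly separable by the indices: with β > 0,
down-gradient post-reorientation runs terminate sooner and less often
survive the 5 s klinotaxis qualification, so the klinotaxis index inherits
a positive bias (≈ +0.14 at β = 0.6, κ = 0). Symmetrically, with κ > 0
undetected small-angle turns merge consecutive runs whose headings are
up-biased, nudging the BRW index positive (≈ +0.2 at κ = 0.6, β = 0). Both
leaks vanish at the null and do not affect single-bias monotonicity, which
is what the calibration checks assert.

## Problem sizes and numerical choices

Simulation-based checks use 200 worms × 30 min per condition (population
means stabilize to ±0.02 at that size), 10 worms × 10 min for tracker
fidelity, and 200 seeds for EC50 coverage; the acceptance script reports
EC50 recoveries as geometric means over 20 independent noisy fits
(noise sd 0.02 on the normalized scale, triplicate wells — typical for the
luminescence assay). Curve fits run with tight tolerances (1e−14) so the
noiseless inversions hold to 1e−6 relative. Strictness conventions
(strict < on thresholds, strict majority for pauses, ties excluded from
both directions) are fixed and tested at the boundary values.

## Limitations

- No identity preservation through collisions and no gap bridging; the
  analysis is designed around track fragments instead.
- No reversal-vs-omega discrimination — both are "turns" by construction of
  the angle rule.
- Shape descriptors beyond blob area are not retained.
- Inferential statistics between experimental groups are out of scope; the
  package emits per-animal values and descriptive summaries only.
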