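# Methods

This note records the models, conventions and design choices behind
`oculomaze`, in the spirit of a statistical package's methods
documentation.  Nothing here states a number the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and gaze ratios

Landmark streams use normalized image coordinates with **y increasing
downward** (the face-mesh convention).  Each eye contributes four iris
landmarks and four contour landmarks (outer corner, inner corner, upper
lid, lower lid).

The pupil is the center of the **minimum enclosing circle** of the iris
landmarks, computed with Welzl's recursive algorithm.  Inputs are at most
16 points, so no randomized restructuring is needed; duplicates are
removed first.  Collinear boundary triples fall back to the widest
covering pair.  The test suite checks the result against two independent
oracles: an exhaustive search over all pair-diameter and triple-circumscribed
circles, and GEOS's minimum bounding circle (via shapely).

Gaze ratios use **axis projections**, not Euclidean distances — the
horizontal pupil-to-outer-corner distance over the horizontal corner-to-
corner distance, and likewise vertically — because the quantities being
normalized are horizontal and vertical displacements:

- lateral: `|x_p − x_outer| / |x_inner − x_outer|` ∈ [0, 1]
- anteroposterior: `−|y_p − y_upper| / |y_lower − y_upper|` ∈ [−1, 0]

The anteroposterior ratio is **negative by construction** (the negated
normalized pupil-to-upper-lid distance), so mid-height gaze reads −0.5;
this sign convention matches the displacement tables the reporting layer
emits.  A pupil detected marginally outside the contour box (landmark
jitter) is **clamped** into range with a per-frame warning rather than
rejected: a streaming pipeline should degrade gracefully, and the
overshoot cases observed in practice are fractions of a percent.  Zero
eye width or height raises `DegenerateGeometryError`.

In monocular sessions the occluded eye's fields are **absent (`None`),
not zero** — zeros are legal gaze values.  The CSV export layer renders
absent signals as `0.00` to match the device's session tables.

## Zone control

The five-zone layout is a center rectangle in ratio space with four
half-plane zones.  Defaults: center (0.5, −0.5), band half-width 0.12
per axis.  STAY requires both ratios strictly inside the band; a sample
on or beyond a border commands a direction.  When both axes exceed their
band, the axis with the larger **band-normalized** deviation wins, ties
going to the lateral axis — deterministic, and reproducing a plus-shaped
partition.  The exact zone borders are an implementation choice: the
rectangular-band reading was adopted over diagonal sectors because it is
fully specified by four thresholds and trivially calibratable.

Calibration from a central-fixation baseline (≥ 10 samples) sets centers
to per-axis **medians** and half-widths to `max(margin, k·IQR)` with
defaults margin = 0.10, k = 1.5 — robust to blinks and outlier frames,
and idempotent at the returned center.  The session distance gate is
400–500 mm inclusive at both ends.

No command smoothing is applied by default (none is modeled in the
original workflow); the engine consumes commands tick by tick, so a
majority-vote window can be layered on the command stream by the caller.

## Maze engine

Discrete cell grid, one ball cell, fixed tick duration (default 100 ms);
all timing is `ticks × tick_ms` exactly, which makes sessions replayable
bit for bit.  Collision semantics: a tick whose move is blocked by a wall
leaves the ball at the last free cell and counts **one error per blocked
tick** — pressing into a wall for n ticks accrues n errors.  This is the
simplest deterministic reading of "collisions with maze walls" and is
what the scripted bot's ground truth asserts.

Checkpoint times are measured **from level start**, and each level times
three checkpoints: two numbered zones and the finish ({1: [2, 4, F],
2: [3, 7, F], 3: [6, 11, F], 4: [3, 7, F], 5: [9, 6, F]}).  The original
device's five layouts are not published, so the package ships five
**serpentine corridor fixtures** of increasing size as versioned JSON:
a single corridor partitioned into numbered zones along the path, which
makes shortest paths unique and ground truth checkable by hand.  Level
5's zone numbering is permuted along the path so its checkpoints are
visited in the documented order (zone 9 before zone 6).  Fixture grids
are coarser than the 128×64 target display to keep the JSON
human-readable; the engine is grid-size agnostic.

An aborted level (command stream ends before the finish) records the
progress made so far; an aborted session keeps its completed prefix.

## Session metrics

Displacement extremes are per-signal maxima/minima over the trace, with
binocular extremes taken over the **pointwise-mean signal** — so when
the two eyes peak at different times the binocular extreme is strictly
inside the mean of the per-eye extremes, an inequality the property
suite checks.  The displacement ellipse is axis-aligned with center at
the midranges and semi-axes at the half-ranges.

The performance ratio is `total_ms / errors` rounded to 2 decimals;
zero-error sessions have **no defined ratio** (`None`, exported as an
empty cell) rather than infinity.  The bundled published session table
reproduces to 2 d.p. for the arithmetically consistent rows and to
±0.02 elsewhere; the +0.01 residuals indicate the original device
divided unrounded totals before printing, the convention adopted here.

All standard deviations are **sample (n−1)** throughout; this is the
convention under which the bundled survey's aggregate STD reproduces.
CV is `100·σ/|μ|` (undefined at μ = 0), invariant under sign flips, so
negative-mean anteroposterior signals print positive CVs.

## Statistics

Progress regressions are ordinary least squares (scipy), with
R² = 1 − SS_res/SS_tot and a **two-sided** t test (n−2 df) on the slope,
reported for n ≥ 3.  A constant response returns slope 0, R² 0, p 1.  A
numerically perfect fit clamps p into (0, 1].

The fixation-validation ANOVA is a balanced two-factor fixed-effects
model with interaction (user × movement axis), fitted via statsmodels
`ols` + `anova_lm`; unbalanced or single-replicate designs are rejected.
A perfectly flat response is the 0/0 degenerate case and returns F = 0,
p = 1 by convention.  The test suite verifies the sums-of-squares
decomposition against hand-computed balanced formulas and its closure
(SS components sum to the directly computed SS_total to 1e−9).

Fixation-validation summary tables report, per user and gaze variable,
the grand mean and the **within-fixation pooled STD** — residual spread
about each (trial, segment) fixation's own mean, pooled over fixations —
with CV = 100·STD/|mean|.  Pooling raw frames across different fixation
targets would fold the programmed target separation (≈ 0.3 ratio units)
into the STD and produce CVs an order of magnitude above plausible
fixation stability; the within-fixation reading measures steadiness of
held gaze, which is what the protocol is for.

SUS scoring is the standard instrument: odd items contribute value−1,
even items 5−value, scaled by 2.5.  Category bands are ≤ 50 /
≤ 68 / > 68.  The cohort **acceptance rate is truncated** (not rounded)
to 2 decimals — the convention under which 13/15 prints 86.66 — and the
marginal rate is the complement, so rates total 100 up to truncation
loss.  Item-derived scores are always multiples of 2.5; ingested
precomputed scores are not required to be (the bundled survey itself
contains a 69), and a consistency warning is logged instead.

## Synthetic generators

The generators exist so every stage is testable against known ground
truth with no hardware.

- `landmark_frames_from_ratios` **inverts** the ratio construction:
  given programmed (lateral, anteroposterior) pairs it places the pupil
  and renders four iris points on the iris circle, so the gaze pipeline
  recovers the programme exactly in the noise-free case.
- **Noise model:** `noise_sd` is expressed in ratio units but applied as
  independent Gaussian jitter on the **pupil position** (scaled to image
  units by the eye extent), per frame and per eye.  Noise therefore
  propagates through the real enclosing-circle and ratio code, while the
  ratio-domain standard deviation equals `noise_sd`, making propagation
  predictions exact (RMSE ≈ σ, verified at σ = 0.01 over 10,000 frames).
- `TraceSpec` programs per-eye sinusoids (center, amplitude, period,
  phase, per-eye offsets).  The sampling rate of the original stream is
  not documented; **30 Hz** is the default and is configurable.
- The fixation protocol emulates the five-point validation sequence:
  three anteroposterior targets (top −0.2, center −0.5, bottom −0.8)
  then three lateral targets (right 0.2, center 0.5, left 0.8), 10 s per
  point, five trials per axis per user, with a small per-user offset so
  inter-user variability is nonzero.  Target placements are package
  choices at roughly 60% of the legal range — steady fixation at the
  anatomical extremes is not realistic.
- `maze_bot` plans the BFS shortest path through a level's checkpoints
  and injects scripted wall bumps at given ticks, guaranteeing
  `errors == len(script)` and `total_ms = len(commands) × tick_ms`.

All generators are seeded (numpy `default_rng`); identical specs produce
byte-identical output, and there are no unseeded entry points.

What the generators do **not** model: saccades, microsaccades, drift and
tremor dynamics; blinks and tracking dropouts; head motion and
perspective distortion of the landmark geometry; asymmetric or
non-Gaussian landmark noise.  Passing tests therefore demonstrate
correctness of the computational pipeline on idealized streams, not
robustness to real camera data.

## Numerical and sizing choices

- Enclosing-circle agreement tolerance 1e−9; gaze round-trip asserted at
  1e−9 noise-free and within 20% of σ for the noisy RMSE.
- Sinusoid extreme/ellipse recovery is checked on noise-free traces with
  periods whose quarter-cycles land exactly on the 30 Hz sample grid, so
  recovery is exact to float precision.  Under pupil noise the max/min
  of a trace is biased upward by the expected extreme of the noise —
  O(σ), irreducible by longer traces — so extreme-based amplitude
  estimates from noisy data overshoot; the noisy pipeline is validated
  through the RMSE check instead.
- Simulation sizes (10,000-frame noise runs, 1000 oracle point sets, 200
  ANOVA replicates, 20 s traces) keep the full suite under ~10 s while
  leaving Monte-Carlo error well below the asserted tolerances.
- The acceptance script derives every stream from the single `--seed`
  via a root generator; sub-seeds stay below 2³¹.

## Known limitations

- The five maze layouts are package fixtures, not the original artwork;
  absolute times/errors from bot play are not comparable to published
  session tables (which come from human play on unpublished layouts).
- Per-patient displacement values in the original evaluation derive from
  unpublished raw recordings; the package reproduces their schemas,
  formulas and qualitative inequalities, not the values.
- The zone partition's diagonal behavior (dominance rule) is an
  implementation choice; the original device's exact border geometry is
  undocumented.
- Face detection and landmark inference are out of scope: the toolkit
  consumes landmark frames behind the JSONL adapter boundary.
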