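# oculomaze

A hardware-free toolkit for gaze-controlled maze therapy in amblyopia
monitoring.  Amblyopia ("lazy eye") therapy increasingly uses interactive
tasks that make the weak eye work; one such device tracks a patient's
eyes with a face camera and lets them steer a ball through on-screen
mazes by gaze alone, recording eye displacement and task performance as
engagement metrics.  `oculomaze` re-implements that device's entire
software stack as a testable Python library: everything downstream of the
camera — gaze estimation from facial landmarks, gaze-to-command control,
the maze game, the session analytics, and the usability reporting — with
seeded synthetic generators standing in for the hardware.

It is written for researchers and engineers building or evaluating
gaze-controlled rehabilitation tools who need a reproducible reference
pipeline rather than a physical device.

## The model

**Gaze from landmarks.** Each video frame provides 8 landmarks per eye:
4 iris points (face-mesh indices 469–472 right, 474–477 left) and 4
contour points (outer/inner corner, upper/lower lid).  The pupil is the
center of the minimum enclosing circle of the iris points (Welzl's
algorithm).  Gaze is then two dimensionless ratios per eye:

```
lateral          r  = |x_pupil − x_outer| / |x_inner − x_outer|   ∈ [0, 1]
anteroposterior  r_V = −|y_pupil − y_upper| / |y_lower − y_upper| ∈ [−1, 0]
```

so a centered pupil reads (0.5, −0.5).  Binocular sessions use the
pointwise mean of the two eyes; monocular sessions track the therapy eye
only.

**Control and game.** The ratio plane is divided into five zones — a
central STAY rectangle (default center (0.5, −0.5), half-width 0.12,
re-calibratable per user from a central-fixation baseline) and four
directional zones mapped to UP/DOWN/LEFT/RIGHT.  Commands drive a ball
across a discrete grid maze; blocked moves count as collisions (errors),
and each level times the first entry into three checkpoints (two numbered
zones, then the finish: level 1 → zones 2, 4; levels 2 and 4 → 3, 7;
level 3 → 6, 11; level 5 → 9, 6).

**Analytics.**  Sessions are summarized by per-signal displacement
extremes and their axis-aligned ellipse (center = midrange, semi-axes =
half-ranges), the performance ratio `total_ms / errors` (ms per
collision), segment statistics (mean, sample STD, CV = 100·σ/|μ|), OLS
progress regressions with R² and two-sided *p*, a balanced two-way
user × movement ANOVA for fixation validation, and System Usability Scale
scoring (odd items value−1, even items 5−value, ×2.5; bands ≤50 / ≤68 /
>68).

## Worked example

Score the bundled 15-respondent usability survey and play a scripted
session (see `examples/` for one script per capability):

```bash
$ oculomaze sus
n = 15
mean score = 75.60
sample std = 9.09
counts = {'Acceptable': 13, 'Marginal': 2, 'Unacceptable': 0}
acceptance rate = 86.66%
marginal rate = 13.34%
```

A mean SUS of 75.6 is "good" usability; 13 of 15 respondents rate the
device Acceptable and none Unacceptable.

```bash
$ python examples/03_play_maze_session.py
  ID  Level  Time-CHKP-1 (ms)  Time-CHKP-2 (ms)  Total Time (ms)  Errors  Performance Ratio (ms/E) Operation
demo      1               900              2200             3600       3                   1200.00       Bin
demo      2              1800              4600             6400       3                   2133.33       Bin
...
session total: 37800 ms, 15 errors
```

The bot deliberately bumps a wall three times per level, so the Errors
column is known ground truth; checkpoint times are first entries into
each level's two timed zones, and the performance ratio is milliseconds
of play per collision.

The CLI also offers `simulate` (synthetic landmark streams, fixation
protocols, sessions), `analyze` (displacement metrics from a stream),
`report` (progress regressions) and `validate` (fixation-validation
tables and ANOVA); the library API is the primary interface.

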