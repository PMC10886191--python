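# Methods

## Scope and model

The package implements a continuous ergonomic-assessment pipeline for
upper-body joint-angle streams recorded at a fixed sampling rate
(default 60 Hz), as produced by wearable inertial motion-capture
systems after sensor fusion.  Sensor fusion itself, calibration, video
coding and questionnaires are out of scope: joint angles, subtask
annotations and load events are consumed as plain-text CSV inputs.

Scoring follows the RULA structure: local angle bins, Table A for each
arm–wrist chain, Table B for the neck–trunk–legs chain, muscle-use and
force/load adders, and Table C for the 1–7 grand score per side.  The
numeric bins and the three tables are not an invention of this package;
they are encoded verbatim from the original published RULA worksheet as
CSV fixtures (144 + 72 + 56 cells) validated by range and monotonicity
tests.  Inputs to Table C of 8 or more collapse onto its 8+ row/column,
which makes the grand score total and saturating.

### Angle conventions and bin boundaries

All angles are degrees, flexion positive, extension negative.  Bin
boundaries are half-open and lower-inclusive: a value exactly on a
boundary takes the higher bin (20° of shoulder flexion scores 2, 60° of
elbow flexion scores 1).  A single stated convention makes per-frame
scores reproducible bit-for-bit on continuous streams.  Neutral-posture
bins use a 1° tolerance for wrist and trunk (`wrist_neutral_eps_deg`,
`trunk_neutral_eps_deg`): continuous angle streams never hit 0 exactly,
so a literal zero test would make the score-1 bin unreachable.  The
neck has no neutral tolerance — its worksheet bins start at 0–10° — and
any neck extension takes the worksheet's extension base score of 4.
Trunk forward and backward lean are binned by magnitude.

### Unmeasured worksheet inputs

The emulated protocol measures 12 angle types (18 channels: six
bilateral, three head, three trunk).  Worksheet inputs that angles
cannot provide are session-level defaults, overridable per run
(`RulaDefaults`): shoulders never raised, legs and feet always
supported, posture neither static beyond the criterion nor repeated
four or more times per minute (muscle-use adder 0).  Two adjustments
are driven by configurable proxy predicates on upper-arm
internal/external rotation (`ScoringAdjustments`):

* upper-arm abduction: |rotation| > 30°, **off by default** to stay
  faithful to the minimal measured set;
* lower-arm "across the midline or out to one side": |rotation| > 45°,
  **on by default** — without this +1 the lower-arm score could never
  exceed 2 on streams whose elbows sit in the 60–100° bin, yet observed
  lower-arm means in this kind of work sit between 2 and 3.

The wrist "bent from midline" +1 uses a 10° radioulnar-deviation
threshold, and wrist twist scores 2 beyond 60° of pronosupination; both
are configurable because the worksheet words ("bent from midline",
"near end of range") do not fix numeric values.

### Force/load adder

Load events are intervals with a mass and static/repeated and
shock/rapid-build-up flags.  The adder at a frame uses the maximum mass
over active events: 0 below 2 kg intermittent, 1 for 2–10 kg
intermittent, 2 for 2–10 kg static/repeated, 3 above 10 kg or with any
shock flag.  Pushing or pulling rolling equipment is represented as a
load event whose mass is the annotated effective load; the engine does
not distinguish push from lift.

## Segmentation and features

Intervals are half-open `[start, end)` everywhere, so annotation
partitions never double-count frames.  Annotation time is mapped onto
the kinematics clock by an affine fit through the two hand claps;
offset-only synchronisation is the degenerate case (scale 1), and a
rescale factor outside [0.99, 1.01] is rejected as implausible drift.

Frames with any missing channel are dropped from scoring and from every
feature denominator, with a logged count — per-frame RULA needs the
full posture, and percentages must use scored frames only.  Frames not
covered by any annotation carry the reserved label `(unassigned)`:
excluded from per-subtask features, included in session-global ones.

Per segment and side: mean/SD of the grand score, mean/SD per
anatomical area, percentage of scored time per grand band, and
percentage of time at a risky level, i.e. local score **at or above**
the per-area threshold (inclusive: with the lower-arm threshold at 2 of
a maximum of 3, only the inclusive reading can produce the near-90%
elbow exposures typical of cleaning work).  The wrist area uses the
combined wrist-and-hand score (posture + twist, range 2–6, threshold
5).  Cross-participant summaries average participant means — each
participant contributes equally regardless of segment length — with
sample SD (n−1) across participants; within a segment the SD is the
population SD of its frames.  Single-participant summaries report SD 0
by convention.

## Inference

Participant × group matrices of mean grand scores (complete blocks
required; missing cells are a hard error, with an optional
drop-incomplete mode) feed:

* **Friedman omnibus** (scipy's implementation: average ranks, standard
  tie correction, df = k − 1).  Perfectly concordant blocks give the
  closed form χ² = n(k − 1); fully tied blocks give 0.
* **Pairwise Wilcoxon signed-rank post hocs**, run only after a
  significant omnibus, two-sided, with the exact null distribution for
  n ≤ 25 non-zero pairs.  The distribution of the positive rank sum is
  built by convolution over doubled ranks — equivalent to enumerating
  all 2ⁿ sign assignments, exact also under tied average ranks — and
  p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))).  Zero differences are
  dropped (classic convention); an all-zero pair records p = 1 with a
  degenerate flag.  Larger n falls back to the normal approximation.
* **Significance counts**: per group, the number of pairwise
  comparisons with p < α (default 0.05), raw by default — at n = 8 the
  exact two-sided floor is p = 2/2⁸ ≈ 0.0078, and corrected counting
  would leave almost nothing — with Holm correction behind a flag.

With fewer than 6 pairs a two-sided exact test cannot reach p < 0.05; a
warning is logged.

## Synthetic studies

The generator emulates the study conditions the analysis assumes: 8
participants, one interval per subtask group (labels drawn from the
27-subtask coding scheme), brief unassigned transitions, 60 Hz, and
archetype durations that sum to a 40–60 min session.  Each channel is
drawn as archetype mean + participant offset + sinusoidal drift
(default 4° amplitude, 20 s period) + Gaussian noise (2–6° per
channel), clipped to ±180°.  This produces realistic bin-crossing
without modelling true human dynamics — the analysis consumes angles
only through bins, so richer biomechanics would add nothing testable.

Risk is designed in three tiers.  Twelve low-tier groups are ordinary
cleaning postures whose designed grand means sit close together in the
3–4 band; their profiles differ by channel (reaching up, mopping,
wrist-heavy scrubbing) but are balanced so that between-participant
variation, not the designed profile, decides their pairwise ordering.
Two medium-tier groups (patient transfer, box lifting) carry
intermittent > 10 kg loads whose active fraction varies strongly
between participants (0.12 ± 0.15 of the interval), yielding the large
between-subject SDs typical of handling tasks.  Three high-tier
"mover" groups (operating table, stretcher, trolley) carry 15 kg
effective loads over tiered fractions (0.95 / 0.80 / 0.65) with flexed
trunks, separating them from each other as well as from everything
else.

Between-participant variability is modelled as Gaussian channel offsets
drawn per participant × archetype × channel (SD 6°, shared between
sides) — each worker's own way of holding each subtask.  A single
per-participant offset would cancel in within-participant group
differences and make the Friedman/Wilcoxon blocks nearly deterministic,
so per-subtask offsets are what keeps the rank tests non-degenerate.

`duration_scale` shrinks every interval and transition by a common
factor, preserving the 17-group structure at a smaller problem size:
the analysis scripts use 0.2 (~8–9 min sessions) and the replicated
recovery experiment 0.08 (~3–4 min sessions), sizes at which segment
means are already estimated from thousands of frames.  A fixed seed
yields byte-identical studies; per-participant generators derive from
the master seed.

What passing tests on synthetic data do **not** show: the generator has
stationary per-interval posture distributions, no task dynamics, no
autocorrelated sensor error, no missing-data bursts, and designed
rather than observed effect sizes — so recovery rates here measure the
pipeline's correctness, not field sensitivity.

## Known limitations

* REBA/OWAS/EAWS and cumulative-exposure modelling are out of scope.
* The abduction and midline proxies are heuristic stand-ins for
  unmeasured worksheet inputs; their thresholds should be re-validated
  against any new sensor set.
* Exact post hocs are uncorrected by default; with 136 pairs the
  expected false-positive count under the global null is ~7 per side.
  Holm correction is available where that matters.
* The generator's archetypes are calibrated to a plausible
  operating-room cleaning regime, not fitted to any recorded data.
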