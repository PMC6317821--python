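# Methods

This note records the models and procedures implemented in `somnarch`, the
assumptions behind them, and the choices made where the design was genuinely
open. It documents what the code computes; every number quoted in the README's
worked example is produced by running the package.

## Sleep scoring from DAM counts

The Drosophila Activity Monitor reports infrared beam-cross counts per
channel. After binning to one-minute intervals, sleep is scored behaviorally:
a **sleep bout** is a maximal run of at least five consecutive minutes with
zero counts. Quiescent runs shorter than five minutes are wake and are
absorbed into the surrounding **motion bout**, so bouts alternate kind and
partition the analyzed minutes exactly. The five-minute threshold
(`min_sleep_min`) is exposed; raising it can only shrink total sleep and bout
counts, a monotonicity the test suite checks.

Minutes are half-open intervals `[t, t+1)`. Zeitgeber time is assigned so the
minute beginning at lights-on is ZT0; under the 12:12 light:dark cycle,
ZT `[0, 720)` is light and `[720, 1440)` is dark. Missing minutes (recording
gaps) are marked with an explicit mask and never zero-filled, because a zero
count *is* the sleep signal; any analysis window containing missing minutes is
rejected rather than silently patched.

**Dead-flagging.** A fly with fewer than 10 minutes containing at least one
beam cross in either the light or the dark phase of any fully covered day is
flagged dead and excluded downstream. "Activity" is measured in minutes, not
raw counts, because the criterion reads as a duration; the boundary is strict
(exactly 10 active minutes passes).

**Phase attribution.** A bout straddling a light/dark boundary contributes its
minutes to each phase for sleep totals but is counted once, in its onset phase
and day, for bout-number and duration statistics. This is the only rule that
keeps both the minute-conservation identity (sleep + wake = phase length) and
per-phase bout counts well defined; the attribution of straddling bouts is
otherwise underdetermined, so the rule is documented rather than inferred.

**Transition bouts.** Flies are aroused around lights-on and lights-off, so
the motion bout containing a ZT0 or ZT720 minute is flagged as a transition
bout; waking-activity statistics (beam crosses per minute awake) can exclude
these minutes to isolate steady-state wake activity. If a transition minute
falls inside a sleep bout, nothing is flagged for that transition.

**Bout-length distribution.** Sleep bouts are binned into
`[5,15), [15,51), [51,150), [150,500), [500,721)` minutes, reporting both
bout counts and summed sleep minutes per bin. The `[51,150)` bin is included
so the edges partition the range even where figures would omit it, and the
final bin is capped at 721 with longer bouts (possible when a bout spans
phases) assigned to it.

## Sleep deprivation and rebound

Mechanical deprivation (SD) occupies the last six hours of the dark phase
(ZT 1080–1440), ending at lights-on; the window is ZT-anchored, not
clock-anchored. All SD quantities compare against the ZT-matched window of
the baseline day 24 h earlier:

- **loss fraction** = 1 − (SD-window sleep)/(baseline-window sleep); flies
  qualify for rebound analysis only when loss > 60%. Zero baseline sleep
  leaves the loss undefined and the fly excluded with a recorded reason.
- **debt curve**: debt(t) = cumulative baseline sleep − cumulative observed
  sleep over the same ZT-aligned span from SD start, on the minute grid. Debt
  at SD end therefore equals baseline-window sleep minus SD-window sleep as
  an exact identity; rebound sleep drives the curve back toward zero and may
  push it negative (excess).
- **recovery sleep** is sleep in the first three hours after SD ends;
  **excess** subtracts the matched baseline window.
- **time to maximum bout** is the time from SD end to the onset of the
  longest post-SD sleep bout, searched over 24 h by default (configurable); a
  bout already in progress at SD end counts from SD end, consistent with a
  fully sleeping post-SD fly having zero latency. Bout-duration statistics
  for the first two hours use bouts whose onset falls in that window.
- flies with no post-SD sleep have latency and time-to-max censored at the
  search horizon and flagged, not dropped.

Sleep minutes inside any window are taken from the full-trace bout
decomposition, so a quiescent run straddling a window edge is scored by its
full length.

## Survival quantification

Two summaries, selected per assay: the starvation assay uses the per-vial
median — the first time the Kaplan-Meier survivor function falls **strictly
below** 50% (touching 0.5 exactly does not trigger; vials never dropping
below 0.5, common under heavy censoring, have an undefined median) — and the
lifespan assay uses the per-vial Weibull scale.

The Weibull model uses S(t) = exp(−(t/scale)^shape), stated explicitly
because scale conventions differ across libraries; scale carries time units
and shape > 1 expresses the increasing hazard of aging cohorts. Fitting is
right-censored maximum likelihood,
`l = Σ_events log h(t_i) + Σ_all log S(t_i)`, maximized in log-parameter
space by Nelder-Mead from a deterministic initialization: an ordinary
least-squares line through `log(−log S_KM(t))` vs `log t` at event times with
S strictly inside (0, 1). The fit is therefore reproducible given the data.
Fixing shape = 1 uses the censored-exponential closed form, scale = total
observed time / number of events (the sample mean when nothing is censored).
Degenerate data — all event times equal, nothing censored later — drive shape
to infinity; this is detected and returned as the closed-form limit
(scale = the common time, shape = inf), flagged and marked non-converged.
Non-converged vials are reported and excluded from scale comparisons, never
silently replaced.

Escapes and accidental deaths are censored at their recorded times; survivors
at study end (89 d for lifespan) are censored there.

## Behavioral indices

- **Courtship index**: CI = 100 × courting seconds / 600, always against the
  full 10-minute trial; shorter trials are rejected.
- **Learning index**: LI = 100 × (1 − CI_trained / CI_naive), computed on
  condition means; negative values (courtship increase) are legal, and a zero
  naive mean leaves LI undefined.
- **Locomotion**: per-frame speed from central differences (one-sided at the
  ends), chosen over forward differences to reduce discretization noise at
  15 Hz; the oracle tests use the same stencil by design. A frame is "moving"
  when speed > 2 mm/s (instantaneous by default; a smoothing window is
  configurable upstream of the threshold). Running velocity averages speed
  over moving frames only, so it exceeds 2 mm/s whenever defined; a fly that
  never crosses the threshold gets NaN with a flag. Positions are in mm —
  calibration from the known 37-mm arena is the caller's explicit input,
  never inferred.
- **Stimulus response**: 60-s velocity windows aligned on the onsets of the
  first five pulse trains, each minus its own 5-min pre-onset baseline, then
  averaged across trains and, at cohort level, across animals. With 60-s
  inter-train spacing, earlier responses leak slightly into later baselines;
  for a 3-s, +4 mm/s square response this depresses the recovered peak by
  ≈ 2% (the worked example prints 3.92 mm/s), an accepted property of the
  published alignment procedure rather than a defect.
- **Mechanical stress**: per-vial fraction of upright flies after repeated
  vortexing, with raw counts preserved for SEM.

## DE-table conventions

Fold changes use the signed reciprocal convention (+x = x-fold up,
−x = x-fold down, linear ratio 1/x), so magnitudes inside (−1, 1) are
invalid and rejected. Printed p-values of exactly 0 are preserved and sort
below any positive p. Ranking ties break by p then gene name, making query
output order-stable. Serialization writes floats with `repr`, so
parse → write → parse is a bit-exact fixed point.

## Synthetic data: what it emulates, and what it does not

The generator is first-class, tested code; its defaults define the study
conditions the tests run under.

**Activity traces** are an alternating-renewal process: sleep and wake bout
durations drawn in continuous time from phase-specific laws at bout onset and
rounded to whole minutes (minimum 1, matching the minute-binned assay). Night
sleep bouts default to lognormal with mean 90 min and day bouts to mean
30 min — a modeling choice standing in for consolidated night sleep and
fragmented day siestas, not an empirically fitted law (no bout-length
distribution family is established for this assay). Wake bouts are
exponential (mean 30 min day / 15 min night); wake minutes carry Poisson
counts (mean 2/min) clipped to ≥ 1 so generator truth and the minute-level
quiescence rule coincide exactly; an off-by-default sub-threshold-wake
probability inserts zero-count wake minutes to exercise the caller's merging
semantics separately from the generator contract. A wake bout is forced to
cover every ZT0 and ZT12 minute, with a 30-min, 3× activity surge anchored
there, emulating transition arousal. Bouts straddling day boundaries continue
uninterrupted; phases are annotated per minute. (scenario, fly index) fully
determines the output via `numpy.random.default_rng([seed, fly_index])`.

The **SD operator** converts each sleeping minute in the window to an active
minute with a given per-minute efficacy (converted counts again ≥ 1), and
records the converted minutes. The **rebound** machinery has two forms: a
scenario-level multiplier on post-SD sleep-bout means (for debt-curve-shape
checks), and an operator that programs a known surplus of sleep minutes in
the recovery window by extending quiescent runs contiguously — every added
minute scores as sleep under the ≥ 5-min rule, so the programmed surplus is
exact generator truth (overshoot at most 4 min when a short quiescent run is
absorbed). The programmed-surplus route is what makes "mean measured excess ≈
programmed 80 min" a parameter-recovery test rather than a tautology.

**Survival cohorts** draw Weibull lifespans (defaults: scale 54 d, shape 4,
10 vials × 30 flies, censoring at 89 d) with optional uniform-time escapes.
**Trajectories** are a two-state (rest/run) Markov chain at frame resolution
whose stationary rest probability equals the requested rest fraction, with a
correlated-random-walk heading during runs, per-run speeds drawn from a
configurable law, and reflection at the arena wall.

What the generator does **not** model: circadian free-running rhythms,
temperature and feeding effects, inter-fly variability in activity rate,
sensor noise (missed or spurious beam crosses), and any coupling between
deprivation and subsequent sleep pressure beyond the explicit rebound knobs.
Passing parameter-recovery tests therefore shows the estimators are correct
under the stated renewal model, not that real flies follow it.

## Numerical choices and problem sizes

- Bout calling is run-length encoding on the zero-count indicator; ties and
  boundaries are exercised against an independent per-minute scanner on 10⁴
  random traces (lengths 1–1440) in the acceptance suite.
- The Weibull recovery study uses 200 vials × 30 flies (scale 54, shape 4,
  censor 89 d) and checks median relative scale error < 5%; the rebound
  study uses 150 three-day flies with full-efficacy SD. These sizes give
  Monte-Carlo standard errors comfortably inside the tolerances while the
  whole acceptance script completes in seconds.
- Stochastic assertions compare means against 3 × SEM (computed from the
  sample) plus a small absolute floor, so they scale with the noise actually
  realized rather than hard-coding a band.

## Known limitations

- Only single-beam DAM counts are supported (no multi-beam position data).
- The DAM reader accepts the 42-column monitor dialect and a long-format
  CSV; other firmware dialects would need a new column map.
- `somnarch sd` analyzes whichever flies the trace file contains; pairing
  deprived and undisturbed control groups is left to the caller.
- The Weibull fit reports but does not correct small-sample bias of the MLE
  (shape is noticeably biased upward at n = 30; scale is not).
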