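"""Synthetic generators for every input the pipeline consumes.

Each generator returns its output together with the ground truth used to
produce it, so every downstream stage has parameter-recovery and oracle tests
without any external data.

Activity traces are built as an alternating-renewal process on the minute
grid: sleep and wake bout durations are drawn in continuous time from the
phase-appropriate law at each bout's onset and rounded to whole minutes
(minimum 1).  Sleep minutes carry zero beam-cross counts; wake minutes carry
Poisson counts clipped to at least 1, so the minute-level quiescence rule and
the generator's ground truth coincide (an optional sub-threshold-wake knob
breaks that guarantee deliberately, to exercise the caller's merging
behavior).  A wake bout is forced to cover every ZT0 and ZT12 minute —
mirroring the aroused light-transition state of real flies — with a
transition surge multiplying the activity rate for a configurable duration.

A mechanical-deprivation operator converts sleep minutes to active minutes
within a ZT window with a given per-minute efficacy, and a rebound operator
programs a known amount of extra post-deprivation sleep, giving the
deprivation module exact generator truth for its recovery metrics.

Survival cohorts draw Weibull lifespans with right censoring at study end
plus optional random escapes; trajectories follow a two-state (rest/run)
correlated random walk confined to a circular arena.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dam_io import ActivityTrace, LIGHT_MINUTES, MINUTES_PER_DAY
from .sleep_core import Bout
from .behavior import Trajectory


# ---------------------------------------------------------------------------
# Bout-duration laws
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoutLaw:
    """Continuous bout-duration law, parameterized by its mean in minutes.

    Families: 'exponential', 'lognormal' (with log-sd ``sigma``) and 'fixed'
    (degenerate, for oracle tests).  Draws are rounded to whole minutes with
    a 1-minute floor by the caller.
    """

    family: str
    mean_min: float
    sigma: float = 0.75  # log-sd for the lognormal family

    def __post_init__(self) -> None:
        if self.family not in {"exponential", "lognormal", "fixed"}:
            raise ValueError(f"unknown bout-law family {self.family!r}")
        if self.mean_min <= 0:
            raise ValueError("bout-law mean must be positive")
        if self.sigma <= 0:
            raise ValueError("lognormal sigma must be positive")

    def sample_continuous(self, rng: np.random.Generator,
                          mean_factor: float = 1.0) -> float:
        mean = self.mean_min * mean_factor
        if self.family == "fixed":
            return mean
        if self.family == "exponential":
            return float(rng.exponential(mean))
        mu = math.log(mean) - self.sigma ** 2 / 2.0
        return float(rng.lognormal(mu, self.sigma))

    def sample(self, rng: np.random.Generator, mean_factor: float = 1.0) -> int:
        """Continuous draw rounded to whole minutes with a 1-minute floor."""
        return max(1, int(round(self.sample_continuous(rng, mean_factor))))


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of the alternating-renewal sleep/wake generator.

    Defaults describe a typical wild-type fly under 12:12 LD: long
    consolidated night sleep (lognormal, mean 90 min), shorter day siestas
    (mean 30 min), wake bouts of ~30 min by day and ~15 min by night, two
    beam crosses per waking minute, and a 30-min activity surge (3x) anchored
    at each light transition.
    """

    period_minutes: int = MINUTES_PER_DAY
    n_days: int = 3
    lights_on_zt: int = 0
    sleep_bout_law_day: BoutLaw = field(
        default_factory=lambda: BoutLaw("lognormal", 30.0))
    sleep_bout_law_night: BoutLaw = field(
        default_factory=lambda: BoutLaw("lognormal", 90.0))
    wake_bout_law_day: BoutLaw = field(
        default_factory=lambda: BoutLaw("exponential", 30.0))
    wake_bout_law_night: BoutLaw = field(
        default_factory=lambda: BoutLaw("exponential", 15.0))
    wake_activity_rate: float = 2.0
    transition_surge: tuple[int, float] = (30, 3.0)
    rebound_multiplier: float = 1.0
    subthreshold_wake_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_minutes <= 0 or self.n_days <= 0:
            raise ValueError("period_minutes and n_days must be positive")
        if self.wake_activity_rate <= 0:
            raise ValueError("wake_activity_rate must be positive")
        if self.rebound_multiplier < 1:
            raise ValueError("rebound_multiplier must be >= 1")
        if not 0 <= self.subthreshold_wake_prob <= 1:
            raise ValueError("subthreshold_wake_prob must be a probability")
        dur, mult = self.transition_surge
        if dur < 0 or mult <= 0:
            raise ValueError("transition surge must have dur >= 0, mult > 0")


def _fly_rng(scenario, fly_index: int) -> np.random.Generator:
    return np.random.default_rng([scenario.seed, fly_index])


def gen_activity_trace(scenario: SyntheticScenario, fly_id: str = "syn0",
                       fly_index: int = 0,
                       rebound_window: tuple[int, int] | None = None
                       ) -> tuple[ActivityTrace, list[Bout]]:
    """Generate one fly's minute-binned trace plus its ground-truth bout list.

    ``rebound_window`` is an absolute-minute interval inside which sleep-bout
    means are multiplied by the scenario's ``rebound_multiplier`` (used to
    emulate post-deprivation rebound drive).  Output is fully determined by
    (scenario, fly_index).
    """
    rng = _fly_rng(scenario, fly_index)
    n = scenario.n_days * scenario.period_minutes
    surge_dur, surge_mult = scenario.transition_surge
    # absolute minutes that must fall inside a wake bout (ZT0 and ZT12)
    transitions = [t for t in range(0, n, LIGHT_MINUTES)]

    segments: list[tuple[str, int, int]] = []  # (kind, start, duration)
    t = 0
    state = "motion"  # traces start at ZT0, a forced-wake transition minute
    while t < n:
        is_light = (t % MINUTES_PER_DAY) < LIGHT_MINUTES
        if state == "sleep":
            law = (scenario.sleep_bout_law_day if is_light
                   else scenario.sleep_bout_law_night)
            factor = 1.0
            if (rebound_window is not None
                    and rebound_window[0] <= t < rebound_window[1]):
                factor = scenario.rebound_multiplier
            dur = law.sample(rng, factor)
            nxt = next((tr for tr in transitions if tr >= t), None)
            if nxt is not None and t + dur > nxt:
                dur = nxt - t  # truncate so a wake bout covers the transition
            if dur > 0:
                segments.append(("sleep", t, min(dur, n - t)))
                t += dur
            state = "motion"
        else:
            law = (scenario.wake_bout_law_day if is_light
                   else scenario.wake_bout_law_night)
            dur = law.sample(rng)
            if t in transitions and surge_dur > 0:
                dur = max(dur, surge_dur)  # anchored bout covers the surge
            segments.append(("motion", t, min(dur, n - t)))
            t += dur
            state = "sleep"

    # merge adjacent same-kind segments (created by zero-length truncations)
    merged: list[list] = []
    for kind, start, dur in segments:
        if merged and merged[-1][0] == kind and merged[-1][1] + merged[-1][2] == start:
            merged[-1][2] += dur
        else:
            merged.append([kind, start, dur])

    counts = np.zeros(n, dtype=np.int64)
    in_surge = np.zeros(n, dtype=bool)
    for tr in transitions:
        in_surge[tr:min(tr + surge_dur, n)] = True
    for kind, start, dur in merged:
        if kind == "motion":
            rate = np.where(in_surge[start:start + dur],
                            scenario.wake_activity_rate * surge_mult,
                            scenario.wake_activity_rate)
            c = rng.poisson(rate)
            counts[start:start + dur] = np.maximum(c, 1)
    if scenario.subthreshold_wake_prob > 0:
        wake = counts > 0
        drop = wake & (rng.random(n) < scenario.subthreshold_wake_prob)
        counts[drop] = 0

    trace = ActivityTrace(fly_id=fly_id, counts=counts, start_zt_min=0,
                          meta={"scenario_seed": scenario.seed,
                                "fly_index": fly_index})
    zt = trace.zt_minutes
    day = trace.day_index
    phase = trace.phase
    truth = [Bout(kind=k, start=s, duration_min=d,
                  onset_zt_min=int(zt[s]), onset_phase=str(phase[s]),
                  day_index=int(day[s]),
                  is_transition=(k == "motion"
                                 and any(s <= tr < s + d for tr in transitions)))
             for k, s, d in merged]
    return trace, truth


def gen_cohort(scenario: SyntheticScenario, n_flies: int,
               rebound_window: tuple[int, int] | None = None
               ) -> list[tuple[ActivityTrace, list[Bout]]]:
    """Generate ``n_flies`` independent traces from one scenario."""
    return [gen_activity_trace(scenario, fly_id=f"syn{i}", fly_index=i,
                               rebound_window=rebound_window)
            for i in range(n_flies)]


# ---------------------------------------------------------------------------
# Deprivation and rebound operators
# ---------------------------------------------------------------------------

def apply_sd_operator(trace: ActivityTrace, window: slice, efficacy: float,
                      seed: int = 0, activity_rate: float = 2.0
                      ) -> tuple[ActivityTrace, np.ndarray]:
    """Mechanical sleep deprivation: wake sleeping flies inside a ZT window.

    Each zero-count minute in ``window`` becomes, with probability
    ``efficacy``, an active minute with at least one beam cross (emulating a
    2-s mechanical jolt every minute).  Returns the perturbed trace and the
    absolute indices of converted minutes (ground truth).
    """
    if not 0 <= efficacy <= 1:
        raise ValueError("efficacy must be a probability")
    start, stop, _ = window.indices(len(trace))
    if stop <= start:
        raise ValueError("SD window lies outside the trace")
    rng = np.random.default_rng(seed)
    out = trace.copy()
    quiet = np.flatnonzero(out.counts[start:stop] == 0) + start
    hit = quiet[rng.random(quiet.size) < efficacy] if quiet.size else quiet
    out.counts[hit] = np.maximum(rng.poisson(activity_rate, hit.size), 1)
    return out, hit


def apply_rebound_operator(trace: ActivityTrace, window: slice,
                           surplus_min: int, min_sleep_min: int = 5
                           ) -> tuple[ActivityTrace, int]:
    """Program a known surplus of sleep minutes inside a recovery window.

    Extends sleep within the window by zeroing active minutes contiguously
    from an existing (or newly seeded) sleep run, so every added minute
    scores as sleep under the >= ``min_sleep_min`` quiescence rule.  Returns
    the modified trace and the surplus actually achieved (it can fall short
    of ``surplus_min`` only if the window runs out of active minutes, and
    can overshoot by at most ``min_sleep_min - 1`` when absorbing a short
    quiescent run).
    """
    if surplus_min < 0:
        raise ValueError("surplus_min must be non-negative")
    start, stop, _ = window.indices(len(trace))
    if stop <= start:
        raise ValueError("rebound window lies outside the trace")
    out = trace.copy()
    counts = out.counts

    def _sleep_minutes() -> int:
        # sleep minutes inside the window under the full-trace quiescence rule
        quiet = counts == 0
        edges = np.flatnonzero(np.diff(quiet.astype(np.int8))) + 1
        bounds = np.concatenate([[0], edges, [counts.size]])
        total = 0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if quiet[lo] and hi - lo >= min_sleep_min:
                total += max(0, min(hi, stop) - max(lo, start))
        return total

    base = _sleep_minutes()
    achieved = 0
    pos = start
    while achieved < surplus_min:
        # find the next active minute in the window to convert
        active = np.flatnonzero(counts[pos:stop] > 0)
        if active.size == 0:
            break
        # prefer extending an existing quiescent run: convert the first
        # active minute; contiguity builds up runs that cross the threshold
        idx = pos + active[0]
        counts[idx] = 0
        pos = idx  # stay local so conversions are contiguous
        achieved = _sleep_minutes() - base
    return out, achieved


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalScenario:
    """Weibull lifespans with right censoring at study end and random escapes.

    Defaults mirror a standard lifespan design: 10 vials of 30 males,
    monitored for 89 days, with an aging-type hazard (shape 4) and a
    characteristic lifespan (scale) of 54 days.
    """

    n_vials: int = 10
    flies_per_vial: int = 30
    weibull_scale: float = 54.0
    weibull_shape: float = 4.0
    censor_time: float = 89.0
    escape_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vials <= 0 or self.flies_per_vial <= 0:
            raise ValueError("cohort sizes must be positive")
        if self.weibull_scale <= 0 or self.weibull_shape <= 0:
            raise ValueError("Weibull scale and shape must be positive")
        if self.censor_time < 0:
            raise ValueError("censor_time must be non-negative")
        if not 0 <= self.escape_rate <= 1:
            raise ValueError("escape_rate must be a probability")


def gen_survival_cohort(scenario: SurvivalScenario) -> pd.DataFrame:
    """Simulate a survival ledger: one row per fly.

    Columns: vial_id, fly_id, time, event ('death' or 'censored'),
    true_death_time (ground truth).  Deaths after ``censor_time`` are
    censored at study end; escapes are censored at a uniform random time if
    it precedes both death and study end.
    """
    s = scenario
    rng = np.random.default_rng(s.seed)
    rows = []
    for v in range(s.n_vials):
        death = s.weibull_scale * rng.weibull(s.weibull_shape, s.flies_per_vial)
        escapes = rng.random(s.flies_per_vial) < s.escape_rate
        escape_t = rng.uniform(0, s.censor_time if np.isfinite(s.censor_time)
                               else s.weibull_scale * 3, s.flies_per_vial)
        for i in range(s.flies_per_vial):
            t, ev = death[i], "death"
            if escapes[i] and escape_t[i] < t:
                t, ev = escape_t[i], "censored"
            if t > s.censor_time:
                t, ev = s.censor_time, "censored"
            rows.append({"vial_id": f"vial{v}", "fly_id": f"vial{v}_fly{i}",
                         "time": float(t), "event": ev,
                         "true_death_time": float(death[i])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def gen_trajectory(duration_s: float, fps: float = 15.0,
                   run_speed_law: BoutLaw | None = None,
                   rest_fraction: float = 0.5,
                   arena_diameter_mm: float = 37.0, seed: int = 0,
                   mean_run_s: float = 2.0, turn_sd_rad: float = 0.3,
                   fly_id: str = "traj0") -> tuple[Trajectory, np.ndarray]:
    """Two-state (rest/run) correlated random walk confined to a round arena.

    ``run_speed_law`` gives the per-run speed in mm/s (reusing the bout-law
    families; default lognormal, mean 8 mm/s).  The per-frame rest/run state
    is a two-state Markov chain whose stationary rest probability equals
    ``rest_fraction``.  Returns the trajectory and the ground-truth boolean
    run-state per frame.
    """
    if fps <= 0 or duration_s <= 0:
        raise ValueError("fps and duration must be positive")
    if not 0 <= rest_fraction <= 1:
        raise ValueError("rest_fraction must be a probability")
    if arena_diameter_mm <= 0:
        raise ValueError("arena diameter must be positive")
    if run_speed_law is None:
        run_speed_law = BoutLaw("lognormal", 8.0, sigma=0.4)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps)) + 1
    dt = 1.0 / fps

    p_run_to_rest = min(1.0, 1.0 / (mean_run_s * fps))
    if rest_fraction == 0:
        run = np.ones(n, dtype=bool)
    elif rest_fraction == 1:
        run = np.zeros(n, dtype=bool)
    else:
        p_rest_to_run = min(1.0, p_run_to_rest * (1 - rest_fraction)
                            / rest_fraction)
        run = np.empty(n, dtype=bool)
        run[0] = rng.random() > rest_fraction
        u = rng.random(n - 1)
        for i in range(1, n):
            if run[i - 1]:
                run[i] = u[i - 1] >= p_run_to_rest
            else:
                run[i] = u[i - 1] < p_rest_to_run
    radius = arena_diameter_mm / 2.0 * 0.95
    x = np.zeros(n)
    y = np.zeros(n)
    heading = rng.uniform(0, 2 * np.pi)
    # speed is redrawn at each rest->run transition and held within the run
    cur_speed = run_speed_law.sample_continuous(rng) if run[0] else 0.0
    for i in range(1, n):
        if run[i] and not run[i - 1]:
            cur_speed = run_speed_law.sample_continuous(rng)
            heading = rng.uniform(0, 2 * np.pi)
        if run[i]:
            heading += rng.normal(0, turn_sd_rad)
            nx = x[i - 1] + cur_speed * dt * np.cos(heading)
            ny = y[i - 1] + cur_speed * dt * np.sin(heading)
            r = np.hypot(nx, ny)
            if r > radius:  # reflect off the wall and clamp inside
                nx, ny = nx * radius / r, ny * radius / r
                heading += np.pi + rng.normal(0, turn_sd_rad)
            x[i], y[i] = nx, ny
        else:
            x[i], y[i] = x[i - 1], y[i - 1]
    t = dt * np.arange(n)
    traj = Trajectory(fly_id=fly_id, t=t, x=x, y=y,
                      arena_diameter_mm=arena_diameter_mm)
    return traj, run


# ---------------------------------------------------------------------------
# Scenario serialization
# ---------------------------------------------------------------------------

def scenario_to_config(scenario) -> str:
    """Serialize a scenario as plain 'key = value' text, seed included."""
    lines = []
    for k, v in vars(scenario).items():
        if isinstance(v, BoutLaw):
            v = f"{v.family}:{v.mean_min}:{v.sigma}"
        lines.append(f"{k} = {v}")
    return "\n".join(lines) + "\n"
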