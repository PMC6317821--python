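"""Sleep/motion bout calling and sleep-architecture metrics.

Sleep in *Drosophila* is scored behaviorally from DAM beam-cross counts: a
sleep bout is a maximal run of at least five consecutive minutes with zero
counts (the field-standard immobility criterion).  Shorter quiescent runs are
treated as wake and absorbed into the surrounding motion bout, so every
analyzed minute belongs to exactly one bout and bouts alternate kind.

From the bout decomposition this module derives the architecture metrics used
to characterize sleep consolidation and fragmentation: per-phase total sleep,
bout counts, mean and maximum bout durations, sleep latency, waking activity
(beam crosses per minute awake, optionally excluding light-transition bouts),
and the bout-length distribution over the duration bins
[5,15), [15,51), [51,150), [150,500), [500,721) minutes.

Phase attribution rule: a bout straddling a light/dark boundary contributes
its minutes to each phase for sleep totals, but is counted once — in its
onset phase and onset day — for bout-number and duration statistics.  This
keeps the minute-conservation identity and the per-phase bout counts both
well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dam_io import ActivityTrace, LIGHT_MINUTES, MINUTES_PER_DAY

MIN_SLEEP_MIN = 5
DEFAULT_BIN_EDGES = (5, 15, 51, 150, 500, 721)


@dataclass
class Bout:
    """A maximal run of sleep (quiescence) or motion minutes.

    ``start`` is the absolute minute index within the trace; onset ZT, phase
    and day are resolved against the owning trace at call time.
    """

    kind: str  # 'sleep' | 'motion'
    start: int
    duration_min: int
    onset_zt_min: int
    onset_phase: str
    day_index: int
    is_transition: bool = False

    @property
    def end(self) -> int:
        return self.start + self.duration_min


class MissingDataError(ValueError):
    """Raised when the analysis window contains missing minutes."""


def _check_window(trace: ActivityTrace, window: slice) -> tuple[int, int]:
    start, stop, _ = window.indices(len(trace))
    if stop <= start:
        raise ValueError("empty analysis window")
    if trace.missing[start:stop].any():
        raise MissingDataError(
            f"trace {trace.fly_id!r} has missing minutes inside the analysis window")
    return start, stop


def sleep_mask(trace: ActivityTrace, min_sleep_min: int = MIN_SLEEP_MIN,
               window: slice = slice(None)) -> np.ndarray:
    """Boolean per-minute sleep indicator over the window (True = asleep).

    A minute is a sleep minute iff it lies in a zero-count run of length at
    least ``min_sleep_min``.
    """
    start, stop = _check_window(trace, window)
    quiet = trace.counts[start:stop] == 0
    # run-length encode the quiescence indicator
    mask = np.zeros(quiet.size, dtype=bool)
    edges = np.flatnonzero(np.diff(quiet.astype(np.int8))) + 1
    bounds = np.concatenate([[0], edges, [quiet.size]])
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if quiet[lo] and hi - lo >= min_sleep_min:
            mask[lo:hi] = True
    return mask


def call_bouts(trace: ActivityTrace, min_sleep_min: int = MIN_SLEEP_MIN,
               window: slice = slice(None)) -> list[Bout]:
    """Segment a trace into alternating sleep and motion bouts.

    Maximal zero-count runs of >= ``min_sleep_min`` minutes are sleep bouts;
    the complementary maximal runs (including sub-threshold quiescence) are
    motion bouts.  Every minute of the window belongs to exactly one bout.
    """
    if min_sleep_min < 1:
        raise ValueError("min_sleep_min must be >= 1")
    start, stop = _check_window(trace, window)
    asleep = sleep_mask(trace, min_sleep_min, window)
    zt = trace.zt_minutes
    day = trace.day_index
    phase = trace.phase
    bouts: list[Bout] = []
    edges = np.flatnonzero(np.diff(asleep.astype(np.int8))) + 1
    bounds = np.concatenate([[0], edges, [asleep.size]])
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        a = start + lo
        bouts.append(Bout(
            kind="sleep" if asleep[lo] else "motion",
            start=a, duration_min=hi - lo,
            onset_zt_min=int(zt[a]), onset_phase=str(phase[a]),
            day_index=int(day[a])))
    return bouts


def flag_dead(trace: ActivityTrace, min_active_min: int = 10) -> str:
    """Classify a fly as 'alive' or 'dead' from per-phase activity.

    A fly is flagged dead if, on any fully covered day, it shows fewer than
    ``min_active_min`` minutes containing at least one beam cross in either
    the light phase or the dark phase.  Activity is measured in minutes, not
    raw counts.
    """
    zt = trace.abs_zt
    first_day = int(np.ceil(zt[0] / MINUTES_PER_DAY))
    last_day = int((zt[-1] + 1) // MINUTES_PER_DAY)
    if last_day <= first_day:
        raise ValueError("trace must cover at least one full light and dark phase")
    active = (trace.counts >= 1) & ~trace.missing
    for day in range(first_day, last_day):
        for zt_lo, zt_hi in ((0, LIGHT_MINUTES), (LIGHT_MINUTES, MINUTES_PER_DAY)):
            sl = trace.zt_window(day, zt_lo, zt_hi)
            if int(active[sl].sum()) < min_active_min:
                return "dead"
    return "alive"


def mark_transition_bouts(bouts: list[Bout]) -> list[Bout]:
    """Flag the motion bouts anchored at the ZT0 and ZT12 light transitions.

    Flies spend the light transitions in an aroused, active state; the motion
    bout whose interval contains a ZT0 or ZT720 minute is marked so waking-
    activity statistics can exclude these consolidated transition periods.
    If a transition minute falls inside a sleep bout, no bout is flagged for
    that transition.
    """
    if not bouts:
        return bouts
    first = bouts[0]
    offset = first.day_index * MINUTES_PER_DAY + first.onset_zt_min - first.start
    lo = offset + first.start
    hi = offset + bouts[-1].end
    transitions = [t for t in range(0, hi + 1, LIGHT_MINUTES) if lo <= t < hi]
    for b in bouts:
        if b.kind != "motion":
            continue
        b.is_transition = any(
            offset + b.start <= t < offset + b.end for t in transitions)
    return bouts


def architecture(trace: ActivityTrace, bouts: list[Bout],
                 exclude_transition: bool = False,
                 min_sleep_min: int = MIN_SLEEP_MIN) -> pd.DataFrame:
    """Per (day, phase) sleep-architecture metrics.

    Columns: total_sleep_min, bout_count, mean_bout_min, max_bout_min,
    sleep_latency_min, latency_censored, waking_activity_per_min,
    motion_bout_mean_min, n_minutes.

    Sleep totals use minute attribution (straddling bouts split at phase
    boundaries); bout counts and duration statistics use onset attribution.
    Waking activity is beam crosses per wake minute, excluding minutes inside
    transition-flagged motion bouts when ``exclude_transition``.
    """
    if not bouts:
        raise ValueError("no bouts supplied")
    if exclude_transition and not any(b.is_transition for b in bouts):
        mark_transition_bouts(bouts)
    lo = bouts[0].start
    hi = bouts[-1].end
    asleep = np.zeros(len(trace), dtype=bool)
    in_transition = np.zeros(len(trace), dtype=bool)
    for b in bouts:
        if b.kind == "sleep":
            asleep[b.start:b.end] = True
        elif b.is_transition:
            in_transition[b.start:b.end] = True
    day = trace.day_index
    light = trace.is_light
    counts = trace.counts
    rows = []
    for d in np.unique(day[lo:hi]):
        for phase_name, phase_sel in (("light", light), ("dark", ~light)):
            sel = np.zeros(len(trace), dtype=bool)
            sel[lo:hi] = True
            sel &= (day == d) & phase_sel
            n_min = int(sel.sum())
            if n_min == 0:
                continue
            total_sleep = int((asleep & sel).sum())
            onset = [b for b in bouts
                     if b.day_index == d and b.onset_phase == phase_name]
            sleep_durs = [b.duration_min for b in onset if b.kind == "sleep"]
            motion_durs = [b.duration_min for b in onset if b.kind == "motion"]
            # latency: minutes from phase start to first sleep onset in phase
            phase_idx = np.flatnonzero(sel)
            phase_start = int(phase_idx[0])
            sleep_onsets = [b.start for b in onset if b.kind == "sleep"]
            if sleep_onsets:
                latency = min(sleep_onsets) - phase_start
                censored = False
            else:
                latency = n_min
                censored = True
            wake = sel & ~asleep
            if exclude_transition:
                wake &= ~in_transition
            n_wake = int(wake.sum())
            waking_activity = (float(counts[wake].sum()) / n_wake
                               if n_wake else np.nan)
            rows.append({
                "fly_id": trace.fly_id, "day": int(d), "phase": phase_name,
                "n_minutes": n_min,
                "total_sleep_min": total_sleep,
                "bout_count": len(sleep_durs),
                "mean_bout_min": float(np.mean(sleep_durs)) if sleep_durs else np.nan,
                "max_bout_min": int(max(sleep_durs)) if sleep_durs else 0,
                "sleep_latency_min": int(latency),
                "latency_censored": censored,
                "waking_activity_per_min": waking_activity,
                "motion_bout_mean_min": (float(np.mean(motion_durs))
                                         if motion_durs else np.nan),
            })
    return pd.DataFrame(rows)


def bout_distribution(bouts: list[Bout],
                      edges: tuple[int, ...] = DEFAULT_BIN_EDGES) -> pd.DataFrame:
    """Sleep-bout duration histogram: bout counts and summed sleep minutes.

    Bins are half-open [edges[i], edges[i+1]); the first edge must equal the
    minimum sleep-bout duration (5).  Durations at or above the last edge are
    assigned to the final bin.  Returned per onset phase.
    """
    edges = tuple(edges)
    if any(b >= a for a, b in zip(edges[1:], edges[:-1])):
        raise ValueError("edges must be strictly increasing")
    if edges[0] != MIN_SLEEP_MIN:
        raise ValueError(f"first edge must be {MIN_SLEEP_MIN}")
    labels = [f"[{a},{b})" for a, b in zip(edges[:-1], edges[1:])]
    rows = []
    for phase in ("light", "dark"):
        durs = np.array([b.duration_min for b in bouts
                         if b.kind == "sleep" and b.onset_phase == phase])
        idx = np.clip(np.searchsorted(edges, durs, side="right") - 1,
                      0, len(labels) - 1) if durs.size else np.array([], dtype=int)
        for i, lab in enumerate(labels):
            in_bin = durs[idx == i] if durs.size else durs
            rows.append({"phase": phase, "bin": lab,
                         "bin_lo": edges[i], "bin_hi": edges[i + 1],
                         "bout_count": int(in_bin.size),
                         "sleep_min": int(in_bin.sum())})
    return pd.DataFrame(rows)
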