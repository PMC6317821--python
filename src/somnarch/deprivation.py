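"""Sleep-deprivation loss, debt and rebound quantification.

Mechanical sleep deprivation (SD) is applied during the last six hours of the
dark phase, ending at lights-on.  Every quantity here is computed against the
ZT-matched window of a baseline day 24 h earlier, which is what makes "sleep
debt" well defined: the flies' own undisturbed day provides the expected
sleep at each zeitgeber minute.

Conventions
-----------
* Flies qualify for rebound analysis only if they lost more than 60% of their
  baseline sleep during the SD window; a baseline window with zero sleep
  leaves the loss fraction undefined and the fly excluded with a reason.
* Recovery sleep is sleep in the first three hours after SD ends; the excess
  is that quantity minus the ZT-matched baseline-day window.
* The sleep-debt curve is cumulative baseline sleep minus cumulative observed
  sleep from SD start, so debt at SD end equals baseline-window sleep minus
  SD-window sleep exactly, and rebound drives the curve back toward zero
  (negative values indicate excess sleep).
* A sleep bout in progress at SD end contributes its post-SD minutes to
  recovery sleep, but bout-duration statistics for the first two hours use
  bouts whose *onset* falls in that window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dam_io import ActivityTrace, MINUTES_PER_DAY
from .sleep_core import (Bout, MIN_SLEEP_MIN, DEFAULT_BIN_EDGES, bout_distribution,
                         call_bouts, sleep_mask)

SD_ZT_START = 1080  # default: last 6 h of dark, ZT18:00-24:00
SD_ZT_END = 1440
RECOVERY_MIN = 180  # first 3 h post-SD
LOSS_THRESHOLD = 0.60


def _full_mask(trace: ActivityTrace, min_sleep_min: int) -> np.ndarray:
    """Sleep mask over the whole trace so runs straddling window edges score
    by their full length, not the part inside the window."""
    return sleep_mask(trace, min_sleep_min)


@dataclass
class DeprivationResult:
    """Per-fly sleep-deprivation outcome relative to the matched baseline day."""

    fly_id: str
    loss_fraction: float          # 1 - SD-window sleep / baseline-window sleep
    included: bool                # loss_fraction > 0.60
    exclusion_reason: str | None
    debt_curve: np.ndarray        # per-minute cumulative debt from SD start
    max_debt_min: float
    recovery_sleep_min: int
    excess_min: int
    time_to_max_bout_h: float
    time_to_max_censored: bool
    first2h_mean_bout_min: float
    latency_to_first_bout_h: float
    latency_censored: bool


def sleep_loss(trace: ActivityTrace, sd_window: slice,
               min_sleep_min: int = MIN_SLEEP_MIN) -> tuple[float, bool, str | None]:
    """Fraction of baseline sleep lost during the SD window.

    The baseline window is the same ZT span 24 h earlier.  Returns
    ``(loss_fraction, included, reason)``; ``included`` is True iff the loss
    exceeds 60%.  Zero baseline sleep makes the loss undefined (NaN) and the
    fly is excluded with a reason.
    """
    base_window = slice(sd_window.start - MINUTES_PER_DAY,
                        sd_window.stop - MINUTES_PER_DAY)
    if base_window.start < 0:
        raise ValueError("trace does not cover the baseline day")
    mask = _full_mask(trace, min_sleep_min)
    sd_sleep = int(mask[sd_window].sum())
    base_sleep = int(mask[base_window].sum())
    if base_sleep == 0:
        return float("nan"), False, "no baseline sleep in matched window"
    loss = 1.0 - sd_sleep / base_sleep
    included = loss > LOSS_THRESHOLD
    return loss, included, None if included else "loss <= 60%"


def debt_curve(trace: ActivityTrace, sd_start: int, horizon_min: int,
               min_sleep_min: int = MIN_SLEEP_MIN) -> np.ndarray:
    """Cumulative sleep debt per minute from SD start over ``horizon_min``.

    debt(t) = baseline cumulative sleep in [sd_start, sd_start+t) minus the
    observed cumulative sleep over the same ZT-aligned span; the returned
    array has length ``horizon_min + 1`` with debt(0) = 0.
    """
    if sd_start - MINUTES_PER_DAY < 0:
        raise ValueError("trace does not cover the baseline day")
    if sd_start + horizon_min > len(trace):
        raise ValueError("horizon extends past the end of the trace")
    mask = _full_mask(trace, min_sleep_min)
    obs = mask[sd_start:sd_start + horizon_min]
    base = mask[sd_start - MINUTES_PER_DAY:
                sd_start - MINUTES_PER_DAY + horizon_min]
    debt = np.concatenate([[0], np.cumsum(base.astype(int) - obs.astype(int))])
    return debt


def recovery_metrics(trace: ActivityTrace, bouts: list[Bout], sd_end: int,
                     min_sleep_min: int = MIN_SLEEP_MIN,
                     search_horizon_min: int = MINUTES_PER_DAY) -> dict:
    """Post-SD recovery quantities for one included fly.

    Returns recovery sleep (first 3 h), excess over the matched baseline
    window, time from SD end to the onset of the longest post-SD sleep bout
    (hours, searched over ``search_horizon_min``), mean duration of sleep
    bouts with onset in the first two hours, and latency to the first
    post-SD sleep-bout onset.  When no qualifying bout exists the time
    metrics are censored at the horizon and flagged.
    """
    rec_window = slice(sd_end, min(sd_end + RECOVERY_MIN, len(trace)))
    base_window = slice(rec_window.start - MINUTES_PER_DAY,
                        rec_window.stop - MINUTES_PER_DAY)
    mask = _full_mask(trace, min_sleep_min)
    recovery_sleep = int(mask[rec_window].sum())
    base_sleep = int(mask[base_window].sum())
    horizon = min(sd_end + search_horizon_min, len(trace))
    # a bout already in progress at SD end counts from SD end onward
    post = [(max(b.start, sd_end), b) for b in bouts
            if b.kind == "sleep" and b.end > sd_end and b.start < horizon]
    if post:
        longest_onset, _ = max(post, key=lambda ob: (ob[1].end - ob[0], -ob[0]))
        time_to_max_h = (longest_onset - sd_end) / 60.0
        latency_h = (min(o for o, _ in post) - sd_end) / 60.0
        censored = False
    else:
        time_to_max_h = latency_h = (horizon - sd_end) / 60.0
        censored = True
    first2h = [b.duration_min for _, b in post
               if sd_end <= b.start < sd_end + 120]
    return {
        "recovery_sleep_min": recovery_sleep,
        "excess_min": recovery_sleep - base_sleep,
        "time_to_max_bout_h": time_to_max_h,
        "time_to_max_censored": censored,
        "first2h_mean_bout_min": float(np.mean(first2h)) if first2h else np.nan,
        "latency_to_first_bout_h": latency_h,
        "latency_censored": censored,
    }


def analyze_deprivation(trace: ActivityTrace, sd_day: int,
                        sd_zt_start: int = SD_ZT_START,
                        sd_zt_end: int = SD_ZT_END,
                        min_sleep_min: int = MIN_SLEEP_MIN,
                        debt_horizon_min: int = 720,
                        search_horizon_min: int = MINUTES_PER_DAY
                        ) -> DeprivationResult:
    """Full per-fly SD analysis: loss, inclusion, debt curve, recovery metrics."""
    sd_window = trace.zt_window(sd_day, sd_zt_start, sd_zt_end)
    loss, included, reason = sleep_loss(trace, sd_window, min_sleep_min)
    debt = debt_curve(trace, sd_window.start,
                      min(debt_horizon_min,
                          len(trace) - sd_window.start), min_sleep_min)
    max_debt = float(debt[sd_window.stop - sd_window.start])
    if included:
        bouts = call_bouts(trace, min_sleep_min)
        rec = recovery_metrics(trace, bouts, sd_window.stop, min_sleep_min,
                               search_horizon_min)
    else:
        rec = dict(recovery_sleep_min=0, excess_min=0,
                   time_to_max_bout_h=float("nan"), time_to_max_censored=True,
                   first2h_mean_bout_min=float("nan"),
                   latency_to_first_bout_h=float("nan"), latency_censored=True)
    return DeprivationResult(
        fly_id=trace.fly_id, loss_fraction=loss, included=included,
        exclusion_reason=reason, debt_curve=debt, max_debt_min=max_debt, **rec)


def post_sd_distribution_shift(bouts_baseline: list[Bout],
                               bouts_recovery: list[Bout],
                               edges: tuple[int, ...] = DEFAULT_BIN_EDGES
                               ) -> pd.DataFrame:
    """Paired baseline vs recovery sleep-bout distributions, per phase."""
    base = bout_distribution(bouts_baseline, edges).assign(day_type="baseline")
    rec = bout_distribution(bouts_recovery, edges).assign(day_type="recovery")
    return pd.concat([base, rec], ignore_index=True)


def post_sd_mortality(status_by_group: dict[str, list[str]]) -> pd.DataFrame:
    """Fraction of flies dead within 24 h post-SD, per experimental group."""
    rows = []
    for group, statuses in status_by_group.items():
        bad = set(statuses) - {"alive", "dead"}
        if bad:
            raise ValueError(f"unknown status values {sorted(bad)}")
        n = len(statuses)
        n_dead = sum(s == "dead" for s in statuses)
        rows.append({"group": group, "n": n, "n_dead": n_dead,
                     "fraction_dead": n_dead / n if n else float("nan")})
    return pd.DataFrame(rows)
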