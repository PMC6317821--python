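"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately written as plain python scans, independent
of the vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from somnarch.dam_io import ActivityTrace


def brute_force_bouts(counts, min_sleep=5):
    """Independent per-minute scanner: list of (kind, start, duration)."""
    n = len(counts)
    sleep = [False] * n
    i = 0
    while i < n:
        if counts[i] == 0:
            j = i
            while j < n and counts[j] == 0:
                j += 1
            if j - i >= min_sleep:
                for k in range(i, j):
                    sleep[k] = True
            i = j
        else:
            i += 1
    segs = []
    i = 0
    while i < n:
        j = i
        while j < n and sleep[j] == sleep[i]:
            j += 1
        segs.append(("sleep" if sleep[i] else "motion", i, j - i))
        i = j
    return segs


def brute_force_sleep_minutes(counts, lo, hi, min_sleep=5):
    """Sleep minutes inside [lo, hi) under the full-trace quiescence rule."""
    total = 0
    for kind, start, dur in brute_force_bouts(counts, min_sleep):
        if kind == "sleep":
            total += max(0, min(start + dur, hi) - max(start, lo))
    return total


def brute_force_km(times, censored):
    """Risk-set Kaplan-Meier: list of (event_time, S_after)."""
    times = list(map(float, times))
    censored = list(map(bool, censored))
    event_times = sorted({t for t, c in zip(times, censored) if not c})
    s = 1.0
    out = []
    for t in event_times:
        at_risk = sum(1 for u in times if u >= t)
        d = sum(1 for u, c in zip(times, censored) if u == t and not c)
        s *= 1.0 - d / at_risk
        out.append((t, s))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def make_trace():
    def _make(counts, start_zt_min=0, fly_id="t0"):
        return ActivityTrace(fly_id=fly_id, counts=np.asarray(counts),
                             start_zt_min=start_zt_min)
    return _make
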