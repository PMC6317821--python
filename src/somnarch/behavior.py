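"""Courtship-conditioning indices, trajectory locomotion metrics and
stimulus-aligned response curves.

Courtship conditioning scores associative learning: a male paired with a
non-receptive mated female learns to suppress courtship.  The courtship index
(CI) is the percentage of a 10-minute trial spent courting; the learning
index (LI) is the relative reduction of mean CI in trained versus naive
males, LI = 100 * (1 - CI_trained / CI_naive).

Locomotion is quantified from tracker output: (t, x, y) samples at a fixed
frame rate (15 Hz in the source assay) inside a circular arena of known
diameter (37 mm).  A frame counts as "moving" when instantaneous speed
exceeds 2 mm/s; running velocity averages speed over moving frames only.
Speeds use central differences away from the ends (forward/backward at the
boundaries) to reduce discretization noise.

Stimulus responses align 60-s velocity windows on the onsets of the first
five vibration-pulse trains and subtract each train's own baseline (the mean
velocity over the preceding five minutes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPEED_THRESHOLD_MM_S = 2.0
TRIAL_SECONDS = 600.0


# ---------------------------------------------------------------------------
# Courtship conditioning
# ---------------------------------------------------------------------------

def courtship_index(courting_seconds: float,
                    trial_seconds: float = TRIAL_SECONDS) -> float:
    """CI = percentage of the 10-min trial spent courting.

    The denominator is always the full 600-s trial even if the recording ran
    slightly long; trials shorter than the nominal duration are rejected.
    """
    if trial_seconds < TRIAL_SECONDS:
        raise ValueError("trial shorter than the nominal 600 s is rejected")
    if not 0 <= courting_seconds <= trial_seconds:
        raise ValueError("courting_seconds must lie in [0, trial length]")
    return 100.0 * courting_seconds / TRIAL_SECONDS


def learning_index(ci_naive_mean: float, ci_trained_mean: float) -> float:
    """LI = 100 * (1 - CI_trained / CI_naive); negative = courtship increase.

    Undefined when the naive mean is zero (nothing to suppress).
    """
    if ci_naive_mean < 0 or ci_trained_mean < 0:
        raise ValueError("CI means must be non-negative")
    if ci_naive_mean == 0:
        raise ValueError("learning index undefined for naive CI mean of 0")
    return 100.0 * (1.0 - ci_trained_mean / ci_naive_mean)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """(t, x, y) samples for one fly at a fixed frame rate, positions in mm."""

    fly_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena_diameter_mm: float = 37.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have matching shapes")
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.arena_diameter_mm <= 0:
            raise ValueError("arena diameter must be positive")

    def __len__(self) -> int:
        return self.t.size

    @classmethod
    def from_csv(cls, path, fly_id=None, arena_diameter_mm: float = 37.0):
        """Load from a tracker-export CSV with columns fly_id, t, x, y."""
        df = pd.read_csv(path)
        if fly_id is not None:
            df = df[df["fly_id"] == fly_id]
        elif "fly_id" in df.columns:
            fly_id = df["fly_id"].iloc[0]
            df = df[df["fly_id"] == fly_id]
        return cls(fly_id=str(fly_id), t=df["t"].to_numpy(),
                   x=df["x"].to_numpy(), y=df["y"].to_numpy(),
                   arena_diameter_mm=arena_diameter_mm)


def frame_speeds(traj: Trajectory) -> np.ndarray:
    """Per-frame speed (mm/s) via central differences; one-sided at the ends."""
    if len(traj) < 2:
        raise ValueError("need at least 2 samples to compute speeds")
    pos = np.column_stack([traj.x, traj.y])
    v = np.empty(len(traj))
    dt_c = traj.t[2:] - traj.t[:-2]
    v[1:-1] = np.linalg.norm(pos[2:] - pos[:-2], axis=1) / dt_c
    v[0] = np.linalg.norm(pos[1] - pos[0]) / (traj.t[1] - traj.t[0])
    v[-1] = np.linalg.norm(pos[-1] - pos[-2]) / (traj.t[-1] - traj.t[-2])
    return v


@dataclass
class LocomotionMetrics:
    running_velocity_mean: float   # mean speed over moving frames (mm/s)
    total_distance_mm: float
    fraction_moving: float
    n_frames: int
    no_movement: bool              # True when no frame exceeded the threshold


def locomotion_metrics(traj: Trajectory,
                       threshold_mm_s: float = SPEED_THRESHOLD_MM_S
                       ) -> LocomotionMetrics:
    """Distance, fraction of frames moving, and running velocity.

    Running velocity is the mean speed over frames faster than
    ``threshold_mm_s``; it is NaN (flagged) for a fly that never moved.
    """
    if len(traj) < 2:
        raise ValueError("locomotion metrics undefined for a single sample")
    speeds = frame_speeds(traj)
    moving = speeds > threshold_mm_s
    steps = np.hypot(np.diff(traj.x), np.diff(traj.y))
    run_mean = float(speeds[moving].mean()) if moving.any() else float("nan")
    return LocomotionMetrics(
        running_velocity_mean=run_mean,
        total_distance_mm=float(steps.sum()),
        fraction_moving=float(moving.mean()),
        n_frames=len(traj),
        no_movement=not bool(moving.any()))


# ---------------------------------------------------------------------------
# Stimulus-aligned responses
# ---------------------------------------------------------------------------

@dataclass
class StimulusTrain:
    """Vibration-pulse train schedule: five 500-ms pulses at 1 Hz per train,
    trains every 60 s."""

    onsets_s: np.ndarray
    pulses_per_train: int = 5
    pulse_duration_s: float = 0.5
    inter_pulse_interval_s: float = 1.0

    def __post_init__(self) -> None:
        self.onsets_s = np.sort(np.asarray(self.onsets_s, dtype=float))
        train_len = self.pulses_per_train * self.inter_pulse_interval_s
        if np.any(np.diff(self.onsets_s) < train_len):
            raise ValueError("trains overlap")


def make_stimulus_train(first_onset_s: float, n_trains: int = 5,
                        inter_train_s: float = 60.0) -> StimulusTrain:
    return StimulusTrain(first_onset_s + inter_train_s * np.arange(n_trains))


def stimulus_response(t, velocity, trains: StimulusTrain,
                      window_s: float = 60.0, baseline_s: float = 300.0,
                      n_trains: int = 5) -> pd.DataFrame:
    """Baseline-subtracted mean velocity response aligned on train onsets.

    For each of the first ``n_trains`` trains, the velocity samples in the
    ``window_s`` window from train onset have that train's baseline (mean
    velocity over the ``baseline_s`` seconds preceding onset) subtracted;
    the aligned windows are then averaged sample-wise across trains.

    Returns a DataFrame with columns ``time_s`` (offset from onset) and
    ``response`` (mm/s above baseline).
    """
    t = np.asarray(t, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if t.shape != velocity.shape:
        raise ValueError("t and velocity must match")
    onsets = trains.onsets_s[:n_trains]
    if onsets.size < n_trains:
        raise ValueError(f"need at least {n_trains} trains")
    dt = np.median(np.diff(t))
    n_win = int(round(window_s / dt))
    aligned = []
    for onset in onsets:
        if onset - baseline_s < t[0] - dt / 2:
            raise ValueError(
                f"train at {onset} s lacks {baseline_s} s of pre-stimulus coverage")
        i0 = int(np.searchsorted(t, onset - dt / 2))
        if i0 + n_win > t.size:
            raise ValueError(f"train at {onset} s lacks a full response window")
        base_sel = (t >= onset - baseline_s) & (t < onset)
        baseline = velocity[base_sel].mean()
        aligned.append(velocity[i0:i0 + n_win] - baseline)
    mean_resp = np.mean(aligned, axis=0)
    return pd.DataFrame({"time_s": dt * np.arange(n_win), "response": mean_resp})


def cohort_stimulus_response(responses: list[pd.DataFrame]) -> pd.DataFrame:
    """Average per-animal response curves sample-wise across a cohort."""
    if not responses:
        raise ValueError("no responses to average")
    resp = np.mean([r["response"].to_numpy() for r in responses], axis=0)
    return pd.DataFrame({"time_s": responses[0]["time_s"], "response": resp})


# ---------------------------------------------------------------------------
# Mechanical stress outcome
# ---------------------------------------------------------------------------

def mechanical_stress_outcome(upright_counts, totals) -> pd.DataFrame:
    """Per-vial fraction of upright flies after repeated vortexing.

    Returns per-vial fractions (upright and its mortality complement) plus a
    ``group`` summary row with the mean fraction; raw counts are preserved so
    SEM can be computed downstream.
    """
    upright = np.asarray(upright_counts, dtype=int)
    totals = np.asarray(totals, dtype=int)
    if upright.shape != totals.shape:
        raise ValueError("upright_counts and totals must match")
    if np.any(upright > totals) or np.any(upright < 0) or np.any(totals <= 0):
        raise ValueError("counts must satisfy 0 <= upright <= total")
    frac = upright / totals
    rows = [{"vial": i, "upright": int(u), "total": int(n),
             "fraction_upright": float(f), "fraction_mortality": float(1 - f)}
            for i, (u, n, f) in enumerate(zip(upright, totals, frac))]
    rows.append({"vial": "group_mean", "upright": int(upright.sum()),
                 "total": int(totals.sum()),
                 "fraction_upright": float(frac.mean()),
                 "fraction_mortality": float(1 - frac.mean())})
    return pd.DataFrame(rows)
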