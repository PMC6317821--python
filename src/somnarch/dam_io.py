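"""Reading, writing and zeitgeber alignment of DAM activity-monitor data.

The TriKinetics *Drosophila* Activity Monitor (DAM) records infrared
beam-crossing counts for up to 32 flies housed in glass tubes.  Monitor files
are plain tab-separated text: one scan line per readout with an index, a date,
a clock time, a status code, six auxiliary fields and 32 per-channel counts.
This module parses those files (and a simple long-format CSV alternative),
bins counts into wall-clock minutes, and aligns minute series to zeitgeber
time (ZT), where ZT0 is lights-on and, under a 12:12 light:dark cycle, minutes
ZT [0, 720) are light and [720, 1440) are dark.

The central in-memory container is :class:`ActivityTrace`: one fly's
minute-binned counts on a ZT timeline.  Missing minutes are tracked with an
explicit mask and are never zero-filled — a zero count is a sleep signal in
this assay, so silent zero-fill would fabricate sleep.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440
LIGHT_MINUTES = 720  # 12:12 LD cycle: ZT [0, 720) light, [720, 1440) dark

N_DAM_CHANNELS = 32
_DAM_META_COLS = 10  # index, date, time, status + 6 auxiliary fields


class DamFormatError(ValueError):
    """Raised for structurally invalid monitor files."""


@dataclass
class ActivityTrace:
    """Minute-binned beam-cross counts for one fly on a zeitgeber timeline.

    Parameters
    ----------
    fly_id : str
        Identifier of the animal (monitor/channel or synthetic id).
    counts : ndarray of int
        One beam-cross count per minute.  Values at missing minutes are
        meaningless; consult :attr:`missing`.
    start_zt_min : int
        ZT minute (0-1439) of the first sample; ZT0 = lights-on.
    missing : ndarray of bool, optional
        True where the minute has no data.  Defaults to all observed.
    """

    fly_id: str
    counts: np.ndarray
    start_zt_min: int = 0
    missing: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if not 0 <= self.start_zt_min < MINUTES_PER_DAY:
            raise ValueError("start_zt_min must lie in [0, 1440)")
        if self.missing is None:
            self.missing = np.zeros(self.counts.shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.counts.shape:
                raise ValueError("missing mask must match counts length")
        if np.any(self.counts[~self.missing] < 0):
            raise ValueError("counts must be non-negative")

    # -- derived per-minute annotations ------------------------------------

    def __len__(self) -> int:
        return self.counts.size

    @property
    def abs_zt(self) -> np.ndarray:
        """Cumulative ZT minute since the lights-on preceding the trace start."""
        return self.start_zt_min + np.arange(self.counts.size)

    @property
    def zt_minutes(self) -> np.ndarray:
        return self.abs_zt % MINUTES_PER_DAY

    @property
    def day_index(self) -> np.ndarray:
        return self.abs_zt // MINUTES_PER_DAY

    @property
    def phase(self) -> np.ndarray:
        """Per-minute phase label, 'light' for ZT [0,720), 'dark' for [720,1440)."""
        return np.where(self.zt_minutes < LIGHT_MINUTES, "light", "dark")

    @property
    def is_light(self) -> np.ndarray:
        return self.zt_minutes < LIGHT_MINUTES

    def zt_window(self, day: int, zt_start: int, zt_end: int) -> slice:
        """Index slice for ZT minutes [zt_start, zt_end) of a given ZT day.

        ``zt_end`` may exceed 1440 to reach into the following day.
        """
        lo = day * MINUTES_PER_DAY + zt_start - self.start_zt_min
        hi = day * MINUTES_PER_DAY + zt_end - self.start_zt_min
        if lo < 0 or hi > len(self):
            raise ValueError(
                f"window ZT[{zt_start},{zt_end}) of day {day} not covered by trace"
            )
        return slice(lo, hi)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-minute table (fly_id, day, zt_min, phase, count)."""
        counts = self.counts.astype(float)
        counts[self.missing] = np.nan
        return pd.DataFrame(
            {
                "fly_id": self.fly_id,
                "day": self.day_index,
                "zt_min": self.zt_minutes,
                "phase": self.phase,
                "count": counts,
            }
        )

    def copy(self) -> "ActivityTrace":
        return replace(
            self, counts=self.counts.copy(), missing=self.missing.copy(),
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# DAM monitor files
# ---------------------------------------------------------------------------

def write_dam_file(path, counts, start: datetime, scan_interval_s: int = 60,
                   status: int = 1) -> None:
    """Write a minute-binned count matrix as a DAMSystem3-style monitor file.

    ``counts`` is (n_scans, n_channels<=32); channels beyond the data are
    zero-padded so every line carries 32 count columns.
    """
    counts = np.asarray(counts)
    if counts.ndim == 1:
        counts = counts[:, None]
    if counts.shape[1] > N_DAM_CHANNELS:
        raise ValueError(f"at most {N_DAM_CHANNELS} channels per monitor")
    pad = np.zeros((counts.shape[0], N_DAM_CHANNELS - counts.shape[1]), dtype=int)
    full = np.hstack([counts.astype(int), pad])
    lines = []
    for i, row in enumerate(full):
        ts = start + timedelta(seconds=i * scan_interval_s)
        meta = [str(i + 1), ts.strftime("%d %b %y"), ts.strftime("%H:%M:%S"),
                str(status), "1", "0", "0", "0", "0", "0"]
        lines.append("\t".join(meta + [str(int(c)) for c in row]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_dam_file(path) -> pd.DataFrame:
    """Parse a DAM monitor file into a scan-line table.

    Returns a DataFrame with columns ``index``, ``datetime``, ``status`` and
    ``ch01`` … ``ch32``.  Malformed lines are reported with their line numbers
    via :class:`UserWarning`; non-monotone timestamps raise
    :class:`DamFormatError`.
    """
    if hasattr(path, "read"):
        raw = path.read()
    else:
        with open(path) as fh:
            raw = fh.read()
    records, bad = [], []
    for lineno, line in enumerate(raw.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < _DAM_META_COLS + N_DAM_CHANNELS:
            bad.append((lineno, "too few columns"))
            continue
        try:
            idx = int(fields[0])
            ts = datetime.strptime(fields[1] + " " + fields[2], "%d %b %y %H:%M:%S")
            status = int(fields[3])
            ch = [int(v) for v in fields[-N_DAM_CHANNELS:]]
        except ValueError as exc:
            bad.append((lineno, str(exc)))
            continue
        if any(c < 0 for c in ch):
            bad.append((lineno, "negative count"))
            continue
        records.append((idx, ts, status, *ch))
    if bad:
        detail = "; ".join(f"line {n}: {r}" for n, r in bad[:10])
        warnings.warn(f"{len(bad)} malformed monitor line(s) skipped ({detail})")
    cols = ["index", "datetime", "status"] + [f"ch{i:02d}" for i in range(1, 33)]
    if not records:
        warnings.warn("monitor file contained no scan lines")
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(records, columns=cols)
    dt = df["datetime"].to_numpy()
    if np.any(dt[1:] <= dt[:-1]):
        raise DamFormatError("scan-line timestamps are not strictly increasing")
    return df


def read_long_csv(path) -> pd.DataFrame:
    """Read the long-format alternative: columns fly_id, datetime, count."""
    df = pd.read_csv(path)
    required = {"fly_id", "datetime", "count"}
    if not required.issubset(df.columns):
        raise DamFormatError(f"long-format CSV needs columns {sorted(required)}")
    df["datetime"] = pd.to_datetime(df["datetime"])
    return df


def detect_format(path) -> str:
    """Return 'dam' for monitor files, 'long' for long-format CSV."""
    with open(path) as fh:
        first = fh.readline()
    if first.count("\t") >= _DAM_META_COLS + N_DAM_CHANNELS - 1:
        return "dam"
    return "long"


# ---------------------------------------------------------------------------
# Minute binning and ZT alignment
# ---------------------------------------------------------------------------

def bin_to_minutes(scans: pd.DataFrame, scan_interval_s: int | None = None
                   ) -> pd.DataFrame:
    """Sum scan counts within each wall-clock minute, per channel.

    The scan interval must divide 60 s (or equal it); it is inferred from the
    modal timestamp difference when not given.  Gaps in coverage become rows
    of NaN (missing-data marker) and are reported with a warning.  Overlapping
    (duplicate) scan times are an error.
    """
    if scans.empty:
        return pd.DataFrame()
    ch_cols = [c for c in scans.columns if c.startswith("ch")]
    ts = pd.to_datetime(scans["datetime"])
    if ts.duplicated().any():
        raise DamFormatError("overlapping scan times")
    if scan_interval_s is None:
        diffs = ts.diff().dropna().dt.total_seconds()
        scan_interval_s = int(diffs.mode().iloc[0])
    if scan_interval_s <= 0 or (scan_interval_s < 60 and 60 % scan_interval_s):
        raise DamFormatError(
            f"scan interval {scan_interval_s}s must divide 60 s or equal 60 s")
    minute = ts.dt.floor("min")
    binned = scans[ch_cols].groupby(minute.values).sum()
    full_index = pd.date_range(binned.index.min(), binned.index.max(), freq="min")
    # a minute is observed only if every expected scan in it is present
    expected = 60 // scan_interval_s if scan_interval_s < 60 else 1
    got = minute.value_counts().reindex(full_index, fill_value=0)
    out = binned.reindex(full_index).astype(float)
    incomplete = got < expected
    out[incomplete.values] = np.nan
    n_missing = int(incomplete.sum())
    if n_missing:
        warnings.warn(f"{n_missing} minute(s) with incomplete coverage marked missing")
    out.index.name = "minute"
    return out


def align_to_zeitgeber(minute_counts: pd.DataFrame, lights_on: str = "08:00",
                       id_prefix: str = "") -> dict[str, ActivityTrace]:
    """Convert a minute-binned count table into per-channel ActivityTraces.

    ``lights_on`` is the clock time of lights-on ("HH:MM"); the minute
    beginning at that time is ZT0.  Minutes are half-open intervals [t, t+1).
    """
    hh, mm = lights_on.split(":")
    lights_on_min = int(hh) * 60 + int(mm)
    first = minute_counts.index[0]
    clock_min = first.hour * 60 + first.minute
    start_zt = (clock_min - lights_on_min) % MINUTES_PER_DAY
    traces = {}
    for col in minute_counts.columns:
        vals = minute_counts[col].to_numpy(dtype=float)
        missing = np.isnan(vals)
        counts = np.where(missing, 0, vals).astype(np.int64)
        fid = f"{id_prefix}{col}"
        traces[fid] = ActivityTrace(fly_id=fid, counts=counts,
                                    start_zt_min=start_zt, missing=missing)
    return traces


def load_monitor(path, lights_on: str = "08:00") -> dict[str, ActivityTrace]:
    """One-call pipeline: read, minute-bin and ZT-align a monitor file or CSV."""
    kind = detect_format(path)
    if kind == "dam":
        scans = read_dam_file(path)
        binned = bin_to_minutes(scans)
        return align_to_zeitgeber(binned, lights_on)
    df = read_long_csv(path)
    traces = {}
    for fid, grp in df.groupby("fly_id"):
        tab = grp.set_index(pd.to_datetime(grp["datetime"]).dt.floor("min"))
        wide = tab[["count"]].rename(columns={"count": str(fid)})
        wide = wide[~wide.index.duplicated()]
        full = pd.date_range(wide.index.min(), wide.index.max(), freq="min")
        wide = wide.reindex(full)
        traces.update(align_to_zeitgeber(wide, lights_on))
    return traces


def traces_to_csv(traces: dict[str, ActivityTrace], path) -> None:
    """Write traces as the tidy per-minute CSV (fly_id, day, zt_min, phase, count)."""
    pd.concat([t.to_frame() for t in traces.values()], ignore_index=True).to_csv(
        path, index=False)


def traces_from_csv(path) -> dict[str, ActivityTrace]:
    """Read traces back from the tidy per-minute CSV."""
    df = pd.read_csv(path)
    out = {}
    for fid, grp in df.groupby("fly_id", sort=False):
        grp = grp.reset_index(drop=True)
        vals = grp["count"].to_numpy(dtype=float)
        missing = np.isnan(vals)
        counts = np.where(missing, 0, vals).astype(np.int64)
        out[str(fid)] = ActivityTrace(
            fly_id=str(fid), counts=counts,
            start_zt_min=int(grp["zt_min"].iloc[0]), missing=missing)
    return out
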