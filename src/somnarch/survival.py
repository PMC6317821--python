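"""Right-censored survival quantification: Kaplan-Meier and Weibull fitting.

Lifespan and starvation-survival assays follow vials of ~30 flies until death
or the end of the study; escapes and accidental deaths are right-censored at
their recorded time, and animals still alive at study end are censored there.
Two summaries are supported, matching the two assay styles:

* median survival per vial — the first time the Kaplan-Meier survivor
  function falls *strictly below* 50% (S(t) = 0.5 exactly does not trigger;
  a vial whose curve never drops below 0.5 has an undefined median);
* the Weibull scale parameter per vial, from a right-censored maximum-
  likelihood fit.  The Weibull survivor function is
  S(t) = exp(-(t/scale)^shape), so the scale carries time units and is
  analogous to a characteristic lifespan, while shape > 1 captures the
  increasing hazard of aging populations (shape = 1 is the exponential,
  constant-hazard special case).

The fit is deterministic given the data: parameters are initialized from an
ordinary least-squares line through the complementary-log-log transform of
the Kaplan-Meier curve, log(-log S(t)) = shape*(log t - log scale), and
refined by maximizing the censored log-likelihood

    l(scale, shape) = sum_events log h(t_i) + sum_all log S(t_i),

with h(t) = (shape/scale) * (t/scale)^(shape-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass
class KaplanMeierCurve:
    """Product-limit survivor estimate as a right-continuous step function."""

    event_times: np.ndarray   # distinct times with at least one death
    survival: np.ndarray      # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray
    all_censored: bool = False

    def survival_at(self, t) -> np.ndarray:
        """Evaluate S(t); S is 1 before the first event and right-continuous."""
        idx = np.searchsorted(self.event_times, np.atleast_1d(t), side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return out if np.ndim(t) else float(out[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.event_times, "at_risk": self.at_risk,
                             "events": self.n_events, "survival": self.survival})


def km_estimate(times, censored) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimator with right censoring.

    Censored subjects leave the risk set at their censoring time without
    contributing an event step.  A cohort with no events yields a flat curve
    at 1, flagged via ``all_censored`` and a warning.
    """
    times = np.asarray(times, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    if times.shape != censored.shape or times.ndim != 1:
        raise ValueError("times and censored must be matching 1-d arrays")
    if times.size == 0:
        raise ValueError("no observations")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if censored.all():
        warnings.warn("all observations censored; survivor curve is flat at 1")
        return KaplanMeierCurve(np.array([]), np.array([]), np.array([]),
                                np.array([]), all_censored=True)
    event_times = np.unique(times[~censored])
    at_risk = np.array([(times >= t).sum() for t in event_times])
    n_events = np.array([((times == t) & ~censored).sum() for t in event_times])
    surv = np.cumprod(1.0 - n_events / at_risk)
    return KaplanMeierCurve(event_times, surv, at_risk, n_events)


def median_survival(km: KaplanMeierCurve) -> float | None:
    """First time the survivor function falls strictly below 0.5.

    Returns None (undefined) when the curve never drops below 0.5 — e.g.,
    heavily censored vials — mirroring how vials that do not reach 50%
    mortality are handled.
    """
    if km.all_censored:
        return None
    below = km.survival < 0.5
    if not below.any():
        return None
    return float(km.event_times[np.argmax(below)])


# ---------------------------------------------------------------------------
# Censored Weibull maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class WeibullSurvivalResults:
    """Fit results for a right-censored Weibull survival model."""

    scale: float
    shape: float
    log_likelihood: float
    converged: bool
    n: int
    n_events: int
    flags: list[str] = field(default_factory=list)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.scale, self.shape])

    def survival_function(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.exp(-np.power(t / self.scale, self.shape))

    def summary(self) -> str:
        lines = [
            "Weibull survival fit (right-censored MLE)",
            f"  observations      : {self.n} ({self.n_events} events, "
            f"{self.n - self.n_events} censored)",
            f"  scale             : {self.scale:.4f}",
            f"  shape             : {self.shape:.4f}",
            f"  log-likelihood    : {self.log_likelihood:.4f}",
            f"  converged         : {self.converged}",
        ]
        if self.flags:
            lines.append(f"  flags             : {', '.join(self.flags)}")
        return "\n".join(lines)


class WeibullSurvival:
    """Right-censored Weibull survival model for one vial or cohort.

    Parameters
    ----------
    times : array-like
        Event or censoring times (must be positive for events).
    censored : array-like of bool
        True where the subject was censored (escape, accidental death, or
        alive at study end).
    """

    def __init__(self, times, censored=None):
        self.times = np.asarray(times, dtype=float)
        if censored is None:
            censored = np.zeros(self.times.shape, dtype=bool)
        self.censored = np.asarray(censored, dtype=bool)
        if self.times.shape != self.censored.shape or self.times.ndim != 1:
            raise ValueError("times and censored must be matching 1-d arrays")
        self.events = self.times[~self.censored]
        if self.events.size < 2:
            raise ValueError("need at least 2 events to fit a Weibull model")
        if np.any(self.events <= 0):
            raise ValueError("event times must be positive")

    def loglike(self, scale: float, shape: float) -> float:
        """Censored Weibull log-likelihood at (scale, shape)."""
        if scale <= 0 or shape <= 0:
            return -np.inf
        z = self.times / scale
        with np.errstate(divide="ignore"):
            log_h = (np.log(shape / scale)
                     + (shape - 1.0) * np.log(self.events / scale))
        log_s = -np.power(z, shape)
        return float(log_h.sum() + log_s.sum())

    def _init_from_km(self) -> tuple[float, float]:
        """Least-squares line through log(-log S_KM) vs log t at event times."""
        km = km_estimate(self.times, self.censored)
        s = km.survival_at(km.event_times)
        ok = (s > 0) & (s < 1) & (km.event_times > 0)
        if ok.sum() >= 2:
            x = np.log(km.event_times[ok])
            y = np.log(-np.log(s[ok]))
            shape, intercept = np.polyfit(x, y, 1)
            if shape > 0:
                scale = np.exp(-intercept / shape)
                if np.isfinite(scale) and scale > 0:
                    return float(scale), float(shape)
        return float(self.events.mean()), 1.0

    def fit(self, fix_shape: float | None = None) -> WeibullSurvivalResults:
        """Maximize the censored log-likelihood.

        ``fix_shape=1`` uses the exponential closed form
        scale = (total observed time) / (number of events), which for fully
        uncensored data is the sample mean.  Degenerate data with all event
        times equal and nothing censored later drives shape to infinity; this
        is detected and returned as the limit, flagged and not converged.
        """
        n, n_ev = self.times.size, self.events.size
        if fix_shape is not None:
            if fix_shape <= 0:
                raise ValueError("fix_shape must be positive")
            if fix_shape == 1.0:
                scale = float(self.times.sum() / n_ev)
            else:
                res = optimize.minimize_scalar(
                    lambda ls: -self.loglike(np.exp(ls), fix_shape),
                    bounds=(np.log(self.events.mean()) - 5,
                            np.log(self.events.mean()) + 5), method="bounded")
                scale = float(np.exp(res.x))
            return WeibullSurvivalResults(
                scale=scale, shape=float(fix_shape),
                log_likelihood=self.loglike(scale, fix_shape),
                converged=True, n=n, n_events=n_ev,
                flags=[f"shape fixed at {fix_shape}"])

        t0 = self.events[0]
        if np.all(self.events == t0) and not np.any(
                self.times[self.censored] > t0):
            # point mass at t0: shape -> inf, scale -> t0 (closed-form limit)
            return WeibullSurvivalResults(
                scale=float(t0), shape=np.inf, log_likelihood=np.inf,
                converged=False, n=n, n_events=n_ev,
                flags=["degenerate: all event times equal"])

        scale0, shape0 = self._init_from_km()
        res = optimize.minimize(
            lambda p: -self.loglike(np.exp(p[0]), np.exp(p[1])),
            x0=np.log([scale0, max(shape0, 1e-3)]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        scale, shape = np.exp(res.x)
        flags = [] if res.success else ["optimizer did not converge"]
        return WeibullSurvivalResults(
            scale=float(scale), shape=float(shape),
            log_likelihood=self.loglike(scale, shape),
            converged=bool(res.success), n=n, n_events=n_ev, flags=flags)


def fit_weibull_censored(times, censored=None, fix_shape: float | None = None
                         ) -> tuple[float, float, float, bool]:
    """Functional wrapper: returns (scale, shape, log_likelihood, converged)."""
    res = WeibullSurvival(times, censored).fit(fix_shape=fix_shape)
    return res.scale, res.shape, res.log_likelihood, res.converged


def vial_scale_summary(ledger: pd.DataFrame) -> pd.DataFrame:
    """Per-vial Weibull scale table from a survival ledger.

    ``ledger`` columns: vial_id, time, event ('death' or 'censored'); an
    optional genotype/group column is carried through.  Non-converged vials
    are reported but marked excluded — the scale is the comparison unit, so
    only converged fits should enter group statistics.
    """
    required = {"vial_id", "time", "event"}
    if not required.issubset(ledger.columns):
        raise ValueError(f"ledger needs columns {sorted(required)}")
    bad = set(ledger["event"]) - {"death", "censored"}
    if bad:
        raise ValueError(f"unknown event values {sorted(bad)}")
    extra = [c for c in ("genotype", "group") if c in ledger.columns]
    rows = []
    for vial, grp in ledger.groupby("vial_id", sort=False):
        times = grp["time"].to_numpy(dtype=float)
        cens = (grp["event"] == "censored").to_numpy()
        km = km_estimate(times, cens)
        med = median_survival(km)
        try:
            res = WeibullSurvival(times, cens).fit()
            scale, shape = res.scale, res.shape
            conv = res.converged
        except ValueError as exc:
            scale = shape = np.nan
            conv = False
            warnings.warn(f"vial {vial!r}: {exc}")
        row = {"vial_id": vial, "n": len(grp),
               "n_events": int((~cens).sum()),
               "km_median": np.nan if med is None else med,
               "weibull_scale": scale, "weibull_shape": shape,
               "converged": conv, "excluded": not conv}
        for c in extra:
            row[c] = grp[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)
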