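"""Product-limit (Kaplan-Meier) survival estimation and the log-rank test.

Right-censored all-cause mortality over fixed horizons (30 and 365 days in
the headline analysis). Ties follow the standard product-limit convention:
deaths are processed before censorings at the same time, so a record censored
at t is still at risk for the deaths at t.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import chi2

from .cohort import Cohort, PatientRecord

__all__ = ["KMCurve", "km_fit", "LogRankResult", "logrank", "mortality_at"]


@dataclass
class KMCurve:
    """Step survival estimate over the distinct event (death) times."""

    event_times: np.ndarray  # distinct death times, ascending
    at_risk: np.ndarray      # risk-set size just before each event time
    events: np.ndarray       # deaths at each event time
    survival: np.ndarray     # S(t) just after each event time

    def survival_at(self, t: float) -> float:
        """S(t); 1 before the first death."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.event_times, "at_risk": self.at_risk,
             "events": self.events, "survival": self.survival}
        )


def km_fit(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Product-limit estimator from follow-up times and death indicators."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("km_fit requires at least one subject")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")

    death_times = np.unique(t[e])
    at_risk = np.empty(death_times.size, dtype=int)
    deaths = np.empty(death_times.size, dtype=int)
    for i, dt in enumerate(death_times):
        at_risk[i] = int(np.sum(t >= dt))  # censored at dt are still at risk
        deaths[i] = int(np.sum(e & (t == dt)))
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - deaths / at_risk
    survival = np.cumprod(factors)
    return KMCurve(event_times=death_times, at_risk=at_risk, events=deaths, survival=survival)


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]
    degenerate: bool = False  # no events in either group


def logrank(
    group_a: tuple[Sequence[float], Sequence[bool]],
    group_b: tuple[Sequence[float], Sequence[bool]],
) -> LogRankResult:
    """Two-group log-rank chi-square (1 df), summed hypergeometric moments."""
    ta = np.asarray(group_a[0], dtype=float)
    ea = np.asarray(group_a[1], dtype=bool)
    tb = np.asarray(group_b[0], dtype=float)
    eb = np.asarray(group_b[1], dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")

    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    death_times = np.unique(all_t[all_e])
    if death_times.size == 0:
        return LogRankResult(0.0, 1.0, (0.0, 0.0), (0.0, 0.0), degenerate=True)

    o_a = e_a = var = 0.0
    total_d = [0.0, 0.0]
    for dt in death_times:
        n1 = int(np.sum(ta >= dt))
        n2 = int(np.sum(tb >= dt))
        n = n1 + n2
        d1 = int(np.sum(ea & (ta == dt)))
        d2 = int(np.sum(eb & (tb == dt)))
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        o_a += d1
        e_a += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
        total_d[0] += d1
        total_d[1] += d2
    if var == 0.0:
        return LogRankResult(0.0, 1.0, (total_d[0], total_d[1]),
                             (e_a, sum(total_d) - e_a), degenerate=True)
    stat = (o_a - e_a) ** 2 / var
    return LogRankResult(
        statistic=float(stat),
        p_value=float(chi2.sf(stat, df=1)),
        observed=(total_d[0], total_d[1]),
        expected=(float(e_a), float(sum(total_d) - e_a)),
    )


def cohort_km(cohort: Cohort, horizon_days: int | None = None) -> KMCurve:
    """KM curve for a cohort; follow-up optionally truncated at a horizon."""
    times, events = [], []
    for r in cohort:
        t, e = r.followup_days, bool(r.death)
        if horizon_days is not None and t > horizon_days:
            t, e = horizon_days, False
        times.append(t)
        events.append(e)
    return km_fit(times, events)


def mortality_at(
    cohort: Cohort,
    predicate: Callable[[PatientRecord], bool],
    horizon_days: int,
) -> tuple[float | None, int, int]:
    """Crude death proportion within a horizon among predicate-selected records.

    Returns ``(proportion, deaths, n_selected)``; the proportion is ``None``
    (undefined) when no record is selected.
    """
    if horizon_days < 0:
        raise ValueError("horizon_days must be non-negative")
    selected = [r for r in cohort if predicate(r)]
    if not selected:
        return None, 0, 0
    deaths = sum(1 for r in selected if r.death and r.followup_days <= horizon_days)
    return deaths / len(selected), deaths, len(selected)
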