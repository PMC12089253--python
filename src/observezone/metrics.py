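"""Diagnostic performance of a low-risk rule against death within a horizon.

Convention: the *positive* test is "flagged not-low-risk" (kept in hospital
for work-up); the event is all-cause death within ``horizon_days``. A
low-risk patient therefore contributes a true negative (no event) or a false
negative (event); a flagged patient a true positive (event) or false
positive. NPV is the safety metric of the rule-out arm, the false-negative
rate (FNR) the share of deaths the rule waves through.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable

from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .cohort import Cohort, PatientRecord

__all__ = [
    "ConfusionTable",
    "MetricEstimate",
    "StratumPerformance",
    "confusion_from_rule",
    "performance",
    "risk_reduction",
    "RiskReduction",
    "eligibility",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, the convention of printed clinical tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """Counts with positive = flagged not-low-risk, event = death in horizon."""

    tp: int
    fp: int
    tn: int
    fn: int
    horizon_days: int | None = None
    n_censored_before_horizon: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def deaths(self) -> int:
        return self.tp + self.fn

    @property
    def survivors(self) -> int:
        return self.tn + self.fp


def confusion_from_rule(
    cohort: Cohort,
    low_risk_predicate: Callable[[PatientRecord], bool],
    horizon_days: int,
) -> ConfusionTable:
    """Cross-classify a low-risk rule against death within the horizon.

    A record censored alive before the horizon counts as a non-event; the
    number of such records is carried on the result so callers can judge
    whether ascertainment was complete.
    """
    if horizon_days <= 0:
        raise ValueError("horizon_days must be positive")
    tp = fp = tn = fn = censored = 0
    for rec in cohort:
        event = bool(rec.death) and rec.followup_days <= horizon_days
        if not event and not rec.death and rec.followup_days < horizon_days:
            censored += 1
        if low_risk_predicate(rec):
            if event:
                fn += 1
            else:
                tn += 1
        else:
            if event:
                tp += 1
            else:
                fp += 1
    return ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn, horizon_days=horizon_days,
                          n_censored_before_horizon=censored)


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its 95% CI; ``defined`` is False on a zero denominator."""

    value: float | None
    ci: tuple[float, float] | None
    defined: bool = True

    @property
    def pct(self) -> float | None:
        return None if self.value is None else 100.0 * self.value


def _logit_ci(k: int, n: int, alpha: float) -> tuple[float, float]:
    # standard-logit interval; falls back to Clopper-Pearson at the boundary
    if k == 0 or k == n:
        return proportion_confint(k, n, alpha=alpha, method="beta")
    p = k / n
    z = norm.ppf(1 - alpha / 2)
    logit = math.log(p / (1 - p))
    se = math.sqrt(1.0 / k + 1.0 / (n - k))
    lo, hi = logit - z * se, logit + z * se
    return 1 / (1 + math.exp(-lo)), 1 / (1 + math.exp(-hi))


def _estimate(k: int, n: int, method: str, alpha: float) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(value=None, ci=None, defined=False)
    if method == "clopper-pearson":
        ci = proportion_confint(k, n, alpha=alpha, method="beta")
    elif method == "logit":
        ci = _logit_ci(k, n, alpha)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return MetricEstimate(value=k / n, ci=(float(ci[0]), float(ci[1])))


@dataclass(frozen=True)
class StratumPerformance:
    npv: MetricEstimate
    ppv: MetricEstimate
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    fnr: MetricEstimate
    eligibility: MetricEstimate
    horizon_days: int | None
    table: ConfusionTable


def performance(
    ct: ConfusionTable, ci_method: str = "default", alpha: float = 0.05
) -> StratumPerformance:
    """All Table-style metrics from one confusion table.

    ``ci_method`` "default" uses exact Clopper-Pearson for sensitivity,
    specificity, FNR and eligibility and the standard-logit interval for the
    predictive values (the usual convention of clinical-statistics packages);
    "clopper-pearson" or "logit" force one method everywhere. Metrics with a
    zero denominator are flagged undefined, never silently NaN.
    """
    if ci_method == "default":
        exact, pred = "clopper-pearson", "logit"
    else:
        exact = pred = ci_method
    return StratumPerformance(
        npv=_estimate(ct.tn, ct.tn + ct.fn, pred, alpha),
        ppv=_estimate(ct.tp, ct.tp + ct.fp, pred, alpha),
        sensitivity=_estimate(ct.tp, ct.tp + ct.fn, exact, alpha),
        specificity=_estimate(ct.tn, ct.tn + ct.fp, exact, alpha),
        fnr=_estimate(ct.fn, ct.tp + ct.fn, exact, alpha),
        eligibility=_estimate(ct.tn + ct.fn, ct.total, exact, alpha),
        horizon_days=ct.horizon_days,
        table=ct,
    )


@dataclass(frozen=True)
class RiskReduction:
    relative: float  # fraction of baseline risk removed
    absolute: float  # percentage points on the proportion scale (as a fraction)


def risk_reduction(p_baseline: float, p_new: float) -> RiskReduction:
    """Relative and absolute risk reduction between two event proportions."""
    if not (0.0 <= p_new <= p_baseline <= 1.0):
        raise ValueError("need 0 <= p_new <= p_baseline <= 1")
    if p_baseline == 0.0:
        raise ValueError("relative risk reduction undefined at zero baseline risk")
    return RiskReduction(relative=(p_baseline - p_new) / p_baseline,
                         absolute=p_baseline - p_new)


def eligibility(
    cohort: Cohort,
    predicate: Callable[[PatientRecord], bool],
    ci_method: str = "clopper-pearson",
    alpha: float = 0.05,
) -> MetricEstimate:
    """Fraction of the cohort a rule would route to out-of-hospital work-up."""
    if len(cohort) == 0:
        raise ValueError("eligibility undefined on an empty cohort")
    k = sum(1 for r in cohort if predicate(r))
    return _estimate(k, len(cohort), ci_method, alpha)
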