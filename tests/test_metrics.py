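"""Confusion tables, predictive values, risk reductions, and CI behaviour."""

import numpy as np
import pytest
from statsmodels.stats.proportion import proportion_confint

from observezone.cohort import Cohort, PatientRecord
from observezone.metrics import (
    ConfusionTable,
    confusion_from_rule,
    eligibility,
    performance,
    risk_reduction,
    round_half_up,
)
from observezone.synthetic import generate_cohort, rapid_like_config


def _rec(pid, death, fu, score):
    return PatientRecord(patient_id=pid, hs_ctnt_0h=16.0, death=death,
                         followup_days=fu, grace_score=score)


def test_confusion_from_grace_rule_on_published_counts(rapid_cohort):
    ct = confusion_from_rule(rapid_cohort, lambda r: r.grace_score < 109, 365)
    assert (ct.tp, ct.fp, ct.tn, ct.fn) == (44, 555, 357, 5)
    assert ct.deaths == 49 and ct.total == 961


def test_zero_death_cohort():
    cohort = Cohort([_rec(f"p{i}", False, 365, 100) for i in range(10)])
    ct = confusion_from_rule(cohort, lambda r: r.grace_score < 109, 365)
    assert ct.tp == ct.fn == 0 and ct.tn == 10


def test_confusion_matches_per_record_loop():
    cohort = generate_cohort(rapid_like_config(n=400, seed=2))
    pred = lambda r: r.grace_score < 109  # noqa: E731
    ct = confusion_from_rule(cohort, pred, 365)
    tp = fp = tn = fn = 0
    for r in cohort:
        event = r.death and r.followup_days <= 365
        if pred(r):
            fn, tn = fn + event, tn + (not event)
        else:
            tp, fp = tp + event, fp + (not event)
    assert (ct.tp, ct.fp, ct.tn, ct.fn) == (tp, fp, tn, fn)


def test_death_beyond_horizon_is_not_an_event():
    cohort = Cohort([_rec("a", True, 400, 95), _rec("b", False, 365, 95)])
    ct = confusion_from_rule(cohort, lambda r: True, 365)
    assert ct.fn == 0 and ct.tn == 2


def test_censoring_before_horizon_is_counted():
    cohort = Cohort([_rec("a", False, 100, 95)])
    ct = confusion_from_rule(cohort, lambda r: True, 365)
    assert ct.tn == 1 and ct.n_censored_before_horizon == 1


@pytest.mark.parametrize(
    "counts, npv, se, sp, ppv",
    [
        # GRACE<109 row: published NPV/Se; Sp and PPV follow the exact count
        # arithmetic (the published table rounds those two cells up by 0.001)
        ((44, 555, 357, 5), 0.986, 0.898, 0.391, 0.073),
        ((48, 695, 217, 1), 0.995, 0.980, None, None),     # no-abnormal row
    ],
)
def test_performance_point_estimates(counts, npv, se, sp, ppv):
    tp, fp, tn, fn = counts
    perf = performance(ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn))
    assert perf.npv.value == pytest.approx(npv, abs=5e-4)
    assert perf.sensitivity.value == pytest.approx(se, abs=5e-4)
    if sp is not None:
        assert perf.specificity.value == pytest.approx(sp, abs=5e-4)
    if ppv is not None:
        assert perf.ppv.value == pytest.approx(ppv, abs=5e-4)
    assert perf.fnr.value == pytest.approx(1 - perf.sensitivity.value, abs=1e-12)


def test_fnr_of_no_abnormal_rule():
    perf = performance(ConfusionTable(tp=48, fp=695, tn=217, fn=1))
    assert perf.fnr.value == pytest.approx(0.020, abs=5e-4)
    assert perf.npv.value == pytest.approx(0.995, abs=5e-4)


def test_undefined_metrics_are_flagged_not_nan():
    perf = performance(ConfusionTable(tp=0, fp=0, tn=10, fn=0))
    assert not perf.sensitivity.defined and perf.sensitivity.value is None
    assert not perf.ppv.defined
    assert perf.npv.defined and perf.npv.value == 1.0


def test_npv_complement_identity():
    perf = performance(ConfusionTable(tp=3, fp=7, tn=50, fn=2))
    assert perf.npv.value + 2 / 52 == pytest.approx(1.0, abs=1e-15)


def test_eligibility_identity():
    ct = ConfusionTable(tp=44, fp=555, tn=357, fn=5)
    perf = performance(ct)
    assert perf.eligibility.value == pytest.approx((357 + 5) / 961, abs=1e-15)


def test_risk_reduction_published_pair():
    rr = risk_reduction(0.0138, 0.0046)
    assert 100 * rr.relative == pytest.approx(66.7, abs=0.05)
    assert 100 * rr.absolute == pytest.approx(0.92, abs=0.005)


def test_risk_reduction_fnr_pair():
    rr = risk_reduction(0.102, 0.020)
    assert 100 * rr.relative == pytest.approx(80.4, abs=0.05)


def test_risk_reduction_degenerate_and_errors():
    rr = risk_reduction(0.3, 0.3)
    assert rr.relative == 0.0 and rr.absolute == 0.0
    with pytest.raises(ValueError):
        risk_reduction(0.0, 0.0)
    with pytest.raises(ValueError):
        risk_reduction(0.1, 0.2)


def test_eligibility_on_cohort(rapid_cohort):
    est = eligibility(rapid_cohort, lambda r: r.grace_score < 109)
    assert est.value == pytest.approx(362 / 961)
    est0 = eligibility(rapid_cohort, lambda r: False)
    assert est0.value == 0.0


def test_ci_methods_differ_but_bracket_estimate():
    ct = ConfusionTable(tp=44, fp=555, tn=357, fn=5)
    cp = performance(ct, ci_method="clopper-pearson")
    lg = performance(ct, ci_method="logit")
    for perf in (cp, lg):
        for est in (perf.npv, perf.sensitivity, perf.specificity, perf.ppv):
            assert est.ci[0] <= est.value <= est.ci[1]
    assert cp.npv.ci != lg.npv.ci


def test_clopper_pearson_empirical_coverage():
    """Exact intervals keep >= 95% coverage over simulated binomial draws."""
    rng = np.random.default_rng(42)
    n, p, reps = 50, 0.3, 2000
    k = rng.binomial(n, p, size=reps)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
    # same exact method the sensitivity/specificity CIs use
    perf = performance(ConfusionTable(tp=int(k[0]), fp=0, tn=0, fn=n - int(k[0])))
    ref = proportion_confint(int(k[0]), n, alpha=0.05, method="beta")
    assert perf.sensitivity.ci == pytest.approx(ref)
    coverage = np.mean((lo <= p) & (p <= hi))
    assert coverage >= 0.95


def test_round_half_up_matches_table_convention():
    assert round_half_up(37.65, 1) == 37.7
    assert round_half_up(34.55, 1) == 34.6
    assert round_half_up(22.68, 1) == 22.7
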