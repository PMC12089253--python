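"""Product-limit estimator and log-rank test, with lifelines as the oracle."""

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from observezone.cohort import Cohort, PatientRecord
from observezone.pipeline import rule_predicate
from observezone.survival import km_fit, logrank, mortality_at


def test_hand_computed_product_limit():
    # 5 subjects: death day 1, censor day 2, death day 3, censored later
    times = [1, 2, 3, 10, 10]
    events = [True, False, True, False, False]
    km = km_fit(times, events)
    assert km.survival_at(1) == pytest.approx(0.8)
    assert km.survival_at(2) == pytest.approx(0.8)
    assert km.survival_at(3) == pytest.approx(0.8 * (2 / 3), abs=1e-12)
    assert list(km.event_times) == [1, 3]
    assert list(km.at_risk) == [5, 3]


def test_no_events_flat_curve():
    km = km_fit([5, 6, 7], [False, False, False])
    assert km.event_times.size == 0
    assert km.survival_at(100) == 1.0


def test_all_die_at_day_one():
    km = km_fit([1, 1, 1], [True, True, True])
    assert km.survival_at(1) == 0.0


def test_tied_death_and_censoring_death_first():
    # censored subject at t=2 is still at risk for the death at t=2
    km = km_fit([2, 2, 5], [True, False, False])
    assert km.at_risk[0] == 3
    assert km.survival_at(2) == pytest.approx(2 / 3)


def test_km_fit_input_validation():
    with pytest.raises(ValueError):
        km_fit([], [])
    with pytest.raises(ValueError):
        km_fit([1, 2], [True])
    with pytest.raises(ValueError):
        km_fit([-1], [True])


def test_logrank_identical_groups_is_zero():
    times, events = [1, 3, 5, 8], [True, False, True, True]
    res = logrank((times, events), (times, events))
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_symmetric_in_group_order():
    a = ([1, 2, 4, 9], [True, True, False, True])
    b = ([3, 5, 7, 8], [False, True, True, False])
    assert logrank(a, b).statistic == pytest.approx(logrank(b, a).statistic, abs=1e-12)


def test_logrank_small_toy_against_hand_hypergeometric_sums():
    # groups A: death@1, death@3; B: death@2, censor@4
    a = ([1, 3], [True, True])
    b = ([2, 4], [True, False])
    # t=1: n=4 (2,2), d=1 in A: E=0.5, V=1*(2/4)*(2/4)*(3/3)=0.25
    # t=2: n=3 (1,2), d=1 in B: E=1/3, V=(1/3)*(2/3)*(1/1)... = 2/9
    # t=3: n=2 (1,1), d=1 in A: E=0.5, V=0.25
    o_minus_e = (1 - 0.5) + (0 - 1 / 3) + (1 - 0.5)
    var = 0.25 + 2 / 9 + 0.25
    res = logrank(a, b)
    assert res.statistic == pytest.approx(o_minus_e**2 / var, abs=1e-12)
    assert res.observed == (2.0, 1.0)


def test_zero_events_degenerate():
    res = logrank(([1, 2], [False, False]), ([3], [False]))
    assert res.degenerate and res.statistic == 0.0 and res.p_value == 1.0


def test_agreement_with_lifelines_on_random_cohorts():
    """100 random censored cohorts: S(t) to 1e-10, chi-square to 1e-8."""
    rng = np.random.default_rng(77)
    for _ in range(100):
        n1, n2 = rng.integers(5, 40, size=2)
        t1 = rng.integers(1, 25, size=n1).astype(float)
        t2 = rng.integers(1, 25, size=n2).astype(float)
        e1 = rng.random(n1) < 0.5
        e2 = rng.random(n2) < 0.5
        if not (e1.any() or e2.any()):
            e1[0] = True
        km = km_fit(t1, e1)
        kmf = KaplanMeierFitter().fit(t1, e1)
        for t in km.event_times:
            assert km.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10)
        ours = logrank((t1, e1), (t2, e2))
        ref = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert ours.statistic == pytest.approx(ref.test_statistic, abs=1e-8)
        assert ours.p_value == pytest.approx(ref.p_value, abs=1e-8)


def test_km_tail_equals_one_minus_crude_mortality_without_censoring():
    rng = np.random.default_rng(9)
    t = rng.integers(1, 300, size=80).astype(float)
    e = rng.random(80) < 0.4
    t[~e] = 365.0  # all censoring at the horizon
    km = km_fit(t, e)
    assert km.survival_at(365) == pytest.approx(1 - e.mean(), abs=1e-12)


def _rec(pid, death, fu, score):
    return PatientRecord(patient_id=pid, hs_ctnt_0h=16.0, death=death,
                         followup_days=fu, grace_score=score)


def test_mortality_at_published_rates(rapid_cohort, bacc_cohort):
    rate, d, n = mortality_at(rapid_cohort, rule_predicate("grace_lt109"), 365)
    assert (d, n) == (5, 362) and 100 * rate == pytest.approx(1.38, abs=0.005)
    rate, d, n = mortality_at(bacc_cohort, rule_predicate("grace_lt109_le1_abnormal"), 365)
    assert (d, n) == (2, 51) and 100 * rate == pytest.approx(3.92, abs=0.005)


def test_mortality_horizon_zero_and_empty_selection():
    cohort = Cohort([_rec("a", True, 180, 95)])
    rate, d, n = mortality_at(cohort, lambda r: True, 0)
    assert rate == 0.0 and d == 0
    rate, d, n = mortality_at(cohort, lambda r: False, 365)
    assert rate is None and n == 0


def test_no_low_risk_deaths_within_30_days(rapid_cohort):
    rate, d, n = mortality_at(rapid_cohort, rule_predicate("grace_lt109_le1_abnormal"), 30)
    assert d == 0 and n == 332
    low = rapid_cohort.select(rule_predicate("grace_lt109_le1_abnormal"))
    rest = rapid_cohort.select(lambda r: not rule_predicate("grace_lt109_le1_abnormal")(r))
    res = logrank(
        ([min(r.followup_days, 30) for r in low], [r.death and r.followup_days <= 30 for r in low]),
        ([min(r.followup_days, 30) for r in rest], [r.death and r.followup_days <= 30 for r in rest]),
    )
    # zero events at 30 d in the fixture: the comparison is degenerate
    assert res.degenerate
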