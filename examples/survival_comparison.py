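"""Kaplan-Meier comparison of the combined low-risk rule vs the rest.

On the derivation fixture, patients with GRACE < 109 and at most one abnormal
marker are compared with everyone else at 30 days and 1 year. The low-risk
arm has zero 30-day deaths (a degenerate log-rank) and a markedly flatter
1-year curve.
"""

from observezone import build_fixture
from observezone.pipeline import survival_comparison

cohort = build_fixture("RAPID_CPU")
res = survival_comparison(cohort, rule="grace_lt109_le1_abnormal")

for horizon, r in res["horizons"].items():
    lr = r["logrank"]
    print(f"\n--- {horizon}-day horizon ---")
    print(f"deaths: low-risk arm {r['deaths_low']}, rest {r['deaths_rest']}")
    s_low = r["km_low"].survival_at(horizon)
    s_rest = r["km_rest"].survival_at(horizon)
    print(f"KM survival at {horizon} d: low-risk {s_low:.4f}, rest {s_rest:.4f}")
    if lr.degenerate:
        print("log-rank: degenerate (no events in the comparison window)")
    else:
        print(f"log-rank: chi2 = {lr.statistic:.2f}, p = {lr.p_value:.2e}")
print("\nA survival of 0.9910 in the low-risk arm at 365 d is the KM restatement "
      "of the 3/332 one-year mortality of that stratum.")
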