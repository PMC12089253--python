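# observezone

Risk stratification for patients with suspected non-ST-elevation acute
coronary syndrome (NSTE-ACS) who land in the **observe zone** of the ESC
0/1-h high-sensitivity troponin T algorithm — the group that meets neither
the rule-out nor the rule-in criteria and carries a ~5% one-year mortality.
The package is aimed at clinical researchers and biostatisticians who want to
evaluate, audit, or re-derive observe-zone triage rules on their own registry
exports without a data download: it ships a synthetic-cohort generator and
exact published-count fixtures so every headline number is recomputable
offline.

## What it computes

1. **ESC 0/1-h triage** — rule-out (`0 h < 5 ng/L` more than 3 h after onset,
   or `0 h < 12 ng/L` with `|Δ1h| < 3 ng/L`), rule-in (`0 h ≥ 52 ng/L` or
   `|Δ1h| ≥ 5 ng/L`), observe zone otherwise.
2. **GRACE 1.0 score** — the eight-variable admission model (age, heart
   rate, systolic BP, creatinine, Killip class, cardiac arrest, ST-segment
   deviation, elevated enzymes) with the conventional categories
   low < 109, intermediate 109–140, high > 140 points.
3. **Six-marker panel** — abnormal when CRP ≥ 10 mg/dL, NT-proBNP ≥ 300 ng/L,
   D-dimer ≥ 5 mg/L, eGFR ≤ 30 mL/min/1.73 m² (CKD-EPI 2021 from creatinine
   when not reported), copeptin ≥ 10 pmol/L, or hemoglobin ≤ 10 g/dL; missing
   markers never count as abnormal.
4. **Fixed risk tree** — GRACE < 109 gate, then the abnormal-marker count
   (0 / ≤1 / >1); plus a from-scratch CART learner (Gini, midpoint
   thresholds, depth 2, min leaf 20) with bootstrap internal validation that
   rediscovers the tree from data.
5. **Performance and survival** — confusion tables against death within a
   horizon, NPV/PPV/Se/Sp/FNR/eligibility with exact (Clopper–Pearson) and
   standard-logit 95% CIs, relative/absolute risk reduction, Kaplan–Meier
   curves and the two-group log-rank test at 30 and 365 days.

## Worked example

```python
from observezone import build_fixture
from observezone.pipeline import evaluate_rules

cohort = build_fixture("RAPID_CPU")      # 961 observe-zone records, 49 deaths
print(evaluate_rules(cohort, 365)[["rule", "npv", "se", "eligibility", "fnr"]])
```

or, from the shell, `observezone repro --which rapid`, which prints

```
                    rule  npv   se   sp  ppv  eligibility  fnr
             grace_lt109 98.6 89.8 39.1  7.3         37.7 10.2
grace_lt109_le1_abnormal 99.1 93.9 36.1  7.3         34.5  6.1
 grace_lt109_no_abnormal 99.5 98.0 23.8  6.5         22.7  2.0
grace_lt109: 365-d mortality 1.38% (5/362)
grace_lt109_le1_abnormal: 365-d mortality 0.9% (3/332)
grace_lt109_no_abnormal: 365-d mortality 0.46% (1/218)
```

Reading: a GRACE score < 109 alone already identifies a stratum (37.7% of the
observe zone) whose one-year mortality is 1.38% with an NPV of 98.6%.
Requiring in addition that no panel marker is abnormal drops mortality to
0.46% and the false-negative rate from 10.2% to 2.0%, at the price of a
smaller eligible fraction (22.7%). The `grace_lt109_le1_abnormal` row is the
compromise rule (≤ 1 abnormal marker) validated externally
(`observezone repro --which bacc`).

The `examples/` directory holds one narrative script per capability
(headline tables, triage/GRACE/panel on hand-made patients, CART split
recovery with bootstrap, KM/log-rank comparison, synthetic-cohort
generation); each prints what it computes and what the numbers mean.

## Command line

`observezone` exposes thin subcommands over the library: `triage`, `grace`,
`panel`, `stratify`, `cart-fit`, `evaluate`, `survival`, `simulate`,
`fixture`, `repro`, and `run` (full pipeline with an atomic output bundle
and JSON run log). All I/O is CSV with a documented header
(`observezone.cohort.COLUMNS`); a `key = value` mapping file adapts foreign
column names.

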