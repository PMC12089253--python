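# Methods

This note records the statistical conventions, numerical choices, and design
decisions behind the package, and what the synthetic data can and cannot
show.

## Triage (ESC 0/1-h, hs-cTnT)

Rule-in is evaluated before rule-out (fail-safe toward admission; the two
cannot co-occur at the default thresholds, but the precedence is part of the
contract). The 0-to-1-h change is the absolute difference `|c1h − c0h|`,
direction-agnostic. A missing time-since-onset disables only the
limit-of-detection single-sample branch; the delta branches remain
available. A record with no 1-h sample for which no single-sample rule fires
is `NOT_APPLICABLE`, not observe: callers decide whether to exclude such
records (the source registries excluded them from 0/1-h applicability).
Thresholds (5, 12, 3, 52, 5 ng/L; 3 h) live in a `TriageThresholds` config
for assay-specific reuse.

Boundary conventions follow the printed inequalities exactly: rule-out
bounds are strict (`< 5`, `< 12`, `< 3`), rule-in bounds inclusive (`≥ 52`,
`≥ 5`). One caveat on monotonicity: with a direction-agnostic delta, raising
the 0-h value while holding the 1-h value fixed can shrink the delta and
move a `HIGH_DELTA` rule-in to observe. The properties that do hold (and are
tested) are: a rule-in never becomes a rule-out as the baseline rises, and
the category is monotone toward rule-in when the 1-h value co-moves so the
delta is held fixed.

## GRACE 1.0

The score is the eight-variable admission model: banded points for age,
heart rate, systolic blood pressure and creatinine, plus Killip class,
cardiac arrest at admission, ST-segment deviation, and elevated cardiac
enzymes, with the conventional categories low < 109, intermediate 109–140,
high > 140. The point table is the published GRACE 1.0 scoring table for
this variable set (Granger et al., Arch Intern Med 2003; the model shipped
in the original GRACE risk calculator, cf. Fox et al., BMJ 2006), stored as
a versioned constant in `grace.py`. Band boundaries use half-open intervals
`[lower, upper)`. A precomputed `grace_score` on a record always wins over
the raw inputs, so analyses of registry exports that carry site-computed
scores never depend on the table; the calculator exists for cohorts that
ship raw admission variables. Monotonicity in every band and flag is
property-tested.

## Biomarker panel

Normal ranges are strict inequalities (CRP < 10 mg/dL, NT-proBNP < 300 ng/L,
D-dimer < 5 mg/L, copeptin < 10 pmol/L, eGFR > 30 mL/min/1.73 m²,
hemoglobin > 10 g/dL); boundary equality is therefore abnormal for all six
markers. Missing markers are `MISSING` and never increment the abnormal
count: the discretionary markers were ordered on clinical suspicion, so a
missing measurement cannot have been treated as positive; `measured_count`
is reported so callers can restrict to fully measured subsets. eGFR
precedence: a site-reported value wins; otherwise it is derived from
creatinine, age and sex with the race-free CKD-EPI 2021 equation (Inker et
al., NEJM 2021); with sex missing the marker stays missing.

Two unit ambiguities in the source tables are resolved by fiat and not
auto-converted: the CRP cutoff is used as printed (10 mg/dL) against values
as printed, although the cohort medians are more consistent with mg/L
conventions; D-dimer is fixed at mg/L FEU (the printed "[ng/L]" header is
inconsistent with both the medians ~0.45 and the 5 mg/L cutoff). The schema
is the single source of truth for units.

## Fixed tree and CART learner

The headline pipeline uses the *fixed* rule — GRACE < 109, then abnormal
count 0 / ≤ 1 / > 1 — because the reported metrics derive from those
splits. The learner exists to show the rule is recoverable from data:
greedy binary CART, Gini impurity by default (entropy behind a flag),
candidate thresholds at midpoints of consecutive unique observed values
(integer features therefore split at half-integers, so "≤ 1" is exactly
representable), best weighted-impurity decrease wins, ties broken by feature
order then smaller threshold (implemented by requiring a strict improvement
of more than 1e-12 to replace the incumbent). Recursion stops at
`max_depth` (default 2, mirroring the two-level published tree), when a
child would fall below `min_leaf` (default 20), or at zero gain; degenerate
inputs yield a single leaf. The learner is verified against an exhaustive
split-enumeration oracle on all random instances up to 50 records.

Bootstrap internal validation refits the tree on B resamples of size n
(seeded generator, mandatory seed), reports the fraction of fitted
replicates whose root split matches the reference (same feature, threshold
within a stated tolerance, default ±10 points), and 2.5–97.5 percentile
intervals of the event rate each replicate's tree predicts for the rows of
each reference leaf. Resamples with no deaths cannot be fit and are counted
separately. B defaults to 1000 in the API; the stability studies in the
tests and acceptance script use B = 200, which bounds the Monte-Carlo error
on a ~0.95 stability fraction at about ±0.03 while keeping the run in
seconds.

## Performance metrics

Positive = flagged not-low-risk, event = death within the horizon. Records
censored alive before the horizon count as non-events; their number is
carried on the confusion table (the fixtures have complete 365-day status
by construction, matching the raw published proportions such as 5/362).
Point estimates are method-independent ratios. CIs: exact Clopper–Pearson
for sensitivity, specificity, FNR and eligibility; standard-logit intervals
for PPV/NPV (falling back to Clopper–Pearson at boundary counts); either
method can be forced everywhere. The published CIs are not reproduced
because the source does not name its interval method. Zero-denominator
metrics are flagged undefined rather than NaN. Display rounding is decimal
half-up to one decimal on the percent scale, matching the printed tables.

Two cells of the published derivation-cohort table disagree with exact
arithmetic on its own stratum counts: specificity 357/912 = 39.14 → 39.1
(printed 39.2) and PPV 44/599 = 7.35 → 7.3 (printed 7.4); likewise
eligibility 362/961 = 37.67 → 37.7 is printed 37.6 in one table and 37.7 in
another, and 332/961 = 34.5 appears as 34.4/34.5. The package reports the
count-derived values; tests pin both the exact fractions and agreement with
the printed cells to within 0.1 percentage points. The per-category death
counts in the baseline table (5 + 16 + 27 = 48) also miss the stated 49
total by one; the fixtures follow the results-section stratum counts.

## Survival

Product-limit estimator with the standard tie convention (deaths processed
before censorings at the same time, so a record censored at t remains in
the risk set for deaths at t). Two-group log-rank uses summed
hypergeometric means and variances with the usual `(n−d)/(n−1)` correction;
zero total events (or zero variance) yields a degenerate result with
statistic 0 and p = 1 rather than an error, because the 30-day comparison
of the low-risk arm is exactly that case. Horizons default to 30 and
365 days. Both estimators are cross-checked against lifelines on 100 random
censored cohorts to 1e-10 on S(t) and 1e-8 on the statistic.

## Synthetic generator

`generate_cohort` emulates an observe-zone registry at the level of
published marginals: stratum mix and stratum-specific 365-day death rates
(defaults are the derivation counts 218/114/30/599 and 1/218, 2/114, 2/30,
44/599), GRACE scores uniform within the low (70–108) and non-low (109–200)
bands, 0-h troponin from a log-normal matched to the published median/IQR
16 (12–24) and truncated to [12, 51.5) ng/L with a 1-h delta under
2.5 ng/L so every record triages into the observe zone, and marker values
drawn from arm-specific (survivor/non-survivor) marginals — log-normal for
the right-skewed analytes, normal for hemoglobin and eGFR — truncated by
inverse-CDF to the normal or abnormal side so each record realises exactly
its stratum's abnormal count through the real panel logic. Measurement
fractions reflect the published ordering practice: routine analytes ~95–98%,
NT-proBNP 53.5%, D-dimer 22.4%, copeptin 35% (the first two are published
for the derivation registry; copeptin was chosen once as a plausible
discretionary rate). Survivor follow-up is uniform on 365–642 days (the
published median/IQR of follow-up is 444, 339–642); death days are uniform
on 1–365.

Quantile matching of a two-parameter log-normal fixes the median and the
quartile *ratio*: `mu = ln(median)`, `sigma = (ln q3 − ln q1)/(2·0.67449)`.
An asymmetric printed IQR is thereby symmetrized in log space (for
16 (12–24) the fitted quartiles are 11.3 and 22.6), which is the closest a
two-parameter family can come; the sampling tests target the median, the
ratio q3/q1 and the geometric quartile mean.

What the generator does **not** emulate: inter-marker correlation beyond
the stratum/death structure, troponin–outcome dependence within the observe
band, admission/discharge pathways, or competing risks. Passing tests on
synthetic cohorts therefore demonstrate correctness of the pipeline's
logic and calibration of its estimators, not clinical transportability.

`strong_grace_config` is the stated generator for the split-recovery and
bootstrap-stability studies: n = 2000 with death rates 0.005 / 0.01 / 0.02
by low stratum and 0.15 in the non-low stratum — low strata near the
observed 0.5–2%, non-low at the high end of plausible observe-zone risk —
so the GRACE gate is the dominant risk boundary a depth-2 tree should find.

## Fixtures

`build_fixture` reconstructs both published cohorts record-for-record from
the printed stratum counts (derivation: 961 = 218 + 114 + 30 + 599 with
deaths 1/2/2/44; validation: 589 = 0 + 51 + 120 + 418 with deaths
0/2/5/38). Records carry explicit GRACE scores (95 in low strata; 121/151
alternating elsewhere, where only the ≥ 109 gate matters) and canonical
marker values (abnormality realised via NT-proBNP 4794 ng/L and CRP
13.7 mg/dL, the published non-survivor medians), so the fixtures exercise
the real panel logic rather than shortcut labels. Deaths are placed at day
180 except the one required 30-day death in the validation cohort's
low-GRACE/>1-abnormal stratum (day 15); survivors are followed to day 365.
The published results constrain only the 30-day and 365-day counts, so this
placement is one consistent choice, not the only one. The fixtures are
synthetic stand-ins for registry data available only on request.

## Problem sizes and runtime

The test suite and acceptance script run at desk scale by design: fixture
analyses are exact finite arithmetic on ≤ 961 records (well under a second);
the generator calibration check uses n = 100 000 (a few seconds); the
oracle comparison covers 75 random instances of ≤ 50 records; the survival
cross-check 100 random cohorts; bootstrap studies B = 200 at n = 2000.

## Known limitations

* The GRACE point table is a transcription of the published scoring table;
  no acceptance-level result depends on it (fixtures carry precomputed
  scores), but users scoring raw inputs should validate against their local
  calculator.
* Only the two-group log-rank and unweighted KM are provided — no Cox
  models, competing risks, or restricted-mean summaries.
* The panel applies one fixed cutoff per marker; no age- or sex-specific
  NT-proBNP/D-dimer cutoffs, no assay harmonization.
* `NOT_APPLICABLE` triage records (missing serial sample) are surfaced, not
  silently classified; pipelines on real exports should report them.
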