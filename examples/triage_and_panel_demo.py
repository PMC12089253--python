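"""Walk three hand-made presentations through triage, GRACE and the panel.

Each patient gets an ESC 0/1-h triage category, a GRACE 1.0 score (computed
from the eight admission variables when no precomputed score is supplied), a
per-marker panel verdict, and the final risk stratum of the fixed tree.
"""

from observezone import PatientRecord, evaluate_panel, grace_assessment, triage
from observezone.pipeline import record_stratum

patients = [
    # late presenter, troponin below the limit of detection: ruled out
    PatientRecord(patient_id="ruled-out", hs_ctnt_0h=4.0, time_since_onset_h=6.0,
                  death=False, followup_days=365, grace_score=80),
    # observe-zone profile with a low GRACE score and one abnormal marker
    PatientRecord(patient_id="observe-low-risk", hs_ctnt_0h=16.0, hs_ctnt_1h=15.0,
                  death=False, followup_days=365, grace_score=95,
                  crp=3.1, ntprobnp=688.0, ddimer=0.44, copeptin=7.5,
                  hemoglobin=13.4, egfr=73.3),
    # observe-zone delta, GRACE computed from raw inputs, several abnormal markers
    PatientRecord(patient_id="observe-high-risk", hs_ctnt_0h=20.0, hs_ctnt_1h=23.0,
                  death=False, followup_days=365,
                  age_y=81, heart_rate_bpm=97, sbp_mmHg=129, creatinine_mg_dl=1.4,
                  killip_class=2, cardiac_arrest=False, st_deviation=True,
                  elevated_enzymes=True, sex="M",
                  crp=13.7, ntprobnp=4794.0, ddimer=5.4, copeptin=12.2,
                  hemoglobin=12.2),
]

for rec in patients:
    tri = triage(rec)
    g = grace_assessment(rec)
    panel = evaluate_panel(rec)
    abnormal = [m for m, s in panel.status.items() if s.value == "ABNORMAL"]
    print(f"{rec.patient_id}: triage={tri.category.value} ({tri.reason.value}); "
          f"GRACE={g.score} [{g.category.value}]; "
          f"abnormal={panel.abnormal_count}/{panel.measured_count} {abnormal}; "
          f"stratum={record_stratum(rec).value}")

print("\nOnly observe-zone patients enter the stratification; the last patient's "
      "eGFR comes from the CKD-EPI 2021 equation since only creatinine was given.")
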