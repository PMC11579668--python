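# Virtual glycemic management service (vGMS): a remote endocrinology team
# reviews the charts of all inpatients meeting dysglycemia reporting criteria
# in the last 24 h and adds management recommendations before morning rounds.
# Published effects reported on patient-days with >= 1 hypoglycemic event,
# so both channels require calibration onto the event-level measure.
# Staffing reference salaries are site-specific and not published; lines are
# funded (new money required) with hours reported regardless.
name: vgms
target_population: all_adult_nonobstetric
published_effect:
  outcome_measure: patient_days
  rr_total_hypo: 0.64    # 95% CI 0.57-0.70
  rr_severe_hypo: 0.31   # 95% CI 0.15-0.59
elicited_rrs:
  realistic: {total_hypo: 0.76, severe_hypo: 0.50}
  optimistic: {total_hypo: 0.70, severe_hypo: 0.20}
  pessimistic: {total_hypo: 0.82, severe_hypo: 0.75}
reporting_criteria:
  min_hyper: 2     # >= 2 hyperglycemia events (>15.0 mmol/L), or
  min_hypo: 1      # >= 1 hypoglycemia event (<4.0 mmol/L)
  window_days: 1   # in the previous 24 h (one model day)
resources:
  staff:
    - {role: endocrinology registrar, fte: 0.2, annual_salary: null, funded: true}
    - {role: CDE nurse, fte: 0.2, annual_salary: null, funded: true}
    - {role: CDE pharmacist, fte: 0.2, annual_salary: null, funded: true}
  once_off_hours: 0
  per_cycle_hours: {}
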