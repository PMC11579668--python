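# Pharmacist-led peri-operative glycemic management team (GMT): takes over
# glycemic management of surgical patients on surgeon request. Published
# effect reported on patients with >= 1 hypoglycemic event; the same study
# yields RR 0.46 or 0.38 depending on the reporting publication, shipped as
# published_variants. Excluded after the preliminary evaluation on staffing
# cost grounds (2.0 FTE pharmacists, AU$210,000/yr), so no elicited RRs
# exist; kept so the exclusion decision is reproducible.
name: gmt_pharmacist
target_population: surgical_incl_icu
published_effect:
  outcome_measure: patients
  rr_total_hypo: 0.46    # 95% CI 0.38-0.57
  rr_severe_hypo: null
published_variants: [0.46, 0.38]
elicited_rrs: {}
reporting_criteria: null
resources:
  staff:
    - {role: pharmacist, fte: 1.0, annual_salary: 105000, funded: true}
    - {role: pharmacist, fte: 1.0, annual_salary: 105000, funded: true}
  once_off_hours: 0
  per_cycle_hours: {}
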