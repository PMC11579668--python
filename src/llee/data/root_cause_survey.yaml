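# Root cause survey with targeted education: an automated EMR pop-up survey
# completed by nurses after each hypoglycemic event, feeding brief targeted
# education sessions. Published effect reported directly on hypoglycemic
# PoC-BGL measurements (the common event-level measure). The severe channel
# has no published or elicited estimate and inherits the total-hypo RR.
name: root_cause_survey
target_population: all_adult_nonobstetric
published_effect:
  outcome_measure: events
  rr_total_hypo: 0.68
  rr_severe_hypo: null
elicited_rrs:
  realistic: {total_hypo: 0.85, severe_hypo: null}
  optimistic: {total_hypo: 0.80, severe_hypo: null}
  pessimistic: {total_hypo: 0.90, severe_hypo: null}
reporting_criteria: null
survey_per_event: true
resources:
  staff: []
  once_off_hours: 88          # develop and test the survey in the EMR
  per_cycle_hours:            # per survey cycle
    nursing_survey_completion: 25
    implementation_education: 19
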