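# SYNTHETIC example configuration: a hypothetical stand-alone clinic offering
# only screening mammography and same-day diagnostic workups.
#
# The parameter values below are user-editable placeholders, NOT calibrated to
# any real clinic.  Edit them to match your own setting, then run e.g.:
#   recallsim matrix --config examples/standalone_screening_clinic.yaml --out results/
checkin_cutoff: 9.5
close: 10.0
no_show_rate: 0.10
expected_checked_in_per_day: 65.0
type_mix:
  screening_mammo: 0.85   # placeholder: screening-dominated volume
  screening_us: 0.0
  diagnostic: 0.15        # same-day / recall diagnostics only
  biopsy: 0.0
biopsy_subtype_mix: [0.3334, 0.3333, 0.3333]
same_day_mix: [0.70, 0.15, 0.15]
scheduled_diagnostic_mix: [0.70, 0.15, 0.15]
followup_delay_mean_days: 20.0
followup_delay_sd_days: 4.0
followup_slot_multiplier: 0.67
resources:
  staff: 3
  consent: 1
  dressing: 3
  gowned_wait: 5
  public_wait: 20
  mammo_tech: 4           # placeholder: extra mammography capacity
  us_tech: 2
  radiologist: 4
service_times:
  checkin: {mean: 0.05, sd: 0.01, family: normal_truncated}
  public_wait_dwell: {mean: 0.17, sd: 0.034, family: normal_truncated}
  consent: {mean: 0.17, sd: 0.034, family: normal_truncated}
  dressing: {mean: 0.03, sd: 0.006, family: normal_truncated}
  gowned_wait_dwell: {mean: 0.017, sd: 0.0034, family: normal_truncated}
  ai_assessment: {mean: 0.25, sd: 0.05, family: normal_truncated}
  screening_mammo: {mean: 0.17, sd: 0.034, family: normal_truncated}
  screening_us: {mean: 0.25, sd: 0.05, family: normal_truncated}
  diagnostic_mammo: {mean: 0.417, sd: 0.0834, family: normal_truncated}
  diagnostic_us: {mean: 0.417, sd: 0.0834, family: normal_truncated}
  diagnostic_review: {mean: 0.083, sd: 0.017, family: normal_truncated}
  biopsy_stereo: {mean: 0.75, sd: 0.15, family: normal_truncated}
  biopsy_us: {mean: 0.75, sd: 0.15, family: normal_truncated}
  biopsy_mr: {mean: 0.5, sd: 0.1, family: normal_truncated}
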