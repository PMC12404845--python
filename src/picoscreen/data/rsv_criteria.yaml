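# Default criteria configuration: RSV vaccine safety scenario.
scenario: rsv_vaccine_safety
picos:
  population: individuals who received the RSV vaccine
  intervention: administration of the RSV vaccine
  comparison: null
  outcomes: safety-related outcomes, such as local adverse events at the injection
    site, systemic adverse events, and serious adverse events
  study_design: experimental and observational studies
exclusion_reasons:
  intervention_comparator: Unrelated to RSV vaccine
  population: Research subjects did not receive the RSV vaccine
  outcome: Not a safety study of RSV vaccine
  study_design: Not an experimental or observational study
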