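# Default synthetic pooled-cohort configuration.  Marginal risk-factor
# moments and prevalences per component cohort and sex mirror the published
# baseline summary of the four Iranian cohorts (TLGS, ICS, GCS phase 2,
# ShECS); the joint correlation structure is SYNTHETIC (only marginals are
# published) with modest positive age-SBP and age-TC correlations.
# Censoring: administrative follow-up horizon per cohort (median follow-up
# exceeded 10 years in TLGS and ICS and was about 5 years in GCS2/ShECS),
# plus a uniform early-dropout fraction.
seed: 20  # default stream; generators accept an explicit seed
age_range: [40.0, 80.0]
correlations:
  age_sbp: 0.2
  age_tc: 0.2
dropout_rate: 0.10
target_10yr_risk:     # pooled 10-year observed fatal-CVD risk to calibrate to
  male: 0.042
  female: 0.021
cause_mix:            # ICD-10 cause assignment for fatal events
  I21: 0.55           # acute myocardial infarction (CHD part)
  I25.1: 0.10         # chronic ischaemic heart disease
  I46.1: 0.05         # sudden cardiac death
  I63: 0.20           # ischaemic stroke
  I61: 0.10           # haemorrhagic stroke
cohorts:
  TLGS:
    follow_up_horizon: 12.0
    male:   {n: 2364, age: [54.4, 10.4], sbp: [125.1, 20.3], tc: [209.6, 42.5], diabetes: 0.120, smoking: 0.288}
    female: {n: 2875, age: [52.6, 9.1],  sbp: [126.7, 21.3], tc: [229.3, 47.6], diabetes: 0.146, smoking: 0.039}
  ICS:
    follow_up_horizon: 11.5
    male:   {n: 2149, age: [54.0, 10.8], sbp: [122.8, 20.4], tc: [209.6, 52.6], diabetes: 0.083, smoking: 0.291}
    female: {n: 2231, age: [53.2, 10.2], sbp: [124.8, 21.9], tc: [224.3, 53.4], diabetes: 0.109, smoking: 0.021}
  GCS:
    follow_up_horizon: 5.5
    male:   {n: 4816, age: [56.0, 8.2],  sbp: [125.8, 21.5], tc: [194.5, 39.8], diabetes: 0.110, smoking: 0.172}
    female: {n: 5410, age: [54.6, 7.5],  sbp: [124.0, 20.6], tc: [211.1, 42.9], diabetes: 0.133, smoking: 0.007}
  ShECS:
    follow_up_horizon: 5.5
    male:   {n: 1858, age: [51.3, 6.2],  sbp: [130.4, 17.9], tc: [189.1, 20.1], diabetes: 0.095, smoking: 0.268}
    female: {n: 2724, age: [50.3, 6.2],  sbp: [127.9, 19.2], tc: [202.2, 19.7], diabetes: 0.129, smoking: 0.004}
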