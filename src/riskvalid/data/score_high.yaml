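# SCORE equation for high-incidence European countries (same risk-factor
# coefficients as the low-incidence equation, different Weibull baselines).
model: score
variant: high
label: score_high
tc_units: mmol/L
centering:
  sbp: 120.0
  tc: 6.0
parts:
  chd:
    coefficients:
      smoking: 0.71
      sbp: 0.018
      tc: 0.24
    baseline:
      male: {alpha: -21.0, p: 4.62, age_offset: 20}
      female: {alpha: -28.7, p: 6.23, age_offset: 20}
  non_chd:
    coefficients:
      smoking: 0.63
      sbp: 0.022
      tc: 0.02
    baseline:
      male: {alpha: -25.7, p: 5.47, age_offset: 20}
      female: {alpha: -30.0, p: 6.42, age_offset: 20}
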