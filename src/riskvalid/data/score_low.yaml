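# SCORE equation for low-incidence European countries, as published in the
# original SCORE derivation.  Two-part Weibull model on the age timescale:
# S0(a) = exp(-exp(alpha) * (a - 20)^p); cholesterol betas are per mmol/L.
model: score
variant: low
label: score_low
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
      male: {alpha: -22.1, p: 4.71, age_offset: 20}
      female: {alpha: -29.8, p: 6.36, age_offset: 20}
  non_chd:
    coefficients:
      smoking: 0.63
      sbp: 0.022
      tc: 0.02
    baseline:
      male: {alpha: -26.7, p: 5.64, age_offset: 20}
      female: {alpha: -31.0, p: 6.62, age_offset: 20}
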