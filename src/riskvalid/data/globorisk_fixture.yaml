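# SYNTHETIC Globorisk-style coefficient set used as the packaged fixture.
# The published Globorisk fatal-CVD coefficients are not redistributed here;
# this set reproduces the model's functional form (proportional hazards on
# the age timescale, sex-stratified piecewise-constant baseline hazard by
# single year of age, age interactions for every risk factor, female-sex
# interactions for smoking and diabetes) with plausible magnitudes.
# Edit or replace with an official coefficient file for real use.
model: globorisk
label: globorisk
tc_units: mg/dL
centering:
  age: 55.0
  sbp: 125.0
  tc: 210.0
coefficients:
  sbp: 0.012        # per mm Hg
  tc: 0.0028        # per mg/dL
  smoking: 0.65
  diabetes: 0.80
age_interactions:   # per year of age over 55, attenuating effects with age
  sbp: -0.00015
  tc: -0.00004
  smoking: -0.018
  diabetes: -0.020
sex_interactions:   # added for women
  smoking: 0.25
  diabetes: 0.30
baseline_hazard:
  # Gompertz-shaped fatal-CVD hazard per year of age, 40 to 94; scaled so a
  # 55-year-old at the covariate centre has roughly the pooled-cohort
  # 10-year risk (4.2% men, 2.1% women).
  age_start: 40
  male: [7.940e-04, 8.644e-04, 9.411e-04, 1.025e-03, 1.116e-03,
         1.215e-03, 1.322e-03, 1.440e-03, 1.567e-03, 1.706e-03,
         1.858e-03, 2.023e-03, 2.202e-03, 2.397e-03, 2.610e-03,
         2.842e-03, 3.094e-03, 3.368e-03, 3.667e-03, 3.992e-03,
         4.346e-03, 4.732e-03, 5.152e-03, 5.609e-03, 6.106e-03,
         6.648e-03, 7.238e-03, 7.880e-03, 8.579e-03, 9.340e-03,
         1.017e-02, 1.107e-02, 1.205e-02, 1.312e-02, 1.429e-02,
         1.555e-02, 1.693e-02, 1.844e-02, 2.007e-02, 2.185e-02,
         2.379e-02, 2.590e-02, 2.820e-02, 3.070e-02, 3.343e-02,
         3.639e-02, 3.962e-02, 4.314e-02, 4.696e-02, 5.113e-02,
         5.566e-02, 6.060e-02, 6.598e-02, 7.183e-02, 7.821e-02]
  female: [3.927e-04, 4.276e-04, 4.655e-04, 5.068e-04, 5.518e-04,
           6.007e-04, 6.540e-04, 7.121e-04, 7.752e-04, 8.440e-04,
           9.189e-04, 1.000e-03, 1.089e-03, 1.186e-03, 1.291e-03,
           1.406e-03, 1.530e-03, 1.666e-03, 1.814e-03, 1.975e-03,
           2.150e-03, 2.341e-03, 2.548e-03, 2.774e-03, 3.020e-03,
           3.288e-03, 3.580e-03, 3.898e-03, 4.244e-03, 4.620e-03,
           5.030e-03, 5.476e-03, 5.962e-03, 6.491e-03, 7.067e-03,
           7.694e-03, 8.376e-03, 9.119e-03, 9.928e-03, 1.081e-02,
           1.177e-02, 1.281e-02, 1.395e-02, 1.519e-02, 1.653e-02,
           1.800e-02, 1.960e-02, 2.134e-02, 2.323e-02, 2.529e-02,
           2.753e-02, 2.998e-02, 3.264e-02, 3.553e-02, 3.868e-02]
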