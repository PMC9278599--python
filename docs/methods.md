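# Methods

## Risk models and the age timescale

Both engines treat attained age, not follow-up time, as the survival time
axis.  A subject aged `a` at baseline has 10-year risk

    risk = 1 − [S₀(a + 10) / S₀(a)]^exp(lp),

the conditional probability of CVD death before age `a + 10` given survival
to `a`, where `lp = Σ βᵢ xᵢ` is the model's linear predictor with the
model's own centering.

**SCORE** is a two-part Weibull model: coronary (CHD) and non-coronary CVD
death each have sex-specific baselines `S₀(a) = exp(−exp(α)(a − 20)^p)` and
their own coefficients for current smoking, systolic blood pressure and
total cholesterol (per mmol/L; the engine converts from the canonical mg/dL
with 1 mmol/L = 38.67 mg/dL).  The parts combine multiplicatively on the
survival scale, `risk = 1 − S_chd · S_non_chd`, which assumes conditionally
independent cause-specific hazards.  Because SCORE carries no diabetes
term, predicted risks of diabetic subjects are multiplied by 2 (men) or
4 (women), capped at 1, following the risk-chart convention; the multiplier
is applied to final risks only and never enters the linear predictor or the
recalibration fits.  The published low- and high-incidence coefficient sets
are packaged as YAML configs.

**Globorisk** is a proportional-hazards model:
`risk = 1 − exp(−[H₀(a+10) − H₀(a)] · exp(lp))` with a sex-stratified
baseline cumulative hazard supplied as a piecewise-constant table by single
year of age (cumulative hazard piecewise linear between year boundaries),
main effects for SBP, total cholesterol, smoking and diabetes, an age
interaction for every main effect, and female-sex interactions for smoking
and diabetes.  Age interactions are evaluated at baseline age and held
fixed over the 10-year interval (a switch evaluates them at the interval
midpoint instead); risk then depends on attained age only through the
baseline-hazard increment.  The original Globorisk coefficients are not
redistributed here; the packaged `globorisk_fixture` set is synthetic with
plausible magnitudes (Gompertz-shaped baseline, mortality doubling every
~8 years; effects attenuating with age) and is clearly labelled as such in
the config.  Any official coefficient file in the same YAML layout drops in.

## Recalibration

The update is the standard two-step "weak" recalibration:

1. **Calibration slope.** The survival model of the engine's form is refit
   on the validation cohort with the frozen linear predictor as the *sole*
   covariate, on the age timescale with delayed entry at baseline age.
   The fitted coefficient is the slope (1 under perfect transportability;
   < 1 indicates weaker effects or original-model overfitting); its 95% CI
   is Wald.  The proportional-hazards form uses a Cox partial likelihood
   (lifelines, with left truncation); the Weibull form uses an in-package
   full likelihood for the left-truncated Weibull proportional-hazards
   model, maximized by BFGS with a finite-difference Hessian for standard
   errors.
2. **Baseline update.** Holding `slope · lp` fixed as an offset, the
   baseline is re-estimated: for the Weibull form, (α, p) by maximum
   likelihood; for the proportional-hazards form, the baseline cumulative
   hazard is rescaled by the single factor that equates mean predicted
   10-year risk with the cohort's KM-observed risk (piecewise
   re-estimation of the hazard table is deliberately out of scope — the
   update granularity matches an intercept update).

SCORE is recalibrated per part against cause-specific outcomes: events
with ICD-10 codes in I20–I25 or I46.1 count against the CHD part,
remaining CVD deaths against the non-CHD part (deaths from the other cause
are censored at the death age).  Baselines are updated per sex within each
part.  Recalibration is run pooled per sex by default (stratify the cohort
and fit per stratum for per-cohort updates).  `refit_model` provides the
separate full refit used only to compare hazard ratios (including
sex-by-smoking and sex-by-diabetes interactions); it never replaces the
deployed model.

## Censoring-aware metrics

**Kaplan–Meier.** The product-limit estimator is implemented directly on
numpy arrays (it sits inside bootstrap loops); ties between events and
censorings at the same time are handled events-first.  Events at exactly
the 10-year horizon count as events, matching the follow-up truncation
rule (time > 10 becomes censored at 10).

**Classification counts.** At threshold `pt`, test-positive is
`risk ≥ pt` (closed on the left, so `pt` below the minimum risk is the
treat-all limit).  Expected counts come from *group-specific* KM curves:
`TP = n⁺(1 − S⁺(10))`, `FP = n⁺S⁺(10)` in the positive group and
symmetrically in the negative group, assuming censoring independent of the
model's predictors (this assumption is a caveat of the method and of any
report built on it).  The incidence `π` attached to each threshold's
metrics is the mixture `(TP + FN)/n` of the two group curves — the unique
definition under which `TP + FN = πn` and the standardized net-benefit
identity `NBF = sens − (1 − spec)·w·(1 − π)/π` hold exactly (to 1e-12 in
tests); the overall pooled KM risk is used wherever a single observed risk
is reported (P/O ratio, treat-all reference).

**C-index.** Harrell's convention: pairs whose shorter time is censored
are not comparable; tied times with exactly one event are usable; ties in
predicted risk count one half.  Pair counting is delegated to
scikit-survival and cross-checked against exhaustive enumeration in tests.
The CI uses the Hanley–McNeil variance approximation driven by event and
non-event counts — the naive `c(1−c)/pairs` form was rejected because
pairs sharing a subject are correlated, and it produces absurdly narrow
intervals at realistic cohort sizes.

**Decision curves.** `NBF(pt)` over a default grid of 0.5%–20% in 0.5%
steps, with percentile bootstrap bands from B = 500 subject-level
resamples (fixed seed; B is configurable and the orchestrated report uses
a coarser grid and B = 200 to keep runtime proportionate).  Treat-none is
identically 0; treat-all is `1 − w(1 − π)/π`, crossing zero at `pt = π`.
Model NBF may legitimately be negative.  Between-model differences use a
paired bootstrap (same resample applied to both risk vectors).

**Agreement.** ICC is the two-way ANOVA, absolute-agreement,
single-measures form — chosen over the consistency form because a
systematic shift between two risk scales should count as disagreement when
the scales feed the same treatment thresholds; the consistency variant is
available by flag.  CIs are F-based (McGraw–Wong), verified against an
independent implementation.  Kappa uses the 2×2 cross-classification at a
5% threshold with an asymptotic-SE CI (statsmodels); degenerate margins
(chance agreement 1) are reported as undefined rather than silently 0.

## Cohort I/O and imputation

Cohort files are delimited text (comma/tab auto-detected) with a header
row; a plain-text schema config maps field names to columns.  Validation
rejects rows with unparseable numerics, non-positive times or pressures,
or event flags outside {0, 1}, reporting row numbers; the eligibility
filter (age 40–80, no CVD history) is applied on request with counts
logged.  ICD-10 outcome definitions ship as editable YAML: the harmonised
definition (I20–I25, I46.1, I60–I69) and the SCORE-specific one (I10–I15,
I20–I25, R96.0/R96.1, I44–I73 minus listed exclusions).  Range membership
is decided on the 3-character category; a category-level exclusion removes
all its subcodes, a subcode-level exclusion only itself.  Diabetes is
fasting glucose ≥ 126 mg/dL, random glucose ≥ 200 mg/dL, or
glucose-lowering medication; all inputs missing is an error (an imputation
candidate), never a silent negative.

Single imputation is regression-based (least squares for continuous
targets, logistic with a 0.5 cut for binary ones — the simplest reading of
"regression models").  A variable entirely missing in one cohort (total
cholesterol) is imputed from an appended donor table by chained equations:
m = 5 stochastic draws (Bayesian linear-regression posterior draws plus
residual noise, 10 burn-in cycles, target last in the chain), averaged into
one completed value; fully reproducible under a seed.

## Synthetic-data generator

The generator emulates the *structure* of a pooled four-cohort validation
study, not any real dataset:

- **Risk factors.** Per cohort and sex, age/SBP/TC are drawn from a
  Gaussian copula with truncated-normal age (40–80) and normal SBP/TC
  marginals matching the published per-cohort means and SDs; smoking and
  diabetes are thresholded latent normals at the published prevalences.
  Only the marginals are published: the default latent correlations
  (age–SBP 0.2, age–TC 0.2, others 0) are a synthetic choice, configurable.
- **Outcomes.** Event ages are drawn exactly from the chosen true model by
  inverting the conditional cumulative hazard on the age timescale
  (piecewise-linear inversion for the hazard-table engine; closed form for
  the Weibull parts, earliest part wins and fixes the cause).  ICD-10
  cause codes for the single-hazard engine are assigned by a fixed
  multinomial (55% I21, 10% I25.1, 5% I46.1, 20% I63, 10% I61) independent
  of covariates — sufficient for the cause-specific SCORE recalibration to
  be exercised, but it cannot test covariate-dependent cause mixes.
- **Censoring.** Administrative horizons per cohort (12 / 11.5 / 5.5 / 5.5
  years, reflecting the ~10 vs ~5-year median follow-up pattern) plus a
  10% uniform early-dropout fraction; follow-up then truncated at 10 years.
- **Calibration.** Per-sex hazard scale factors are solved so the pooled
  10-year risk matches the configured targets (4.2% men, 2.1% women).
  Because those targets are themselves KM estimates from censored data,
  the solved quantity is the *expected KM-observed* risk under the
  censoring scheme, computed analytically as the product integral of the
  at-risk-averaged hazard (per-cohort horizons make censoring weakly
  covariate-dependent, so the KM limit differs from the mean true risk by
  about 0.002 here — the same subtlety affects any pooled-cohort study
  with unequal follow-up).  When no censoring scheme is supplied the
  calibration targets the mean true risk instead.

What passing tests show — and don't: parameter-recovery and
self-consistency results demonstrate the estimators are correct under the
generator's assumptions (proportional hazards exactly true, censoring
(almost) independent, no measurement error, no competing non-CVD
mortality).  They cannot certify performance on real cohorts, where all
four assumptions fail to some degree.

## Numerical choices and defaults

- Follow-up horizon 10 years; thresholds {3, 5, 7, 10}%; kappa threshold
  5%; decision-curve grid 0.5–20% by 0.5%.
- Weibull PH fits start at p = 5 with α solved from the event count;
  BFGS (gtol 1e-7) with a Nelder-Mead fallback; non-convergence raises
  with the trace rather than returning a doubtful fit.
- Baseline-hazard rescale solved by Brent's method on log-scale in
  [e⁻¹⁵, e¹⁵].
- Decile calibration orders by (risk, subject id) — the deterministic
  tie-break — and splits into near-equal groups (sizes differ by ≤ 1);
  when ties straddle a boundary, near-equal sizes take precedence over
  keeping ties together.
- Slope fits warn below 10 events and refuse degenerate (constant) linear
  predictors; refits warn below 10 events per term.
- Report display rounds proportions to 2 decimals and C/slopes to 3;
  machine-readable CSVs keep full precision.
- Monte-Carlo problem sizes in the test suite (cohorts of 6k–100k, 50
  slope-recovery replicates at n = 20 000, bootstrap B = 25–300) were
  chosen as the smallest sizes at which the checked asymptotics are
  comfortably inside their tolerance bands.

## Known limitations

- No competing-risks treatment: 10-year risk is one minus cause-specific
  survival, and KM "observed risk" ignores non-CVD death.  Fine–Gray-style
  classification is out of scope.
- The SCORE part combination assumes independent part hazards given
  covariates.
- Censoring independent of predictors is assumed by the KM-adjusted
  classification counts; the generator itself mildly violates it across
  cohorts (see above), which is realistic but means group-specific KM
  counts carry a small bias there too.
- ICD-9 codes are not parsed; only ICD-10.
- The C-index CI is an approximation (Hanley–McNeil); bootstrap CIs can be
  obtained by resampling externally if exactness matters.
- `refit_model` fits are for hazard-ratio comparison and reporting, not
  for deployment as an updated model.
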