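# Methods notes

## Risk scoring

Flags are strict or inclusive exactly as defined for the cohort:
glycemia > 1.26 g/L, SBP ≥ 140 mmHg, DBP ≥ 90 mmHg, cholesterol
> 2.5 mmol/L, BMI > 30, GDS > 9, GCI > 1.45. The blood-pressure clause is
read disjunctively (systolic **or** diastolic elevation flags
hypertension); the conjunctive reading is available as
`hypertension_rule="and"`. The repeated-visit hypertension clause is
longitudinal and does not apply to a single baseline visit. Missing
boolean fields raise a named error rather than silently defaulting to
false, because silent imputation biases composite scores; the opt-in
`assume_absent_when_missing=True` restores the permissive behavior. APOE
ε4 carriage is carried as a column but is a non-modifiable factor and
never enters the combined score. The cholesterol field is compared at
2.5 mmol/L without interpreting which assay produced it.

## Across-test variability

The 14-subtest battery composition is: MMSE, Mattis, Corsi (mean of z of
direct + inverse), digit span (mean of z of direct + inverse),
Grober–Buschke total recall, DMS immediate, Rey immediate, Rey 3-min,
Stroop interference time (lower is better), TMT B − A (lower is better),
BREF, phonematic fluency, semantic fluency, DO80. This is the unique
grouping of the raw score columns consistent with K = 14; it is shipped as
a default and fully overridable through a YAML battery definition.

Orientation is applied before standardization so that larger always means
better; since z-scoring absorbs sign and scale, orientation matters only
through consistency across subtests. Both the cohort z-scoring and V_i use
the sample (n − 1) standard deviation. TMT enters as the raw time
difference B − A, not a ratio. The default missing-data policy refuses to
compute and lists the affected subjects, because the K − 1 denominator is
part of the definition; the explicit `missing="available"` policy computes
over the available k_used ≥ 8 subtests and reports k_used per subject.

## Volumetrics

The package consumes segmentation *result* tables, never images; an
optional reader for FreeSurfer `aseg.stats`-style global-measure lines is
provided. All normalized quantities are stored as unitless TIV fractions;
report layers multiply by 100. Total lesion volume is the plain sum of
per-lesion volumes (no probability weighting). Visual ratings (Fazekas)
pass through untouched.

## Inference engine

* OLS uses a QR factorization with classical standard errors; rank
  deficiency (relative diagonal tolerance 1e-10) raises rather than
  pseudo-inverting.
* LOOCV residuals use the exact identity e_(i) = e_i/(1 − h_ii), which is
  algebraically the n-refit loop; a leverage of 1 means the held-out fit
  is singular and raises with the offending index. The "bias-corrected"
  RMSE used for selection is the SD of the LOOCV residuals,
  sqrt(MSE − bias²); the plain LOOCV RMSE is emitted alongside.
* Model selection enumerates all 2^p − 1 nonempty candidate subsets
  (p ≤ 12). Ties break toward the smaller subset, then lexicographic
  name order, making the selection independent of column order.
* Partial correlation is Pearson on residuals (each variable regressed on
  the covariates with intercept), with p from t on n − q − 2 df; a
  rank-based variant would be a straightforward extension but is not the
  default. Spearman uses mid-rank ties with the t approximation for p,
  adequate at the cohort sizes involved (n ≈ 140).
* Group comparisons use the pooled-variance Student's t (df
  n_a + n_b − 2); Welch is available behind a flag.
* Median split assigns scores equal to the mid-rank median to the low
  group, which reproduces the "no or one risk factor" vs "more than one"
  partition when the median is 1.
* Holm step-down: adjusted p_(j) = max_{i≤j} min(1, (m − i + 1) p_(i)).
  Families are declared explicitly per analysis block in the plan (the
  V_i + six temporal thickness comparisons form one family; PET blocks
  and lesion-class correlations form their own), since family membership
  is an analysis decision, not a property of the data.
* The engine itself is fully deterministic; only simulation-based tests
  draw random numbers, always from explicit seeds.

## Synthetic cohort generator

The generator emulates the study conditions, not any individual dataset:

* **Age** is truncated normal on [50, 70] centered at 60. A parent SD of
  15 gives a truncated SD ≈ 5.7 — the printed SD of 6.3 is not attainable
  by any truncated normal on that interval (the uniform limit caps the SD
  at 20/√12 ≈ 5.77), so the generator accepts the slightly narrower
  spread. Ages are standardized by their exact truncated moments, which
  keeps the linear correlation targets exact.
* **Risk fields** are drawn flag-first with the printed marginal
  prevalences (hypertension 30.3%, dyslipidemia 27.5%, diabetes 5.9%,
  smoking 5.6%, obesity 11.3%, depression 6.3%, lower education 16.9%),
  then raw clinical values are synthesized consistently with each flag's
  mechanism (elevated measurement, self-report, or medication). Flags are
  mutually independent, which reproduces the printed composite-score
  distribution to a good approximation (e.g. ~38% with no cardiovascular
  risk factor vs 54/142 printed).
* **Battery**: each raw subtest is an affine rescaling of
  g_i + σ_i·ε_ik with g_i ~ N(0,1) general cognition and σ_i a
  log-normal subject-specific inconsistency scale,
  log σ_i = μ_σ + τ·u_i + β·(combined risk, standardized). The scales
  (μ_σ = 1.346, τ = 0.372, β = 0.094) were calibrated once by simulation
  at n = 1e5 against V_i mean 0.89, SD 0.40 and partial corr(risk,
  V_i | age, gender) = 0.21, then frozen. A consequence of forcing mean
  V_i ≈ 0.89 with 14 z-scored subtests is a low implied inter-subtest
  correlation (≈ 0.05); no within-battery correlation matrix is published,
  so the single-factor structure is an assumption of the generator, not a
  claim about the real battery. Scores are continuous: ceiling effects,
  discreteness and norm-based rounding of real instruments are *not*
  emulated, so tests passing here say nothing about those features.
* **Volumes**: TIV ~ normal with a 1.078-SD male–female gap (matching the
  printed t(140) = 6.41); WM and GM fractions carry age (and for WM,
  latent-inconsistency) loadings equal to the target correlations; CSF
  closes the TIV budget exactly. Temporal thickness carries a negative
  combined-risk loading (largest on the left medial temporal lobe).
* **Lesions**: counts are negative binomial (mean 10.6, SD 7.1); total
  lesion fraction is log-normal with CV 1.38 around mean 8.72e-4, with
  standardized loadings 0.556 (age, calibrated for a raw-scale correlation
  of 0.39 under the truncated age distribution), 0.31 (cardiovascular)
  and 0.21 (cognitive) on the log scale. Individual lesions get classes
  from a multinomial (0.5/0.3/0.2) with class size multipliers chosen so
  expected volume shares are 83.8/10.3/5.9% (periventricular /
  juxtacortical / deep white). A subject drawn with zero lesions
  contributes zero volume.
* **PET**: a random ~57% subset receives a GCI from a two-component
  mixture with 8.6% above the 1.45 cut, independent of age and cognition
  by construction.
* One global seed spawns independent per-table substreams, so adding a
  table never perturbs existing ones. `generate_null_cohort` zeroes every
  cross-domain effect while keeping all marginals.

## Problem sizes used in the test-suite simulations

Simulation-based checks use: calibration at n = 10,000 (one seed);
null-pipeline family-wise error at n = 142 over 100 seeds; selection power
at n = 300 over 200 seeds; effect-direction recovery at n = 600 over 40
seeds. These sizes give stable Monte-Carlo estimates for the properties
asserted while keeping the default test run fast.

## Known limitations

* The generator's marginals are normal/log-normal idealizations; skewness
  and floor/ceiling behavior of real instruments are not modeled.
* Risk flags are independent of age and of each other, whereas real
  cardiovascular risk accumulates with age; only the modeled cross-domain
  paths (risk → lesions, risk → inconsistency, risk → thickness) exist.
* The pipeline is baseline-only: no longitudinal trajectories,
  alternative-version equating, mixed models or robust standard errors.
* Exhaustive subset selection is exponential in the number of candidates
  and deliberately capped at 12.
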