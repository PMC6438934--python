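# Methods

## Model and assumptions

The outcome is the square root of the ultrasonographic estimated fetal
weight (EFW, grams). On that scale fetal growth between 16 and 37 weeks is
treated as linear in gestational week with pregnancy-level heterogeneity:

    √EFW_ij = (β₀ + u₀ᵢ) + (β₁ + u₁ᵢ)·w_ij + ε_ij,
    (u₀ᵢ, u₁ᵢ) ~ N(0, Σᵤ),  ε_ij ~ N(0, σ²ₑ)

Assumptions worth stating explicitly:

* **Shared pregnancy effect.** The grouping unit is the pregnancy
  ("patient"), so co-twins share one random intercept/slope. This induces
  a positive intraclass correlation between co-twins and is the reading
  most consistent with a patient-level random effect; a fetus-level extra
  effect is deliberately not modelled (co-twin discordance beyond the
  residual is out of scope).
* **Symmetric normal predictive on the sqrt scale.** No skew/kurtosis
  modelling (LMS-type); centiles come from the normal predictive squared
  back to grams.
* **Linearity on the sqrt scale.** The published median column is fit by a
  straight line with residuals under 0.02 sqrt-g at every week, which
  justifies the transform empirically.

## Priors and sampler

Conjugate priors: β ~ N((0,0), diag(1000, 1000)); Σᵤ ~
Inverse-Wishart(ν = 2, S = diag(0.02, 20)); σ²ₑ ~
Inverse-Gamma(shape 0.01, scale 0.01). Every hyperparameter is
config-overridable, so the prior interpretation is falsifiable rather
than baked in.

The Gibbs sampler cycles the full conditionals in the fixed order
β → {uᵢ} → Σᵤ → σ²ₑ (deterministic order for reproducibility):

* β | rest — bivariate normal (normal-normal update on y − Zu);
* uᵢ | rest — bivariate normal per pregnancy, vectorised over pregnancies
  with closed-form 2×2 inverses/Cholesky factors;
* Σᵤ | u — Inverse-Wishart(ν + G, S + Σᵢ uᵢuᵢᵀ);
* σ²ₑ | residuals — Inverse-Gamma(a + n/2, b + ½Σr²).

Schedule defaults: burn-in 1000, thinning 5, 5000 retained draws (26 000
iterations total; ~10 s for ~8500 observations on one CPU). All
randomness flows from a single counter-based Philox stream seeded once,
so a seed fixes the retained draws bit-for-bit, and group indices are
assigned by order of first appearance so relabelling pregnancy ids cannot
change the draws.

**Inverse-Wishart convention.** Σ ~ IW(ν, S) means Σ⁻¹ ~ Wishart(ν, S⁻¹)
with E[Σ] = S/(ν − p − 1) for ν > p + 1. Draws use the Bartlett
decomposition; the convention is verified in the tests against
`scipy.stats.invwishart` (which is never used inside the sampler).

**Posterior predictive.** For a *new* pregnancy: per retained draw,
sample (u₀*, u₁*) ~ N(0, Σᵤ-draw) and ε ~ N(0, σ²ₑ-draw) and form
(β₀+u₀*) + (β₁+u₁*)·w + ε. The alternative — conditioning on in-sample
pregnancies — would describe the observed cohort rather than a population
reference, so the new-pregnancy reading is the default and only mode.

**Diagnostics.** Effective sample size per scalar parameter (via arviz)
and a Geweke-style comparison of the first 10% vs the last 50% of the
retained chain, with segment standard errors scaled by segment ESS;
|z| > 3 is flagged. Constant chains are reported as degenerate rather
than crashing.

## Reference table construction

Cell(w, z) is the empirical Φ(z)-quantile of the squared predictive
sample, rounded half-up to integer grams (unrounded values are kept on
the table object). Because x ↦ x² is monotone for x > 0, this equals the
square of the sqrt-scale quantile; `table_row_from_moments` provides that
closed form, and `reconstruct_moments_from_table` inverts it
(m_w = √cell(w,0), s_w = (√cell(w,+2) − √cell(w,−2))/4 — the ±2 columns
give the widest lever arm; the ±1.5 columns carry ~1 g integer-rounding
noise and serve as a cross-check only).

Percentile labels are 100·Φ(z) **truncated** to two decimals; truncation
(not rounding) is the rule that reproduces the conventional label set
2.27 / 6.68 / 50.00 / 93.31 / 97.72, and a test demonstrates round-half-up
fails on 2.27 and 93.31.

Clinical Z-scores: z = (√EFW − m_w)/s_w, with z < −1.5 flagged as a
fetal-growth-restriction candidate (the Japanese diagnostic threshold;
strictly below). Off-grid weeks interpolate linearly in m and s only when
explicitly requested.

## Synthetic cohort generator

The generator is the study-conditions stand-in for clinical data and is
first-class, tested code. It emulates:

* **Visit schedule** — from week 16: dichorionic every 4 weeks and
  monochorionic every 2 weeks until 24; both every 2 weeks from 24 to 36;
  weekly from 36 to delivery. Visits are integer weeks and stop at
  delivery; this yields ≈ 10.5–11 examinations per fetus, matching the
  protocol's reported ~10.9.
* **Delivery gestational age** — normal with median 37.1 and sd derived
  from the IQR 36.7–37.4 (sd = 0.7/1.349 ≈ 0.52), clipped to [33, 38.5]
  (planned early-term delivery; only median/IQR are available, so a
  clipped normal is the simplest faithful choice).
* **Chorionicity** — one Bernoulli draw per pregnancy, monochorionic
  fraction 0.478 by default.
* **Planted eligibility violations** — each exclusion flag is planted
  independently at rate 0.01 by default (≈ 9% of pregnancies carry at
  least one flag), so the filter stage is always exercised; the generator
  ledgers its plan (per-pregnancy flags, per-reason counts under the
  documented precedence) as the oracle for downstream tests.

It does **not** simulate twin–twin transfusion dynamics, co-twin
discordance mechanisms, or biometry-level measurement error (EFW is
simulated directly; biometry columns exist only for I/O). Passing tests
therefore demonstrate the statistical machinery under the assumed model,
not robustness to the messiness of real clinical data.

### Calibration from a printed table

`derive_truth_from_reference` anchors the generator on a printed
reference: β₀, β₁ by OLS of √(Z=0 column) on week over weeks 16–36 (slope
≈ 1.897 sqrt-g/week for the bundled published table), and the per-week
predictive sd s(w) from the ±2 columns. The variance decomposition

    s(w)² = var_u0 + 2w·cov + w²·var_u1 + σ²ₑ

cannot separate var_u0 from σ²ₑ (both are intercept terms), so the split
is a calibration rule: σ²ₑ = `residual_fraction` × (the largest residual
variance still compatible with a positive-semidefinite Σᵤ), default 0.5.
For the bundled table this gives Σᵤ ≈ [[4.78, −0.219], [−0.219, 0.0130]]
and σ²ₑ ≈ 1.11. A flat sd profile (no identifiable slope heterogeneity)
degrades gracefully to var_u1 = cov = 0.

## Eligibility engine

A pregnancy is included iff live-born, delivered at ≥ 22 weeks, first
visit at ≤ 16.0 weeks ("after 16 weeks" is strict), and no exclusion flag
set. A pregnancy failing several criteria is counted once under the first
matching reason in a fixed order: the inclusion criteria
(not_live_born, delivery_before_22_weeks), then the ten clinical flags in
their conventional listing order (oocyte_donation … fetal_therapy), then
late_first_visit. Missing flag columns are fatal at read time — ambiguous
eligibility never defaults to included. Decisions are order-stable under
permutation of the input and satisfy recruited = included + excluded by
construction.

## Comparison utilities

* Ratio curves: 100·twin(w, z)/singleton(w, z) per week, one decimal;
  scale-equivariant by construction. Band summaries (min–max over a week
  range) support "X–Y% of singletons" statements.
* Z-score crosswalk: the singleton Z-score of the twin Z=z curve,
  z_single(w) = (twin sqrt-quantile − m_single)/s_single; the identity law
  (twin vs itself returns z everywhere) is tested.
* Chorionicity curves: cubic smoothing spline on per-week group mean EFW,
  weighted by per-week observation counts, smoothing chosen by
  generalized cross-validation (`scipy.interpolate.make_smoothing_spline`)
  unless a penalty is given; λ = 0 interpolates. The original analysis
  specifies no basis/knots, so this is a documented package choice and
  the curves are qualitative. With exactly 4 distinct weeks a plain
  interpolating cubic is used (the penalized fit needs 5); fewer than 4
  is an error.

## Numerical choices and scales

* Problem sizes: the bundled end-to-end runs use 400 simulated
  pregnancies (≈ 8500 fetus-visits) with the full chain schedule — the
  package's scaled-down replica of a several-hundred-pregnancy study; unit
  tests use smaller cohorts and shorter chains where only plumbing or
  determinism is at stake.
* Table cells are rounded half-up to integer grams; reconstruction and
  round-trip tests use tolerances that just absorb that rounding.
* Empirical quantiles use linear interpolation (numpy default) in table
  construction; the exact quantile/square commutation property is stated
  for order-statistic quantiles and holds to ~1e-3 relative under
  interpolation at realistic sample sizes.
* The EFW floor (1 g) guards the square-back transform against negative
  sqrt-scale draws in extreme tails of the simulator.

## Known limitations

* **Slope-variance prior scale.** The stated Inverse-Wishart scale
  diag(0.02, 20) places substantial prior mass on the random-slope
  variance: with G pregnancies the posterior slope variance is bounded
  below by roughly 20/(G − 1), which exceeds the calibrated truth
  (≈ 0.013) until G is in the thousands. The predictive *median* is
  unaffected (all extra spread is symmetric), so median-column recovery
  is excellent, but the fitted ±2 columns are wider than the published
  ones at the 400-pregnancy scale. Notably, the published table's own
  spread is inconsistent with that prior under the standard IW
  convention, suggesting the original software's parameterization acted
  differently; since the hyperparameters are config values, users can
  tighten the scale (e.g. diag(0.02, 0.2)) when reproducing narrow
  spreads at small cohort sizes.
* β mixes slowly when random effects are present (the fixed intercept and
  the mean of the random intercepts are strongly coupled); the default
  schedule compensates with thinning, and ESS/Geweke diagnostics expose
  any shortfall.
* The generator's clipped-normal delivery distribution and integer-week
  visits are simplifications; per-fetus biometry noise is not modelled.
* Chorionicity spline output is qualitative (no inferential claims about
  DC–MC differences), and no statistical test of the difference is
  provided by design.
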