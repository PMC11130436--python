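# Methods

## Dose-response model

The core model is the quantal (dichotomous) multistage form
P(d) = r + (1−r)(1−exp(−Σ aᵢ dⁱ)) with background r ∈ [0, 1) and
non-negative stage coefficients aᵢ. It assumes each cohort stratum's case
count is binomial at the probability implied by the stratum's dose
midpoint — lifetime incidence proportions, not person-years; no
person-time or competing-risk adjustment is made. The dose metric is
cumulative exposure in mg/m³·year, entered at the printed stratum
midpoints, and is treated as exchangeable with C_TWA × T (intensity ×
duration): protraction effects are outside the model.

### Fitting

`MultistageModel.fit()` maximizes the binomial log-likelihood under the
box constraints. Implementation:

* Nelder–Mead from six deterministic starts on an unconstrained
  reparameterisation (logit r, log aᵢ); starts combine two background
  guesses (zero-dose incidence, pooled incidence) with three slope scales
  around a crude (Δincidence / Δdose) estimate.
* The best candidate is polished with box-constrained L-BFGS-B on the raw
  scale (ftol 1e-15), so boundary maxima (aᵢ = 0, r = 0) are reachable
  exactly. A coefficient at the a = 0 boundary is a valid MLE and still
  counts as an estimated parameter in the GOF degrees of freedom.
* When the model is saturated (#groups = degree+1, a zero-dose group
  present, proportions non-decreasing), the closed-form interpolating
  solution (r = observed background; Vandermonde solve for aᵢ) is checked
  and used if it attains the best likelihood — this makes the saturated
  case exact to ~1e-12 rather than optimizer-tolerance accurate.
* All-zero case counts pin r to 0 with a warning; non-convergence is
  flagged on the results object, never silent.

### Goodness of fit and degree choice

Pearson chi-square Σ (y − nP)²/(nP(1−P)) with df = #groups − #parameters;
the deviance is reported as a secondary statistic. `select_degree` fits
degrees 1..max and keeps the highest GOF p-value, breaking ties toward the
lower degree; saturated degrees cannot be scored and are skipped. On the
bundled three-stratum cohort the degree-1 fit gives r = 4.321×10⁻⁴,
a₁ = 1.386×10⁻⁶ (mg/m³·year)⁻¹, chi² = 1.276 on 1 df, p = 0.259.

Benchmark-dose lower bounds (BMDL) and profile-likelihood intervals are
deliberately out of scope.

## Risk engine

Worker risk is P(C_TWA × T); only the product matters. Because
a₁·Dc ≪ 1 for every group here, the curve is locally linear and the group
mean of per-worker risks agrees with the risk at the group mean exposure to
well under 0.5% — group tables therefore use the mean of per-worker risks,
with a t-interval (mean ± t₀.₉₇₅,ₙ₋₁·SE) on the worker-level risk
distribution. The headline value is P(Dc), which includes the background;
the added risk P(d) − r and extra risk (P(d) − r)/(1 − r) are exposed
separately. Display convention: risks in 10⁻⁴ units, two decimals.

The trend test is a one-way ANOVA linear contrast with equally spaced
scores over group rank: F = SS_contrast / MSE on (1, N−k) df, equivalent to
the two-sided t test on the contrast. Degenerate inputs: identical values
give statistic 0 and p = 1; zero within-group variance with a non-zero
contrast gives p = 0.

## Biomarker bridge

ln(metabolite) is regressed on ln(C_TWA) and a smoker dummy by OLS
(statsmodels), per sample (each monitoring round is an observation).
Inversion solves the regression for C_TWA at a measured metabolite value
and exactly round-trips the forward prediction; biomarker risk is the
multistage curve at inverted-air × duration. The frozen published
coefficient sets (S-PMA: 0.77/0.12/0.54, R²=0.58; t,t-MA: 0.68/0.08/4.73,
R²=0.45) are shipped as constants so published-anchored tables do not
depend on a refit. At equal metabolite value a smoker is assigned a lower
inferred air level (part of the metabolite load is tobacco-derived), hence
a lower risk. Pharmacokinetic modelling and cotinine-based smoking
adjustment are out of scope.

## QC and grouping

Sample exclusions: creatinine outside 0.3–3 g/L (missing creatinine is a
separate counter), and t,t-MA > 1000 μg/g Cr with air < 3 mg/m³ (dietary
sorbic-acid signature). Air < 0.05 mg/m³ is below the monitor's detection
limit: such samples are neither imputed (no LOD/√2) nor dropped — they are
excluded from the regression data and the worker is assessed through the
t,t-MA route alone (median metabolite across the below-LOD workers, mean
duration). Worker C_TWA is the unweighted mean of valid rounds; grouping
uses fixed left-closed bins [0,3), [3,5), [5,12), [12,∞) mg/m³·year (the
study's rounded quartiles); `quartile_boundaries` recomputes rounded
quartiles for other datasets.

## EPA and Singapore cross-models

EPA: Risk = IUR × EC with EC = CA·ET·EF·ED/AT. Defaults: ET = 8 h/d (the
monitored shift), EF = 250 d/y (standard occupational assumption),
ED = group mean working duration, AT = 77.93 y × 365 × 24 h (Chinese life
expectancy), IUR ∈ (2.2, 7.8)×10⁻⁶ per μg/m³. The mg/m³→μg/m³ conversion
happens inside the adapter. With these defaults the lowest group
reconstructs to (0.1–0.4)×10⁻⁴ and the highest group's lower bound to
6.1×10⁻⁴; the highest group's upper bound evaluates to 21.5×10⁻⁴ against a
published 21.7, and the 3–5 group's published range (0.3–1.2) is not
recoverable from any printed CA/ED pair — both are documented rather than
matched.

Singapore matrix: ER bins E/OEL into 1–5 (left-closed at 0.1/0.5/1/2), and
the risk value is √(HR×ER) — the standard semi-quantitative formula, which
is what the published values (3.87, 4.47, 5) follow even where the plain
product is quoted. Grades round the value to the nearest integer
(rounding up would misgrade √20 = 4.47 as "very high", contradicting the
published label). The exposure dose E defaults to average CE / mean
duration, the exposure-time-weighted air level; this reconstructs all four
published group ratings, whereas the plain group mean C_TWA moves the 3–5
group (mean air 4.28 but CE-consistent air 2.36 mg/m³) one ER bin up. The
`singapore_e="c_twa"` option selects the plain mean instead.

## Synthetic worker panels

No worker-level measurements are deposited, so `benzrisk.simulate`
generates panels with the study's structure: four groups of 23/24/26/25
workers plus 5 below-detection workers; 2–3 monitoring rounds (P(3 rounds)
= 0.215, giving ≈217 detectable samples in expectation); smoking
prevalence 0.235; air benzene log-normal per group, moment-matched on the
arithmetic scale to the published group means/SDs, with 70% of the log
variance as a shared worker-level random effect; working duration
log-normal around the group mean with CV 0.5; metabolites from the
published regressions plus Gaussian ln-scale noise with
resid² = b²·Var(lnC)·(1−R²)/R² calibrated on the realised ln-air variance
(the small smoking term folded into the explained part); creatinine
uniform on 0.3–3 g/L with a 5% invalid fraction; a 2% sorbic-acid-style
t,t-MA spike rate so the QC rule is exercised; below-detection workers are
non-smokers with latent exposure ≈0.01 mg/m³. Duration CV, creatinine
distribution and the worker-effect share are not constrained by any
published moment; they are fixed defaults exposed in `SyntheticConfig`.
Randomness uses one seed with named substreams per variable, so adding a
variable leaves the others' draws unchanged.

What the generator does not emulate: within-worker temporal autocorrelation
beyond the shared random effect, heavy-tailed metabolite SDs (these emerge
from, rather than being matched by, the log-normal + regression structure),
dietary covariates, and any worker-level confounding between air level and
duration. Passing tests on synthetic panels therefore demonstrate that the
pipeline recovers known generating parameters and identities — not that
the published worker-level tables (biomarker columns, CIs, trend p-values)
are reproduced, which would require the raw data.

## Problem sizes and numerical choices

Parameter-recovery checks use 200 replicate cohorts at the real stratum
sizes (median refitted a₁ within 15% of truth) and 200 synthetic panels of
~98 workers / ~217 samples for OLS slope recovery (mean within 2%, ~95%
CI coverage); the grid oracle for the MLE uses 50×50 (r, a₁) grids around
the optimum on small four-group cohorts. Probabilities are clipped to
[1e-300, 1−1e-12] inside the likelihood; convergence tolerances are 1e-12
(simplex) and ftol 1e-15 (polish). CSV outputs use fixed float formatting,
and every subcommand is deterministic given (inputs, config, seed).

## Known limitations

The cohort fit rests on three strata, so the GOF test has a single degree
of freedom and little power; extrapolation from a high-exposure cohort to
low exposures inherits any non-linearity above ~30 mg/m³ as bias; the
t-intervals on group risks describe sampling variability of the worker
panel only, not parameter uncertainty of the fitted curve (no BMDL); and
the biomarker route treats the regression coefficients as fixed, ignoring
their estimation error.
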