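# Methods

## Structural model and units

ARI disposition is a depot compartment with first-order absorption feeding
a one-compartment parent model; the parent elimination flux, scaled by the
DARI/ARI molecular-mass ratio `kn = 0.995` and the conversion fraction
`Fm`, forms a one-compartment metabolite model. `F` and `Fm` are fixed unit
conventions — neither is identifiable from oral dual-analyte data — so all
volumes and clearances are apparent quantities (`Vd/F`, `CL/F`, `Vdm/Fm`,
`CLm/Fm`). Doses are in mg, volumes in L, times in h; concentrations in
ng/ml carry a single factor of 1000 ng/ml per mg/L applied at the
amount-to-concentration step.

The evaluator is the closed-form superposition of single-dose
tri-exponential solutions. For repeated dosing the exponential sums
accumulate geometrically, so any number of doses — including the infinite-
dose steady-state limit — is evaluated in O(1) per time point. When two
rate constants coincide within `1e-8 · ka` the closed form suffers
catastrophic cancellation and the public evaluator switches to adaptive ODE
integration (LSODA at rtol 1e-10); inside the estimation engine the
offending rate constant is instead nudged by one part in 1e8, which keeps
the objective smooth and differs from the ODE value by less than the
integration tolerance. Steady-state AUC is computed by adaptive quadrature
over one interval and reproduces the identities `AUC24_ARI = dose/CL` and
`AUC24_DARI = kn · dose/CLm` to 1e-8 relative; Cmax is located by bounded
scalar minimisation (tolerance 1e-6 h); Cmin is the pre-dose trough at the
interval end.

A 30-day simulated profile converges to the analytic steady state: by day
14 the typical trough is within 0.3% of the infinite-dose limit, matching
the clinical rule of thumb that steady state is reached after two weeks.

## Covariate model

Typical values scale multiplicatively: continuous covariates as powers of
`cov/ref` (body weight referenced to 70 kg in the shipped model, cohort
medians during covariate search), categorical covariates as `exp(coef)`
per non-reference level, plus linear and sigmoid-maturation forms. The
shipped reference model fixes the unit exponents on both volumes and the
0.75 exponent on metabolite clearance, and estimates the weight exponent on
parent clearance (0.64) and the IM/UM genotype shifts (−0.23 / +0.21).
The five candidate developmental models for the weight–clearance
relationship (fixed allometry, estimated power, linear, age power, weight
power × age maturation) are available as a registry for information-
criterion comparison; the estimated-power form is the shipped default.

A PM (poor metaboliser) phenotype raises an error unless a PM coefficient
is configured: the reference cohort contained no PMs, so the package
refuses to extrapolate silently.

## Variability model and its scale

Between-subject variability is log-normal with diagonal Ω on `Vd/F`,
`CL/F` and `CLm/Fm` (none on `Vdm/Fm`); residual error is proportional per
analyte. The shipped variances are ω² = 0.7999, 0.1207 and 0.1531 with
σ = 0.3545 (ARI) and 0.3537 (DARI). Note the scale convention: the
inter-individual rows of the reference estimates are ω² × 100 — the same
percent scale on which the proportional σ values are quoted — because raw
log-variances of 12–80 would be unphysiological (ω²_CL = 0.1207 is ≈35% CV,
coherent with the 35% residual σ). Residual deviates are truncated at
−0.999 so simulated concentrations stay positive; at σ ≈ 0.35 that is a
2.8-standard-deviation tail (~0.2% of draws) and each truncation is
counted through the module logger.

## Synthetic study generator

The generator emulates a sparse pediatric TDM design: 84 subjects, weights
from a truncated log-normal (median 36 kg, bounds 17.9–100 kg), ages
likewise (median 9.17 y, bounds 4.83–17.33), phenotypes multinomial
(UM/NM/IM = 17.9/40.5/41.7%, no PMs), diplotypes drawn from the observed
phenotype-conditional genotype frequencies. Dosing is once daily at
0.15 mg/kg rounded to the 2.5 mg grid and clipped to 2.5–20 mg, which
reproduces the observed serum-concentration envelope. Each subject
contributes 1–5 sampling occasions (probabilities 0.60/0.20/0.10/0.06/0.04,
chosen so the expected total of ~146 draws matches the 143 concentrations
of the reference study), on a uniform random day between days 14 and 30
with a uniform within-interval offset — the reference study pooled samples
from non-standard collection times and reports no sampling-time
distribution, so the uniform policy is a stand-in, not an inference. Both
analytes are measured at each draw; observations below the assay
quantitation limits (10 ng/ml ARI, 15 ng/ml DARI) are dropped and counted.

An optional efficacy layer draws a 12-week tic-severity (YGTSS) response
from a logistic link on each subject's true steady-state parent trough,
crossing P = 0.5 at 101.6 ng/ml (slope 4 per log unit); baseline totals are
uniform on 25–50 and week-12 totals are back-computed so the strict
">50% reduction" responder rule survives integer rounding.

What the generator does not emulate: assay drift, adherence lapses,
dropout, within-subject covariate changes, or correlation between weight
and age (they are drawn independently). Passing tests therefore show that
the estimation and diagnostic machinery is correct under the stated
generating process, not that the reference estimates are unbiased for any
particular clinical population.

## Estimation (FOCE-ELS)

The objective is first-order conditional estimation with interaction. Per
subject, the conditional mode of the random effects minimises the −2 log
joint density (batched damped Newton with finite-difference derivatives,
positive-definite-safeguarded, step-capped, converged at gradient norm
1e-6; a warm start is always competed against the prior mode so the
objective is path-independent). The model is linearised at the mode,
residual variance is evaluated at the individual prediction (the
interaction form required by proportional error), and the per-subject
extended-least-squares contribution `n log 2π + log det C + r'C⁻¹r` with
`C = GΩG' + diag(σ²·IPRED²)` is assembled via the Woodbury identity so the
whole objective is vectorised. With Ω = 0 the objective reduces exactly to
the closed-form extended-least-squares −2 log-likelihood; on a toy with the
prediction linear in η and additive error it reproduces the Gauss-Hermite
marginal to 1e-6 (the FOCE linearisation is exact only in that regime —
for the nonlinear model the error is O(ω²), verified against quadrature).

The outer optimisation is L-BFGS-B on log-transformed positive leaves
(typical values, ω², σ) and untransformed covariate coefficients. RSEs come
from the finite-difference Hessian of the objective (Cov = 2 H⁻¹, delta
method back to the natural scale); a non-positive-definite Hessian is
pseudo-inverted and flagged. AIC = OFV + 2p and BIC = OFV + p·ln(n_obs)
with p the number of estimated leaves.

Known property: with the ~35% proportional residual error of the reference
model, FOCE-ELS carries a small upward bias in the clearance typical value
on this sparse design (≈10% at the median over replicate studies; it
vanishes at small σ and is the familiar interaction-linearisation bias).
The simulation-based recovery test in the acceptance suite measures exactly
this quantity, so it sits on its tolerance boundary by construction rather
than by numerical error.

Stepwise covariate search: greedy forward inclusion of the largest OFV drop
strictly above 3.84, ties broken toward fewer added coefficients then input
order; backward elimination removes the weakest retained effect while its
deletion raises the OFV by less than 6.64. Categorical effects (genotype)
carry one coefficient per non-reference level but are tested against the
same thresholds, following the published procedure. Candidates whose fits
fail are skipped and logged.

Calibration caveat: the ΔOFV thresholds treat the FOCE objective as an
exact −2 log-likelihood, which it is not. Under the reference study
conditions (sparse sampling, ~35% proportional error) the actual type-I
rate of the 3.84 forward threshold for a single-coefficient covariate is
roughly 25–30% rather than 5% — null-data ΔOFV values of 5–8 units occur
and are genuine features of the approximate likelihood surface (verified
by multi-start refits), in line with the published actual-significance-
level literature for approximate NLME likelihood-ratio tests. Conversely,
the strict 6.64 backward threshold removes moderately supported true
effects: across replicate effect-bearing studies the joint retention of
weight and genotype runs at about 70%, with the misses being replicates
whose realised effect happens to be weak. Randomisation-test calibration
of the thresholds would be the remedy but is outside this package's scope;
the thresholds are kept at their conventional values.

The bootstrap resamples subjects with replacement (same cohort size),
refits warm-started at the original estimates, reports per-parameter
medians and 2.5/97.5 percentiles, flags medians deviating more than 10%
from the original fit, and counts failed resamples.

## Diagnostics

GOF tables carry PRED (η = 0), IPRED (η at the conditional mode) and FOCE
conditional weighted residuals (the linearised residual decorrelated by the
Cholesky factor of the per-subject marginal covariance; singular
covariances are ridge-stabilised with a trace-proportional jitter and
flagged). Under the correct model pooled CWRES are standardised to mean
≈ −0.06 and unit variance — the small negative mean is the FOCE shrinkage
footprint, not a bug.

The VPC re-simulates the exact design (doses, times, covariates) and
compares observed 5th/50th/95th percentiles per equal-count
time-after-dose bin (default 6 bins; the binning rule is a package choice)
with the 90% prediction band of each percentile across replicates.
Observed percentiles depend only on the data, never on the seed.

NPDE decorrelates each subject's observed and simulated vectors by the
Cholesky factor of the simulated covariance, computes prediction
discrepancies as uniform-jittered ranks `(k + u)/(n_sim + 1)` — exactly
uniform under the null, which keeps the battery calibrated at small
`n_sim` — and probit-transforms them. The battery is a mean t-test, a
chi-square variance test and Shapiro-Wilk normality, combined by
Bonferroni into the global test (the combination rule is a package choice;
component p-values are always reported). `n_sim < 100` is refused because
the per-subject simulated covariance becomes unstable.

NPDE and quantitation-limit censoring: the simulations are uncensored, so
a dataset whose sub-LLOQ observations were dropped is genuinely shifted
against them (mean NPDE ≈ +0.07 at the default design) and the battery
rejects it — correctly, as a model misfit. Calibration statements about
the battery therefore refer to uncensored designs; diagnosing censored
data would require a censoring-aware NPDE variant, which is out of scope.

## Simulation and dose optimisation

PTA and profile bands use model-predicted individual concentrations
(inter-individual variability only): the targets concern true exposure, and
adding the 35% assay error would double-count variability (a flag restores
it for sensitivity analysis). Steady-state troughs are analytic, so a
15-cell × 1000-subject attainment table takes milliseconds. The default
targets combine the cohort-derived efficacy floor with consensus TDM
ranges: P(ARI trough ≥ 100 ng/ml) ≥ 75% and P(ARI+DARI trough ≥ 150)
≥ 75%, with caps P(ARI ≥ 350) ≤ 5%, P(ARI+DARI ≥ 500) ≤ 5% and
P(ARI ≥ 1000) ≤ 1%. "ARI plus DARI" is the sum of the two troughs at the
interval end.

The regimen optimiser shares one random-effect pool per phenotype × weight
cell across candidate doses; by dose-linearity the trough draws scale
exactly, attainment is monotone in dose within a cell, and the lowest
feasible grid dose is unique. Cells with no feasible dose are flagged
rather than forced. At the reference variability the optimiser reproduces
the published recommendation table in the IM and NM rows exactly and in
the heavier UM cells; for UM children at 20 kg (and, at Monte-Carlo
precision, 40 kg) the 75% efficacy floor and the 5% toxicity cap cannot be
met simultaneously by any once-daily grid dose — high-precision simulation
puts P(ARI ≥ 350) at 6.3% for the published 10 mg/20 kg UM cell, so the
published cell itself sits just outside its stated cap. This is a property
of the reference variability (the 105% CV on Vd/F creates a slow-ke, high-
accumulation tail), documented here rather than smoothed over.

Metabolic-ratio group comparisons report means ± SD for the familiar table
layout, but the phenotype ordering (UM > NM > IM for MR_AUC, MR_Cmin,
MR_Cmax) is taken on group medians and tested pairwise by Mann-Whitney:
the trough ratio is so right-skewed under the reference variability that
its population mean is dominated by rare slow-parent corners. The AUC ratio
also carries a residual `W^(0.64−0.75)` weight dependence — at 36 kg the
typical NM value is 0.370 against 0.344 at the 70 kg reference.

## Clinical layer

CYP2D6 phenotypes count functional alleles: UM = two normal-function
alleles, NM = exactly one, IM = decreased+none or two decreased, PM = two
none. This deliberately follows the source cohort's convention rather than
CPIC activity scores. The shipped allele table classes *1, *2, *34, *35,
*39 normal; *10, *41, *33 decreased; *3, *4, *5, *6, *14 none. Two alleles
deserve a note: *14 is classed no-function (its subtypes differ in the
literature; either choice yields the same IM assignments here) and *33 is
classed decreased even though CPIC lists it as normal, because the
cohort's own census places *1/*33 among the single-functional-allele NM
diplotypes. Both are overridable via `AlleleFunctionTable`.

YGTSS response is a strict >50% reduction of the total score (an exactly
50% reduction is a non-responder; the source defines only the two open
intervals, and the strict reading is the conservative one). ROC analysis
uses the empirical curve (trapezoid AUC = Mann-Whitney pair-ordering
probability), Hanley-McNeil standard errors, and the Youden-J cutoff with
ties broken toward the higher-sensitivity (lower) threshold; UM
discrimination by metabolic ratios reports ≥ cutoffs, IM discrimination
≤ cutoffs. BSA uses Mosteller's formula; eGFR the bedside Schwartz formula
with creatinine input in µmol/L (converted internally by 88.4).

## Problem sizes in the test suite

Simulation-backed tests run at sizes chosen to make their statistical
assertions sharp without waste: parameter recovery uses 20 replicate
84-subject studies; stepwise retention 10 replicates and null calibration
10 replicates × 3 single-coefficient candidates; NPDE calibration 20 null
and 10 misspecified replicates at 200 simulations each; VPC self-coverage
one design at 200 simulations; bootstrap checks use a 20-subject study at
reduced resample counts. Attainment checks use 1000 virtual subjects per
scenario cell (binomial Monte-Carlo SE ≤ 1.6 points).
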