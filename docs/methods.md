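# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `pigtrial`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Study context

The package implements the analysis layer of a randomized two-arm
preclinical trial in newborn piglets: an inflammation-amplified
hypoxic-ischemic (IA-HI) insult, then randomization to vehicle or
intravenous azithromycin (20 mg/kg over 1 h at 1, 24 and 48 h post-insult),
with neurocritical care to 65 h. Outcomes are magnetic resonance
spectroscopy (log10 Lac/NAA in a basal-ganglia/thalamic and a white-matter
voxel at 60 h), hourly aEEG background scores (0 isoelectric … 4 normal
voltage) over 60 h, an 8-region immunohistochemistry panel
(cCTX, sCTX, PvWM, IC, Hip, CAUD, PTMN, THAL) for several markers, timed
plasma drug concentrations, and serial blood counts. The animal data are
not publicly deposited; every analysis is therefore exercised against the
synthetic generator described below.

## Probability of superiority and the decision rules

All treatment-effect models report Pr(sup), the posterior probability that
the treatment effect favours treatment in a *declared* direction (lower
Lac/NAA, higher aEEG score, marker-specific for histology). The direction
is an argument, never inferred from the data.

For a two-arm Gaussian comparison with flat prior on the mean difference
and Jeffreys prior on the common variance, the posterior of the difference
is Δ̂ + s_p·√(2/n)·t(2n−2), so Pr(sup) = T₂ₙ₋₂(Δ̂/(s_p√(2/n))). Because the
same statistic has that t distribution under the null, Pr(sup) is exactly
Uniform(0,1) over null trials. Three consequences, each verified by
simulation in the test suite rather than assumed:

- the futility rule "stop if Pr(sup) ≤ 0.5" stops null trials with
  probability 0.5 (the study-scale simulation reproduces ≈49.8–50%);
- the superiority threshold 0.95 has a one-sided type I error of 5%, and
  calibrating a threshold to a 2.5% error yields c ≈ 0.975 in both the
  known-variance and the Student-t mode (the posterior-t cdf applied to
  its own sampling distribution is uniform — there is no "heavier-tail"
  correction to the threshold);
- the power of "Pr(sup) ≥ 0.95 at final analysis" under a 0.5 log10-unit
  difference, SD 0.4, n = 12/arm is the noncentral-t value
  1 − F_nct(t₀.₉₅,₂₂; df=22, ncp=3.06) ≈ 0.907, which the simulation
  reproduces to Monte-Carlo error.

Sample size uses the exact noncentral-t power formula iterated over n
(df = 2n−2), with the normal-approximation value reported for reference.
At the study's assumptions (δ=0.5, σ=0.4, 80% power, 5% two-sided) the
exact calculation gives 12 per group; the normal approximation gives 10.0
and understates the requirement at these sizes.

Operating characteristics are estimated from ≥10⁴ simulated trials per
condition (20,000 in the acceptance script); Monte-Carlo standard errors
√(p(1−p)/n_sims) are attached to every estimate. Futility is evaluated at
a single full-sample analysis: the near-50% null stopping probability is
the single-look uniform-null value, and no interim timing is modelled.

## Posterior computation without a PPL

No probabilistic-programming framework is used. Priors are flat on
location coefficients and half-Normal(0, 10 × sample SD) on residual
scales.

*Linear regressions* (MRS; each histology region): with these priors the
posterior factors exactly. The 1-D marginal of σ,
p(σ|y) ∝ σ^−(n−p) exp(−SSR/2σ²) · halfN(σ), is sampled by inverse-CDF on a
4096-point log-spaced grid spanning e^±4 around the residual SD; β|σ is
Gaussian around the least-squares solution. Draws are therefore iid and
exact to grid resolution. Four "chains" of 2000 draws are kept so the
split-R̂ diagnostic (computed with arviz, threshold 1.01) applies uniformly
across model families.

*aEEG linear mixed model*: hourly scores are averaged into 6-h epochs per
animal (missing hours excluded, counts recorded; trailing partial epochs
reported separately and excluded from modelling). Epoch means are Box-Cox
transformed with a +0.5 offset (scores include 0); λ is profile-selected
on the vehicle arm only, then held fixed, so the transform cannot absorb
treatment information. The model has fixed arm, epoch (sum-to-zero coded)
and arm×epoch effects plus an animal random intercept. Sampling is a
blocked Gibbs sampler: (β, u) are drawn jointly from their Gaussian full
conditional (a single sparse-normal solve), then the two variances from
inverse-gamma(10⁻³, 10⁻³) conditionals — chosen over a half-Normal scale
prior for conjugacy; with ~24 animals × 10 epochs the variance posteriors
are data-dominated and the choice is immaterial. Four chains × 2000 draws
after 1000 warm-up; blocked updates make mixing near-iid (R̂ ≈ 1.000–1.002
in the suite). The arm main effect under sum coding is the arm difference
averaged over epochs; per-epoch contrasts add the interaction draws.

*Histology panel*: for one marker, densities are pivoted to an
animal × 8-region panel. Missing cells (<50% per region enforced) are
completed by chained-equation multiple imputation — scikit-learn's
IterativeImputer with Bayesian-ridge posterior sampling, 10 cycles, one
sub-seed per imputation; arm and sex enter the imputation model as
auxiliary columns; observed cells are never altered, and complete data
short-circuit to a single fit, making the multiple-imputation path exactly
equal to the single-fit path there. Per imputation and region, a
sex-adjusted linear regression gives posterior draws (mixed over
imputations) and a frequentist estimate; estimates are pooled by Rubin's
rules (total variance = within + (1+1/m)·between, Barnard-Rubin-style df)
into per-region p-values, which are Benjamini-Hochberg adjusted across the
8-region family (the family is the regions within one marker). The
*overall* effect is the posterior of the arm coefficient in a regression of
each animal's across-region mean of standardized densities. Two
scale/correlation subtleties drove this design: standardization uses the
pooled *within-arm* SD, because the marginal SD is inflated by the
treatment effect itself and would shrink large effects; and the overall
posterior is computed from the animal-level means rather than by averaging
per-region posteriors, because per-region fits share each animal's random
effect — averaging their draws misstates the uncertainty of the mean
(too wide if the region samplers share noise, too narrow if independent),
while the animal-level regression carries the between-region correlation
exactly. Under a uniform +1 SD region shift at n = 12/arm this overall
test has ≈0.93 power at the 0.95 threshold, matching its analytic
noncentral-t value for the generator's between-region correlation of 0.5.

## Two-compartment population PK

Parameterization CL, V1, Q, V2 (clearances L/h, volumes L), micro-constants
k10 = CL/V1, k12 = Q/V1, k21 = Q/V2; disposition rates α ≥ β are the roots
of λ² − (k10+k12+k21)λ + k10k21 = 0, with Q = 0 degenerating to one
compartment. The central concentration for a constant-rate infusion is the
standard biexponential closed form, superposed over dose events (linear
kinetics); it agrees with LSODA integration of the compartment ODEs to
<10⁻⁶ relative sup-norm on a 0–72 h grid. Derived values: t½ = ln2/β,
AUC∞ = total dose/CL (mass balance, exact), Cmax by a 0.01-h grid anchored
on infusion-end times plus bounded local refinement (infusion profiles
peak at the end of an infusion).

The published population-estimate table is not machine-readable in the
source text, so the package ships *synthetic reference estimates*
(CL = 40/12.3 ≈ 3.25 L/h, V1 = 20 L, Q = 2 L/h, V2 = 55.8 L for a ~2 kg
piglet), solved so the 20 mg/kg course reproduces all three printed
study-scale quantities: terminal half-life 33 h, single-dose AUC∞
12.3 mg·h/L, and end-of-infusion concentrations ≈1.8–1.9 mg/L at 2, 25 and
49 h (flat across doses, as observed — the large V1 reflects azithromycin's
extensive early distribution). They are labelled synthetic in the code and
are a stand-in, not the published fit.

Fitting maximizes a proportional-error Gaussian likelihood
(σᵢ = cv × predictionᵢ) in two modes. *Naive-pooled*: one parameter set
for all subjects, optimized on log-parameters (L-BFGS-B, ftol 10⁻⁸, ≤500
iterations, Nelder-Mead polish). *Mixed-effects*: lognormal between-subject
variability on a declared parameter subset, integrated by a Laplace
approximation per subject; when a single random effect and a shared
sampling schedule allow it, the inner mode search runs as a damped Newton
iteration on all subjects' η at once against a vectorized population
concentration kernel (~1.5 s per 12-subject fit). Standard errors come
from a numeric Hessian on the log scale (delta method); non-convergence is
flagged on the result. AIC supports the one- vs two-compartment
comparison.

Two estimation facts the test suite documents: under ω_CL = 0.3
heterogeneity the pooled mode is misspecified and its ML estimate of CL is
unreliable (occasionally degenerate), so parameter-recovery validation
uses the mixed-effects mode; and with a 33-h terminal half-life, sampling
confined to the 65-h study window cannot identify CL tightly (relative
MLE SD ≈ 0.16), so the recovery-validation schedule
(`PK_VALIDATION_TIMES`) spans the terminal phase with 11 samples to 120 h
(relative SD ≈ 0.08). The synthetic *trial* keeps the study's sparse
bedside schedule (2, 25, 49 h); the two schedules serve different
purposes.

## Bedside scores

- Ramification index per field: RI = intersections²/somata from a
  50×50 µm grid with 3+3 gridlines. Zero-somata fields are undefined and
  excluded (never scored 0, which would bias regional means downward).
  Regional RI is the mean of per-field RIs — the formula is defined per
  field — over 6 fields (3 for hippocampus, which appears in one section
  only); field-count mismatches warn. The ×60-magnification sensitivity
  analysis is the same code on a second dataset.
- SIRI = neutrophils × monocytes / lymphocytes; undefined at zero
  lymphocytes. Degree-1 homogeneous in the counts.
- aEEG: hourly scores aggregate to 6-h epoch means. A rule-based
  re-classifier from voltage margins is provided as a convenience with
  config-overridable cutoffs (defaults: isoelectric <2 µV upper margin;
  burst suppression → 2; upper >10 µV with lower >5 → 4, else 3;
  otherwise 1); the cutoffs are conventions, since the underlying criteria
  are cited by reference in the literature.

## Repeated-measures ANOVA

Longitudinal physiology/haematology/cytokines use a linear mixed model
with fixed treatment, time and treatment×time effects and an animal random
intercept (statsmodels MixedLM, REML, gradient tolerance 10⁻¹²).
Contrasts are least-squares (model-predicted) cell-mean differences with
95% CIs and p-values on the between-subject stratum df (n_animals − 2),
the Satterthwaite-consistent choice for a between-subject factor in a
random-intercept design (richer covariance structures such as AR(1) are
out of scope; the random intercept is the declared default). On balanced
complete data the LS means equal raw cell means and the treatment Wald F
equals the classical repeated-measures ANOVA F (verified to 10⁻⁸
relative). A single-timepoint table reduces exactly to the pooled-variance
two-sample t test and is fitted as such. Skewed analytes can be log10
transformed first; values at or below a declared detection limit are set
to half the limit and flagged, and nonpositive values without a declared
limit are an error. No multiplicity adjustment is applied in this family
(only the histology panel is FDR-adjusted).

## Synthetic-trial generator

Defaults are the study conditions: 12 animals/arm, sex ratio 0.5, weight
2.0 ± 0.25 kg.

- *MRS*: log10 Lac/NAA drawn Gaussian directly on the log10 scale
  (the analyses log-transform first), vehicle mean 0.1, SD 0.4 (the
  study's sizing value), treated shift −0.143 log10 units (the scale of
  the reported basal-ganglia effect), plus a small fixed sex offset so sex
  adjustment is non-degenerate.
- *aEEG*: a latent state starts near 0–0.8, drifts up at 0.055 score/h
  (vehicle) with N(0, 0.35) hourly innovations, clipped to [0,4] and
  rounded — reproducing the post-insult suppression, stochastic recovery
  and plateaus at 0 and 4 seen in such traces. The treated arm adds
  0.012 score/h. These rates were chosen once so that vehicle animals
  typically reach scores 3–4 by 60 h and the arm contrast emerges late.
- *Histology*: density = marker baseline + animal-level random effect +
  residual, with the animal effect carrying a share ρ = 0.5 of the
  marker's between-animal variance — a single random effect giving
  exchangeable between-region correlation (the true correlation is
  unknown; ρ is a config knob). Baselines (cells/mm²): NeuN 500 ± 100,
  TUNEL 60 ± 25, Iba1 200 ± 60, OLIG2 300 ± 80. Default treated shifts
  follow the reported directions: NeuN +40, Iba1 +25, TUNEL 0, OLIG2 −8.
  Missingness is completely at random (default 5%), so multiple-imputation
  validity is testable without further assumptions.
- *PK*: treated animals sampled at 2, 25, 49 h with 25% proportional
  error around the reference-parameter profile; zero concentrations stay
  zero.
- *Blood*: lognormal counts with an inflammation bump peaking ≈6 h
  post-insult, an animal-level frailty, treated-arm reductions in
  neutrophils/monocytes from 24 h and a platelet increase from 48 h.

Everything is a pure function of (config, seed): identical configs give
byte-identical tables. What passing tests on this generator do *not* show:
real Lac/NAA can be skewed even after log transform, real aEEG scoring has
inter-rater noise and seizure artefacts, real histology missingness is
unlikely to be completely at random, and real PK has covariate structure
(weight, maturation) the generator omits. The generator matches the
statistical *structure* the analyses assume, which is what the end-to-end
tests exercise; it cannot validate those assumptions against the animal
data.

## Pipeline

A run is one `RunConfig` (YAML): exactly one of an input-CSV directory or
a synthesis block, plus seeds, sampler settings and module toggles. Inputs
are schema-validated (required columns, score range 0–4, non-negative
counts/concentrations, fixed region vocabulary) with a violation report
rather than a hard stop; each outcome family runs independently so one
failure cannot abort the rest; the manifest records package version,
config hash, seeds and per-stage diagnostics (R̂, imputation counts,
convergence flags). Identical config + seed reproduces results.csv
byte-for-byte. The bundled null demo (`examples/demo_null.yaml`,
study-default generator with all effects zero, seed 1) illustrates
calibration: every Pr(sup) lands inside (0.02, 0.98). Since Pr(sup) is
uniform under the null, a single demo run sits outside such a band with
the corresponding tail probability per outcome; the property that holds
for *every* seed is the distributional one (uniformity), which the suite
checks over hundreds of replicates.

## Problem sizes used by the suite

Operating-characteristic checks use 10,000–20,000 simulated trials
(Monte-Carlo SE ≤ 0.5 percentage points); credible-interval coverage uses
200 replicate trials at the design conditions; null-calibration checks use
100–500 replicate model fits; the PK recovery study uses 100 replicates of
12 subjects; the histology power check uses 50 replicates. These sizes
put Monte-Carlo noise well below every margin being asserted.

## Known limitations

- The published posterior summaries for the animal outcomes are not
  reproduction targets; only the desk-reproducible design and PK-derived
  quantities are.
- The EEG model treats transformed epoch means as Gaussian; an
  ordinal-likelihood model is out of scope by design.
- The Laplace approximation is not verified against adaptive Gaussian
  quadrature; its parameter-recovery behaviour is verified by simulation
  instead.
- `fit_population` assumes a common dose regimen across subjects in a
  dataset (per-kg differences in the synthetic trial's PK table are below
  the resolution of anything asserted on it).
- The voltage re-classifier's cutoffs are conventions, not a reprint of
  the cited clinical criteria.
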