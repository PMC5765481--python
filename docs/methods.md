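# Methods

## The kinetic model

Both labels are assumed to leave body water by first-order kinetics.  With
the standard dose-dilution protocol (dose D g to the subject; an aliquot of
d g diluted into T g of water of enrichment δ_T, measured as δ_dd), the
enrichment of one isotope at t days post-dose is

    δ(t) = [D·T·(δ_dd − δ_T) / (18.02·N·d)] · exp(−k·t) + δ_b

with N the isotope's dilution space (mol of water), k its elimination rate
(day⁻¹) and δ_b the measured pre-dose (basal) enrichment, all enrichments
in ‰ vs VSMOW.  The bracketed term is the t = 0 excess enrichment; the
factor 18.02 g/mol converts gram doses to mol of water.

## Physiological re-parameterization

The two-isotope kinetics (N_H, N_O, k_H, k_O) carry exactly four degrees of
freedom, re-expressed as:

* rCO₂ = α₁(k_O·N_O − k_H·N_H) + α₂ — CO₂ production, mol/day;
* S = N_H/N_O — the dilution-space ratio (physiologically ≈ 1.03–1.04;
  values outside 1.015–1.060 are flagged as a quality warning, never
  rejected);
* R_W = β₁·k_H·N_H + (1 − β₁)·k_O·N_O + β₂ — water turnover, mol/day;
* F = 1 − (γ₁·N_H + γ₂·N_O)/W — body-fat fraction for weight W kg.

The inverse map solves the linear flux system: with x = k_H·N_H,
y = k_O·N_O, the pair (x, y) follows from y − x = (rCO₂ − α₂)/α₁ and
β₁x + (1 − β₁)y = R_W − β₂, and the pools from
N_O = W(1 − F)/(γ₁S + γ₂), N_H = S·N_O.  The composition of the two maps
is an exact algebraic identity, property-tested to 1e−10 relative over the
prior support.

### Constants

Fractionation factors f₁ = 0.941, f₂ = 0.991, f₃ = 1.037 (water vapour ²H,
water vapour ¹⁸O, CO₂ ¹⁸O).  The α/β/γ constants default to:

* α₁ = 1/(2f₃ + 2.1(f₂ − f₁)) = 1/2.179, α₂ = 0 — the Schoeller
  fractionation model; a Coward-model alternative
  (α₁ = 1/(2f₃ + 1.1(f₂ − f₁)), α₂ = −27.3(f₂ − f₁)/(2f₃ + 1.1(f₂ − f₁)))
  is available via `ModelConstants.coward()`.
* β₁ = 1, β₂ = 0 — water turnover taken as the ²H efflux.  A consequence
  worth knowing: with β₁ = 1 every in-support physiological point maps to
  valid kinetics, so likelihood rejection of invalid kinetics only occurs
  for fractionation variants with β₁ < 1.
* γ₁ = 18.02/(2·1000·0.732·1.041), γ₂ = 18.02/(2·1000·0.732·1.007) kg/mol —
  the mean of the two space-corrected pools (²H spaces overestimate body
  water by 4.1%, ¹⁸O by 0.7%) converted to kg of water and divided by the
  hydration of fat-free mass (0.732).  The mol↔kg bridge lives only inside
  these constants.

All six are plain fields of `ModelConstants` and can be overridden from
configuration to reproduce any other fractionation convention.

Classical estimation uses the published closed forms directly rather than
the α-form: the Coward equation
rCO₂ = (k_O·N_O − k_H·N_H − 27.3(f₂ − f₁))/(2f₃ + 1.1(f₂ − f₁)) for
natural spaces and the Schoeller equation
rCO₂ = (k_O·N_O − k_H·N_H)/(2f₃ + 2.1(f₂ − f₁)) for normalized spaces.
Both groupings reproduce the reference subject's printed rCO₂ values to
better than 0.3% from the printed pools and rate constants, which is the
validation we rely on for the parenthesization.

## Energy conversion

TEE (kJ/day) = 22.4·(15.48/RQ + 5.55)·rCO₂ with a common respiratory
quotient RQ = 0.85, giving a proportionality constant of 532.26 ≈ 532 kJ
per mol CO₂.  The division by RQ (rather than multiplication) is forced by
that printed constant: 22.4·(15.48·0.85 + 5.55) would give 419, not 532.
Because TEE is an exact scalar multiple of rCO₂, posterior TEE draws are
obtained by scaling the rCO₂ draws, draw by draw.

## Space normalization and its effect on TEE

Two fixed-ratio corrections are provided:

* Schoeller weighting: N_H′ = (N_H + 1.03·N_O)/2, N_O′ = (N_H/1.03 + N_O)/2;
  output ratio exactly 1.03.
* IAEA weighting: both spaces scaled from the mean body-water estimate
  (N_H/1.041 + N_O/1.007)/2; output ratio 1.041/1.007 = 1.0338 ≈ 1.034.

Both weightings reduce to N_O′ = ½(S/S′ + 1)·N_O with S the natural and S′
the target ratio, so the change in TEE has the closed form

    TEE′ − TEE = λ·(S/S′ − 1)·[(k_O + S′·k_H)/2]·N_O,   λ = 532.26·α₁,

an identity the tests verify against direct recomputation to 1e−12.  Its
sign follows S − S′: normalization lowers TEE for subjects whose natural
ratio is below the target and raises it above, linearly in S across a
cohort.

## Classical fitting

Three flavours, differing only in the implied error structure:

* `logarithmic` — OLS on ln(δ − δ_b) vs t (the traditional slope-intercept
  analysis; optimal when ‰ error is proportional to excess enrichment);
* `poisson` — WLS on the log scale with weights ∝ excess enrichment
  (var(δ) ∝ excess, the intermediate error model);
* `exponential` — nonlinear least squares on the untransformed curve
  (optimal for constant instrumental ‰ error), initialized from the
  logarithmic fit.

On noise-free data the three coincide exactly (same model class).  Under
constant-‰ noise the exponential fit is the maximum-likelihood estimator
and has the smallest sampling variance, with the Poisson weighting between
the other two; our simulations confirm the variance ordering but show that
the ordering of the *mean* estimates across flavours is dataset-specific,
so no test asserts it.  The pool size N is recovered from the fitted
intercept via the dose equation at t = 0.  Basal enrichments are taken as
measured, duplicate timepoints are averaged, and points at or below basal
are dropped with a logged warning (late timepoints can cross baseline by
noise); no automatic outlier rejection is performed.

Approximate uncertainty: a first-order delta method propagates each fit's
(N, k) covariance (isotopes independent, within-isotope covariance kept)
to a CV for rCO₂, which TEE inherits unchanged.  At the default noise
levels this lands in the low single digits of percent.

## Bayesian model and priors

Independent model, per subject:

* rCO₂ ~ Uniform(0, 100) mol/day, R_W ~ Uniform(0, 1000) mol/day,
  F ~ Uniform(0, 1) — vague;
* S ~ Normal(1.035, sd 0.01) — informative (precision 10⁴; note the
  stated 99% limits of 1.005–1.065 correspond to ±3 sd, a discrepancy we
  record rather than resolve — sd = 0.01 is what we implement);
* measurement error: independent Gaussians, sd 2 ‰ (²H) and 0.5 ‰ (¹⁸O),
  fixed.

Hierarchical model, one stratum (sex) at a time: individual parameters are
normal around population means; precisions τ ~ Gamma(0.01, 0.01) for rCO₂,
R_W, F and τ_S ~ Uniform(1, 10⁵).  Hypermean priors are not part of the
published specification; we give them the independent model's per-subject
priors (uniforms for rCO₂/R_W/F, the informative normal for S).  Individual
parameters remain constrained to the physical supports (F in (0, 1), etc.),
which acts as a truncation of the population normals.

F is sampled although TEE does not require it; it makes the ²H dataset
yield a body-composition estimate at no extra cost.  Basal enrichments are
fixed at their measured values (a meteoric-water-line prior for basals is a
known extension, deliberately not enabled).

## Sampler

Component-wise random-walk Metropolis over (rCO₂, S, R_W, F); each
proposal maps to kinetics, and invalid or out-of-support states are
rejected via log-density −inf, never raised.  Proposal scales adapt toward
a 0.44 acceptance rate in windows of 50 iterations **during burn-in only**,
preserving detailed balance afterwards.  In the hierarchical model the
individual-parameter updates are Metropolis-within-Gibbs against their
conditional normal population prior; hypermeans and precisions are
Gibbs-updated from conjugate (normal) or truncated-conjugate
(truncated-normal / truncated-gamma via inverse-CDF) full conditionals.

Defaults: 50,000 iterations, 4,000 burn-in, thinning 1.  Two chains are run
by default for diagnosability (split-chain R-hat and bulk ESS via arviz are
attached to every result; thresholds warn, never block); a single-chain
mode is available.  Chains are seeded from a SeedSequence spawned per
chain, so identical (seed, config) runs are bit-identical.  Initial values
come from the classical exponential fit when it is usable, otherwise from
prior draws.

Sampler correctness is tested against independent oracles rather than by
eye: a one-parameter restriction (S free, the rest fixed) must match a
dense numerical posterior to total-variation < 0.05, and prior-only runs
(likelihood switched off) must reproduce the S prior's mean and sd within
Monte-Carlo error.

## Synthetic cohort generator

The generator emulates a medium-sized adult survey: defaults of 37 women
and 22 men, 14 daily post-dose samples (days 1–14), measurement noise 2 ‰
(²H) and 0.5 ‰ (¹⁸O).  Per-sex truncated-normal populations are calibrated
to typical adult survey medians — women rCO₂ 18.1 mol/day, fat fraction
0.376, weight 68 kg; men 25.9 mol/day, 0.274, 82 kg — with spreads chosen
so cohort ranges resemble those surveys report.  Water turnover (women
155 ± 20, men 210 ± 25 mol/day ≈ 2.8/3.8 L/day) is a package choice at
typical adult values, since it is not part of the calibration targets.
The space ratio is drawn around a population mean of 1.038 with
between-subject sd 0.008; that sd is our reconciliation of a tight
population-mean uncertainty (~0.002) with observed individual ratios
spanning roughly 1.01–1.07.  Doses are constructed to give initial excess
enrichments of 350 ‰ (²H) and 120 ‰ (¹⁸O), typical of multipoint DLW
practice, and basal enrichments sit on the meteoric water line
(δ²H = 8·δ¹⁸O + 10, with δ¹⁸O = −7 ‰).

What the generator does *not* emulate: analytical drift or nonlinearity of
the mass spectrometers, within-subject variation of turnover across the
sampling window, correlated errors between isotopes, missing samples, and
seasonal baseline shifts.  Passing recovery tests therefore demonstrates
correctness of the estimators under the stated noise model, not robustness
to every artefact of real survey data.

A three-subject fixed-seed fixture set provides textbook-like 70-kg
subjects (N ≈ 2500 mol, k_H ≈ 0.083, k_O ≈ 0.108 day⁻¹), the third with a
single +10 ‰ outlier injected into the day-11 ¹⁸O sample for exercising
outlier behaviour.  Note that at 0.5 ‰ noise on a ~120 ‰ intercept the
fitted space ratio of such a fixture has a standard error of ≈ 0.004, so
single-realization checks on S use a ±3 SE band around the generating
value.

## Problem sizes and numerical choices

The test suite and acceptance checks scale the MCMC down to keep runs
interactive: parameter-recovery uses a 20-subject cohort at the stated
noise with 10,000-iteration chains (scaled down from the 50,000-iteration
default), the grid-oracle and prior-recovery checks use ~40,000 iterations
on one subject, and smoke-level checks use a few thousand.  Posterior
medians of rCO₂ then recover truth with a median absolute error below 5%,
and hierarchical per-subject S medians are strictly less dispersed than
independent ones on every cohort tested.

Other numerical choices: duplicate timepoints are averaged before fitting;
two-point fits are exact with undefined (NaN) standard errors; truncated
distributions in the Gibbs steps fall back to clipping when the
normalization window underflows (never observed in practice); the Coward
offset 27.3 is treated as a fixed constant in mol/day·(fractionation)
units.

## Known limitations

* The measurement-error sds are fixed, not estimated; misspecifying them
  miscalibrates posterior widths.
* The plateau (two-point) protocol is out of scope; curves need ≥ 2 points
  above basal per isotope, and slope-intercept data are assumed.
* Hierarchical analysis requires ≥ 3 subjects per stratum and assumes
  exchangeability within a stratum; pooling across sexes is possible but
  the default splits by sex.
* The error propagation for classical fits is first-order only and treats
  the two isotope fits as independent.
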