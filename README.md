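# dlw — doubly labelled water analysis of total energy expenditure

`dlw` estimates free-living total energy expenditure (TEE) from doubly
labelled water (DLW) experiments, for researchers in human energetics,
nutrition surveys and isotope biology.  In a DLW experiment a subject drinks
water labelled with ²H and ¹⁸O; both labels wash out of body water by
first-order kinetics, but ¹⁸O also leaves as CO₂, so the difference of the
two elimination fluxes measures CO₂ production and hence energy expenditure.

The package implements, side by side:

* **classical least-squares analysis** — per-isotope curve fits
  (log-linear, Poisson-weighted, or untransformed nonlinear), the Coward
  and Schoeller rCO₂ equations, and dilution-space normalization (fixed
  ratio 1.03 or the IAEA 1.041/1.007 weighting);
* **a Bayesian re-parameterization** — the two-isotope kinetics
  (N_H, N_O, k_H, k_O) expressed through four physiological parameters:
  CO₂ production rCO₂, the dilution-space ratio S = N_H/N_O, water
  turnover R_W and body-fat fraction F, sampled by component-wise
  random-walk Metropolis under vague priors for rCO₂, R_W, F and an
  informative prior S ~ N(1.035, 0.01²);
* **a hierarchical extension** — per-sex population distributions over the
  physiological parameters, which shrinks extreme individual estimates
  toward the population mean;
* **a synthetic-cohort generator** with known ground truth, so every
  estimator can be validated end to end without access to survey data.

## The model

For each isotope the enrichment above the pre-dose baseline follows

δ(t) = [D·T·(δ_dd − δ_T) / (18.02·N·d)] · exp(−k·t) + δ_b,

where D, d, T and the diluted-dose enrichments describe the dose
preparation, N (mol) is the isotope dilution space and k (day⁻¹) the
elimination rate.  CO₂ production is a linear function of the flux
difference, rCO₂ = α₁(k_O·N_O − k_H·N_H) + α₂, and TEE follows from the
modified Weir equation TEE = 22.4·(15.48/RQ + 5.55)·rCO₂, which at the
assumed RQ = 0.85 gives TEE ≈ 532·rCO₂ kJ per mol CO₂.  The Bayesian model
inverts the (rCO₂, S, R_W, F) ↔ (N_H, N_O, k_H, k_O) map exactly, predicts
every observed δ, and uses Gaussian measurement error (2 ‰ for ²H, 0.5 ‰
for ¹⁸O).

## Worked example

Simulate a small cohort, fit it classically with and without space
normalization, and compare the two arms:

```sh
$ dlw simulate --out demo --seed 7 --n-women 6 --n-men 6
wrote 12 subjects to demo

$ dlw fit-classical --data demo --method logarithmic --normalize none --out demo/natural.csv
$ dlw fit-classical --data demo --method logarithmic --normalize schoeller --out demo/normalized.csv
$ dlw compare --a demo/natural.csv --b demo/normalized.csv
{
  "n": 12,
  "mean_difference": 73.52542718964385,
  "median_difference": 74.95634268288632,
  "sd_difference": 587.5775951757786,
  "lower_loa": -1078.1266593548821,
  "upper_loa": 1225.1775137341697,
  "slope": -0.03729206408030646
}
```

The per-subject results carry the fitted pools and rate constants, the
natural space ratio, rCO₂, TEE and an approximate CV:

```
subject_id,sex,N_H,N_O,k_H,k_O,S,rCO2,TEE,cv,flags
F001,F,1826.94,1788.91,0.083259,0.105419,1.02126,16.4922,8778.20,0.0257,
F002,F,1736.97,1671.99,0.104286,0.126777,1.03886,13.8385,7365.73,0.0224,
```

(Here subject F001's natural ratio 1.021 is below the 1.03 normalization
target, so normalization lowers her TEE; the Bland-Altman stats above
summarize that per-subject effect across the cohort.)

The full four-arm comparison (natural, normalized, independent Bayesian,
hierarchical Bayesian) runs all estimators and emits a JSON report:

```sh
$ dlw four-arm --data demo --iterations 10000 --burnin 1000 --seed 11 --out demo/report.json
```

which for this cohort gives per-sex TEE medians (ranges) in kJ/day of

```
F natural      9230 (6569-10009)      M natural      12863 (11278-14874)
F normalized   8951 (6941-10024)      M normalized   13316 (11489-14606)
F independent  9421 (6728-10379)      M independent  12834 (11325-15009)
F hierarchical 9416 (6718-10348)      M hierarchical 12849 (11388-14993)
```

together with the population space-ratio hyperparameter per stratum
(e.g. S_g = 1.0335 ± 0.0038 for the men above) and Bland-Altman statistics
between arms.

As a library, the same pieces compose directly:

```python
from dlw import PhysioParams, core
from dlw.bayes import MCMCConfig, sample_independent
from dlw.simulate import CohortDesign, simulate_cohort

subjects, truths = simulate_cohort(CohortDesign(n_women=1, n_men=0, seed=21))
res = sample_independent(subjects[0], cfg=MCMCConfig(iterations=10_000, burn_in=1_000, seed=1))
tee = res.stacked("TEE")
print(tee.mean(), tee.std())   # posterior mean and sd of TEE, kJ/day
```

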