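# cdtkit

Coalescent rate calibration by **demographic transition (CDT)** for
single-locus mitochondrial population genetics.

Dating recent events in marine populations — post-glacial expansions,
splits between local populations — requires a substitution rate, and for
most invertebrates neither fossils nor geological vicariance provide one.
Worse, apparent molecular rates accelerate toward the present, so deep
phylogenetic rates systematically overestimate the age of shallow
coalescent events. CDT sidesteps both problems: it assumes the population
expanded in response to post-glacial warming, infers the *mutation-scaled*
timing of that expansion from sequence data, equates it with calendar
dates drawn from the warming rate of a temperature proxy, and so obtains a
full probability distribution for the rate — which then calibrates a
Bayesian skyline reconstruction and split-time estimates on the same data.

`cdtkit` implements that pipeline end to end, with seeded synthetic-data
generators so every stage is testable without any external download:

* **popgen_stats** — haplotype collapsing, h, π, Tajima's D, Fu's Fs, R2
  (with coalescent nulls), AMOVA Φst with permutation tests, T92+Γ
  distances, minimum spanning networks.
* **tem_inference** — Bayesian two-epoch model (TEM): an ancient constant
  size θ₁ followed by exponential or logistic growth to θ₂, with the
  transition time TT in substitutions/site; HKY+Γ tree likelihood, strict
  and relaxed clocks, Metropolis–Hastings MCMC, harmonic-mean and
  stepping-stone marginal likelihoods, 2·lnBF model comparison.
* **cdt_calibration** — warming-rate date weights, rate = TT/date crossing
  (the full 9×10⁷ cross product handled without materialization),
  log-normal/Gaussian ML fits selected by AIC, exact unit conversions
  (2.2×10⁻⁸ subst/site/yr ≡ 2.2 %/My).
* **skyline_split** — piecewise-linear Bayesian skyline under a CDT or
  fixed-rate clock, Ne trajectories with HPD bands, MCC trees with median
  node heights, split-time posteriors of designated taxon sets.
* **synthetic_data** — two-epoch coalescent simulation by time rescaling,
  HKY+Γ sequence evolution, clean-split histories, synthetic deglacial
  temperature records, deterministic fixture sets.

The model core, in the field's usual notation: k lineages coalesce at rate
k(k−1)/(2N(t)) with N(t)=θ(t) mutation-scaled; the logistic TEM is
N(t) = θ₁ + (θ₂−θ₁)/(1+e^((t−TT)/s)); the CDT rate is r = TT/τ with τ
drawn ∝ max(−dT/d(age), 0) from the proxy record; and the skyline
interpolates Ne linearly between grouped coalescent-event times. See
`docs/methods.md` for the full specification of priors, proposals and
numerical choices.

## Worked example

Simulate a ~100-fold expansion that began 12 kya at a true rate of
2×10⁻⁸ subst/site/yr (so TT = 2.4×10⁻⁴), then recover the rate:

```python
import numpy as np
from cdtkit import (
    TwoEpochModel, SubstitutionModel, simulate_coalescent, simulate_sequences,
    tajimas_d, collapse_haplotypes, run_tem_mcmc, synth_temperature,
    warming_rate_weights, sample_calibration_dates, cross_rate_samples,
    fit_rate_distribution,
)
from cdtkit.tem_inference import extract_posterior

true_rate = 2.0e-8
model = TwoEpochModel("logistic", theta_modern=0.02, theta_ancient=2e-4,
                      transition_time=12_000 * true_rate)
genealogy = simulate_coalescent(40, model, seed=1)
alignment = simulate_sequences(
    genealogy, SubstitutionModel(kappa=4.0, gamma_shape=0.5), 608, seed=2)

table = collapse_haplotypes(alignment)
print(f"haplotypes: {table.n_haplotypes}, segregating sites: "
      f"{len(table.segregating_sites)}, Tajima's D: {tajimas_d(alignment):.2f}")

trace = run_tem_mcmc(alignment, tem_kind="logistic", clock_kind="strict",
                     chain={"length": 150_000, "sample_interval": 150}, seed=3)
tt = extract_posterior(trace, "transition_time", burn_in_fraction=0.1)
print(f"TT median: {tt.median:.2e} subst/site "
      f"(95% HPD {tt.hpd_lower:.1e}-{tt.hpd_upper:.1e})")

record = synth_temperature(warming_onset=12_000, warming_width=2_000,
                           amplitude=8.0, noise_sd=0.2, seed=4)
ages, weights = warming_rate_weights(record)
dates = sample_calibration_dates(ages, weights, k=10_000, seed=5)
fit = fit_rate_distribution(cross_rate_samples(tt.samples, dates, mode="full"))
print(f"CDT rate: median {fit.median_rate_pct_per_my:.2f} %/My, "
      f"{fit.selected} fit (LogMean={fit.lognormal['LogMean']:.2f}, "
      f"LogSD={fit.lognormal['LogSD']:.2f})")
```

Output:

```
haplotypes: 8, segregating sites: 8, Tajima's D: -2.17
TT median: 3.57e-04 subst/site (95% HPD 1.4e-06-7.7e-04)
CDT rate: median 3.01 %/My, lognormal fit (LogMean=-3.36, LogSD=1.07)
```

Reading it: the expansion leaves the classic signature (strongly negative
Tajima's D, few haplotypes for 40 sequences); the mutation-scaled
transition time is recovered with the true value 2.4×10⁻⁴ well inside the
wide posterior a single 608-bp locus supports; crossing the TT posterior
with 10,000 warming-weighted calendar dates gives a log-normal rate
distribution whose median (3 %/My here) brackets the generating rate of
2 %/My — single-locus CDT rates are distributions, not point values, and
downstream stages propagate that uncertainty.

There is also a subcommand CLI (`cdtkit simulate | stats | tem | cdt |
skyline | split | all`) that chains the stages on files and writes a
manifest with every seed and parameter; `cdtkit stats --alignment a.fasta
--population-map pops.tsv --outdir out` reproduces the per-population
statistics table (N, H, h, π, D, Fs, R2 with p-values) of a typical
mitochondrial survey.

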