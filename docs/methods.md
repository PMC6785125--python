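# Methods

`cdtkit` implements a complete single-locus pipeline for dating recent
demographic events in species without usable fossil or geological
calibrations: classical diversity/neutrality statistics, Bayesian inference
of a two-epoch demographic model (TEM), calibration of the molecular rate
against a climatic proxy (calibration of demographic transition, CDT),
Bayesian skyline reconstruction, and split-time estimation. This note
records the models, the parameter choices that matter, and the design
decisions taken where the literature leaves them open.

## Coalescent units

All inference runs in mutation-scaled time (substitutions/site): the mean
clock rate is fixed at 1, so genealogy node heights, the transition time TT
and the population-size parameters θ are all in substitutions/site. k
lineages coalesce at rate k(k−1)/(2 N(t)) with N(t) = θ(t); a constant
θ = 1 therefore gives the standard pairwise coalescence rate 1 and, for
n = 2, an Exp(1) TMRCA. The CDT step is what converts mutation-scaled time
to years: rate = TT / calendar date, which is the reason the inference must
stay mutation-scaled.

## Two-epoch demographic model

An ancient epoch of constant size θ₁ precedes a modern growth epoch ending
at θ₂ at the present. Time t runs backwards from 0.

* **exponential**: N(t) = θ₂·e^(−gt) for t < TT, θ₁ for t ≥ TT, with g
  fixed by continuity at TT (so θ₁ = θ₂ degenerates to a constant size
  without error).
* **logistic**: N(t) = θ₁ + (θ₂−θ₁)/(1 + e^((t−TT)/s)); TT is the
  inflection (half-growth) time, making TT comparable across both kinds.
  The steepness s defaults to TT/10 — a sharp but smooth transition.

Both kinds have closed-form cumulative inverse-size integrals
A(t) = ∫₀ᵗ du/N(u) (the logistic one via log-sum-exp for numerical
stability at large t), used three ways: coalescent simulation by time
rescaling (unit exponentials mapped through A⁻¹, inverted with Brent's
method on a bracketed interval), the coalescent log-density
Σ −k(k−1)/2·ΔA − Σ ln N(t_c), and the MCMC prior. The simulator is
validated distributionally against msprime and the density against adaptive
quadrature.

## Sequence evolution

HKY85 with empirical or specified base frequencies and discrete-Gamma
among-site rate variation (4 equal-probability categories, mean-of-bin
rates via the closed-form incomplete-gamma identity, renormalized to mean
1). The generator draws the root from the stationary distribution and one
rate category per site; the likelihood uses Felsenstein pruning over
compressed site patterns with the same model family, so simulation and
inference are exactly matched. Transition matrices come from the symmetric
eigendecomposition of the reversible generator. The pruning kernel skips
per-node rescaling: with ≤ ~100 contemporaneous tips and intraspecific
branch lengths, per-pattern likelihoods stay far above the double-precision
underflow threshold (worst case ~10⁻⁵⁰ for 79 tips).

## Summary statistics

Missing data (N or −) are handled by complete deletion (any column with a
missing character is dropped before any statistic), matching common
Arlequin/MEGA defaults and keeping S well-defined; pairwise deletion is
available for distances. Haplotypes are equivalence classes of identical
sequences after that filter.

* h (Nei) with Nei (1987) sampling variance; π per site with the standard
  total variance (sampling + stochastic terms).
* Tajima's D from mean pairwise difference counts and Watterson's θ with
  the 1989 normalizing constants (the n = 4 singleton toy gives −0.612).
* Fu's Fs = ln(S′/(1−S′)) with S′ = P(K ≥ k_obs | θ̂ = π) under the Ewens
  sampling formula; unsigned Stirling numbers of the first kind are built
  exactly with integer recursion and used in log space, and the
  rising-factorial normalization cancels in the odds ratio. K ≥ k_obs is
  certain for k_obs = 1 (Fs = +∞, signalled as `inf`); π = 0 raises.
* R2 (Ramos-Onsins & Rozas) from per-sequence singleton counts, folded
  (a base observed exactly once defines the singleton and its carrier).
* Significance: the sources describe "1000 permutations", but permutation
  is undefined for single-population neutrality statistics; the null is
  instead the constant-size coalescent conditioned on (n, S) — S
  infinite-sites mutations placed uniformly on a simulated genealogy —
  with one-tailed p = P(stat ≤ observed), small values indicating
  expansion. 1000 replicates by default.
* Φst: two-level AMOVA from squared pairwise molecular distances (pairwise
  difference counts by default, T92+Γ optionally), with the p-value from
  random reassignment of individuals to populations holding sizes fixed.
* T92+Γ distances require an explicit Γ shape (no hidden default, since the
  source analyses never report one); saturated pairs yield NaN and the MST
  refuses NaN inputs rather than guessing.
* The minimum spanning tree uses Kruskal with ties broken by (distance,
  lexicographic label pair) for determinism.

## Bayesian TEM inference

A Metropolis-Hastings sampler over (genealogy, θ₁, θ₂, TT, κ, α, base
frequencies, branch rates). Moves: scale moves on positive scalars,
uniform node slides, root-height and whole-tree scales, a joint scale of
all node times and demographic scalars (which follows the strong
height–θ–TT posterior ridge; without it the chain random-walks across that
ridge an order of magnitude more slowly), narrow and wide exchanges for
topology, delta-exchange for frequencies, and prior-independence proposals
for relaxed-clock branch rates. Relaxed clocks are uncorrelated with mean
exactly 1: log-normal(−σ²/2, σ) with σ sampled, or Exp(1).

Default priors (all configurable, all echoed into run manifests):

| parameter | prior | rationale |
|---|---|---|
| θ₁, θ₂ | LogNormal(ln 10⁻³, 3) | diffuse over 10⁻⁶–1, centred on intraspecific mtDNA scale |
| TT | Uniform(0, 2.5×10⁻³) | see below |
| κ | LogNormal(1, 1.25) | standard weakly-informative transition-bias prior |
| α | Exponential(mean 0.5) | standard |
| clock σ | Exponential(mean 1/3) | standard |

The TT window deserves its own justification. CDT presumes the inferred
demographic transition is the post-glacial warming (≤ ~25 kya); at the
fastest plausible invertebrate mtDNA rate (10%/My = 10⁻⁷/site/yr) that is
2.5×10⁻³ substitutions/site. Beyond that bound the two-epoch model
degenerates into a constant-size model over the whole genealogy, the
likelihood goes flat in TT, and a wider uniform prior simply pours
posterior mass into that unidentifiable region — the prior would dominate
the calibration quantity. The window therefore spans every transition time
the method could subsequently calibrate, and nothing else.

Chains default to 10⁵ steps (production analyses of this kind run 10⁸–10⁹
steps; the package's desk-scale default keeps a TEM run under a minute at
n = 40×608 and is overridable in one argument). Convergence is gated on bulk ESS ≥ 100 for
every sampled scalar; failing chains complete but carry an explicit
warning flag — non-convergence of particular model/clock combinations is
an expected outcome to surface, not an exception. Starting trees are UPGMA
on p-distances with
heights jittered into strict order; starting θs come from Watterson's
estimate.

Prior-sampling validity is tested by switching the likelihood off: because
the coalescent density is normalized over genealogies, every scalar
parameter's marginal must then equal its prior (a KS check that exercises
the tree moves, the Hastings ratios, and the coalescent density jointly).

Marginal likelihoods: harmonic-mean from the posterior trace (provided for
parity with common trace tools, documented as unstable) and stepping-stone
over a power ladder of tempered chains (recommended; validated against a
conjugate normal–normal toy with an analytic marginal likelihood). Models
are ranked by 2·lnBF with exact antisymmetry.

## CDT rate calibration

The temperature record is linearly interpolated to a regular age grid
(100-yr steps over 0–25 kyr BP by default); the per-age weight is the
warming rate toward the present, floored at zero — cooling cannot trigger
an expansion, so monotone-cooling windows raise an error rather than
producing arbitrary dates. Calendar dates are drawn with probability
proportional to the weights (10,000 by default), and every (TT, date) pair
yields a rate TT/date.

The full posterior × dates cross product (9×10⁷ at the source's scale) is
never materialized: because ln(TT/date) = ln TT − ln date with independent
factors, the log-moments of the full product are exact sums of the factor
moments, the Gaussian moments follow the same product identities, and
quantiles are found by bisection on the pair-counting function
#{TT_i ≤ x·d_j} (O((n+m) log n) per probe). Sub-sampling mode exists for
quick work and agrees with the full product to <1% on the median.

Both a log-normal and a Gaussian density are fitted by closed-form ML on
the substitutions/site/My scale — the scale on which a LogMean of about
−3.9 corresponds to ~2%/My — and selected by AIC (k = 2 each). Unit
conversions are exact: %/My = 10⁸ × subst/site/yr.

## Bayesian skyline and split times

The piecewise-linear skyline groups the n−1 coalescent intervals into
n_groups (10 in the study configuration; remainder intervals assigned to
the oldest groups) and interpolates Ne linearly between the group-boundary
coalescent times, with closed-form ∫dt/Ne per linear segment. One group
with equal boundary sizes reproduces the Kingman density exactly.

Two design choices here departed from a first, simpler implementation
after it measurably failed:

* **Size priors.** The skyline has n_groups+1 sizes, the deepest informed
  by a single coalescent interval. With fully diffuse independent priors
  the deep sizes are prior-dominated and drag the posterior root height
  toward the prior's scale (∼3× TMRCA inflation on star-like expansion
  data). The default marginal prior is LogNormal(ln 10⁻³, 1.5) — still
  spanning the intraspecific mtDNA range 10⁻⁵–10⁻¹ at ±3σ — and adjacent
  sizes are tied by a Markov smoothing prior (each older size log-normally
  centred on its younger neighbour, SD 1.25 log units), in the tradition
  of smoothed skyline estimators. The SD leaves a 100-fold size change
  between adjacent boundaries within ~1.8σ, so genuine expansions remain
  expressible.
* **Rate handling.** Sequence data alone cannot separate rate from time,
  so the genealogy is sampled mutation-scaled and the clock rate — drawn
  from the CDT log-normal fit (mode a) or fixed (e.g. 0.7%/My) — enters
  as an independent per-recorded-state draw used to rescale that state's
  times and sizes to years. This is marginally identical to sampling the
  rate jointly (its posterior equals its prior in either case) and mixes
  better; a point-mass CDT fit reproduces the fixed-rate pipeline
  exactly. Post-hoc rescaling of stored mutation-scaled trees by
  independent CDT draws (mode b) is the same operation applied later.

Trajectories are summarized on a 200-point year grid from 0 to the 97.5%
TMRCA quantile (per-sample sizes held at the root value beyond that
sample's TMRCA), as per-grid-point medians and 95% HPD (shortest-interval)
bands, with Ne = θ/(rate·g) for generation time g (1 yr in the study
configuration).

The MCC tree is the sampled topology maximizing the product of clade
posterior frequencies, with per-clade median heights (which can produce
locally negative branches; the summary tree is deliberately not
re-validated). Split times are the per-tree MRCA ages of a taxon set
divided by that tree's rate, reported with the central 95% interval and
the monophyly frequency — the MRCA is used whether or not the set is
monophyletic, since posterior topologies vary.

A caution the tests make explicit: the clade-MRCA age estimates the
population split only in the demographic regime where within-deme
coalescence is slow relative to the split (large deme θ, small ancestor) —
precisely the regime a post-glacial expansion creates. With small demes
the MRCA tracks the much younger within-deme coalescence and no
single-locus functional of the gene tree estimates the split.

## What the synthetic data do and do not emulate

The generators reproduce the statistical structure the analysis assumes:
inhomogeneous coalescent genealogies under the two-epoch model, HKY+Γ
mutation, clean two-deme splits with no post-split migration (the species'
biology: no planktonic stage, negligible effective migration), and a
sigmoidal deglacial warming with seeded noise. They do not emulate
recombination, selection, migration, multi-locus data, sequencing error,
or the millennial-scale wiggles of real ice-core records — so passing
tests demonstrate correctness of the inference machinery under its own
model, not robustness to violations of it. Every generator is bitwise
reproducible from (configuration, seed), with per-fixture seeds spawned
from one root `SeedSequence` in sorted fixture-name order.

## Problem sizes used in the test suite

Chain lengths and replicate counts in the tests are the package's
desk-scale choices: TEM recovery uses 20 replicates of 40×608 data at
1.5×10⁵ steps; the CDT end-to-end check 10 replicates at 10⁵ steps; BSP
checks 6–10 replicates at 1.5–5×10⁴ steps. The expansion-onset power test
uses a 3 kb locus and 10 groups because, at 608 bp, individual
coalescent-event times are not mutationally resolved and the onset of the
reconstructed decline smears toward the root — a resolution limit of the
data scale, not of the implementation. Full-scale settings (5×10⁸ steps,
10⁴ recorded states) remain one config value away.

## Known limitations

* Single locus only; the two-epoch prior applies to one genealogy.
* The harmonic-mean estimator is provided for tool parity but its variance
  is effectively unbounded; use stepping-stone for model choice.
* MCMC convergence at the default desk-scale chain lengths is adequate for
  the data sizes above but should be re-gated (ESS ≥ 100–200) for larger
  alignments.
* The temperature loader expects a two-column CSV (age yr BP, anomaly °C);
  real proxy records must be reduced to that shape upstream.
* With uninformative data the TT posterior is prior-bounded; the
  calibration window prior (see above) is then doing real work and must be
  reported alongside any rate estimate.
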