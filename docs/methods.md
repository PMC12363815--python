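# Methods

## The model

Crossover interference — the tendency of meiotic crossovers to be spaced
more evenly than a Poisson process would place them — is described here by
two standard statistical models of crossover placement on a transmitted
chromatid, both defined on the genetic (map) scale, in Morgans.

**Gamma model.** Chiasmata on the four-strand bundle form a stationary
renewal process whose inter-arrival distances are Gamma with shape ν and
rate 2νλ, where λ is the resulting crossover rate per Morgan on one
chromatid. Each chiasma resolves on a given chromatid with probability 1/2
independently (no chromatid interference), so the crossover process on the
chromatid is again a stationary renewal process with inter-arrival density

    g(x) = Σ_{k≥1} 2^(−k) · GammaPDF(x; shape kν, rate 2νλ),

survival S = 1 − G and event rate λ. ν = 1 telescopes the mixture to an
Exponential(λ) density — no interference; larger ν means stronger, more
regular spacing. For the plain gamma model λ = 1, by the definition of map
distance.

**Gamma-sprinkling (Housworth–Stahl) model.** A proportion p ∈ (0, 1) of
crossovers escape interference. The interfering component runs as above at
rate λ_I = 1 − p and an independent homogeneous Poisson process of rate p
is superposed ("sprinkled"). Total rate stays 1 per Morgan, so the genetic
map is preserved for every (ν, p).

**Likelihood.** For ordered crossover positions x₁ < … < x_k on a
chromatid of map length L, the stationary renewal likelihood is

    k = 0:  1 − λ ∫₀^L S(t) dt
    k ≥ 1:  λ S(x₁) · Π_{i=2..k} g(x_i − x_{i−1}) · S(L − x_k),

and the sprinkling likelihood sums, over all 2^k assignments of the
observed crossovers to the interfering versus escaping component, the
renewal likelihood of the interfering subset times p^(#escaping) e^(−pL).
Zero-crossover chromatids are first-class observations — the k = 0 term
carries real information — so absent chromosomes are materialized from a
meiosis manifest rather than silently dropped. The integral ∫₀^L S is
evaluated term-by-term with the closed form
∫₀^L (1 − F(t; a, b)) dt = L(1 − F(L; a, b)) + (a/b) F(L; a + 1, b).

## Hierarchical structure

ν and p vary over groups of meioses (parental sex, i = 1..m) and groups of
chromosomes (j = 1..n; a single level, per-chromosome, or size bins
long = chr1–5, medium = chr6–12, short = chr13–19) through log/logit links:

    log ν_ij  = β₀ + β_i + β_j
    logit p_ij = α₀ + α_i + α_j

with independent Normal(0, σ_ν²) priors on the β effects and
Normal(0, σ_p²) on the α effects. The links are translation-invariant, so
effects within each factor are constrained to sum to zero and the
intercepts carry the global level. Where the effect prior is silent the
package chooses weakly-informative defaults: intercepts ~ Normal(0, 5²) on
their transformed scales and σ_ν, σ_p ~ Half-Normal(1), all overridable in
`MCMCConfig`.

## Sampling

Inference is by Metropolis-coupled MCMC: by default three chains at
inverse temperatures (1, 0.7, 0.49) — a geometric ladder — each updated by
blocked Gaussian random walks, with one random adjacent-pair swap proposal
per iteration using the usual tempered acceptance ratio. Block proposal
SDs are adapted by Robbins–Monro during burn-in toward an acceptance rate
of 0.6 (i.e. a rejection rate near 0.4) and frozen afterwards, preserving
the post-burn-in Markov property. Default run length is 25000 iterations
with 5000 discarded as burn-in; only the cold chain is recorded.

Two sampling choices deserve explanation:

* **Non-centred effects.** The flat chain state stores standardized
  effects u with unit-normal priors and reconstructs the model-scale
  effects as σ·u. With only one free effect per factor (m = 2, n = 1) the
  centred parameterization puts the sampler in a funnel — the posterior
  for σ concentrates near zero, freezing the effects and collapsing the
  adapted proposal scales — which we observed directly as an effect-block
  acceptance rate near zero. The non-centred form removes the funnel and
  is exactly the same posterior.
* **Two blocks, not three.** Because σ enters the likelihood through σ·u
  in the non-centred form, each log-scale is sampled inside the block of
  its own link (β-block: β₀, u_β, log σ_ν; α-block: α₀, u_α, log σ_p)
  rather than in a separate prior-only scales block.

## Numerical choices

* Positions are stored in Morgans; cM is accepted and emitted at file
  boundaries. Crossovers exactly at 0 or L are legal boundary events.
* The mixture series for g, S and ∫S is truncated once three consecutive
  terms contribute < 1e−13 relative to the running sum (hard cap 200
  terms); the 2^(−k) weights make the tail geometric. The density and
  survival series are accumulated with logaddexp so extreme shapes remain
  finite in log space.
* The zero-event probability switches to the tail form λ ∫_L^∞ S when the
  direct 1 − λ∫₀^L S would cancel catastrophically (very long L).
* The 2^k subset sum is evaluated by log-sum-exp; chromatids with more
  than 10 crossovers (configurable) are rejected as data errors — the
  observed maximum in data of this design is about 4.
* Repeated likelihood evaluation (MCMC, MLE) uses a compiled evaluator
  that pools every needed evaluation point across the dataset, runs one
  vectorized series pass, and reassembles per-chromatid subset sums by
  indexed reductions. For sampling, evaluation points are optionally
  snapped to a 1e−3 Morgan (0.1 cM) grid — below the junction uncertainty
  of real crossover calls — which collapses near-duplicate points and cuts
  the cost roughly tenfold; exact evaluation (`position_resolution=None`)
  is the default everywhere correctness is asserted.
* MLE runs on (log ν, logit p) with multi-start Nelder–Mead (≥ 3 starts,
  objective tolerance 1e−8); the box constraints are implicit in the
  transform. The LRT uses the plain chi-square with df = 2 for the
  sex-specific comparison; p strictly interior by parameterization, no
  boundary correction.
* HPD intervals use the shortest-window construction on sorted draws
  (window of ⌈mass·N⌉ draws, leftmost tie wins), the same construction the
  common MCMC summary tools use.

## The synthetic-data generator

`simulate.default_cc_design()` emulates the Collaborative Cross study
population: 474 scored meioses per parental sex, 19 autosomes with
per-chromosome lengths declining linearly from chr1 to chr19 and summing
to 13.55 Morgans (female) and 12.21 Morgans (male), and generating
parameters equal to the published sex-specific estimates
(ν_f = 11.2, p_f = 0.0094; ν_m = 18.6, p_m = 0.027). The chiasma renewal
process is started a burn-in distance of 20 mean inter-arrivals before the
chromosome and truncated to [0, L] (sampling the first arrival from the
analytic equilibrium residual-life distribution is available as an
alternative); chiasmata are thinned 1/2 independently and the escaping
Poisson component is superposed.

What the generator does **not** emulate: interval censoring of junctions
(real crossovers are located between informative markers, so double
crossovers closer than the marker spacing are unobservable in array data),
the obligate crossover, pedigree structure, or genotyping error. The
practical consequence is visible in the misspecified-model fits: synthetic
data contains arbitrarily short inter-crossover gaps, which depress a
pure-gamma fit (ν₀ near 7.9 female / 5.7 male on full-size synthetic
datasets) and inflate the gamma-versus-sprinkling likelihood-ratio
statistic relative to what array-resolution data of the same design would
give. Recovery of the *generating* sprinkling parameters is unbiased — a
24-replicate repeat study at (ν = 18.6, p = 0.027), 300 meioses, gave
ν̂ = 18.80 ± 1.13 and p̂ = 0.0268 ± 0.0044 — so passing tests demonstrate
correctness of the likelihood/simulator pair and of the inference
machinery, not that real data of this design would yield these exact
misspecified-model statistics.

## Problem sizes used in tests and the acceptance script

The full 25000-iteration configuration is the package default; the test
suite and the acceptance script run the same code at reduced but still
study-scale sizes chosen to exercise every component meaningfully: the
parameter-recovery check simulates the full design (474 meioses per sex,
18012 chromatids) and samples 5000 iterations with 1000 burn-in; the
acceptance script uses 3500/700 for the sprinkling model and 2500/500 for
the reduced gamma model; distributional checks use 10⁶ simulated
inter-crossover distances and 10⁴ simulated meioses.

## Known limitations

* The likelihood is for point-located crossovers; interval-censored
  junctions are collapsed (midpoint by default) before fitting rather than
  integrated over.
* No X-chromosome model; autosomes only.
* The escape proportion p is a statistical mixture weight; the model makes
  no claim that it isolates the class II crossover pathway.
* With m = 2 sexes the hierarchical scales σ_ν, σ_p are informed by a
  single free effect each; their posteriors are prior-dominated, which is
  expected and harmless for the cell-level parameters.
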