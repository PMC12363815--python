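# xover — sex-specific crossover interference from transmitted chromatids

Meiotic crossovers are spaced more evenly along chromosomes than chance
would allow — crossover interference — and a minority of crossovers escape
interference altogether. This package estimates both phenomena from
crossover positions observed on transmitted chromatids (for example,
haplotype junctions called in a multi-parent mouse cross), separately for
female and male meiosis and optionally by chromosome or chromosome-size
group. It is aimed at quantitative geneticists analysing pedigree or
panel data where each crossover can be assigned to a specific meiosis.

## Models

Positions live on the genetic map (Morgans). Under the **gamma model**,
chiasmata form a stationary gamma renewal process (shape ν, rate 2νλ) on
the four-strand bundle and each appears on a transmitted chromatid with
probability 1/2, giving a chromatid crossover process with inter-arrival
density

    g(x) = Σ_{k≥1} 2^(−k) GammaPDF(x; kν, 2νλ),   λ = 1 crossover/Morgan.

ν = 1 is no interference (Poisson); larger ν, stronger interference. The
**gamma-sprinkling (Housworth–Stahl) model** adds an escape proportion
p ∈ (0, 1): the interfering component runs at rate 1 − p and an
independent Poisson process of rate p is superposed. The package provides

* exact per-chromatid log-likelihoods for both models (including the
  informative zero-crossover term),
* sex-specific maximum-likelihood fits with the nested likelihood-ratio /
  ΔAIC comparison,
* a hierarchical Bayesian model, log ν_ij = β₀ + β_i + β_j and
  logit p_ij = α₀ + α_i + α_j over sex and chromosome groups, fitted by
  Metropolis-coupled MCMC with adaptive random-walk proposals,
* posterior summaries (means, quantile intervals, 95% HPDIs), sex and
  chromosome-size ratio contrasts, and posterior-predictive checks of the
  inter-crossover distance distribution,
* a forward simulator of both processes that doubles as a synthetic-data
  generator emulating a Collaborative-Cross-like design (474 scored
  meioses per sex, 19 autosomes, sex-specific maps of 1355 / 1221 cM).

See `docs/methods.md` for the full model description and numerical
choices.

## Worked example

Simulate a study-scale dataset at the published mouse estimates and refit
it (the numbered scripts under `analysis/` run the same steps with
narrative output):

```sh
python analysis/01_simulate.py --seed 123
python analysis/02_summarize.py
python analysis/03_fit_mle.py
python analysis/04_fit_bayes.py --seed 42
python analysis/05_posterior_checks.py
```

For the seed-123 dataset `02_summarize.py` prints

```
total crossovers: 12129; non-recombinant 42.9%, single 47.2%, multi 9.9%
```

with 13.44 crossovers per meiosis in females and 12.15 in males — the
per-sex rates track the map totals of 13.55 and 12.21 Morgans, as rate
conservation requires. `04_fit_bayes.py` (5000 iterations, 1000 burn-in,
seed 42) summarizes the posterior as

```
parameter     sex    mean  hpdi_lower  hpdi_upper
nu         female  10.453       9.570      11.321
nu           male  18.888      16.845      20.888
p          female  0.0086      0.0043      0.0134
p            male  0.0263      0.0195      0.0328

         contrast  posterior_mean  hpdi_lower  hpdi_upper
nu_male/nu_female           1.810       1.574       2.073
  p_male/p_female           3.322       1.468       5.437
```

The generating truth (ν 11.2 / 18.6, p 0.0094 / 0.027) falls inside every
95% HPDI: interference markedly stronger in male meiosis, the escape
proportion about three times larger, and both sex differences resolved
from a single study-scale dataset. `05_posterior_checks.py` closes the
loop with a posterior-predictive check (observed mean adjacent distance
42.7 cM versus predictive 42.3 cM).

A command-line interface wraps the same stages for on-disk data:

```sh
xover simulate --seed 3 --out sim/cc
xover fit-bayes --crossovers sim/cc.crossovers.tsv --map sim/cc.map.tsv \
    --iterations 25000 --burn-in 5000 --seed 1 --out bayes/run
xover compare --crossovers ... --map ... --out comparison
```

Input formats are plain TSV: a crossover table
(`meiosis_id sex chromosome position_cM`), a genetic map
(`chromosome sex length_cM`), an optional meiosis manifest
(`meiosis_id sex`) naming every scored meiosis so that zero-crossover
chromosomes are counted, and optionally a BED-like haplotype-segment table
from which crossovers are derived at junction midpoints.

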