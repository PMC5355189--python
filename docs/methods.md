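# Methods

`flypop` implements an integrated population model (IPM) for female-only
nest-box monitoring data of the kind collected for Siberian flying
squirrels: an annual census of broods, a productivity table, and
capture-recapture histories of ear-tagged females. This note records the
model, the choices made where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and known limitations.

## The integrated model

Population size is the number of females aged one year or more. Three
latent stages are tracked per year `t`:

* `N1[t]` — locally recruited one-year-olds,
* `Nad[t]` — older females that survived and stayed,
* `Nimm[t]` — immigrant females in their year of arrival,

with `Ntot = N1 + Nad + Nimm`. The state process is

    N1[t+1]   ~ Poisson(Ntot[t] · f[t] · φj[t])
    Nad[t+1]  ~ Binomial(Ntot[t], φa[t])
    Nimm[t+1] ~ Poisson(m[t])

and the census is observed as `y[t] ~ Poisson(Ntot[t])`. Three data
likelihoods share these parameters:

1. **Capture-recapture** (Cormack–Jolly–Seber on age-structured
   m-arrays): separates recapture probability `p` from *apparent* survival
   — first-year `φj` for animals tagged in the natal nest, `φa`
   thereafter. Apparent survival confounds death with permanent
   emigration, so no separate emigration process exists. A single `p` is
   shared by both age classes. The log-likelihood is written without the
   multinomial coefficient, making it exactly equal to the product of
   per-individual history likelihoods (the test suite verifies this
   identity against a brute-force enumeration over death times).
2. **Productivity**: `J[t] ~ Poisson(R[t] · f[t])`, daughters tagged per
   identified reproductive female. Unsexed offspring count 0.5 daughter,
   so `J` is half-integer valued; the Poisson log-density uses its
   continuous gamma-function extension, which preserves the printed data
   exactly and perturbs the likelihood negligibly.
3. **Census** as above. Immigration has no data of its own: the posterior
   of `m[t]` (one free parameter per year) is driven entirely by the gap
   between the census and what survival plus local recruitment explain.

Annual rates are hierarchical: `φ[t] = logit⁻¹(logit(μ) + ε[t])` and
`f[t] = exp(log(μf) + εf[t])` with `ε ~ Normal(0, σ²)` per rate family.

**Priors.** Uniform(0,1) on the mean probabilities, Normal(0, 10²) on
`log μf`, Uniform(0, 10) on all σ, Uniform(0, 30) on each expected
immigrant count `m[t]`, and positive-truncated Normal(10, 100²) rounded to
integers on the initial stage sizes. The historical analyses this model
family descends from used a uniform immigration prior extending to −10;
counts cannot be negative, so the support here starts at 0 with a
Poisson layer on the realized count. A consequence, documented below, is a
positive floor on estimated immigration when true immigration is absent.

**Fecundity applies to all females** (`Ntot · f · φj`), not only to
identified mothers: the monitoring design identifies a female only when
she is caught at a box check, so `R` is a thinned sample of breeders, and
all females are treated as breeding-capable each year.

## Sampler

Adaptive Metropolis-within-Gibbs, compiled with numba:

* scalar random-walk updates for the four hyper-means (logit/log scale),
  the four σ, and every annual effect, with diminishing Robbins–Monro
  scale adaptation toward 44% acceptance during burn-in;
* each `m[t]` drawn exactly from its full conditional, a
  Gamma(`Nimm[t+1]`+1, 1) truncated to the prior support;
* integer random-walk proposals (steps of ±1, ±2) on each latent stage
  size, plus a stage-swap move that transfers one female between stages
  within a year, preserving the census-constrained total;
* defaults: 3 chains, 50 000 iterations, half burn-in, thinning 10.
  Convergence is monitored by the potential scale reduction factor of all
  hyper-parameters (threshold 1.1; exceedances raise a warning and the
  draws are still returned). Tests and the acceptance checks run reduced
  chains (2 × 4000, burn-in 1600, thin 3), which were verified to
  reproduce the long-run posterior on simulated data.

The kernel's joint posterior is cross-checked term by term against an
independent composition of the component likelihoods (scipy-based) to
1e-8, and the sampler's stationary distribution was verified to be
independent of whether latent immigration is initialized at zero or at
15% of the census.

## Posterior summaries and derived quantities

Point estimates are posterior **modes** from a Gaussian kernel density
estimate (Silverman bandwidth) and intervals are 95% **highest posterior
density** intervals (narrowest sorted window), the appropriate convention
for the skewed posteriors of variance and rate parameters. The KDE mode
of a boundary-peaked posterior overshoots the boundary by O(bandwidth);
this is inherent to the convention.

All derived series are computed inside each draw and summarized last:
growth rate `λ[t] = Ntot[t+1]/Ntot[t]`, immigration rate
`ω[t] = Nimm[t+1]/Ntot[t]`, geometric-mean growth
`(Ntot[end]/Ntot[start])^(1/steps)`. Correlations (drivers of growth,
density dependence, between-population synchrony) are Pearson across
years within each draw — Spearman available as an option — yielding a
posterior distribution of the coefficient; `P(r > 0)` at or beyond
0.975/0.025 is flagged significant. Draws with a zero `Ntot` denominator
are excluded and counted. Cross-population correlations pair draws by
retained-draw index and require equal retained counts; transition steps
are aligned on calendar years (the last census year begins no step, so a
13-year and a 20-year fit sharing 2002–2014 overlap on the 12 steps
2002–2013).

## The synthetic-data generator

Individual-based, one named RNG stream per demographic process
(reproduction, survival, immigration, detection, tag loss, sexing,
census), so single-process experiments are independently reproducible.
Each year: every female may add a second detected brood to the census
(default probability 0.1 — the census can overcount); each female is
detected with probability `p[t]`; detected mothers are identified (they
enter `R`) and their daughters are tagged in the nest (entering the
capture histories as juveniles, and `J` with weight 1, or 0.5 if
unsexed); daughters recruit with probability `φj[t]`; all ≥1-year-olds
survive with `φa[t]`; `Poisson(m[t])` immigrant females arrive untagged.
Tag loss (default 3% per interannual recapture, the rate measured in the
field data) splits an identity: the old id's history simply ends and the
animal re-enters as a newly tagged adult — estimation deliberately
ignores this, reproducing the study's small downward survival bias.

Defaults are the published-rate world: `φj = 0.15`, `φa = 0.45`,
`f = 1.13`, `p = 0.8`, `m = 4`/year, T = 20, initial stages (6, 16, 4).
Between-year SDs (0.3, 0.2, 0.3 logit; 0.05 log) are mid-range values of
the two populations' reported σ. The second-brood probability is a knob,
not a claim: the study reports no second-brood frequency.

What a green test does **not** establish: the generator draws all
processes at their stated rates with independent individuals — it does
not emulate spatial structure, nest-box saturation, observer effort
changes, breeder/non-breeder heterogeneity, or correlated detection
within families; recovery results certify the estimator under the model's
own assumptions plus the two deliberate violations (tag loss, second
broods).

## Behavior of latent immigration when none exists

Because realized immigrant counts are non-negative and each year's
expected count has a flat prior, the latent immigrant stage absorbs every
upward census surprise while downward surprises instead pull survival
down (the stage cannot go negative). In a population simulated *without*
immigration this produces a floor of roughly 2–3 spurious immigrants per
year at `Ntot ≈ 25` (ω ≈ 0.1–0.2) and an additional downward drag of
~0.03–0.04 on the survival hyper-means beyond the tag-loss effect. This
is a property of the model class, not of the sampler (verified by
init-independence and long chains). Two consequences for the shipped
checks:

* the **immigration-detection** scenario compares the published-rate
  world at its immigration-sustained stationary size (ω ≈ 0.38) against a
  demographically *self-sustaining* population of similar size without
  immigration — with the published rates a no-immigration population is
  extinct within a decade, leaving ω undefined;
* the **degenerate exactness** check (perfect detection, single broods,
  constant rates, no immigration) fits with the immigration prior forced
  to `{0}`, as its scenario states.

## Numerical details

* Half-open interval convention: `φ[t]` covers `t → t+1`; `p[t]` applies
  at occasion `t+1`; vectors of annual survival/recapture have length
  T−1, fecundity length T.
* `−inf` propagates from any off-support value (σ outside (0, 10),
  `m` outside its bounds, `Nad[t+1] > Ntot[t]`, a positive count with a
  zero-probability cell); the sampler rejects such proposals.
* A release on the final occasion carries no information and is dropped
  from the m-arrays.
* Years with `R[t] = 0` contribute nothing to the fecundity likelihood.
* Latent-state initialization splits the census 20/65/15% across stages
  and clips `Nad[t+1] ≤ Ntot[t]` so every chain starts on support.
* Seeds: a single user seed drives `numpy.random.SeedSequence`; per-chain
  kernel seeds are 31-bit values spawned from it; identical seeds
  reproduce draws exactly (tested byte-for-byte through the pipeline).

## Limitations

* Immigration estimates inherit the positive floor described above;
  interpret small estimated immigration rates against that baseline.
* The census observation model is Poisson only; the overdispersion
  introduced by second broods is absorbed partly by latent immigration.
  (A Normal observation alternative was considered and not implemented.)
* Males, robust-design within-year structure, spatially explicit
  dispersal, and formal two-mark tag-loss corrections are out of scope.
* The potential scale reduction threshold (1.1) is a screening heuristic;
  short exploratory chains can trip it on variance parameters whose
  posteriors pile near zero.
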