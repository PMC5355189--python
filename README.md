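# flypop

Integrated population modelling of nest-box monitoring data for the
Siberian flying squirrel (*Pteromys volans*) — and, more generally, for
any small-mammal study that combines an annual brood census, a
productivity table, and capture-recapture histories of individually
marked females.

Long-term nest-box studies observe three things about a female
population: how many broods were found each year (`y`), how many tagged
daughters (`J`) the identified reproductive females (`R`) produced, and
which marked females were re-encountered in which years. None of these
observes immigration. `flypop` fits the Bayesian state-space model that
links all three data streams and infers immigration as the demographic
rate the observed data cannot otherwise explain, then asks the downstream
questions: which rate drives the annual population growth rate, which
rates are density dependent, and whether two populations share dynamics.

## Model

Females are split into locally recruited one-year-olds `N1`, older
survivors `Nad`, and newly arrived immigrants `Nimm`
(`Ntot = N1 + Nad + Nimm`):

    N1[t+1]   ~ Poisson(Ntot[t] · f[t] · φj[t])      y[t] ~ Poisson(Ntot[t])
    Nad[t+1]  ~ Binomial(Ntot[t], φa[t])             J[t] ~ Poisson(R[t] · f[t])
    Nimm[t+1] ~ Poisson(m[t])                        + age-structured CJS m-array
                                                       likelihood for φj, φa, p

Apparent survival (`φ`) confounds death with emigration; `f` is daughters
per reproductive female; `m[t]` is the expected immigrant count, one free
parameter per year with a flat prior — its posterior is purely model
based. Annual rates vary on the logit/log scale around hyper-means with
estimated between-year SDs. Posteriors are summarized by kernel-density
mode and 95% highest-posterior-density interval. Derived quantities
(annual growth rate `λ[t] = Ntot[t+1]/Ntot[t]`, immigration rate
`ω[t] = Nimm[t+1]/Ntot[t]`, geometric-mean growth, and all posterior
correlations) are computed inside each draw. See `docs/methods.md` for
priors, the sampler, and known limitations.

The census and productivity tables of the two study populations (Vaasa
2002–2014, Luoto 1995–2014) ship with the package
(`flypop.datasets`). The capture histories behind the published survival
estimates were never released; `flypop.simulate` generates
individual-based data with known truth — including 3% tag loss, unsexed
offspring counted as half a daughter, and second broods — so every stage
of the pipeline is testable end to end.

## Worked example

Fecundity from the bundled Vaasa table:

```python
from flypop import datasets
from flypop.analysis import summarize
from flypop.fecundity import fit_fecundity, pooled_fecundity

table = datasets.load_productivity("vaasa")
print(f"pooled fecundity (sum J / sum R): {pooled_fecundity(table):.4f}")
draws = fit_fecundity(table, seed=1)
mode, lo, hi = summarize(draws.stacked("mu_f"))
print(f"posterior mode of mean fecundity: {mode:.3f}  95% HPD [{lo:.3f}, {hi:.3f}]")
```

```
pooled fecundity (sum J / sum R): 1.1325
posterior mode of mean fecundity: 1.125  95% HPD [0.990, 1.277]
```

Each identified Vaasa female produced about 1.13 tagged daughters per
year, essentially constant across years.

A full integrated fit on simulated data with known truth
(φj = 0.15, φa = 0.45, f = 1.13, p = 0.8, m = 4 immigrants/yr):

```python
import warnings
from flypop.simulate import SimulationConfig, simulate_population
from flypop.ipm import FitConfig, fit_ipm
from flypop.analysis import demographic_table, pgr_correlation_table

res = simulate_population(SimulationConfig(seed=42))
fit = fit_ipm(res.census, res.captures, res.productivity,
              FitConfig(chains=2, iterations=4000, burnin=1600, thin=3, seed=0))
print(demographic_table(fit).round(3).to_string(index=False))
print(pgr_correlation_table(fit).round(3).to_string(index=False))
```

```
        parameter  mode  hpd_low  hpd_high  sigma_mode  sigma_hpd_low  sigma_hpd_high
juvenile_survival 0.115    0.060     0.168       0.706          0.217           1.475
   adult_survival 0.419    0.343     0.536       0.632          0.159           1.205
        fecundity 1.206    0.994     1.377       0.169          0.024           0.339
     capture_prob 0.893    0.791     0.997       0.539          0.092           2.850
           gm_pgr 0.980    0.955     1.008         NaN            NaN             NaN

        parameter  correlation  hpd_low  hpd_high  p_positive  significant
juvenile_survival        0.274   -0.184     0.602       0.878        False
   adult_survival        0.482    0.031     0.754       0.974        False
        fecundity        0.035   -0.386     0.500       0.581        False
 immigration_rate        0.918    0.675     0.982       1.000         True
```

All four hyper-mean HPDs cover their true values; the geometric-mean
growth rate sits just below 1 (a population kept afloat by immigrants);
and the correlation analysis singles out the immigration rate as the only
significant driver of annual growth — the signature this model class was
built to detect.

## Command line

```sh
flypop simulate  --config scenario.yaml --out data/        # synthetic data + truth
flypop fit       --census data/census.csv --captures data/captures.csv \
                 --productivity data/productivity.csv --out draws.csv --seed 1
flypop summarize --draws draws.csv --out table2.csv
flypop correlate --draws draws.csv --mode pgr|density --out table3.csv
flypop run-all   --config pipeline.yaml --out run/         # two populations,
                                                           # all report tables
```

`run-all` writes a deterministic layout (`data/`, `draws/`, `tables/`,
`run.log` with seeds and convergence diagnostics); reruns with the same
config are byte-identical.

## Acceptance script

`scripts/acceptance.py` refits the hierarchical fecundity model from
scratch to the bundled productivity tables of both populations and writes
the posterior mode of mean fecundity (with its 95% HPD and the pooled
closed-form ratio) for each to a JSON file:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
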