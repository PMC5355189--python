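"""Joint state-space model with latent immigration, and its MCMC sampler.

The female population is split into three latent stages: locally recruited
one-year-olds ``N1``, older surviving females ``Nad``, and newly arrived
immigrants ``Nimm``.  The state process is

* ``N1[t+1]  ~ Poisson(Ntot[t] * f[t] * phi_j[t])``
* ``Nad[t+1] ~ Binomial(Ntot[t], phi_a[t])``
* ``Nimm[t+1] ~ Poisson(m[t])``

with the census observed as ``y[t] ~ Poisson(Ntot[t])``.  The expected
immigrant count ``m[t]`` has one free parameter per year with a flat prior
on [0, 30]: immigration is never observed directly, so its posterior is
driven entirely by the gap between the census and what survival plus local
recruitment can explain.  The capture-recapture and productivity
likelihoods (:mod:`flypop.cjs`, :mod:`flypop.fecundity`) share the annual
survival and fecundity parameters, which is what makes the model
"integrated".

Three data likelihoods are treated as independent given the parameters,
the standard IPM assumption (the same animals contribute to more than one
data stream, but the induced dependence is known to be benign at these
sample sizes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, logit

from . import _kernel
from .cjs import SurvivalParams, cjs_loglik
from .data import (
    CaptureData,
    CensusSeries,
    DemographicParams,
    LatentStates,
    MArraySet,
    PosteriorDraws,
    ProductivityTable,
    ValidationError,
    build_marrays,
)
from .fecundity import fecundity_loglik, pooled_fecundity

__all__ = [
    "ImmigrationParams",
    "PriorConfig",
    "FitConfig",
    "ConvergenceWarning",
    "state_process_loglik",
    "census_loglik",
    "joint_log_posterior",
    "fit_ipm",
]


class ConvergenceWarning(UserWarning):
    """Emitted when the potential scale reduction exceeds its threshold."""


@dataclass
class ImmigrationParams:
    """Expected number of immigrant females entering at each year t+1."""

    m: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.atleast_1d(np.asarray(self.m, dtype=float))
        if np.any(self.m < 0):
            raise ValidationError("expected immigrant counts must be >= 0")


@dataclass
class PriorConfig:
    """Hyper-prior settings; defaults are the vague standard choices.

    ``m_bounds`` is the flat-prior support for each annual expected
    immigrant count.  The published analysis used a uniform prior that
    extended below zero as a sampler device; counts cannot be negative, so
    the support here starts at 0 (set ``m_bounds=(0, 0)`` to disable
    immigration entirely).
    """

    m_bounds: tuple[float, float] = (0.0, 30.0)
    sigma_upper: float = 10.0
    muf_prior_sd: float = 10.0
    init_mean: float = 10.0
    init_sd: float = 100.0

    def __post_init__(self) -> None:
        lo, hi = self.m_bounds
        if lo < 0 or hi < lo:
            raise ValidationError("m_bounds must satisfy 0 <= lo <= hi")


@dataclass
class FitConfig:
    """MCMC settings; defaults follow the long-run reference configuration."""

    chains: int = 3
    iterations: int = 50_000
    burnin: int | None = None
    thin: int = 10
    seed: int | None = None
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValidationError("need at least 2 chains")
        self.burnin = (self.iterations // 2 if self.burnin is None
                       else self.burnin)
        if not 0 < self.burnin < self.iterations:
            raise ValidationError("burnin must lie in (0, iterations)")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")


def _poisson_logpmf(k, lam) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    lam = np.asarray(lam, dtype=float)
    out = np.where(lam > 0,
                   k * np.log(np.where(lam > 0, lam, 1.0)) - lam
                   - gammaln(k + 1.0),
                   np.where(k == 0, 0.0, -np.inf))
    return out


def state_process_loglik(states: LatentStates, params: DemographicParams,
                         imm: ImmigrationParams) -> float:
    """Log-density of a latent trajectory under the stage process."""
    T = states.n_years
    if len(imm.m) != T - 1:
        raise ValidationError("imm.m must have length T-1")
    phi_j = params.phi_j(T - 1)
    phi_a = params.phi_a(T - 1)
    f = params.f(T)
    ntot = states.Ntot.astype(float)
    lp = float(np.sum(_poisson_logpmf(states.N1[1:], ntot[:-1] * f[:-1]
                                      * phi_j)))
    # binomial survival of all >= 1-year-olds
    k = states.Nad[1:]
    n = states.Ntot[:-1]
    if np.any(k > n):
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        binom = (gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)
                 + k * np.log(phi_a) + (n - k) * np.log1p(-phi_a))
    bad = (phi_a <= 0) | (phi_a >= 1)
    if np.any(bad):
        binom = np.where(bad & (phi_a <= 0), np.where(k == 0, 0.0, -np.inf),
                         binom)
        binom = np.where(bad & (phi_a >= 1), np.where(k == n, 0.0, -np.inf),
                         binom)
    lp += float(np.sum(binom))
    lp += float(np.sum(_poisson_logpmf(states.Nimm[1:], imm.m)))
    return lp


def census_loglik(census: CensusSeries, states: LatentStates) -> float:
    """Poisson observation model: y[t] ~ Poisson(Ntot[t])."""
    if census.n_years != states.n_years:
        raise ValidationError(
            f"census spans {census.n_years} years, states {states.n_years}")
    return float(np.sum(_poisson_logpmf(census.y, states.Ntot)))


def _log_prior(params: DemographicParams, states: LatentStates,
               imm: ImmigrationParams, priors: PriorConfig, T: int) -> float:
    sig = np.array([params.sigma_phi_j, params.sigma_phi_a, params.sigma_p,
                    params.sigma_f])
    if np.any(sig <= 0) or np.any(sig >= priors.sigma_upper):
        return -np.inf
    lo, hi = priors.m_bounds
    if np.any(imm.m < lo) or np.any(imm.m > hi):
        return -np.inf
    lp = 0.0
    for mu in (params.mu_phi_j, params.mu_phi_a, params.mu_p):
        if not 0.0 < mu < 1.0:
            return -np.inf
        lp += np.log(mu) + np.log1p(-mu)
    lmu_f = np.log(params.mu_f)
    lp += -(lmu_f ** 2) / (2.0 * priors.muf_prior_sd ** 2)
    for eps, s, n in ((params.eps_phi_j, sig[0], T - 1),
                      (params.eps_phi_a, sig[1], T - 1),
                      (params.eps_p, sig[2], T - 1),
                      (params.eps_f, sig[3], T)):
        e = np.zeros(n) if eps is None else np.asarray(eps, dtype=float)
        lp += float(-np.sum(e ** 2) / (2.0 * s ** 2) - n * np.log(s))
    for n0 in (states.N1[0], states.Nad[0], states.Nimm[0]):
        lp += -((n0 - priors.init_mean) ** 2) / (2.0 * priors.init_sd ** 2)
    return float(lp)


def joint_log_posterior(census: CensusSeries, marrays: MArraySet,
                        productivity: ProductivityTable,
                        params: DemographicParams, states: LatentStates,
                        imm: ImmigrationParams,
                        priors: PriorConfig | None = None) -> float:
    """Unnormalized joint log-posterior of the integrated model.

    The sum of the state-process, census, capture-recapture, and
    productivity log-likelihoods plus the log-priors (up to constants not
    involving parameters).  Propagates ``-inf`` for any off-support value.
    """
    priors = priors or PriorConfig()
    T = census.n_years
    prior_lp = _log_prior(params, states, imm, priors, T)
    if prior_lp == -np.inf:
        return -np.inf
    lp = prior_lp
    lp += state_process_loglik(states, params, imm)
    lp += census_loglik(census, states)
    lp += fecundity_loglik(productivity, params.f(T))
    sp = SurvivalParams(phi_j=params.phi_j(T - 1),
                        phi_a=params.phi_a(T - 1), p=params.p(T - 1))
    lp += cjs_loglik(marrays, sp)
    return float(lp)


# ---------------------------------------------------------------------------
# fitting


def _initial_states(y: np.ndarray, rng: np.random.Generator,
                    no_immigration: bool) -> np.ndarray:
    """Feasible starting trajectory: census-sized, binomially consistent."""
    T = len(y)
    N = np.zeros((3, T), dtype=np.int64)
    ntot_prev = 0
    for t in range(T):
        tot = max(int(y[t]), 1) + int(rng.integers(0, 3))
        n1 = max(1, int(round(0.2 * tot)))
        nim = 0 if no_immigration else max(1, int(round(0.15 * tot)))
        nad = max(tot - n1 - nim, 0)
        if t > 0:
            nad = min(nad, ntot_prev)  # binomial support
        N[0, t], N[1, t], N[2, t] = n1, nad, nim
        ntot_prev = n1 + nad + nim
    return N


def fit_ipm(census: CensusSeries, captures: CaptureData | MArraySet,
            productivity: ProductivityTable,
            config: FitConfig | None = None,
            priors: PriorConfig | None = None) -> PosteriorDraws:
    """Sample the joint posterior of the integrated population model.

    ``captures`` may be raw capture histories (reduced to m-arrays here) or
    a prebuilt :class:`MArraySet`.  All data must cover the same span of
    years.  Returns draws of the hyper-parameters, annual rates, expected
    immigrant counts, and latent stage trajectories, with the potential
    scale reduction factor of every hyper-parameter recorded in ``meta``;
    a :class:`ConvergenceWarning` is raised if any exceeds the threshold.
    """
    config = config or FitConfig()
    priors = priors or PriorConfig()
    T = census.n_years
    if productivity.n_years != T or not np.array_equal(productivity.years,
                                                       census.years):
        raise ValidationError("census and productivity must share years")
    if isinstance(captures, MArraySet):
        marrays = captures
    else:
        if not np.array_equal(captures.years, census.years):
            raise ValidationError("captures and census must share years")
        marrays = build_marrays(captures)
    if marrays.n_occasions != T:
        raise ValidationError("m-arrays must span the census years")

    y = census.y.astype(np.int64)
    Jv = productivity.J.astype(float)
    Rv = productivity.R.astype(np.int64)
    mj = marrays.marray_juv.astype(np.int64)
    ma = marrays.marray_ad.astype(np.int64)
    m_lo, m_hi = priors.m_bounds
    no_imm = m_hi <= m_lo

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.generate_state(config.chains, dtype=np.uint32) % (2**31)
    rng = np.random.default_rng(ss.spawn(1)[0])
    f0 = max(pooled_fecundity(productivity), 0.05) if Rv.sum() > 0 else 1.0

    results = []
    for c in range(config.chains):
        lmu = np.array([
            logit(np.clip(0.2 + rng.normal(0, 0.05), 0.02, 0.9)),
            logit(np.clip(0.45 + rng.normal(0, 0.05), 0.05, 0.95)),
            logit(np.clip(0.7 + rng.normal(0, 0.05), 0.1, 0.97)),
            np.log(f0) + rng.normal(0, 0.1),
        ])
        sig = rng.uniform(0.05, 0.4, 4)
        epsj = np.zeros(T - 1)
        epsa = np.zeros(T - 1)
        epsp = np.zeros(T - 1)
        epsf = np.zeros(T)
        m0 = np.zeros(T - 1) if no_imm else np.clip(
            rng.uniform(2.0, 6.0, T - 1), m_lo + 1e-6, m_hi)
        N0 = _initial_states(y, rng, no_imm)
        lp0 = _kernel.joint_logpost(
            y, Jv, Rv, mj, ma, lmu, sig, epsj, epsa, epsp, epsf, m0, N0,
            m_lo, m_hi, priors.sigma_upper, priors.muf_prior_sd,
            priors.init_mean, priors.init_sd)
        if not np.isfinite(lp0):
            raise RuntimeError("infeasible initial state; data inconsistent")
        out = _kernel.run_chain(
            int(chain_seeds[c]), config.iterations, config.burnin,
            config.thin, y, Jv, Rv, mj, ma,
            lmu, sig, epsj, epsa, epsp, epsf, m0, N0,
            m_lo, m_hi, priors.sigma_upper, priors.muf_prior_sd,
            priors.init_mean, priors.init_sd)
        results.append(out)

    def stack(i):
        return np.stack([r[i] for r in results])

    lmu_d = stack(0)
    sig_d = stack(1)
    epsj_d, epsa_d, epsp_d, epsf_d = (stack(i) for i in range(2, 6))
    m_d = stack(6)
    N_d = stack(7)
    lp_d = stack(8)

    params: dict[str, np.ndarray] = {
        "mu_phi_j": expit(lmu_d[:, :, 0]),
        "mu_phi_a": expit(lmu_d[:, :, 1]),
        "mu_p": expit(lmu_d[:, :, 2]),
        "mu_f": np.exp(lmu_d[:, :, 3]),
        "sigma_phi_j": sig_d[:, :, 0],
        "sigma_phi_a": sig_d[:, :, 1],
        "sigma_p": sig_d[:, :, 2],
        "sigma_f": sig_d[:, :, 3],
        "phi_j": expit(lmu_d[:, :, 0:1] + epsj_d),
        "phi_a": expit(lmu_d[:, :, 1:2] + epsa_d),
        "p_annual": expit(lmu_d[:, :, 2:3] + epsp_d),
        "f": np.exp(lmu_d[:, :, 3:4] + epsf_d),
        "m": m_d,
        "N1": N_d[:, :, 0, :],
        "Nad": N_d[:, :, 1, :],
        "Nimm": N_d[:, :, 2, :],
        "Ntot": N_d.sum(axis=2),
        "log_posterior": lp_d,
    }

    rhat = _rhat_scalars(params)
    bad = {k: float(v) for k, v in rhat.items()
           if np.isfinite(v) and v > config.rhat_threshold}
    if bad:
        warnings.warn(
            "potential scale reduction above "
            f"{config.rhat_threshold} for: "
            + ", ".join(f"{k}={v:.3f}" for k, v in sorted(bad.items())),
            ConvergenceWarning, stacklevel=2)

    return PosteriorDraws(
        params,
        seed=config.seed,
        meta={
            "model": "ipm",
            "years": census.years.tolist(),
            "population_id": census.population_id,
            "rhat": {k: float(v) for k, v in rhat.items()},
            "config": {"chains": config.chains,
                       "iterations": config.iterations,
                       "burnin": config.burnin, "thin": config.thin},
            "m_bounds": list(priors.m_bounds),
        },
    )


_RHAT_PARAMS = ("mu_phi_j", "mu_phi_a", "mu_p", "mu_f",
                "sigma_phi_j", "sigma_phi_a", "sigma_p", "sigma_f")


def _rhat_scalars(params: dict[str, np.ndarray]) -> dict[str, float]:
    import arviz as az

    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in _RHAT_PARAMS:
            out[name] = float(az.rhat(
                az.convert_to_dataset({name: params[name]}))[name].values)
    return out
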