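"""Hierarchical Poisson model of annual fecundity.

Tagged daughters ``J[t]`` produced by ``R[t]`` identified reproductive
females follow ``J[t] ~ Poisson(R[t] * f[t])`` with lognormal annual
variation ``log f[t] = mu + eps[t]``, ``eps[t] ~ Normal(0, sigma^2)``.
Because unsexed offspring count 0.5 daughter, ``J`` can be half-integer;
the Poisson log-density is evaluated through its continuous gamma-function
extension, which preserves the printed data exactly and perturbs the
likelihood negligibly.

Priors: ``mu ~ Normal(0, 10^2)`` on the log scale and ``sigma ~
Uniform(0, 10)`` — the usual vague choices for this model family.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit
from scipy.special import gammaln

from .data import PosteriorDraws, ProductivityTable, ValidationError

__all__ = ["fecundity_loglik", "pooled_fecundity", "fit_fecundity"]


def fecundity_loglik(table: ProductivityTable, f: np.ndarray) -> float:
    """Log-likelihood of per-year fecundities ``f`` given the table.

    Years with ``R[t] = 0`` carry no information and contribute zero.
    """
    f = np.atleast_1d(np.asarray(f, dtype=float))
    if len(f) == 1:
        f = np.full(table.n_years, f[0])
    if len(f) != table.n_years:
        raise ValidationError("f must be scalar or one value per year")
    active = table.R > 0
    if np.any(f[active] <= 0):
        if np.any(table.J[active][f[active] <= 0] > 0):
            return -np.inf
        # f == 0 with J == 0 is a degenerate point mass
        zero = active & (f <= 0)
        active = active & (f > 0)
        if np.any(table.J[zero] > 0):  # pragma: no cover - caught above
            return -np.inf
    lam = table.R[active] * f[active]
    J = table.J[active]
    return float(np.sum(J * np.log(lam) - lam - gammaln(J + 1.0)))


def pooled_fecundity(table: ProductivityTable) -> float:
    """Closed-form constant-fecundity MLE: total daughters per total mothers."""
    total_R = int(table.R.sum())
    if total_R == 0:
        raise ValidationError("no reproductive females in table")
    return float(table.J.sum() / total_R)


@njit(cache=True)
def _fec_loglik_year(J, R, mu, eps_t, t):  # pragma: no cover - jitted
    if R[t] == 0:
        return 0.0
    lam = R[t] * math.exp(mu + eps_t)
    return J[t] * math.log(lam) - lam - math.lgamma(J[t] + 1.0)


@njit(cache=True)
def _fec_chain(seed, n_iter, n_burn, thin, J, R,
               mu0, sigma0, prior_mu_sd, sigma_hi
               ):  # pragma: no cover - jitted
    np.random.seed(seed)
    T = J.shape[0]
    mu = mu0
    sigma = sigma0
    eps = np.zeros(T)

    # current per-year likelihood terms
    ll_year = np.empty(T)
    for t in range(T):
        ll_year[t] = _fec_loglik_year(J, R, mu, eps[t], t)

    n_save = (n_iter - n_burn) // thin
    out_mu = np.empty(n_save)
    out_sigma = np.empty(n_save)
    out_eps = np.empty((n_save, T))

    s_mu, s_sigma, s_eps = 0.1, 0.1, 0.2
    acc = np.zeros(3)
    tries = np.zeros(3)
    saved = 0
    for it in range(n_iter):
        # mu: affects every year term plus its own prior
        prop = mu + np.random.normal() * s_mu
        new_terms = np.empty(T)
        delta = (mu * mu - prop * prop) / (2.0 * prior_mu_sd * prior_mu_sd)
        for t in range(T):
            new_terms[t] = _fec_loglik_year(J, R, prop, eps[t], t)
            delta += new_terms[t] - ll_year[t]
        tries[0] += 1
        if math.log(np.random.random()) < delta:
            mu = prop
            ll_year = new_terms
            acc[0] += 1

        # sigma: only the eps prior changes
        prop = sigma + np.random.normal() * s_sigma
        tries[1] += 1
        if 0.0 < prop < sigma_hi:
            sse = 0.0
            for t in range(T):
                sse += eps[t] * eps[t]
            delta = (T * (math.log(sigma) - math.log(prop))
                     + sse / 2.0 * (1.0 / (sigma * sigma)
                                    - 1.0 / (prop * prop)))
            if math.log(np.random.random()) < delta:
                sigma = prop
                acc[1] += 1

        # annual effects
        for t in range(T):
            prop = eps[t] + np.random.normal() * s_eps
            new_t = _fec_loglik_year(J, R, mu, prop, t)
            delta = (new_t - ll_year[t]
                     + (eps[t] * eps[t] - prop * prop)
                     / (2.0 * sigma * sigma))
            tries[2] += 1
            if math.log(np.random.random()) < delta:
                eps[t] = prop
                ll_year[t] = new_t
                acc[2] += 1

        # diminishing adaptation toward ~40% acceptance during burn-in
        if it < n_burn and (it + 1) % 50 == 0:
            step = min(0.1, 5.0 / math.sqrt(it + 1.0))
            if acc[0] / tries[0] > 0.44:
                s_mu *= math.exp(step)
            else:
                s_mu *= math.exp(-step)
            if acc[1] / tries[1] > 0.44:
                s_sigma *= math.exp(step)
            else:
                s_sigma *= math.exp(-step)
            if acc[2] / tries[2] > 0.44:
                s_eps *= math.exp(step)
            else:
                s_eps *= math.exp(-step)
            acc[:] = 0.0
            tries[:] = 0.0

        if it >= n_burn and (it - n_burn) % thin == 0 and saved < n_save:
            out_mu[saved] = mu
            out_sigma[saved] = sigma
            out_eps[saved] = eps
            saved += 1

    return out_mu, out_sigma, out_eps


def fit_fecundity(table: ProductivityTable, chains: int = 3,
                  iterations: int = 12000, burnin: int | None = None,
                  thin: int = 4, seed: int | None = None) -> PosteriorDraws:
    """Sample the hierarchical fecundity posterior by adaptive MCMC.

    Returns draws of the mean fecundity ``mu_f = exp(mu)``, the log-scale
    between-year SD ``sigma_f``, and the annual fecundities ``f[t]``.
    """
    if chains < 2:
        raise ValidationError("need at least 2 chains")
    burnin = iterations // 2 if burnin is None else burnin
    if burnin >= iterations:
        raise ValidationError("burnin must be smaller than iterations")
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.generate_state(chains, dtype=np.uint32) % (2 ** 31)
    rng = np.random.default_rng(ss.spawn(1)[0])

    J = np.asarray(table.J, dtype=float)
    R = np.asarray(table.R, dtype=np.int64)
    if np.all(R == 0):
        raise ValidationError("no reproductive females: nothing to fit")
    mu_start = np.log(max(pooled_fecundity(table), 1e-3))

    mus, sigmas, epss = [], [], []
    for c in range(chains):
        mu0 = mu_start + rng.normal(0.0, 0.2)
        sigma0 = float(rng.uniform(0.05, 0.5))
        out_mu, out_sigma, out_eps = _fec_chain(
            int(chain_seeds[c]), iterations, burnin, thin, J, R,
            mu0, sigma0, 10.0, 10.0)
        mus.append(out_mu)
        sigmas.append(out_sigma)
        epss.append(out_eps)

    mu = np.stack(mus)
    sigma = np.stack(sigmas)
    eps = np.stack(epss)
    draws = PosteriorDraws(
        {
            "mu_f": np.exp(mu),
            "log_mu_f": mu,
            "sigma_f": sigma,
            "f": np.exp(mu[:, :, None] + eps),
        },
        seed=seed,
        meta={"model": "fecundity", "iterations": iterations,
              "burnin": burnin, "thin": thin},
    )
    return draws
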