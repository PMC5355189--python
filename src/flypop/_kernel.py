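"""Numba kernels for the integrated-model posterior and its MCMC sampler.

Everything here works on plain arrays; :mod:`flypop.ipm` owns the public
typed interface and re-derives the same joint posterior from the individual
likelihood components, which the tests compare against ``joint_logpost``
term for term.

Parameter layout for one chain:

* ``lmu[4]``   — logit(mean juvenile survival), logit(mean adult survival),
  logit(mean capture probability), log(mean fecundity)
* ``sig[4]``   — between-year SDs on the same transformed scales
* ``epsj, epsa, epsp`` (length T-1) and ``epsf`` (length T) — annual effects
* ``m[T-1]``   — expected immigrant count entering in year t+1
* ``N[3, T]``  — integer latent stages (recruits, adults, immigrants)

Priors (up to additive constants): Uniform(0,1) on each mean probability
(logistic density on the logit scale), Normal(0, muf_sd^2) on log mean
fecundity, Uniform(0, sigma_hi) on SDs, Uniform(m_lo, m_hi) on each m[t],
and positive-truncated Normal(init_mean, init_sd^2) on initial stage sizes.
"""

import math

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def _expit(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


@njit(cache=True)
def poisson_logpmf(k, lam):
    if lam <= 0.0:
        return 0.0 if k == 0 else NEG_INF
    return k * math.log(lam) - lam - math.lgamma(k + 1.0)


@njit(cache=True)
def binomial_logpmf(k, n, q):
    if k < 0 or k > n or n < 0:
        return NEG_INF
    if q <= 0.0:
        return 0.0 if k == 0 else NEG_INF
    if q >= 1.0:
        return 0.0 if k == n else NEG_INF
    return (math.lgamma(n + 1.0) - math.lgamma(k + 1.0)
            - math.lgamma(n - k + 1.0)
            + k * math.log(q) + (n - k) * math.log(1.0 - q))


@njit(cache=True)
def cjs_loglik_arrays(mj, ma, phi_j, phi_a, p):
    """Joint m-array log-likelihood (no multinomial coefficient)."""
    K = mj.shape[0] + 1
    total = 0.0
    for age in range(2):
        for i in range(K - 1):
            if age == 0:
                alive = phi_j[i]
            else:
                alive = phi_a[i]
            rowsum = 0.0
            for j in range(i, K - 1):
                cell = alive * p[j]
                c = mj[i, j] if age == 0 else ma[i, j]
                if c > 0:
                    if cell <= 0.0:
                        return NEG_INF
                    total += c * math.log(cell)
                rowsum += cell
                alive *= (1.0 - p[j])
                if j + 1 < K - 1:
                    alive *= phi_a[j + 1]
            c = mj[i, K - 1] if age == 0 else ma[i, K - 1]
            if c > 0:
                never = 1.0 - rowsum
                if never <= 0.0:
                    return NEG_INF
                total += c * math.log(never)
    return total


@njit(cache=True)
def joint_logpost(y, J, R, mj, ma,
                  lmu, sig, epsj, epsa, epsp, epsf, m, N,
                  m_lo, m_hi, sigma_hi, muf_sd, init_mean, init_sd):
    T = y.shape[0]
    # support checks
    for b in range(4):
        if sig[b] <= 0.0 or sig[b] >= sigma_hi:
            return NEG_INF
    for t in range(T - 1):
        if m[t] < m_lo or m[t] > m_hi:
            return NEG_INF
    for t in range(T):
        for s in range(3):
            if N[s, t] < 0:
                return NEG_INF

    # annual rates
    phi_j = np.empty(T - 1)
    phi_a = np.empty(T - 1)
    p = np.empty(T - 1)
    f = np.empty(T)
    for t in range(T - 1):
        phi_j[t] = _expit(lmu[0] + epsj[t])
        phi_a[t] = _expit(lmu[1] + epsa[t])
        p[t] = _expit(lmu[2] + epsp[t])
    for t in range(T):
        f[t] = math.exp(lmu[3] + epsf[t])

    lp = 0.0
    # hyper-mean priors: Uniform(0,1) on the probability scale
    for b in range(3):
        q = _expit(lmu[b])
        if q <= 0.0 or q >= 1.0:
            return NEG_INF
        lp += math.log(q) + math.log(1.0 - q)
    lp += -(lmu[3] * lmu[3]) / (2.0 * muf_sd * muf_sd)

    # annual-effect priors
    for t in range(T - 1):
        lp += -(epsj[t] * epsj[t]) / (2.0 * sig[0] * sig[0])
        lp += -(epsa[t] * epsa[t]) / (2.0 * sig[1] * sig[1])
        lp += -(epsp[t] * epsp[t]) / (2.0 * sig[2] * sig[2])
    for t in range(T):
        lp += -(epsf[t] * epsf[t]) / (2.0 * sig[3] * sig[3])
    lp += -(T - 1) * (math.log(sig[0]) + math.log(sig[1])
                      + math.log(sig[2]))
    lp += -T * math.log(sig[3])

    # initial stage sizes: positive-truncated normal kernel
    for s in range(3):
        d = N[s, 0] - init_mean
        lp += -(d * d) / (2.0 * init_sd * init_sd)

    # census observation: y[t] ~ Poisson(Ntot[t])
    for t in range(T):
        ntot = N[0, t] + N[1, t] + N[2, t]
        v = poisson_logpmf(y[t], float(ntot))
        if v == NEG_INF:
            return NEG_INF
        lp += v

    # state process
    for t in range(T - 1):
        ntot = N[0, t] + N[1, t] + N[2, t]
        v = poisson_logpmf(N[0, t + 1], ntot * f[t] * phi_j[t])
        if v == NEG_INF:
            return NEG_INF
        lp += v
        v = binomial_logpmf(N[1, t + 1], ntot, phi_a[t])
        if v == NEG_INF:
            return NEG_INF
        lp += v
        v = poisson_logpmf(N[2, t + 1], m[t])
        if v == NEG_INF:
            return NEG_INF
        lp += v

    # productivity: J[t] ~ Poisson(R[t] f[t]), gamma-extended for half counts
    for t in range(T):
        if R[t] > 0:
            lam = R[t] * f[t]
            lp += J[t] * math.log(lam) - lam - math.lgamma(J[t] + 1.0)

    # capture-recapture
    v = cjs_loglik_arrays(mj, ma, phi_j, phi_a, p)
    if v == NEG_INF:
        return NEG_INF
    return lp + v


@njit(cache=True)
def run_chain(seed, n_iter, n_burn, thin,
              y, J, R, mj, ma,
              lmu, sig, epsj, epsa, epsp, epsf, m, N,
              m_lo, m_hi, sigma_hi, muf_sd, init_mean, init_sd):
    """Adaptive Metropolis-within-Gibbs chain; mutates the state in place.

    Continuous parameters move by scalar random-walk Metropolis with
    diminishing scale adaptation during burn-in; each m[t] is drawn exactly
    from its truncated-gamma full conditional; latent stage sizes move on
    integer neighborhoods (steps of 1 or 2) plus a stage-swap move that
    preserves the year total.
    """
    np.random.seed(seed)
    T = y.shape[0]
    n_save = (n_iter - n_burn) // thin

    out_lmu = np.empty((n_save, 4))
    out_sig = np.empty((n_save, 4))
    out_epsj = np.empty((n_save, T - 1))
    out_epsa = np.empty((n_save, T - 1))
    out_epsp = np.empty((n_save, T - 1))
    out_epsf = np.empty((n_save, T))
    out_m = np.empty((n_save, T - 1))
    out_N = np.empty((n_save, 3, T), np.int64)
    out_lp = np.empty(n_save)

    # proposal scales: 4 hyper-means, 4 SDs, 4 annual-effect families
    scales = np.full(12, 0.1)
    scales[8:] = 0.2
    acc = np.zeros(12)
    tries = np.zeros(12)

    lp = joint_logpost(y, J, R, mj, ma, lmu, sig, epsj, epsa, epsp, epsf,
                       m, N, m_lo, m_hi, sigma_hi, muf_sd, init_mean,
                       init_sd)
    saved = 0
    for it in range(n_iter):
        # --- hyper-means and SDs -------------------------------------
        for b in range(4):
            old = lmu[b]
            lmu[b] = old + np.random.normal() * scales[b]
            lp_new = joint_logpost(y, J, R, mj, ma, lmu, sig, epsj, epsa,
                                   epsp, epsf, m, N, m_lo, m_hi, sigma_hi,
                                   muf_sd, init_mean, init_sd)
            tries[b] += 1
            if math.log(np.random.random()) < lp_new - lp:
                lp = lp_new
                acc[b] += 1
            else:
                lmu[b] = old
        for b in range(4):
            old = sig[b]
            sig[b] = old + np.random.normal() * scales[4 + b]
            lp_new = joint_logpost(y, J, R, mj, ma, lmu, sig, epsj, epsa,
                                   epsp, epsf, m, N, m_lo, m_hi, sigma_hi,
                                   muf_sd, init_mean, init_sd)
            tries[4 + b] += 1
            if math.log(np.random.random()) < lp_new - lp:
                lp = lp_new
                acc[4 + b] += 1
            else:
                sig[b] = old

        # --- annual effects ------------------------------------------
        for t in range(T - 1):
            old = epsj[t]
            epsj[t] = old + np.random.normal() * scales[8]
            lp_new = joint_logpost(y, J, R, mj, ma, lmu, sig, epsj, epsa,
                                   epsp, epsf, m, N, m_lo, m_hi, sigma_hi,
                                   muf_sd, init_mean, init_sd)
            tries[8] += 1
            if math.log(np.random.random()) < lp_new - lp:
                lp = lp_new
                acc[8] += 1
            else:
                epsj[t] = old
        for t in range(T - 1):
            old = epsa[t]
            epsa[t] = old + np.random.normal() * scales[9]
            lp_new = joint_logpost(y, J, R, mj, ma, lmu, sig, epsj, epsa,
                                   epsp, epsf, m, N, m_lo, m_hi, sigma_hi,
                                   muf_sd, init_mean, init_sd)
            tries[9] += 1
            if math.log(np.random.random()) < lp_new - lp:
                lp = lp_new
                acc[9] += 1
            else:
                epsa[t] = old
        for t in range(T - 1):
            old = epsp[t]
            epsp[t] = old + np.random.normal() * scales[10]
            lp_new = joint_logpost(y, J, R, mj, ma, lmu, sig, epsj, epsa,
                                   epsp, epsf, m, N, m_lo, m_hi, sigma_hi,
                                   muf_sd, init_mean, init_sd)
            tries[10] += 1
            if math.log(np.random.random()) < lp_new - lp:
                lp = lp_new
                acc[10] += 1
            else:
                epsp[t] = old
        for t in range(T):
            old = epsf[t]
            epsf[t] = old + np.random.normal() * scales[11]
            lp_new = joint_logpost(y, J, R, mj, ma, lmu, sig, epsj, epsa,
                                   epsp, epsf, m, N, m_lo, m_hi, sigma_hi,
                                   muf_sd, init_mean, init_sd)
            tries[11] += 1
            if math.log(np.random.random()) < lp_new - lp:
                lp = lp_new
                acc[11] += 1
            else:
                epsf[t] = old

        # --- expected immigrant counts: truncated-gamma Gibbs ---------
        if m_hi > m_lo:
            for t in range(T - 1):
                k = N[2, t + 1]
                old = m[t]
                for _ in range(100):
                    prop = np.random.gamma(k + 1.0, 1.0)
                    if m_lo <= prop <= m_hi:
                        m[t] = prop
                        lp += (poisson_logpmf(k, prop)
                               - poisson_logpmf(k, old))
                        break

        # --- latent stage sizes ---------------------------------------
        for t in range(T):
            for s in range(3):
                step = 1 if np.random.random() < 0.7 else 2
                if np.random.random() < 0.5:
                    step = -step
                old = N[s, t]
                if old + step < 0:
                    continue
                N[s, t] = old + step
                lp_new = joint_logpost(y, J, R, mj, ma, lmu, sig, epsj,
                                       epsa, epsp, epsf, m, N, m_lo, m_hi,
                                       sigma_hi, muf_sd, init_mean, init_sd)
                if math.log(np.random.random()) < lp_new - lp:
                    lp = lp_new
                else:
                    N[s, t] = old
            # swap one individual between stages, preserving the total
            a = np.random.randint(0, 3)
            b = np.random.randint(0, 3)
            if a != b and N[a, t] > 0:
                N[a, t] -= 1
                N[b, t] += 1
                lp_new = joint_logpost(y, J, R, mj, ma, lmu, sig, epsj,
                                       epsa, epsp, epsf, m, N, m_lo, m_hi,
                                       sigma_hi, muf_sd, init_mean, init_sd)
                if math.log(np.random.random()) < lp_new - lp:
                    lp = lp_new
                else:
                    N[a, t] += 1
                    N[b, t] -= 1

        # --- adaptation ------------------------------------------------
        if it < n_burn and (it + 1) % 50 == 0:
            step = min(0.1, 5.0 / math.sqrt(it + 1.0))
            for b in range(12):
                if tries[b] > 0:
                    if acc[b] / tries[b] > 0.44:
                        scales[b] *= math.exp(step)
                    else:
                        scales[b] *= math.exp(-step)
            acc[:] = 0.0
            tries[:] = 0.0

        if it >= n_burn and (it - n_burn) % thin == 0 and saved < n_save:
            out_lmu[saved] = lmu
            out_sig[saved] = sig
            out_epsj[saved] = epsj
            out_epsa[saved] = epsa
            out_epsp[saved] = epsp
            out_epsf[saved] = epsf
            out_m[saved] = m
            out_N[saved] = N
            out_lp[saved] = lp
            saved += 1

    return (out_lmu, out_sig, out_epsj, out_epsa, out_epsp, out_epsf,
            out_m, out_N, out_lp)
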