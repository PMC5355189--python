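"""Independent brute-force oracles used to validate likelihood code.

These deliberately avoid the package's m-array machinery: the capture
history likelihood is computed per individual by enumerating the
unobserved death time, which is exact for any history.
"""

import math

import numpy as np

from flypop.cjs import SurvivalParams
from flypop.data import CaptureData


def history_loglik_bruteforce(captures: CaptureData,
                              params: SurvivalParams) -> float:
    """CJS likelihood as a product over individual capture histories.

    For each individual, sums over every possible last-occasion-alive d
    (from the last detection to the end of the study): survive the
    intervals up to d, die in interval (d, d+1) unless d is the final
    occasion, and miss/score the intermediate detections.  Conditions on
    the first capture, as CJS does.
    """
    K = params.n_occasions
    total = 0.0
    for i in range(captures.n_individuals):
        det = np.flatnonzero(captures.history[i])
        a, last = int(det[0]), int(det[-1])
        if a == K - 1:
            continue  # released on the final occasion: no information
        juv = captures.age_at_first[i] == "juvenile"
        detset = set(int(t) for t in det)

        def phi(t):
            return params.phi_j[t] if (juv and t == a) else params.phi_a[t]

        lik = 0.0
        for d in range(last, K):
            pr = 1.0
            for t in range(a, d):
                pr *= phi(t)
            if d < K - 1:
                pr *= 1.0 - phi(d)
            for t in range(a + 1, d + 1):
                pr *= params.p[t - 1] if t in detset else 1.0 - params.p[t - 1]
            lik += pr
        total += math.log(lik)
    return total


def random_capture_data(rng: np.random.Generator, n_individuals: int,
                        n_occasions: int, start_year: int = 2000
                        ) -> CaptureData:
    """A random but valid set of capture histories."""
    years = np.arange(start_year, start_year + n_occasions)
    hist = np.zeros((n_individuals, n_occasions), dtype=np.int64)
    first = np.zeros(n_individuals, dtype=np.int64)
    age = np.empty(n_individuals, dtype=object)
    for i in range(n_individuals):
        f = int(rng.integers(0, n_occasions))
        hist[i, f] = 1
        hist[i, f + 1:] = rng.random(n_occasions - f - 1) < 0.5
        first[i] = years[f]
        age[i] = "juvenile" if rng.random() < 0.5 else "adult"
    return CaptureData(ids=[f"i{i}" for i in range(n_individuals)],
                       first_year=first, age_at_first=age, history=hist,
                       years=years)


def random_survival_params(rng: np.random.Generator,
                           n_occasions: int) -> SurvivalParams:
    k = n_occasions - 1
    return SurvivalParams(phi_j=rng.uniform(0.05, 0.95, k),
                          phi_a=rng.uniform(0.05, 0.95, k),
                          p=rng.uniform(0.05, 0.95, k))
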