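"""Age-structured Cormack-Jolly-Seber likelihood on m-arrays.

Apparent survival here confounds mortality with permanent emigration: a
female that leaves the nest-box network is indistinguishable from one that
died.  First-year survival ``phi_j`` applies to the interval following a
juvenile's natal year; from the next interval on she survives with the
adult rate ``phi_a``.  A single recapture probability ``p`` is shared by
both age classes.

Index convention (half-open intervals): with K occasions, ``phi[t]`` covers
the interval t -> t+1 for t = 0..K-2, and ``p[t]`` is the probability of
capture at occasion t+1.  All vectors therefore have length K-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MArraySet, ValidationError

__all__ = ["SurvivalParams", "marray_cell_probs", "cjs_loglik"]


@dataclass
class SurvivalParams:
    """Annual survival and recapture probabilities for K occasions."""

    phi_j: np.ndarray
    phi_a: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.phi_j = np.atleast_1d(np.asarray(self.phi_j, dtype=float))
        self.phi_a = np.atleast_1d(np.asarray(self.phi_a, dtype=float))
        self.p = np.atleast_1d(np.asarray(self.p, dtype=float))
        if not (len(self.phi_j) == len(self.phi_a) == len(self.p)):
            raise ValidationError("phi_j, phi_a, p must share length K-1")
        for name, v in (("phi_j", self.phi_j), ("phi_a", self.phi_a),
                        ("p", self.p)):
            if np.any((v <= 0) | (v >= 1)):
                raise ValidationError(f"{name} outside (0, 1)")

    @property
    def n_occasions(self) -> int:
        return len(self.p) + 1


def marray_cell_probs(params: SurvivalParams, age: str) -> np.ndarray:
    """Multinomial cell probabilities of one m-array.

    Returns a (K-1, K) matrix: entry (i, j) for j < K-1 is the probability
    that an animal released at occasion i is next recaptured at occasion
    j+1; the last column is the probability of never being seen again.
    For ``age="juvenile"`` the first interval after release uses ``phi_j``,
    later intervals ``phi_a``; for ``age="adult"`` all intervals use
    ``phi_a``.  Every row sums to one.
    """
    if age not in ("juvenile", "adult"):
        raise ValueError(f"age must be 'juvenile' or 'adult', got {age!r}")
    K = params.n_occasions
    probs = np.zeros((K - 1, K))
    for i in range(K - 1):
        # survive interval i, then chains of (miss capture, survive)
        surv = params.phi_j[i] if age == "juvenile" else params.phi_a[i]
        alive_undetected = surv
        for j in range(i, K - 1):
            probs[i, j] = alive_undetected * params.p[j]
            alive_undetected *= (1.0 - params.p[j])
            if j + 1 < K - 1:
                alive_undetected *= params.phi_a[j + 1]
        probs[i, K - 1] = 1.0 - probs[i, : K - 1].sum()
    return probs


def cjs_loglik(marrays: MArraySet, params: SurvivalParams) -> float:
    """Joint CJS log-likelihood of both age-class m-arrays.

    Computed as ``sum(count * log(cell prob))`` without the multinomial
    coefficient, which makes it identical (not merely proportional) to the
    product of per-individual capture-history likelihoods.  A zero-
    probability cell with a nonzero count yields ``-inf``.
    """
    if marrays.n_occasions != params.n_occasions:
        raise ValidationError(
            f"m-array has {marrays.n_occasions} occasions, params "
            f"{params.n_occasions}")
    total = 0.0
    for age, arr in (("juvenile", marrays.marray_juv),
                     ("adult", marrays.marray_ad)):
        probs = marray_cell_probs(params, age)
        mask = arr > 0
        if np.any(probs[mask] <= 0.0):
            return -np.inf
        total += float(np.sum(arr[mask] * np.log(probs[mask])))
    return total
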