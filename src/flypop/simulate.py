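"""Individual-based simulator of a nest-box breeding population.

Generates census, productivity, and capture-history data with known ground
truth, emulating the field protocol: boxes are checked annually, broods are
counted (the census), mothers caught during a check are identified, their
daughters are ear-tagged in the nest (entering the capture histories as
juveniles), and every tagged female may be recaptured in later years.

Design choices mirrored from the study system:

* All females are treated as breeding-capable every year; the census counts
  broods, and a female may produce a second detected brood with a small
  probability, so the count can exceed the number of females present.
* Survival is *apparent* survival: a simulated death is indistinguishable
  from permanent emigration, so no separate emigration process exists.
* Tag loss splits an identity: the old id's history simply ends and the
  animal re-enters the data as a newly tagged adult.
* Unsexed offspring count 0.5 toward the daughter tally ``J``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import (
    ADULT,
    JUVENILE,
    CaptureData,
    CensusSeries,
    DemographicParams,
    LatentStates,
    ProductivityTable,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulationResult",
    "default_params",
    "simulate_population",
    "simulate_two_populations",
]

#: order in which per-process RNG streams are spawned from the master seed;
#: fixing the order makes each process independently reproducible
_STREAMS = ("vitals", "reproduction", "survival", "immigration",
            "detection", "tagloss", "sexing", "census")


def default_params() -> DemographicParams:
    """Hyper-parameters of the default simulated world.

    Means follow the demographic estimates of the study populations
    (juvenile survival 0.15, adult survival 0.45, capture probability 0.8,
    fecundity 1.13 daughters per reproductive female); between-year SDs are
    moderate values in the range reported for the two populations.
    """
    return DemographicParams(
        mu_phi_j=0.15, mu_phi_a=0.45, mu_p=0.8, mu_f=1.13,
        sigma_phi_j=0.3, sigma_phi_a=0.2, sigma_p=0.3, sigma_f=0.05,
    )


@dataclass
class SimulationConfig:
    """World description for :func:`simulate_population`.

    ``m`` is the expected number of immigrant females entering per year
    (scalar or length ``T - 1`` vector).  ``tag_loss_prob`` applies per
    interannual recapture event, ``unsexed_prob`` per offspring, and
    ``second_brood_prob`` is the chance a female adds a second detected
    brood to the census.
    """

    T: int = 20
    n1_init: int = 6
    nad_init: int = 16
    nimm_init: int = 4
    params: DemographicParams = field(default_factory=default_params)
    m: float | np.ndarray = 4.0
    tag_loss_prob: float = 0.03
    unsexed_prob: float = 0.05
    second_brood_prob: float = 0.1
    start_year: int = 2001
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.T < 3:
            raise ValidationError("T must be at least 3")
        for name in ("tag_loss_prob", "unsexed_prob", "second_brood_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} = {v} outside [0, 1]")
        m = np.atleast_1d(np.asarray(self.m, dtype=float))
        if m.size == 1:
            m = np.full(self.T - 1, float(m[0]))
        if len(m) != self.T - 1:
            raise ValidationError("m must be scalar or length T-1")
        if np.any(m < 0):
            raise ValidationError("m must be non-negative")
        self.m = m
        for name in ("n1_init", "nad_init", "nimm_init"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass
class AnnualRates:
    """Realized annual demographic rates driving one simulation."""

    phi_j: np.ndarray  # length T-1, interval t -> t+1
    phi_a: np.ndarray  # length T-1
    p: np.ndarray      # length T, detection probability in year t
    f: np.ndarray      # length T, daughters per female in year t


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside the generated data."""

    states: LatentStates
    rates: AnnualRates
    m: np.ndarray
    n_tag_loss: int
    n_interannual_recaptures: int
    fates: pd.DataFrame

    @property
    def tag_loss_fraction(self) -> float:
        if self.n_interannual_recaptures == 0:
            return float("nan")
        return self.n_tag_loss / self.n_interannual_recaptures


@dataclass
class SimulationResult:
    truth: SimulationTruth
    census: CensusSeries
    productivity: ProductivityTable
    captures: CaptureData


def _draw_rates(config: SimulationConfig, rng: np.random.Generator
                ) -> AnnualRates:
    from scipy.special import expit, logit

    par = config.params
    T = config.T

    def prob_series(mu, sigma, n):
        if mu <= 0.0 or mu >= 1.0:
            return np.full(n, float(mu))
        return expit(logit(mu) + rng.normal(0.0, sigma, n))

    f = (np.zeros(T) if par.mu_f == 0 else
         np.exp(np.log(par.mu_f) + rng.normal(0.0, par.sigma_f, T)))
    return AnnualRates(
        phi_j=prob_series(par.mu_phi_j, par.sigma_phi_j, T - 1),
        phi_a=prob_series(par.mu_phi_a, par.sigma_phi_a, T - 1),
        p=prob_series(par.mu_p, par.sigma_p, T),
        f=f,
    )


class _Female:
    __slots__ = ("tag", "tag_year", "entry_year", "origin", "exit_year")

    def __init__(self, entry_year: int, origin: str):
        self.tag: str | None = None
        self.tag_year: int | None = None
        self.entry_year = entry_year
        self.origin = origin
        self.exit_year: int | None = None


def simulate_population(config: SimulationConfig,
                        rates: AnnualRates | None = None,
                        seed: int | None = None) -> SimulationResult:
    """Run one individual-based realization of the stated world.

    ``rates`` overrides the annual demographic rates (used to couple two
    populations); otherwise they are drawn from the hyper-parameters in
    ``config``.  ``seed`` overrides ``config.seed``.
    """
    master = np.random.SeedSequence(
        seed if seed is not None else config.seed)
    streams = dict(zip(_STREAMS,
                       (np.random.default_rng(s)
                        for s in master.spawn(len(_STREAMS)))))
    if rates is None:
        rates = _draw_rates(config, streams["vitals"])

    T = config.T
    rng_rep = streams["reproduction"]
    rng_sur = streams["survival"]
    rng_imm = streams["immigration"]
    rng_det = streams["detection"]
    rng_tag = streams["tagloss"]
    rng_sex = streams["sexing"]
    rng_cen = streams["census"]

    # histories keyed by tag id
    hist: dict[str, dict] = {}
    next_tag = [0]

    def new_tag(year: int, age: str) -> str:
        tag = f"F{next_tag[0]:05d}"
        next_tag[0] += 1
        hist[tag] = {"first_year": year, "age": age, "det": {year}}
        return tag

    # stage bookkeeping: females alive at the start of year t
    females: list[_Female] = []
    for _ in range(config.n1_init):
        females.append(_Female(0, "initial_1yo"))
    for _ in range(config.nad_init):
        females.append(_Female(0, "initial_adult"))
    for _ in range(config.nimm_init):
        females.append(_Female(0, "initial_immigrant"))

    N1 = np.zeros(T, dtype=np.int64)
    Nad = np.zeros(T, dtype=np.int64)
    Nimm = np.zeros(T, dtype=np.int64)
    N1[0], Nad[0], Nimm[0] = config.n1_init, config.nad_init, config.nimm_init

    census = np.zeros(T, dtype=np.int64)
    J = np.zeros(T)
    R = np.zeros(T, dtype=np.int64)
    n_tag_loss = 0
    n_inter_recap = 0
    all_females: list[_Female] = list(females)

    for t in range(T):
        n_alive = len(females)
        census[t] = n_alive + (
            rng_cen.binomial(n_alive, config.second_brood_prob)
            if n_alive else 0)

        # annual box check: detection, identification, tag loss
        detected: list[bool] = []
        for fem in females:
            det = bool(rng_det.random() < rates.p[t])
            detected.append(det)
            if not det:
                continue
            if fem.tag is None:
                fem.tag = new_tag(t, ADULT)
                fem.tag_year = t
            elif t > fem.tag_year:
                n_inter_recap += 1
                if rng_tag.random() < config.tag_loss_prob:
                    # identity lost: old history ends, new adult id begins
                    n_tag_loss += 1
                    fem.tag = new_tag(t, ADULT)
                    fem.tag_year = t
                else:
                    hist[fem.tag]["det"].add(t)
            else:
                hist[fem.tag]["det"].add(t)

        # reproduction and tagging of daughters in the nest
        recruits: list[_Female] = []
        for fem, det in zip(females, detected):
            daughters = rng_rep.poisson(rates.f[t])
            if det:
                R[t] += 1
                sons = rng_rep.poisson(rates.f[t])
                unsexed_d = rng_sex.binomial(daughters, config.unsexed_prob)
                unsexed_s = rng_sex.binomial(sons, config.unsexed_prob)
                J[t] += (daughters - unsexed_d) + 0.5 * (unsexed_d + unsexed_s)
            if t == T - 1:
                continue
            for _ in range(daughters):
                if rng_sur.random() < rates.phi_j[t]:
                    child = _Female(t + 1, "recruit")
                    if det:
                        child.tag = new_tag(t, JUVENILE)
                        child.tag_year = t
                    recruits.append(child)
                    all_females.append(child)
                elif det:
                    # tagged in the nest but never recruits
                    doomed = _Female(t, "recruit_died")
                    doomed.tag = new_tag(t, JUVENILE)
                    doomed.exit_year = t
                    all_females.append(doomed)

        if t == T - 1:
            for fem in females:
                fem.exit_year = t
            break

        # apparent survival of all >= 1-year-old females
        survivors = []
        for fem in females:
            if rng_sur.random() < rates.phi_a[t]:
                survivors.append(fem)
            else:
                fem.exit_year = t
        immigrants = []
        for _ in range(rng_imm.poisson(config.m[t])):
            imm = _Female(t + 1, "immigrant")
            immigrants.append(imm)
            all_females.append(imm)

        N1[t + 1] = len(recruits)
        Nad[t + 1] = len(survivors)
        Nimm[t + 1] = len(immigrants)
        females = survivors + recruits + immigrants

    years = np.arange(config.start_year, config.start_year + T)
    ids = sorted(hist)
    history = np.zeros((len(ids), T), dtype=np.int64)
    first_year = np.zeros(len(ids), dtype=np.int64)
    age_at_first = np.empty(len(ids), dtype=object)
    for i, tag in enumerate(ids):
        rec = hist[tag]
        first_year[i] = years[rec["first_year"]]
        age_at_first[i] = rec["age"]
        for occ in rec["det"]:
            history[i, occ] = 1

    fates = pd.DataFrame({
        "tag": [f.tag for f in all_females],
        "entry_year": [years[min(f.entry_year, T - 1)] for f in all_females],
        "exit_year": [None if f.exit_year is None else years[f.exit_year]
                      for f in all_females],
        "origin": [f.origin for f in all_females],
    })

    truth = SimulationTruth(
        states=LatentStates(N1=N1, Nad=Nad, Nimm=Nimm),
        rates=rates,
        m=config.m.copy(),
        n_tag_loss=n_tag_loss,
        n_interannual_recaptures=n_inter_recap,
        fates=fates,
    )
    pid = "sim"
    return SimulationResult(
        truth=truth,
        census=CensusSeries(pid, years, census),
        productivity=ProductivityTable(pid, years, J, R),
        captures=CaptureData(ids=ids, first_year=first_year,
                             age_at_first=age_at_first, history=history,
                             years=years),
    )


def simulate_two_populations(config_a: SimulationConfig,
                             config_b: SimulationConfig,
                             coupling: float = 0.0,
                             seed: int | None = None
                             ) -> tuple[SimulationResult, SimulationResult]:
    """Simulate a pair of populations with optional environmental coupling.

    ``coupling`` correlates the annual logit/log-scale effects on survival,
    capture, and fecundity between the populations (0 = fully independent
    dynamics, 1 = identical annual effects given equal hyper-parameters).
    Demographic (individual-level) noise is always independent.
    """
    if not -1.0 <= coupling <= 1.0:
        raise ValidationError("coupling must lie in [-1, 1]")
    if config_a.T != config_b.T:
        raise ValidationError("populations must share T for coupled effects")
    master = np.random.SeedSequence(seed)
    ss_rates, ss_a, ss_b = master.spawn(3)
    rng = np.random.default_rng(ss_rates)

    from scipy.special import expit, logit

    def coupled_pair(mu_a, sig_a, mu_b, sig_b, n, link):
        za = rng.normal(0.0, 1.0, n)
        zb = coupling * za + np.sqrt(1.0 - coupling ** 2) * \
            rng.normal(0.0, 1.0, n)

        def series(mu, sig, z):
            if link == "logit":
                if mu <= 0.0 or mu >= 1.0:
                    return np.full(n, float(mu))
                return expit(logit(mu) + sig * z)
            return (np.zeros(n) if mu == 0 else
                    np.exp(np.log(mu) + sig * z))

        return series(mu_a, sig_a, za), series(mu_b, sig_b, zb)

    pa, pb = config_a.params, config_b.params
    T = config_a.T
    phi_j_a, phi_j_b = coupled_pair(pa.mu_phi_j, pa.sigma_phi_j,
                                    pb.mu_phi_j, pb.sigma_phi_j, T - 1,
                                    "logit")
    phi_a_a, phi_a_b = coupled_pair(pa.mu_phi_a, pa.sigma_phi_a,
                                    pb.mu_phi_a, pb.sigma_phi_a, T - 1,
                                    "logit")
    p_a, p_b = coupled_pair(pa.mu_p, pa.sigma_p, pb.mu_p, pb.sigma_p, T,
                            "logit")
    f_a, f_b = coupled_pair(pa.mu_f, pa.sigma_f, pb.mu_f, pb.sigma_f, T,
                            "log")

    res_a = simulate_population(
        replace(config_a),
        rates=AnnualRates(phi_j_a, phi_a_a, p_a, f_a),
        seed=_seed_from(ss_a))
    res_b = simulate_population(
        replace(config_b),
        rates=AnnualRates(phi_j_b, phi_a_b, p_b, f_b),
        seed=_seed_from(ss_b))
    return res_a, res_b


def _seed_from(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0])
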