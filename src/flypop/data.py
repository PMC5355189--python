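"""Domain types and CSV interchange for nest-box population monitoring data.

The observed layers of the model are

* a census time series: broods found per year (``y``),
* a productivity table: tagged daughters ``J`` produced by ``R`` identified
  reproductive females per year (unsexed offspring count 0.5 daughter, so
  ``J`` may be half-integer),
* individual capture histories of ear-tagged females, with age class at
  first capture (juvenile = tagged in the natal nest, adult otherwise).

Capture histories are reduced to age-structured m-arrays, the sufficient
statistic of the Cormack-Jolly-Seber likelihood.  All types are female-only:
population size throughout the package means the number of females.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "CensusSeries",
    "ProductivityTable",
    "CaptureData",
    "MArraySet",
    "LatentStates",
    "DemographicParams",
    "PosteriorDraws",
    "read_census",
    "write_census",
    "read_productivity",
    "write_productivity",
    "read_captures",
    "write_captures",
    "build_marrays",
    "tag_loss_rate",
]

JUVENILE = "juvenile"
ADULT = "adult"


class ValidationError(ValueError):
    """Raised when input data violate a structural invariant."""


def _as_int_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.size and not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValidationError(f"{name} must be integer valued")
    return arr.astype(np.int64)


@dataclass
class CensusSeries:
    """Annual count of broods found in one nest-box population.

    ``years`` must be strictly consecutive calendar years (the model indexes
    them 1..T internally); ``y`` are non-negative brood counts.
    """

    population_id: str
    years: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.years = _as_int_array(self.years, "years")
        self.y = _as_int_array(self.y, "y")
        if len(self.years) != len(self.y):
            raise ValidationError("years and y differ in length")
        if len(self.years) < 3:
            raise ValidationError(
                f"census needs at least 3 years, got {len(self.years)}"
            )
        if np.any(np.diff(self.years) != 1):
            bad = int(np.flatnonzero(np.diff(self.years) != 1)[0])
            raise ValidationError(
                f"years not consecutive between rows {bad} and {bad + 1} "
                f"({self.years[bad]} -> {self.years[bad + 1]})"
            )
        neg = np.flatnonzero(self.y < 0)
        if neg.size:
            raise ValidationError(f"negative count in row {int(neg[0])}")

    @property
    def n_years(self) -> int:
        return len(self.years)


@dataclass
class ProductivityTable:
    """Per-year daughters produced by identified reproductive females.

    ``J[t]`` may end in .5 because unsexed offspring are counted as half a
    daughter; any other fractional part is rejected.  A year with no
    identified mothers (``R = 0``) cannot have tagged daughters.
    """

    population_id: str
    years: np.ndarray
    J: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.years = _as_int_array(self.years, "years")
        self.J = np.asarray(self.J, dtype=float)
        self.R = _as_int_array(self.R, "R")
        if not (len(self.years) == len(self.J) == len(self.R)):
            raise ValidationError("years, J, R differ in length")
        if np.any(self.J < 0):
            raise ValidationError("J must be non-negative")
        if np.any(self.R < 0):
            raise ValidationError("R must be non-negative")
        frac = np.mod(self.J * 2, 1)
        if np.any(frac != 0):
            bad = int(np.flatnonzero(frac != 0)[0])
            raise ValidationError(
                f"J[{bad}] = {self.J[bad]} is not a multiple of 0.5"
            )
        bad = np.flatnonzero((self.R == 0) & (self.J > 0))
        if bad.size:
            raise ValidationError(
                f"row {int(bad[0])}: J > 0 with no reproductive females (R = 0)"
            )

    @property
    def n_years(self) -> int:
        return len(self.years)


@dataclass
class CaptureData:
    """Detection histories of ear-tagged females over a common year span.

    ``history`` is an (n_individuals, n_years) binary matrix; column ``t``
    is 1 if the individual was captured in ``years[t]``.  ``age_at_first``
    is "juvenile" or "adult" at the first capture.  Tag loss splits an
    individual into two ids upstream; it is *not* represented here.
    """

    ids: list[str]
    first_year: np.ndarray
    age_at_first: np.ndarray
    history: np.ndarray
    years: np.ndarray

    def __post_init__(self) -> None:
        self.years = _as_int_array(self.years, "years")
        self.first_year = _as_int_array(self.first_year, "first_year")
        self.history = _as_int_array(self.history, "history")
        self.age_at_first = np.asarray(self.age_at_first, dtype=object)
        n = len(self.ids)
        if self.history.shape != (n, len(self.years)):
            raise ValidationError(
                f"history shape {self.history.shape} does not match "
                f"{n} individuals x {len(self.years)} years"
            )
        if not np.isin(self.age_at_first, [JUVENILE, ADULT]).all():
            raise ValidationError("age_at_first must be 'juvenile' or 'adult'")
        if np.any((self.history != 0) & (self.history != 1)):
            raise ValidationError("history entries must be 0/1")
        for i in range(n):
            f = int(self.first_year[i]) - int(self.years[0])
            if f < 0 or f >= len(self.years):
                raise ValidationError(
                    f"individual {self.ids[i]}: first_year outside study span"
                )
            if self.history[i, f] != 1:
                raise ValidationError(
                    f"individual {self.ids[i]}: not detected in its first year"
                )
            if np.any(self.history[i, :f]):
                raise ValidationError(
                    f"individual {self.ids[i]}: detection before first capture"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_years(self) -> int:
        return len(self.years)


@dataclass
class MArraySet:
    """Age-structured m-arrays: the CJS sufficient statistic.

    Each array has one row per release occasion 1..K-1 and columns for first
    recapture at occasions 2..K plus a trailing never-seen-again column, so
    the shape is (K-1, K).  ``marray_juv`` rows are releases of individuals
    in their juvenile year; every re-release (including of a former
    juvenile) lands in ``marray_ad``.
    """

    marray_juv: np.ndarray
    marray_ad: np.ndarray

    def __post_init__(self) -> None:
        self.marray_juv = _as_int_array(self.marray_juv, "marray_juv")
        self.marray_ad = _as_int_array(self.marray_ad, "marray_ad")
        for name, arr in (("marray_juv", self.marray_juv),
                          ("marray_ad", self.marray_ad)):
            if arr.ndim != 2 or arr.shape[1] != arr.shape[0] + 1:
                raise ValidationError(f"{name} must have shape (K-1, K)")
            if np.any(arr < 0):
                raise ValidationError(f"{name} has negative counts")
        if self.marray_juv.shape != self.marray_ad.shape:
            raise ValidationError("juvenile and adult m-arrays differ in shape")
        # column j < K-1 is a recapture at occasion j+2; a release at
        # occasion i (row i) cannot be recaptured at or before occasion i+1-1
        K = self.n_occasions
        for name, arr in (("marray_juv", self.marray_juv),
                          ("marray_ad", self.marray_ad)):
            for i in range(K - 1):
                if np.any(arr[i, :i]):
                    raise ValidationError(
                        f"{name}: recapture before release in row {i}"
                    )

    @property
    def n_occasions(self) -> int:
        return self.marray_juv.shape[0] + 1

    @property
    def releases_juv(self) -> np.ndarray:
        return self.marray_juv.sum(axis=1)

    @property
    def releases_ad(self) -> np.ndarray:
        return self.marray_ad.sum(axis=1)


@dataclass
class LatentStates:
    """One trajectory of female stage sizes.

    ``N1``: locally recruited one-year-olds; ``Nad``: older survivors;
    ``Nimm``: immigrants in their year of arrival.  ``Ntot`` is their sum
    and is the quantity the census observes.
    """

    N1: np.ndarray
    Nad: np.ndarray
    Nimm: np.ndarray

    def __post_init__(self) -> None:
        self.N1 = _as_int_array(self.N1, "N1")
        self.Nad = _as_int_array(self.Nad, "Nad")
        self.Nimm = _as_int_array(self.Nimm, "Nimm")
        if not (len(self.N1) == len(self.Nad) == len(self.Nimm)):
            raise ValidationError("stage vectors differ in length")
        for name, arr in (("N1", self.N1), ("Nad", self.Nad),
                          ("Nimm", self.Nimm)):
            if np.any(arr < 0):
                raise ValidationError(f"{name} has negative entries")

    @property
    def Ntot(self) -> np.ndarray:
        return self.N1 + self.Nad + self.Nimm

    @property
    def n_years(self) -> int:
        return len(self.N1)


@dataclass
class DemographicParams:
    """Hyper-parameters of the annual demographic rates.

    Means are on the natural scale (probabilities for survival/capture,
    daughters per reproductive female for fecundity); the between-year SDs
    act on the logit scale for probabilities and the log scale for
    fecundity.  Annual rates are
    ``phi[t] = expit(logit(mu) + eps[t])`` and ``f[t] = exp(log(mu) + eps[t])``.
    """

    mu_phi_j: float
    mu_phi_a: float
    mu_p: float
    mu_f: float
    sigma_phi_j: float = 0.0
    sigma_phi_a: float = 0.0
    sigma_p: float = 0.0
    sigma_f: float = 0.0
    eps_phi_j: np.ndarray | None = None
    eps_phi_a: np.ndarray | None = None
    eps_p: np.ndarray | None = None
    eps_f: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("mu_phi_j", "mu_phi_a", "mu_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} = {v} outside [0, 1]")
        if self.mu_f < 0:
            raise ValidationError("mu_f must be non-negative")
        for name in ("sigma_phi_j", "sigma_phi_a", "sigma_p", "sigma_f"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def _annual(self, mu: float, sigma: float, eps, T: int,
                link: str) -> np.ndarray:
        eps = np.zeros(T) if eps is None else np.asarray(eps, dtype=float)
        if len(eps) != T:
            raise ValidationError("annual effect vector has wrong length")
        if link == "logit":
            from scipy.special import expit, logit
            if mu <= 0.0 or mu >= 1.0:  # degenerate boundary rate
                return np.full(T, float(mu))
            return expit(logit(mu) + eps)
        if mu == 0.0:
            return np.zeros(T)
        return np.exp(np.log(mu) + eps)

    def phi_j(self, T: int) -> np.ndarray:
        return self._annual(self.mu_phi_j, self.sigma_phi_j, self.eps_phi_j,
                            T, "logit")

    def phi_a(self, T: int) -> np.ndarray:
        return self._annual(self.mu_phi_a, self.sigma_phi_a, self.eps_phi_a,
                            T, "logit")

    def p(self, T: int) -> np.ndarray:
        return self._annual(self.mu_p, self.sigma_p, self.eps_p, T, "logit")

    def f(self, T: int) -> np.ndarray:
        return self._annual(self.mu_f, self.sigma_f, self.eps_f, T, "log")


class PosteriorDraws:
    """Chain-indexed posterior draws with tidy-CSV round trip.

    ``params`` maps a parameter name to an array of shape
    ``(n_chains, n_draws)`` for scalars or ``(n_chains, n_draws, k)`` for
    vector-valued parameters (annual rates, latent state trajectories).
    """

    def __init__(self, params: dict[str, np.ndarray], seed: int | None = None,
                 meta: dict | None = None):
        if not params:
            raise ValidationError("empty draw set")
        shapes = {k: v.shape[:2] for k, v in params.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise ValidationError("parameters disagree on (chains, draws)")
        if first[0] < 2:
            raise ValidationError("need at least 2 chains for diagnostics")
        self.params = {k: np.asarray(v) for k, v in params.items()}
        self.seed = seed
        self.meta = meta or {}

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def __contains__(self, name: str) -> bool:
        return name in self.params

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated: shape (n_chains * n_draws, ...)."""
        v = self.params[name]
        return v.reshape(-1, *v.shape[2:])

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for name, v in self.params.items():
            if v.ndim == 2:
                df = pd.DataFrame({
                    "chain": np.repeat(np.arange(v.shape[0]), v.shape[1]),
                    "iter": np.tile(np.arange(v.shape[1]), v.shape[0]),
                    "parameter": name,
                    "value": v.reshape(-1),
                })
                rows.append(df)
            else:
                for k in range(v.shape[2]):
                    df = pd.DataFrame({
                        "chain": np.repeat(np.arange(v.shape[0]), v.shape[1]),
                        "iter": np.tile(np.arange(v.shape[1]), v.shape[0]),
                        "parameter": f"{name}[{k}]",
                        "value": v[:, :, k].reshape(-1),
                    })
                    rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def write_csv(self, path: str | Path) -> None:
        self.to_tidy().to_csv(path, index=False)

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, seed: int | None = None
                  ) -> "PosteriorDraws":
        n_chains = int(df["chain"].max()) + 1
        n_draws = int(df["iter"].max()) + 1
        vec: dict[str, dict[int, np.ndarray]] = {}
        scal: dict[str, np.ndarray] = {}
        for name, sub in df.groupby("parameter", sort=False):
            arr = np.full((n_chains, n_draws), np.nan)
            arr[sub["chain"].to_numpy(), sub["iter"].to_numpy()] = \
                sub["value"].to_numpy()
            if name.endswith("]") and "[" in name:
                base, idx = name[:-1].rsplit("[", 1)
                vec.setdefault(base, {})[int(idx)] = arr
            else:
                scal[name] = arr
        params: dict[str, np.ndarray] = dict(scal)
        for base, parts in vec.items():
            k = max(parts) + 1
            params[base] = np.stack([parts[i] for i in range(k)], axis=-1)
        return cls(params, seed=seed)

    @classmethod
    def read_csv(cls, path: str | Path, seed: int | None = None
                 ) -> "PosteriorDraws":
        return cls.from_tidy(pd.read_csv(path), seed=seed)


# ---------------------------------------------------------------------------
# CSV readers / writers


def read_census(path: str | Path, population_id: str | None = None
                ) -> CensusSeries:
    """Read a ``year,y`` CSV into a validated :class:`CensusSeries`."""
    df = pd.read_csv(path)
    _require_columns(df, ["year", "y"], path)
    df = df.sort_values("year")
    return CensusSeries(
        population_id=population_id or Path(path).stem,
        years=df["year"].to_numpy(),
        y=df["y"].to_numpy(),
    )


def write_census(census: CensusSeries, path: str | Path) -> None:
    pd.DataFrame({"year": census.years, "y": census.y}).to_csv(
        path, index=False)


def read_productivity(path: str | Path, population_id: str | None = None
                      ) -> ProductivityTable:
    """Read a ``year,J,R`` CSV into a validated :class:`ProductivityTable`."""
    df = pd.read_csv(path)
    _require_columns(df, ["year", "J", "R"], path)
    df = df.sort_values("year")
    return ProductivityTable(
        population_id=population_id or Path(path).stem,
        years=df["year"].to_numpy(),
        J=df["J"].to_numpy(),
        R=df["R"].to_numpy(),
    )


def write_productivity(table: ProductivityTable, path: str | Path) -> None:
    pd.DataFrame({"year": table.years, "J": table.J, "R": table.R}).to_csv(
        path, index=False)


def read_captures(path: str | Path) -> CaptureData:
    """Read ``id,first_year,age_at_first,h_<year>...`` capture histories."""
    df = pd.read_csv(path)
    _require_columns(df, ["id", "first_year", "age_at_first"], path)
    hcols = [c for c in df.columns if c.startswith("h_")]
    if not hcols:
        raise ValidationError(f"{path}: no history columns h_<year>")
    years = np.array(sorted(int(c[2:]) for c in hcols))
    hist = df[[f"h_{yr}" for yr in years]].to_numpy()
    return CaptureData(
        ids=[str(i) for i in df["id"]],
        first_year=df["first_year"].to_numpy(),
        age_at_first=df["age_at_first"].to_numpy(),
        history=hist,
        years=years,
    )


def write_captures(captures: CaptureData, path: str | Path) -> None:
    df = pd.DataFrame({
        "id": captures.ids,
        "first_year": captures.first_year,
        "age_at_first": captures.age_at_first,
    })
    for t, yr in enumerate(captures.years):
        df[f"h_{yr}"] = captures.history[:, t]
    df.to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------------------
# m-array construction


def build_marrays(captures: CaptureData) -> MArraySet:
    """Reduce capture histories to age-structured m-arrays.

    Every capture is a release (no losses on capture).  An individual first
    caught as a juvenile contributes its first release to the juvenile
    array; recaptured individuals are re-released as adults.  Cell (i, j)
    of an array counts first recaptures at occasion j+2 of animals released
    at occasion i+1 (0-based rows over release occasions 1..K-1); the last
    column counts releases never seen again.
    """
    K = captures.n_years
    mj = np.zeros((K - 1, K), dtype=np.int64)
    ma = np.zeros((K - 1, K), dtype=np.int64)
    for i in range(captures.n_individuals):
        det = np.flatnonzero(captures.history[i])
        juvenile_first = captures.age_at_first[i] == JUVENILE
        for k, occ in enumerate(det):
            arr = mj if (juvenile_first and k == 0) else ma
            if occ == K - 1:
                continue  # release on the last occasion carries no information
            if k + 1 < len(det):
                arr[occ, det[k + 1] - 1] += 1
            else:
                arr[occ, K - 1] += 1
    return MArraySet(marray_juv=mj, marray_ad=ma)


def tag_loss_rate(n_lost: int, n_recaptures: int) -> float:
    """Fraction of interannual recaptures where identity was lost to tag loss.

    The estimator is the plain ratio of identity-loss events to interannual
    recaptures in the double-checked subset (broken-eared adults over all
    recaptured adults).
    """
    if n_recaptures <= 0:
        raise ValidationError("n_recaptures must be positive")
    if not 0 <= n_lost <= n_recaptures:
        raise ValidationError("n_lost must lie in [0, n_recaptures]")
    return n_lost / n_recaptures
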