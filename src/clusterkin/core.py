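"""Shared domain types and reaction propensities.

The state of one host's intestinal bacterial population is a multiset of
cluster sizes.  Four reactions act on it:

* growth — cell division within a cluster, rate ``r * n`` per cluster,
  throttled by a logistic factor ``(1 - N/K)`` when a carrying capacity
  ``K`` is set;
* fragmentation ("chipping") — a single cell escapes a cluster of size
  ``n >= 2``, rate ``beta * n**nu_F``, sharing the growth logistic factor;
* aggregation — two clusters of sizes ``n`` and ``m`` merge, with the
  homogeneous kernel ``A_nm = alpha * (n*m)**nu_A``;
* expulsion — a whole cluster is swept out of the intestine at rate
  ``lambda_ * n**nu_E``.

Cluster sizes are kept real-valued internally because the full model grows
clusters deterministically between stochastic events; observable outputs
round sizes up to the nearest integer, matching how imaging-derived cell
counts are recorded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "KineticParams",
    "ClusterPopulation",
    "EventLog",
    "logistic_factor",
    "growth_rates",
    "fragmentation_rates",
    "total_aggregation_propensity",
    "aggregation_pair_propensity_bruteforce",
    "expulsion_rates",
]


@dataclass
class KineticParams:
    """All kinetic rates and exponents of the cluster model.

    Parameters
    ----------
    r : float
        Cell division rate (1/hr).
    K : float or None
        Carrying capacity in cells; ``None`` means unbounded growth.
    beta : float
        Fragmentation rate coefficient (1/hr).
    nu_F : float
        Fragmentation exponent; clusters of size n fragment at
        ``beta * n**nu_F``.  0, 1/3, 2/3 and 1 are the typical choices.
    alpha : float
        Aggregation rate coefficient (1/hr).
    nu_A : float
        Aggregation exponent of the homogeneous kernel ``alpha*(n*m)**nu_A``.
    lambda_ : float
        Expulsion rate coefficient (1/hr).
    nu_E : float
        Expulsion exponent; clusters of size n are expelled at
        ``lambda_ * n**nu_E``.
    """

    r: float = 0.0
    K: float | None = None
    beta: float = 0.0
    nu_F: float = 1.0
    alpha: float = 0.0
    nu_A: float = 0.0
    lambda_: float = 0.0
    nu_E: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r", "beta", "alpha", "lambda_"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate coefficient {name!r} must be >= 0")
        for name in ("nu_F", "nu_A", "nu_E"):
            if getattr(self, name) < 0:
                raise ValueError(f"exponent {name!r} must be >= 0")
        if self.K is not None:
            if not math.isfinite(self.K):
                self.K = None
            elif self.K < 1:
                raise ValueError("carrying capacity K must be >= 1 cell (or None)")

    # --- serialization: flat JSON, key "lambda", K=null for unbounded ---

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "K": self.K,
            "beta": self.beta,
            "nu_F": self.nu_F,
            "alpha": self.alpha,
            "nu_A": self.nu_A,
            "lambda": self.lambda_,
            "nu_E": self.nu_E,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        d = dict(d)
        if "lambda" in d:
            d["lambda_"] = d.pop("lambda")
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "KineticParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def replace(self, **kwargs) -> "KineticParams":
        return replace(self, **kwargs)


@dataclass
class ClusterPopulation:
    """A multiset of cluster sizes for one (simulated or observed) host.

    ``sizes`` is a 1-D float array with every entry >= 1; ``time`` is the
    simulation time in hours.  Total cell count ``N`` and cluster count
    ``M`` are always recomputed from ``sizes``.
    """

    sizes: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float).ravel()
        if self.sizes.size and self.sizes.min() < 1:
            raise ValueError("all cluster sizes must be >= 1")

    @property
    def total_cells(self) -> float:
        """N, the total number of cells across clusters."""
        return float(self.sizes.sum())

    @property
    def n_clusters(self) -> int:
        """M, the number of clusters."""
        return int(self.sizes.size)

    def as_integer_sizes(self) -> np.ndarray:
        """Sizes binned to the nearest integer (minimum 1).

        Clusters grow continuously in the full model, so a newly shed
        single cell spends time at sizes in (1, 2); nearest-integer
        binning keeps it in the size-1 bin until it has effectively
        doubled, matching the integer-grid bookkeeping of the mean-field
        equations.  (Ingested imaging data use their own recording
        convention — sizes rounded up — applied at read time.)
        """
        return np.maximum(np.round(self.sizes), 1.0).astype(np.int64)

    def copy(self) -> "ClusterPopulation":
        return ClusterPopulation(self.sizes.copy(), self.time)

    @classmethod
    def single_cells(cls, n: int, time: float = 0.0) -> "ClusterPopulation":
        """A population of ``n`` size-1 clusters (initial colonization)."""
        return cls(np.ones(n, dtype=float), time)


GROWTH = "growth-step"
FRAGMENTATION = "fragmentation"
AGGREGATION = "aggregation"
EXPULSION = "expulsion"

_EVENT_KINDS = (GROWTH, FRAGMENTATION, AGGREGATION, EXPULSION)


class EventLog:
    """Timestamped record of stochastic events from one simulation run.

    Each record holds (time, kind, size1, size2).  ``size2`` is only
    meaningful for aggregation events (the two merging partner sizes);
    elsewhere it is NaN.  Times are nondecreasing by construction.
    """

    def __init__(self) -> None:
        self.times: list[float] = []
        self.kinds: list[str] = []
        self.sizes1: list[float] = []
        self.sizes2: list[float] = []

    def append(self, time: float, kind: str, size1: float, size2: float = math.nan) -> None:
        if kind not in _EVENT_KINDS:
            raise ValueError(f"unknown event kind {kind!r}")
        if self.times and time < self.times[-1] - 1e-12:
            raise ValueError("event times must be nondecreasing")
        if kind == AGGREGATION and not math.isfinite(size2):
            raise ValueError("aggregation records need exactly two participant sizes")
        self.times.append(float(time))
        self.kinds.append(kind)
        self.sizes1.append(float(size1))
        self.sizes2.append(float(size2))

    def __len__(self) -> int:
        return len(self.times)

    def count(self, kind: str, window: tuple[float, float] | None = None) -> int:
        """Number of events of ``kind``, optionally within ``(t0, t1]``."""
        if window is None:
            return sum(k == kind for k in self.kinds)
        t0, t1 = window
        return sum(
            k == kind and t0 < t <= t1 for k, t in zip(self.kinds, self.times)
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "kind": self.kinds,
                "size1": self.sizes1,
                "size2": self.sizes2,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Propensities
# ---------------------------------------------------------------------------


def logistic_factor(N: float, K: float | None) -> float:
    """Logistic throttle (1 - N/K), clamped at 0; 1 when K is None."""
    if K is None:
        return 1.0
    return max(0.0, 1.0 - N / K)


def growth_rates(population: ClusterPopulation, params: KineticParams) -> np.ndarray:
    """Per-cluster cell-division rates ``r * n * (1 - N/K)`` (1/hr)."""
    n = population.sizes
    L = logistic_factor(population.total_cells, params.K)
    return params.r * n * L


def fragmentation_rates(population: ClusterPopulation, params: KineticParams) -> np.ndarray:
    """Per-cluster chipping rates ``beta * n**nu_F * (1 - N/K)``.

    Clusters must contain at least two cells to shed one; sizes below 2
    (including fractional sizes in (1, 2)) have rate 0.
    """
    n = population.sizes
    L = logistic_factor(population.total_cells, params.K)
    rates = params.beta * np.power(n, params.nu_F) * L
    rates[n < 2] = 0.0
    return rates


def aggregation_weights(sizes: np.ndarray, nu_A: float) -> np.ndarray:
    """Kernel half-weights ``n**nu_A`` used for pair selection."""
    return np.power(sizes, nu_A)


def total_aggregation_propensity(population: ClusterPopulation, params: KineticParams) -> float:
    """Total merge rate ``alpha * sum_{i<j} (n_i n_j)**nu_A``.

    Uses the factorized identity (alpha/2) * [(sum w)^2 - sum w^2] with
    w = n**nu_A, which is exact for the unordered pair sum.
    """
    if population.n_clusters < 2 or params.alpha == 0.0:
        return 0.0
    w = aggregation_weights(population.sizes, params.nu_A)
    s1 = w.sum()
    s2 = (w * w).sum()
    return 0.5 * params.alpha * (s1 * s1 - s2)


def aggregation_pair_propensity_bruteforce(
    population: ClusterPopulation, params: KineticParams
) -> float:
    """O(M^2) reference pair sum; kept as the oracle for the identity above."""
    n = population.sizes
    total = 0.0
    for i in range(n.size):
        for j in range(i + 1, n.size):
            total += (n[i] * n[j]) ** params.nu_A
    return params.alpha * total


def expulsion_rates(population: ClusterPopulation, params: KineticParams) -> np.ndarray:
    """Per-cluster removal rates ``lambda_ * n**nu_E`` (whole cluster lost)."""
    n = population.sizes
    return params.lambda_ * np.power(n, params.nu_E)
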