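"""Closed-form exponent predictions and summary statistics.

For the minimal growth-fragmentation process (division rate r, chipping
rate beta * n**nu_F) the long-time, large-size density exponent mu of
p(n) ~ n**-mu admits closed forms in the slow-fragmentation regime
beta/r < 1:

    nu_F = 1   :  mu = 1 + 1 / (1 - beta/r)        (well-mixed limit)
    nu_F = 2/3 :  mu = 5/3 + beta/r                (surface fragmentation)
    nu_F = 0   :  mu = 1 + (beta/r) / (1 + beta/r) (size-independent; see note)

All of them respect the normalizability bound mu > nu_F + 1 that follows
from requiring a finite total rate of cluster production.

Note on the nu_F = 0 entry: the printed source formula is typographically
ambiguous; the form used here is the reading consistent with its stated
limits (mu -> 1 as beta -> 0, sublinear growth in beta/r).  It is treated
as indicative, not as a precise benchmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import AGGREGATION, EventLog
from .distributions import SizeDistribution

__all__ = [
    "ExponentPrediction",
    "analytic_mu",
    "min_mu_bound",
    "is_stationary",
    "aggregation_events_per_hour",
    "aggregation_rate_bounds",
]


@dataclass(frozen=True)
class ExponentPrediction:
    """Predicted density exponent mu with its regime-validity flags."""

    mu: float
    nu_F: float
    beta_over_r: float
    slow_fragmentation: bool  # beta/r < 1, where the formulas hold
    asymptotic: bool = True  # long-time, large-size limit

    @property
    def cumulative_exponent(self) -> float:
        """Exponent of P(size>n) ~ n**-(mu-1), reported as -(mu-1)."""
        return -(self.mu - 1.0)


def analytic_mu(nu_F: float, beta: float, r: float) -> ExponentPrediction:
    """Closed-form density exponent for the minimal model.

    Only nu_F in {0, 2/3, 1} is supported (the cases with known forms);
    requires r > 0 and 0 <= beta/r < 1.
    """
    if r <= 0:
        raise ValueError("growth rate r must be positive")
    x = beta / r
    if x >= 1:
        raise ValueError(
            f"beta/r = {x:.3g} >= 1: closed forms are only valid for slow "
            "fragmentation (beta/r < 1)"
        )
    if math.isclose(nu_F, 1.0):
        mu = 1.0 + 1.0 / (1.0 - x)
    elif math.isclose(nu_F, 2.0 / 3.0):
        mu = 5.0 / 3.0 + x
    elif math.isclose(nu_F, 0.0):
        mu = 1.0 + x / (1.0 + x)
    else:
        raise ValueError("closed forms exist only for nu_F in {0, 2/3, 1}")
    return ExponentPrediction(mu=mu, nu_F=nu_F, beta_over_r=x, slow_fragmentation=True)


def min_mu_bound(nu_F: float) -> float:
    """Lower bound mu > nu_F + 1 for a finite cluster-production rate."""
    if nu_F < 0:
        raise ValueError("nu_F must be >= 0")
    return nu_F + 1.0


def is_stationary(
    dist_t: SizeDistribution,
    dist_1p5t: SizeDistribution,
    tol: float = 0.05,
    min_clusters: int = 5,
) -> bool:
    """Has the size distribution stopped changing?

    Compares two (pooled) reverse CDFs taken at times t and 1.5 t and
    returns True iff ``|log10 P_t - log10 P_1.5t| < tol`` at every common
    support point backed by at least ``min_clusters`` clusters in both
    samples.  This is a quantitative stand-in for the visual
    "unchanged after 50% more simulation time" criterion.
    """
    s1, s2 = dist_t, dist_1p5t
    common = np.intersect1d(s1.support, s2.support)
    if common.size == 0:
        return False
    i1 = np.searchsorted(s1.support, common)
    i2 = np.searchsorted(s2.support, common)
    ok = (s1.tail_counts[i1] >= min_clusters) & (s2.tail_counts[i2] >= min_clusters)
    if not ok.any():
        # tiny samples (e.g. a single condensed cluster) never clear the
        # count filter; fall back to comparing the full common support
        ok = np.ones(common.size, dtype=bool)
    p1 = s1.cum_prob[i1][ok]
    p2 = s2.cum_prob[i2][ok]
    both_zero = (p1 == 0) & (p2 == 0)
    one_zero = (p1 == 0) != (p2 == 0)
    if one_zero.any():
        return False
    live = ~both_zero
    if not live.any():
        return True
    return bool(np.max(np.abs(np.log10(p1[live]) - np.log10(p2[live]))) < tol)


def aggregation_events_per_hour(
    event_logs: Sequence[EventLog], window: tuple[float, float]
) -> tuple[float, float]:
    """Mean and sample std of aggregation events per hour across replicates.

    ``window = (t0, t1)`` selects events with t0 < t <= t1; each
    replicate's count is divided by the window length.  The standard
    deviation uses the n-1 (sample) convention.
    """
    t_start, t_end = window
    if t_end <= t_start:
        raise ValueError("window must have positive length")
    if len(event_logs) < 1:
        raise ValueError("need at least one event log")
    rates = np.array(
        [log.count(AGGREGATION, window) / (t_end - t_start) for log in event_logs]
    )
    std = float(rates.std(ddof=1)) if rates.size > 1 else 0.0
    return float(rates.mean()), std


def aggregation_rate_bounds(
    typical_cluster_count: float,
    condensation_period_hr: float,
    expulsion_period_hr: float,
    clusters_grouped_per_expulsion: float,
) -> tuple[float, float]:
    """Order-of-magnitude bounds on the total aggregation event rate.

    Upper bound: condensing a typical population of M clusters into one
    takes of order M/2 pairwise merges; populations condensed into a
    single cluster are rare, so complete condensation happens at most
    once per ``condensation_period_hr``, capping the total event rate at
    (M/2) / condensation_period.

    Lower bound: if each large expulsion (every ``expulsion_period_hr``)
    sweeps up ``clusters_grouped_per_expulsion`` small clusters, that
    contributes clusters_grouped / period merges per hour.
    """
    if min(
        typical_cluster_count,
        condensation_period_hr,
        expulsion_period_hr,
        clusters_grouped_per_expulsion,
    ) <= 0:
        raise ValueError("all inputs must be positive")
    upper = (typical_cluster_count / 2.0) / condensation_period_hr
    lower = clusters_grouped_per_expulsion / expulsion_period_hr
    return lower, upper
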