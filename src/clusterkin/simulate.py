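"""Stochastic simulators for cluster-size kinetics.

Three schemes, matched to the three model variants:

* :func:`simulate_minimal` — fixed-step Poisson tau-leaping for the
  growth-fragmentation process (no aggregation, expulsion or capacity).
  Per step and per cluster, the numbers of cell additions and chipping
  events are Poisson draws at the start-of-step rates.
* :func:`simulate_full` — hybrid Gillespie for the full model:
  fragmentation, aggregation and expulsion fire as discrete events with
  exponential waiting times, while growth advances deterministically as
  logistic dynamics in Euler steps of at most 0.1 hr.  If the waiting time
  to the next reaction exceeds one doubling time ln(2)/r, growth is
  advanced by a doubling time and the propensities are recomputed before
  redrawing.
* :func:`simulate_pure_aggregation` — exact Gillespie for a finite system
  of purely aggregating particles (Marcus-Lushnikov process) from a
  monodisperse initial condition, stopped by default when the largest
  cluster first reaches a tenth of the mass (a practical finite-system
  gel-point criterion).

Stationarity drivers extend full-model runs by 50% of elapsed time until
the (pooled) size distribution stops changing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .analytics import is_stationary
from .core import (
    AGGREGATION,
    EXPULSION,
    FRAGMENTATION,
    ClusterPopulation,
    EventLog,
    KineticParams,
    aggregation_weights,
    expulsion_rates,
    fragmentation_rates,
    logistic_factor,
    total_aggregation_propensity,
)
from .distributions import SizeDistribution, pooled_reverse_cdf, reverse_cdf

__all__ = [
    "SimulationResult",
    "EnsembleResult",
    "simulate_minimal",
    "simulate_full",
    "FullModelSimulation",
    "simulate_pure_aggregation",
    "run_to_stationarity",
    "run_replicates_to_stationarity",
]

_EULER_H = 0.1  # max deterministic-growth Euler step (hr)


@dataclass
class SimulationResult:
    """Outcome of one stochastic run.

    Snapshots hold ceiled integer sizes (the observation convention);
    ``final_population`` keeps the internal real-valued state.
    """

    final_population: ClusterPopulation
    snapshots: list[tuple[float, ClusterPopulation]]
    event_log: EventLog | None
    seed: int | None
    params: KineticParams
    stationary: bool | None = None
    extinct: bool = False
    last_distributions: tuple[SizeDistribution, SizeDistribution] | None = None

    def final_sizes(self) -> np.ndarray:
        """Final cluster sizes, rounded up to integers."""
        return self.final_population.as_integer_sizes()


@dataclass
class EnsembleResult:
    """A set of replicate full-model runs extended to joint stationarity."""

    simulations: list["FullModelSimulation"]
    stationary: bool
    window: tuple[float, float]
    dist_previous: SizeDistribution | None
    dist_final: SizeDistribution | None

    def pooled_sizes(self) -> np.ndarray:
        return np.concatenate(
            [s.population().as_integer_sizes() for s in self.simulations if s.sizes.size]
        )

    def event_logs(self) -> list[EventLog]:
        return [s.log for s in self.simulations if s.log is not None]


def _snapshot(sizes: np.ndarray, t: float) -> tuple[float, ClusterPopulation]:
    return (t, ClusterPopulation(np.maximum(np.round(sizes), 1.0), t))


# ---------------------------------------------------------------------------
# Minimal model: Poisson tau-leaping
# ---------------------------------------------------------------------------


def simulate_minimal(
    params: KineticParams,
    initial: ClusterPopulation,
    t_max: float,
    tau: float = 0.1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    snapshot_times: Sequence[float] | None = None,
) -> SimulationResult:
    """Tau-leap the growth-fragmentation process to ``t_max``.

    Within each leap of length ``tau``, every cluster of size n receives
    Poisson(r*n*tau) new cells and sheds Poisson(beta*n**nu_F*tau) single
    cells (only clusters with n >= 2 fragment), with both counts drawn at
    the start-of-step state.  Growth is applied before fragmentation, and
    fragmentation draws are truncated at n-1 so no cluster drops below
    size 1.  Each shed cell becomes a new size-1 cluster; fragmentation
    conserves total cell number.
    """
    if params.alpha != 0 or params.lambda_ != 0:
        raise ValueError(
            "simulate_minimal handles the growth-fragmentation process only; "
            "aggregation/expulsion rates must be zero (use simulate_full)"
        )
    if params.K is not None:
        raise ValueError("the minimal model has no carrying capacity; set K=None")
    if tau <= 0:
        raise ValueError("tau must be positive")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    sizes = np.asarray(initial.sizes, dtype=float).copy()
    t = initial.time
    snaps: list[tuple[float, ClusterPopulation]] = []
    pending = sorted(snapshot_times) if snapshot_times else []
    si = 0

    n_steps = int(round((t_max - t) / tau))
    for _ in range(n_steps):
        frag_rate = params.beta * np.power(sizes, params.nu_F)
        frag_rate[sizes < 2] = 0.0
        growth = rng.poisson(params.r * sizes * tau)
        frags = rng.poisson(frag_rate * tau)
        sizes = sizes + growth
        # cannot chip a cluster below one cell within a single leap
        frags = np.minimum(frags, (sizes - 1).astype(np.int64))
        n_new = int(frags.sum())
        sizes = sizes - frags
        if n_new:
            sizes = np.concatenate([sizes, np.ones(n_new)])
        t += tau
        while si < len(pending) and pending[si] <= t + 1e-9:
            snaps.append(_snapshot(sizes, t))
            si += 1

    final = ClusterPopulation(sizes, t)
    return SimulationResult(
        final_population=final,
        snapshots=snaps,
        event_log=None,
        seed=seed,
        params=params,
    )


# ---------------------------------------------------------------------------
# Full model: hybrid Gillespie with deterministic logistic growth
# ---------------------------------------------------------------------------


class FullModelSimulation:
    """Resumable hybrid-Gillespie run of the full model.

    Exposes ``run_until(t)`` so stationarity drivers can extend a run
    without restarting it.  All randomness comes from ``rng``; the same
    seed and parameters reproduce the event log exactly.
    """

    def __init__(
        self,
        params: KineticParams,
        initial: ClusterPopulation,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
        record_events: bool = True,
    ) -> None:
        self.params = params
        self.sizes = np.asarray(initial.sizes, dtype=float).copy()
        self.t = float(initial.time)
        self.rng = rng if rng is not None else np.random.default_rng(seed)
        self.seed = seed
        self.log: EventLog | None = EventLog() if record_events else None
        self.extinction_time: float | None = None

    def population(self) -> ClusterPopulation:
        return ClusterPopulation(self.sizes.copy(), self.t)

    # -- deterministic growth -------------------------------------------

    def _grow(self, dt: float) -> None:
        """Advance logistic growth by ``dt`` in Euler steps of <= 0.1 hr."""
        p = self.params
        if dt <= 0:
            return
        if p.r > 0 and self.sizes.size:
            remaining = dt
            while remaining > 1e-12:
                h = min(_EULER_H, remaining)
                L = logistic_factor(self.sizes.sum(), p.K)
                if L <= 0:
                    break
                self.sizes *= 1.0 + p.r * L * h
                remaining -= h
        self.t += dt

    # -- Gillespie loop --------------------------------------------------

    def run_until(self, t_end: float) -> None:
        p = self.params
        doubling = math.log(2.0) / p.r if p.r > 0 else math.inf
        while self.t < t_end - 1e-12:
            if self.sizes.size == 0:
                self.t = t_end
                return
            pop = ClusterPopulation(self.sizes, self.t)
            fr = fragmentation_rates(pop, p)
            er = expulsion_rates(pop, p)
            agg = total_aggregation_propensity(pop, p)
            sum_f = float(fr.sum())
            sum_e = float(er.sum())
            a0 = sum_f + sum_e + agg
            if a0 <= 0.0:
                if p.r > 0 and logistic_factor(self.sizes.sum(), p.K) > 0:
                    self._grow(min(doubling, t_end - self.t))
                    continue
                self.t = t_end
                return
            wait = self.rng.exponential(1.0 / a0)
            if wait > doubling:
                # growth catch-up, then recompute propensities
                self._grow(min(doubling, t_end - self.t))
                continue
            if self.t + wait > t_end:
                self._grow(t_end - self.t)
                return
            self._grow(wait)
            self._fire(fr, sum_f, agg, er, a0)

    def _fire(self, fr, sum_f, agg, er, a0) -> None:
        """Execute one reaction chosen from the frozen propensities."""
        u = self.rng.uniform(0.0, a0)
        if u < sum_f:
            i = int(np.searchsorted(np.cumsum(fr), u, side="right"))
            i = min(i, self.sizes.size - 1)
            if self.log is not None:
                self.log.append(self.t, FRAGMENTATION, self.sizes[i])
            self.sizes[i] -= 1.0
            self.sizes = np.append(self.sizes, 1.0)
        elif u < sum_f + agg:
            w = aggregation_weights(self.sizes, self.params.nu_A)
            c = np.cumsum(w)
            i = int(np.searchsorted(c, self.rng.uniform(0.0, c[-1]), side="right"))
            i = min(i, self.sizes.size - 1)
            w[i] = 0.0
            c = np.cumsum(w)
            j = int(np.searchsorted(c, self.rng.uniform(0.0, c[-1]), side="right"))
            j = min(j, self.sizes.size - 1)
            if self.log is not None:
                self.log.append(self.t, AGGREGATION, self.sizes[i], self.sizes[j])
            self.sizes[i] += self.sizes[j]
            self.sizes = np.delete(self.sizes, j)
        else:
            v = u - sum_f - agg
            i = int(np.searchsorted(np.cumsum(er), v, side="right"))
            i = min(i, self.sizes.size - 1)
            if self.log is not None:
                self.log.append(self.t, EXPULSION, self.sizes[i])
            self.sizes = np.delete(self.sizes, i)
            if self.sizes.size == 0 and self.extinction_time is None:
                self.extinction_time = self.t


def simulate_full(
    params: KineticParams,
    initial: ClusterPopulation,
    t_max: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    snapshot_times: Sequence[float] | None = None,
    record_events: bool = True,
) -> SimulationResult:
    """Run the full model (growth, fragmentation, aggregation, expulsion)."""
    if t_max <= initial.time:
        raise ValueError("t_max must exceed the initial time")
    if initial.n_clusters == 0:
        raise ValueError("initial population must be nonempty")
    sim = FullModelSimulation(params, initial, seed=seed, rng=rng, record_events=record_events)
    snaps: list[tuple[float, ClusterPopulation]] = []
    for ts in sorted(snapshot_times or []):
        if ts <= t_max:
            sim.run_until(ts)
            snaps.append(_snapshot(sim.sizes, sim.t))
    sim.run_until(t_max)
    return SimulationResult(
        final_population=sim.population(),
        snapshots=snaps,
        event_log=sim.log,
        seed=seed,
        params=params,
        extinct=sim.sizes.size == 0,
    )


# ---------------------------------------------------------------------------
# Pure aggregation (Marcus-Lushnikov) with gel-point stopping
# ---------------------------------------------------------------------------


def simulate_pure_aggregation(
    n_monomers: int,
    alpha: float,
    nu_A: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    gel_mass_fraction: float | None = 0.1,
    t_max: float = math.inf,
    record_events: bool = False,
) -> SimulationResult:
    """Gillespie simulation of pure aggregation from n monomers.

    Merges fire with the homogeneous kernel alpha*(n*m)**nu_A.  By
    default the run stops when the largest cluster first reaches
    ``gel_mass_fraction`` = 0.1 of the total mass.  For kernels with
    nu_A >= 1/2 this captures the finite-system gelation transition
    (for 10^4 monomers the gel emerges at roughly n**(2/3) ~ 5% of the
    mass), where the size distribution decays as ~ n**-5/2; stopping much
    later samples the post-gel regime, whose depleted sol makes the
    apparent decay steeper.  Mass is conserved exactly; each merge
    removes one cluster, so full condensation takes exactly
    n_monomers - 1 events.
    """
    if n_monomers < 2:
        raise ValueError("need at least 2 monomers to aggregate")
    if alpha <= 0:
        raise ValueError("aggregation rate alpha must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    params = KineticParams(alpha=alpha, nu_A=nu_A)
    sizes = np.ones(n_monomers, dtype=float)
    total = float(n_monomers)
    t = 0.0
    log: EventLog | None = EventLog() if record_events else None
    gel_target = (
        gel_mass_fraction * total if gel_mass_fraction is not None else math.inf
    )
    while sizes.size >= 2:
        w = np.power(sizes, nu_A)
        s1 = w.sum()
        s2 = (w * w).sum()
        a0 = 0.5 * alpha * (s1 * s1 - s2)
        t_next = t + rng.exponential(1.0 / a0)
        if t_next > t_max:
            t = t_max
            break
        t = t_next
        c = np.cumsum(w)
        i = int(np.searchsorted(c, rng.uniform(0.0, c[-1]), side="right"))
        i = min(i, sizes.size - 1)
        w[i] = 0.0
        c = np.cumsum(w)
        j = int(np.searchsorted(c, rng.uniform(0.0, c[-1]), side="right"))
        j = min(j, sizes.size - 1)
        if log is not None:
            log.append(t, AGGREGATION, sizes[i], sizes[j])
        sizes[i] += sizes[j]
        sizes = np.delete(sizes, j)
        if sizes.max() >= gel_target:
            break
    return SimulationResult(
        final_population=ClusterPopulation(sizes, t),
        snapshots=[],
        event_log=log,
        seed=seed,
        params=params,
    )


# ---------------------------------------------------------------------------
# Stationarity drivers (extend by 50% until the distribution stops moving)
# ---------------------------------------------------------------------------


def run_to_stationarity(
    params: KineticParams,
    initial: ClusterPopulation,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    t_init: float = 24.0,
    tol: float = 0.1,
    min_clusters: int = 5,
    max_time: float = 600.0,
    record_events: bool = True,
) -> SimulationResult:
    """Extend a single full-model run until its size distribution is stationary.

    Runs to ``t_init``, then repeatedly extends by 50% of elapsed time,
    comparing the (ceiled) size distribution before and after each
    extension.  Returns the run flagged ``stationary`` (never raises on
    non-convergence; the last two distributions are attached for
    diagnosis).  An emptied population is an absorbing state: it is
    flagged both ``extinct`` and ``stationary``.
    """
    if params.K is None and params.r > 0:
        raise ValueError("stationarity requires a finite carrying capacity K")
    sim = FullModelSimulation(params, initial, seed=seed, rng=rng, record_events=record_events)
    sim.run_until(t_init)
    t = t_init
    stationary = False
    d_prev = d_new = None
    while True:
        if sim.sizes.size == 0:
            return SimulationResult(
                final_population=sim.population(),
                snapshots=[],
                event_log=sim.log,
                seed=seed,
                params=params,
                stationary=True,
                extinct=True,
            )
        d_prev = reverse_cdf(sim.population().as_integer_sizes(), source=f"t={t:g}")
        t_new = 1.5 * t
        sim.run_until(t_new)
        if sim.sizes.size:
            d_new = reverse_cdf(
                sim.population().as_integer_sizes(), source=f"t={t_new:g}"
            )
            if is_stationary(d_prev, d_new, tol=tol, min_clusters=min_clusters):
                stationary = True
                t = t_new
                break
        t = t_new
        if t >= max_time:
            break
    return SimulationResult(
        final_population=sim.population(),
        snapshots=[],
        event_log=sim.log,
        seed=seed,
        params=params,
        stationary=stationary,
        extinct=sim.sizes.size == 0,
        last_distributions=(d_prev, d_new) if d_new is not None else None,
    )


def run_replicates_to_stationarity(
    params: KineticParams,
    initial: ClusterPopulation,
    n_replicates: int,
    seed: int | None = None,
    t_init: float = 24.0,
    tol: float = 0.1,
    min_clusters: int = 5,
    max_time: float = 600.0,
    record_events: bool = True,
) -> EnsembleResult:
    """Run replicates jointly until the *pooled* distribution is stationary.

    The pooled reverse CDF across replicates is the quantity the model's
    stationary distributions are defined on; all replicates are extended
    in lockstep by 50% of elapsed time until it stops changing.  The
    returned ``window`` is the final extension interval, suitable for
    event-rate statistics at stationarity.
    """
    if params.K is None and params.r > 0:
        raise ValueError("stationarity requires a finite carrying capacity K")
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    sims = [
        FullModelSimulation(
            params, initial, rng=np.random.default_rng(s), record_events=record_events
        )
        for s in streams
    ]
    for s in sims:
        s.run_until(t_init)
    t = t_init
    stationary = False
    d_prev = d_new = None
    while True:
        live = [s.population().as_integer_sizes() for s in sims if s.sizes.size]
        if not live:
            return EnsembleResult(sims, True, (t, t), None, None)
        d_prev = pooled_reverse_cdf(live, source=f"t={t:g}")
        t_new = 1.5 * t
        for s in sims:
            s.run_until(t_new)
        live = [s.population().as_integer_sizes() for s in sims if s.sizes.size]
        if live:
            d_new = pooled_reverse_cdf(live, source=f"t={t_new:g}")
            if is_stationary(d_prev, d_new, tol=tol, min_clusters=min_clusters):
                stationary = True
                window = (t, t_new)
                t = t_new
                break
        window = (t, t_new)
        t = t_new
        if t >= max_time:
            break
    return EnsembleResult(sims, stationary, window, d_prev, d_new)


def stationary_aggregation_rate(
    ensemble: EnsembleResult,
    window_length: float = 60.0,
    min_alive_fraction: float = 0.2,
) -> tuple[float, float, int]:
    """Aggregation events per hour at stationarity, averaged over replicates.

    Extends every replicate of a stationary ensemble so the measurement
    window starting at the beginning of the final stationarity check
    spans ``window_length`` hours (long enough to average over the
    expulsion-regrowth cycles of capacity-limited populations).  Each
    replicate's event count is normalized by the time it was alive inside
    the window; replicates alive for less than ``min_alive_fraction`` of
    the window are excluded, since their rate estimate is dominated by a
    single cycle fragment.  Returns (mean, sample std, replicates used).
    """
    w_start = ensemble.window[0]
    w_end = max(ensemble.window[1], w_start + window_length)
    for sim in ensemble.simulations:
        sim.run_until(w_end)
    rates = []
    for sim in ensemble.simulations:
        if sim.log is None:
            raise ValueError("event recording was disabled for this ensemble")
        t_end = w_end if sim.extinction_time is None else min(sim.extinction_time, w_end)
        alive = t_end - w_start
        if alive < min_alive_fraction * (w_end - w_start):
            continue
        rates.append(sim.log.count(AGGREGATION, (w_start, t_end)) / alive)
    if len(rates) < 2:
        raise ValueError("too few replicates alive in the measurement window")
    rates = np.asarray(rates)
    return float(rates.mean()), float(rates.std(ddof=1)), int(rates.size)
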