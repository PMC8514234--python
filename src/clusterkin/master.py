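"""Deterministic (mean-field) cluster-density dynamics.

In the infinite-system limit the list of individual clusters is replaced
by densities ``c_n`` of clusters of each integer size n, which evolve as

    dc_n/dt = (alpha/2) * sum_{m=1}^{n-1} [(n-m) m]**nu_A c_{n-m} c_m
              - alpha * n**nu_A c_n * sum_m m**nu_A c_m
              + r (1 - N/K) [(n-1) c_{n-1} - n c_n]
              - lambda * n**nu_E c_n
              + beta (1 - N/K) [(n+1)**nu_F c_{n+1} - n**nu_F c_n
                                + delta_{n,1} sum_{m>=2} m**nu_F c_m],

with N = sum n c_n.  The five terms are: aggregation gain and loss,
logistic growth advection, expulsion loss, and single-cell fragmentation
(chipping).  The fragmentation loss and monomer source only involve
clusters of size >= 2, matching the stochastic simulators, which makes
the chipping terms conserve mass exactly.

The system is integrated by forward Euler on a bounded grid n in
[1, n_max] with reflecting boundary conditions at n_max: growth advection
out of the top bin is suppressed and aggregation events that would exceed
n_max deposit their product in the top bin.  With a carrying capacity the
natural grid is n_max = K; without one, n_max = ceil(exp(r * t_max)), the
expected final population size.

The aggregation gain is a discrete self-convolution of the vector
``n**nu_A * c_n`` (the product kernel factorizes) and is evaluated with an
FFT in O(n_max log n_max); a direct O(n_max^2) reference path is kept for
testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .core import ClusterPopulation, KineticParams, logistic_factor
from .distributions import SizeDistribution

__all__ = ["DensityGrid", "rhs", "integrate", "integrate_to_stationarity", "default_n_max"]


@dataclass
class DensityGrid:
    """Cluster densities c_n on the integer size grid n = 1 .. n_max."""

    c: np.ndarray
    params: KineticParams
    time: float = 0.0

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float).ravel()
        if self.c.size < 2:
            raise ValueError("grid needs at least sizes 1 and 2")
        if self.c.min() < 0:
            raise ValueError("densities must be nonnegative")

    @property
    def n_max(self) -> int:
        return self.c.size

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(1, self.c.size + 1)

    @property
    def total_cells(self) -> float:
        """N = sum n * c_n."""
        return float(self.sizes @ self.c)

    @property
    def n_clusters(self) -> float:
        """M = sum c_n."""
        return float(self.c.sum())

    @classmethod
    def from_monomers(
        cls, params: KineticParams, n_monomers: float, n_max: int, time: float = 0.0
    ) -> "DensityGrid":
        c = np.zeros(n_max)
        c[0] = n_monomers
        return cls(c, params, time)

    @classmethod
    def from_population(
        cls, params: KineticParams, population: ClusterPopulation, n_max: int
    ) -> "DensityGrid":
        c = np.zeros(n_max)
        sizes = population.as_integer_sizes()
        if sizes.max() > n_max:
            raise ValueError("initial population exceeds the size grid")
        np.add.at(c, sizes - 1, 1.0)
        return cls(c, params, population.time)

    def to_size_distribution(self, density_floor: float = 0.0) -> SizeDistribution:
        """Reverse CDF P(size > n) implied by the densities.

        ``density_floor`` drops trailing support whose tail density (in
        clusters) falls below the floor, which keeps log-scale comparisons
        away from meaninglessly small mean-field tails.
        """
        M = self.n_clusters
        if M <= 0:
            raise ValueError("empty density grid")
        tail = np.maximum(M - np.cumsum(self.c), 0.0)
        keep = self.c > 0
        if density_floor > 0:
            keep &= tail >= density_floor
            if not keep.any():
                raise ValueError("density floor removed the whole support")
        support = self.sizes[keep]
        return SizeDistribution(
            support=support,
            cum_prob=tail[keep] / M,
            counts=self.c[keep],
            n_total=max(int(round(M)), 1),
            source="master-equation",
        )


def default_n_max(params: KineticParams, t_max: float) -> int:
    """K when a carrying capacity is set, else ceil(exp(r * t_max))."""
    if params.K is not None:
        return int(params.K)
    return int(math.ceil(math.exp(params.r * t_max)))


def _powers(params: KineticParams, n_max: int):
    n = np.arange(1, n_max + 1, dtype=float)
    w_agg = n**params.nu_A
    f_frag = n**params.nu_F
    f_frag[0] = 0.0  # size-1 clusters cannot chip
    e_exp = n**params.nu_E
    return n, w_agg, f_frag, e_exp


def _rhs_core(
    c: np.ndarray,
    params: KineticParams,
    n: np.ndarray,
    w_agg: np.ndarray,
    f_frag: np.ndarray,
    e_exp: np.ndarray,
    method: str = "fft",
) -> np.ndarray:
    p = params
    out = np.zeros_like(c)
    N = float(n @ c)
    L = logistic_factor(N, p.K)

    # aggregation
    if p.alpha > 0:
        w = w_agg * c
        if method == "fft":
            conv = fftconvolve(w, w)
        elif method == "direct":
            conv = np.convolve(w, w)
        else:
            raise ValueError("method must be 'fft' or 'direct'")
        gain = np.zeros_like(c)
        # conv[k] collects pairs of sizes summing to k + 2
        gain[1:] = 0.5 * p.alpha * conv[: c.size - 1]
        # reflecting boundary: products larger than n_max land in the top bin
        gain[-1] += 0.5 * p.alpha * conv[c.size - 1 :].sum()
        out += gain
        out -= p.alpha * w * w.sum()

    # logistic growth advection (outflux suppressed at the top bin)
    if p.r > 0 and L > 0:
        flux = n * c  # n c_n
        adv = np.zeros_like(c)
        adv[1:] += flux[:-1]
        adv -= flux
        adv[-1] += flux[-1]  # reflecting: no advection out of n_max
        out += p.r * L * adv

    # expulsion
    if p.lambda_ > 0:
        out -= p.lambda_ * e_exp * c

    # fragmentation (chipping): remnant moves down one bin, monomer source
    if p.beta > 0 and L > 0:
        fc = f_frag * c
        frag = np.zeros_like(c)
        frag[:-1] += fc[1:]  # gain of size-n remnants from size n+1
        frag -= fc  # loss of fragmenting clusters
        frag[0] += fc.sum()  # one new monomer per chipping event
        out += p.beta * L * frag

    return out


def rhs(grid: DensityGrid, method: str = "fft") -> np.ndarray:
    """Time derivative dc/dt of the density grid."""
    n, w_agg, f_frag, e_exp = _powers(grid.params, grid.n_max)
    return _rhs_core(grid.c, grid.params, n, w_agg, f_frag, e_exp, method=method)


def integrate(
    grid: DensityGrid,
    t_max: float,
    dt: float = 1e-3,
    method: str = "fft",
    snapshot_times=None,
) -> tuple[DensityGrid, list[tuple[float, np.ndarray]]]:
    """Forward-Euler integration up to ``t_max``.

    Returns the final grid and snapshots of ``c`` at the requested times.
    Negative densities beyond a small tolerance abort the integration with
    an error naming the offending step size; tiny negative round-off is
    clipped to zero.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n, w_agg, f_frag, e_exp = _powers(grid.params, grid.n_max)
    c = grid.c.copy()
    t = grid.time
    snaps: list[tuple[float, np.ndarray]] = []
    pending = sorted(snapshot_times) if snapshot_times else []
    si = 0
    n_steps = int(round((t_max - t) / dt))
    neg_tol = 1e-9
    for k in range(n_steps):
        c = c + dt * _rhs_core(c, grid.params, n, w_agg, f_frag, e_exp, method=method)
        cmin = c.min()
        if cmin < 0:
            if cmin < -neg_tol * max(1.0, c.max()):
                raise RuntimeError(
                    f"Euler integration unstable at t={t + (k + 1) * dt:.4f} hr with "
                    f"dt={dt}: negative density {cmin:.3e}; reduce dt"
                )
            c[c < 0] = 0.0
        while si < len(pending) and pending[si] <= t + (k + 1) * dt + 1e-9:
            snaps.append((t + (k + 1) * dt, c.copy()))
            si += 1
    return DensityGrid(c, grid.params, t + n_steps * dt), snaps


def _log_tail_close(
    g1: DensityGrid, g2: DensityGrid, tol: float, density_floor: float
) -> bool:
    t1 = np.maximum(g1.n_clusters - np.cumsum(g1.c), 0.0)
    t2 = np.maximum(g2.n_clusters - np.cumsum(g2.c), 0.0)
    p1 = t1 / g1.n_clusters
    p2 = t2 / g2.n_clusters
    keep = (t1 >= density_floor) & (t2 >= density_floor)
    if not keep.any():
        return False
    return bool(
        np.max(np.abs(np.log10(p1[keep]) - np.log10(p2[keep]))) < tol
    )


def integrate_to_stationarity(
    grid: DensityGrid,
    dt: float = 1e-3,
    t_init: float = 24.0,
    tol: float = 0.05,
    density_floor: float = 0.05,
    max_time: float = 600.0,
    method: str = "fft",
) -> tuple[DensityGrid, bool]:
    """Integrate until the implied reverse CDF is unchanged after +50% time."""
    cur, _ = integrate(grid, t_init, dt=dt, method=method)
    t = t_init
    while True:
        t_new = 1.5 * t
        nxt, _ = integrate(cur, t_new, dt=dt, method=method)
        if _log_tail_close(cur, nxt, tol, density_floor):
            return nxt, True
        cur = nxt
        t = t_new
        if t >= max_time:
            return cur, False
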