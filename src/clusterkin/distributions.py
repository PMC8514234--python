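"""Empirical cluster-size distributions.

The primary descriptive statistic is the reverse cumulative distribution

    P(size > n) = (# clusters with size > n) / (total # clusters),

evaluated at every observed integer size, per host or pooled across hosts.
Log-binned probability densities are provided as a secondary view; the
cumulative form sidesteps bin-width choices and is what the analyses here
fit against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SizeDistribution",
    "reverse_cdf",
    "pooled_reverse_cdf",
    "log_binned_density",
]


@dataclass
class SizeDistribution:
    """Reverse cumulative distribution of cluster sizes.

    ``support`` holds the sorted unique sizes; ``cum_prob[i]`` is
    P(size > support[i]).  ``counts[i]`` is the number of clusters of size
    exactly ``support[i]``, so tail counts are recoverable for
    support-filtering (e.g. the stationarity check ignores sizes backed by
    fewer than 5 clusters).
    """

    support: np.ndarray
    cum_prob: np.ndarray
    counts: np.ndarray
    n_total: int
    source: str = "pooled"

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support)
        self.cum_prob = np.asarray(self.cum_prob, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.support) <= 0):
            raise ValueError("support must be strictly increasing")
        if np.any(self.cum_prob < -1e-12) or np.any(self.cum_prob > 1 + 1e-12):
            raise ValueError("cumulative probabilities must lie in [0, 1]")
        if np.any(np.diff(self.cum_prob) > 1e-12):
            raise ValueError("P(size>n) must be nonincreasing in n")

    @property
    def tail_counts(self) -> np.ndarray:
        """Number of clusters strictly larger than each support point."""
        return np.round(self.cum_prob * self.n_total).astype(np.int64)

    def evaluate(self, n) -> np.ndarray:
        """P(size > n) at arbitrary n (step function; P(size>0) = 1)."""
        n = np.atleast_1d(np.asarray(n, dtype=float))
        # P is the value at the largest support point <= n; below the
        # smallest observed size every cluster is larger, so P = 1
        pos = np.searchsorted(self.support, n, side="right") - 1
        out = np.ones_like(n, dtype=float)
        inside = pos >= 0
        out[inside] = self.cum_prob[pos[inside]]
        return out if out.size > 1 else float(out[0])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"n": self.support, "P_gt_n": self.cum_prob, "count": self.counts}
        )


def _from_counts(support: np.ndarray, counts: np.ndarray, source: str) -> SizeDistribution:
    n_total = int(counts.sum())
    # clusters strictly greater than each support point
    gt = n_total - np.cumsum(counts)
    return SizeDistribution(
        support=support,
        cum_prob=gt / n_total,
        counts=counts,
        n_total=n_total,
        source=source,
    )


def reverse_cdf(sizes: Sequence[float] | np.ndarray, source: str = "host") -> SizeDistribution:
    """Reverse cumulative distribution of one host's cluster sizes."""
    sizes = np.asarray(sizes)
    if sizes.size == 0:
        raise ValueError("cannot compute a size distribution from no clusters")
    if sizes.min() < 1:
        raise ValueError("cluster sizes must be >= 1")
    support, counts = np.unique(sizes, return_counts=True)
    return _from_counts(support, counts, source)


def pooled_reverse_cdf(
    per_host_sizes: Iterable[Sequence[float] | np.ndarray], source: str = "pooled"
) -> SizeDistribution:
    """Pool sizes across hosts/replicates and compute the reverse CDF.

    Counts are accumulated host by host and normalized once at the end, so
    arbitrarily many replicates can be streamed without concatenating their
    size lists.  The result is identical to ``reverse_cdf`` on the
    concatenation, and is invariant to host order.
    """
    acc: dict = {}
    n_hosts = 0
    for sizes in per_host_sizes:
        sizes = np.asarray(sizes)
        if sizes.size == 0:
            continue
        if sizes.min() < 1:
            raise ValueError("cluster sizes must be >= 1")
        support, counts = np.unique(sizes, return_counts=True)
        for s, c in zip(support.tolist(), counts.tolist()):
            acc[s] = acc.get(s, 0) + c
        n_hosts += 1
    if not acc:
        raise ValueError("no clusters in any host")
    support = np.array(sorted(acc))
    counts = np.array([acc[s] for s in support])
    return _from_counts(support, counts, source)


def log_binned_density(
    sizes: Sequence[float] | np.ndarray, bin_width_decades: float = 0.4
) -> tuple[np.ndarray, np.ndarray]:
    """Probability density from logarithmically spaced bins.

    Bins start at n = 1 with edges at ``10**(k * bin_width_decades)``.
    Counts are divided by (total count * linear bin width), i.e. the
    density is probability per unit size, so a p(n) ~ n**-2 sample shows a
    slope of -2 on log-log axes.

    Returns (geometric bin centers, densities) for all bins up to the one
    containing the largest size.
    """
    if bin_width_decades <= 0:
        raise ValueError("bin width must be positive")
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("cannot bin an empty sample")
    n_bins = int(np.ceil(np.log10(sizes.max()) / bin_width_decades)) + 1
    edges = 10.0 ** (bin_width_decades * np.arange(n_bins + 1))
    counts, _ = np.histogram(sizes, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    density = counts / (sizes.size * widths)
    return centers, density
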