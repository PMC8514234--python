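"""Synthetic cohort-style cluster-size tables and table I/O.

Imaging studies of mono-associated larval zebrafish yield, per host, a
list of bacterial cluster sizes (cell counts).  This module generates
tables with the same statistical structure — a power-law bulk with
exponent near 2, a strain-dependent plateau of system-scale clusters, and
fish-to-fish variation around a few hundred clusters per host — so the
whole analysis pipeline is testable without any experimental download.
The table schema is CSV with columns ``strain, fish_id, cluster_size``,
one row per cluster.

The large-size plateau is injected mechanistically: a random subset of a
host's clusters is condensed into one large cluster carrying a target
fraction of the host's cells, mimicking the aggregation-driven gel-like
condensation of the kinetic model rather than mixing in a second
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ClusterPopulation, KineticParams
from .powerlaw import sample_discrete_power_law

__all__ = [
    "CohortSpec",
    "STRAIN_PRESETS",
    "generate_cohort",
    "simulate_cohort_from_model",
    "read_cluster_table",
    "write_cluster_table",
]

REQUIRED_COLUMNS = ("strain", "fish_id", "cluster_size")


@dataclass
class CohortSpec:
    """Parameters of one synthetic strain cohort.

    ``clusters_per_fish_mean``/``_sd`` set a lognormal cluster count per
    host (observed cohorts average a couple hundred clusters per fish with
    comparable spread); ``mu`` is the density exponent of the power-law
    bulk; ``plateau_mass_fraction`` is the expected fraction of a host's
    cells condensed into its single largest cluster.
    """

    strain: str = "synthetic"
    n_fish: int = 6
    clusters_per_fish_mean: float = 244.0
    clusters_per_fish_sd: float = 182.0
    mu: float = 2.0
    plateau_mass_fraction: float = 0.0
    max_size: int = 100_000

    def __post_init__(self) -> None:
        if self.mu <= 1:
            raise ValueError("mu must exceed 1 for a normalizable power law")
        if not 0 <= self.plateau_mass_fraction < 1:
            raise ValueError("plateau_mass_fraction must lie in [0, 1)")
        if self.clusters_per_fish_mean <= 0:
            raise ValueError("clusters_per_fish_mean must be positive")
        if self.n_fish < 1:
            raise ValueError("need at least one fish")


# Illustrative presets keyed by the eight strains with published cohort
# sizes (fish counts and mean clusters-per-fish match the real cohorts;
# exponents and plateau fractions are synthetic stand-ins, chosen to span
# the qualitative range from straight power laws to strong plateaus).
STRAIN_PRESETS: dict[str, CohortSpec] = {
    "Aeromonas-ZOR0001": CohortSpec("Aeromonas-ZOR0001", 6, 74, 50, 2.1, 0.1),
    "Aeromonas-ZOR0002": CohortSpec("Aeromonas-ZOR0002", 6, 317, 150, 2.0, 0.0),
    "Enterobacter-ZOR0014": CohortSpec("Enterobacter-ZOR0014", 18, 200, 120, 2.2, 0.4),
    "Plesiomonas-ZOR0011": CohortSpec("Plesiomonas-ZOR0011", 3, 74, 40, 2.0, 0.2),
    "Pseudomonas-ZWU0006": CohortSpec("Pseudomonas-ZWU0006", 6, 22, 12, 2.1, 0.2),
    "Vibrio-ZOR0036": CohortSpec("Vibrio-ZOR0036", 6, 405, 200, 2.0, 0.3),
    "Vibrio-ZWU0020-dmot": CohortSpec("Vibrio-ZWU0020-dmot", 11, 535, 250, 1.9, 0.1),
    "Vibrio-ZWU0020-dche": CohortSpec("Vibrio-ZWU0020-dche", 11, 323, 150, 1.9, 0.1),
}


def _lognormal_count(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Integer draw from a lognormal with the given mean and spread."""
    if sd <= 0:
        return max(1, int(round(mean)))
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu_log = np.log(mean) - sigma2 / 2.0
    return max(1, int(round(rng.lognormal(mu_log, np.sqrt(sigma2)))))


def generate_cohort(
    spec: CohortSpec, seed: int | None = None, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Generate one strain's cohort table.

    Per fish: draw a cluster count, draw sizes from the discrete power law
    with exponent ``spec.mu`` (truncated at ``spec.max_size``), then, if a
    plateau is requested, condense a random subset of clusters into a
    single large one holding ``plateau_mass_fraction`` of the host's
    cells.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for fish in range(1, spec.n_fish + 1):
        m = _lognormal_count(rng, spec.clusters_per_fish_mean, spec.clusters_per_fish_sd)
        sizes = sample_discrete_power_law(spec.mu, m, rng=rng, x_max=spec.max_size)
        if spec.plateau_mass_fraction > 0 and sizes.size > 1:
            target = spec.plateau_mass_fraction * sizes.sum()
            order = rng.permutation(sizes.size)
            csum = np.cumsum(sizes[order])
            k = int(np.searchsorted(csum, target)) + 1
            k = min(max(k, 2), sizes.size)  # merge at least two clusters
            merged = int(sizes[order[:k]].sum())
            sizes = np.concatenate([sizes[order[k:]], [merged]])
        rows.append(
            pd.DataFrame(
                {
                    "strain": spec.strain,
                    "fish_id": fish,
                    "cluster_size": np.asarray(sizes, dtype=np.int64),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_cohort_from_model(
    params: KineticParams,
    n_fish: int,
    seed: int | None = None,
    t_max: float = 24.0,
    n_initial_cells: int = 10,
    strain: str = "simulated",
    to_stationarity: bool = False,
) -> pd.DataFrame:
    """Run one full-model simulation per fish and tabulate final sizes.

    Bridges simulator output into the cohort table schema so simulated
    and observed cohorts flow through the same distribution and fitting
    code.  Fish whose population went extinct contribute no rows.
    """
    from .simulate import run_to_stationarity, simulate_full

    streams = np.random.SeedSequence(seed).spawn(n_fish)
    rows = []
    for fish, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        initial = ClusterPopulation.single_cells(n_initial_cells)
        if to_stationarity:
            result = run_to_stationarity(params, initial, rng=rng, record_events=False)
        else:
            result = simulate_full(
                params, initial, t_max=t_max, rng=rng, record_events=False
            )
        sizes = result.final_sizes()
        if sizes.size:
            rows.append(
                pd.DataFrame(
                    {"strain": strain, "fish_id": fish, "cluster_size": sizes}
                )
            )
    if not rows:
        return pd.DataFrame(
            {"strain": pd.Series(dtype=str), "fish_id": pd.Series(dtype=np.int64),
             "cluster_size": pd.Series(dtype=np.int64)}
        )
    return pd.concat(rows, ignore_index=True)


def write_cluster_table(table: pd.DataFrame, path) -> None:
    """Write a validated cohort table as CSV (schema: strain,fish_id,cluster_size)."""
    _validate_table(table)
    table.to_csv(path, index=False, columns=list(REQUIRED_COLUMNS))


def read_cluster_table(path) -> pd.DataFrame:
    """Read and validate a cohort table.

    Non-integer sizes are rounded up to the nearest integer with a
    warning (the convention used for imaging-derived cell counts);
    nonpositive sizes or missing columns are errors that name the
    offending rows.
    """
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cluster table is missing required columns: {missing}")
    sizes = table["cluster_size"].to_numpy()
    bad = np.flatnonzero(~(sizes > 0))
    if bad.size:
        raise ValueError(
            f"nonpositive cluster sizes at rows {bad.tolist()[:20]}"
            + (" ..." if bad.size > 20 else "")
        )
    if not np.allclose(sizes, np.round(sizes)):
        frac = np.flatnonzero(sizes != np.ceil(sizes))
        warnings.warn(
            f"{frac.size} non-integer cluster sizes rounded up to the nearest integer",
            stacklevel=2,
        )
    table = table.copy()
    table["cluster_size"] = np.ceil(sizes).astype(np.int64)
    return table[list(REQUIRED_COLUMNS) + [c for c in table.columns if c not in REQUIRED_COLUMNS]]


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cluster table is missing required columns: {missing}")
    sizes = table["cluster_size"].to_numpy()
    bad = np.flatnonzero(~(sizes > 0))
    if bad.size:
        raise ValueError(f"nonpositive cluster sizes at rows {bad.tolist()[:20]}")
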