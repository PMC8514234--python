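# clusterkin

Kinetic models of gut bacterial cluster-size distributions.

Bacteria in the intestine live mostly as three-dimensional multicellular
aggregates whose sizes span four orders of magnitude.  Imaging cohorts of
larval zebrafish mono-associated with single bacterial strains show a
common family of cluster-size distributions: the reverse cumulative
distribution P(size > n) decays roughly as n⁻¹ (a density exponent near
2) and flattens into a strain-dependent plateau at large sizes.
`clusterkin` implements the kinetic theory that explains both features
and the statistical machinery to test it:

* **growth + single-cell fragmentation** (a Yule–Simons-type process)
  generates the power-law bulk, with closed-form exponents
  — e.g. μ = 1 + 1/(1 − β/r) for well-mixed fragmentation,
  μ = 5/3 + β/r for surface fragmentation;
* **size-dependent aggregation** (homogeneous kernel α(nm)^ν_A) condenses
  the system toward one massive cluster, producing the plateau — the
  population behaves like a gelling material, but only in finite
  stochastic systems: the mean-field (master-equation) limit has no
  plateau;
* **carrying capacity and expulsion** make the stationary state a
  quasi-stochastic cycle of condensation, expulsion and regrowth.

The package is aimed at quantitative microbiome researchers who want to
simulate these kinetics, solve the corresponding mean-field equations,
and fit discrete power laws to measured or simulated cluster-size
tables.

## What's inside

| module | contents |
|---|---|
| `clusterkin.core` | `KineticParams`, `ClusterPopulation`, `EventLog`, reaction propensities |
| `clusterkin.simulate` | tau-leaping (minimal model), hybrid Gillespie (full model), pure-aggregation/gelation simulator, stationarity drivers |
| `clusterkin.master` | mean-field cluster-density equations, FFT-accelerated forward-Euler integrator |
| `clusterkin.distributions` | reverse cumulative distributions, streaming pooling, log-binned densities |
| `clusterkin.powerlaw` | discrete (zeta) power-law MLE with KS-selected minimum size, linear log-log fits, singleton-sensitivity protocol |
| `clusterkin.analytics` | closed-form exponent predictions, stationarity metric, aggregation-event statistics and rate bounds |
| `clusterkin.cohort` | synthetic cohort generator, cluster-table CSV I/O, strain presets |
| `clusterkin.sweeps`, `clusterkin.cli` | reproducible experiment drivers and the `clusterkin` command-line tool |

## Worked example

Simulate the full model at its strongest size-dependent aggregation
setting, measure the aggregation-event rate at stationarity, and fit the
pooled size distribution:

```python
import numpy as np
from clusterkin import (
    ClusterPopulation, KineticParams, fit_mle,
    run_replicates_to_stationarity, stationary_aggregation_rate,
)

params = KineticParams(r=0.5, K=1000.0, beta=0.5, nu_F=2/3,
                       alpha=1e-3, nu_A=2/3, lambda_=0.01, nu_E=1/3)
ens = run_replicates_to_stationarity(
    params, ClusterPopulation.single_cells(10), n_replicates=30, seed=1)
mean, std, n = stationary_aggregation_rate(ens)
print(f"aggregation events/hr: {mean:.1f} +- {std:.1f} across {n} replicates")

fit = fit_mle(ens.pooled_sizes())
print(f"density exponent mu = {fit.mu:.2f} (n_min={fit.n_min})")
```

Output:

```
aggregation events/hr: 14.2 +- 5.0 across 28 replicates
density exponent mu = 1.99 (n_min=3)
```

About 14 merge events per hour sustain the large-cluster plateau
(consistent with the 1–100 events/hr band that order-of-magnitude
observational estimates allow), and the pooled distribution's bulk
exponent sits near 2, i.e. P(size > n) ~ n⁻¹.  The closed-form
prediction for the growth/fragmentation part alone is available as
`analytic_mu(nu_F, beta, r)`.

The same computations are scriptable from a shell:

```bash
clusterkin predict-mu --nu-f 1.0 --beta 0.05 --r 0.5
clusterkin synth-cohort --strain Enterobacter-ZOR0014 --seed 1 --out cohort.csv
clusterkin fit --table cohort.csv --method mle
```

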