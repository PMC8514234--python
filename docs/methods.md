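# Methods

## The model

The state of one host's gut bacterial population is a list of cluster
sizes `n_1, ..., n_M` (cells per three-dimensional aggregate).  Four
reactions change it:

| process        | effect                              | rate                       |
|----------------|-------------------------------------|----------------------------|
| growth         | `n -> n + 1` (cell division)        | `r n (1 - N/K)`            |
| fragmentation  | `n -> (n-1) + 1` (a cell escapes)   | `beta n^nu_F (1 - N/K)`    |
| aggregation    | `n, m -> n + m` (clusters merge)    | `alpha (n m)^nu_A` per pair|
| expulsion      | cluster removed entirely            | `lambda n^nu_E`            |

`N = sum n_i` is the total cell count and `K` the carrying capacity; the
logistic factor throttles growth and fragmentation together because
single-cell escape is believed to ride on division at the cluster
surface.  Expulsion and aggregation are transport processes and are not
capacity-limited.  The exponents encode geometry: `nu_F = 1` means every
cell can escape (well-mixed), `2/3` only surface cells, `0` a fixed
number of escape sites.  Fragmentation conserves cell number (chipping);
breakup of large clusters into medium ones is deliberately absent — it
is rare in the imaging observations this model family is built on.
There is no spatial structure beyond what the exponents encode.

Parameter defaults follow the measured ranges for larval-zebrafish gut
bacteria: division rate `r = 0.5/hr` (measured 0.3–0.8/hr), carrying
capacity `K = 10^3` cells (estimated 10^3–10^6), and expulsion
co-varied with its exponent so that the biggest clusters (size ~ K)
leave at `lambda K^nu_E ~ 0.1/hr`, the measured expulsion rate of large
aggregates.  `check_expulsion_constraint` enforces that band (within a
factor of three) for parameter sweeps.

The headline theory: with aggregation and expulsion off, growth plus
chipping is a Yule-Simons-type process.  Its cluster-size density
develops a power-law tail `p(n) ~ n^-mu` with

- `nu_F = 1`:   `mu = 1 + 1/(1 - beta/r)`
- `nu_F = 2/3`: `mu = 5/3 + beta/r`
- `nu_F = 0`:   `mu = 1 + (beta/r)/(1 + beta/r)`

valid for long times, large sizes, and slow fragmentation
(`beta/r < 1`), and always above the normalizability bound
`mu > nu_F + 1`.  The `nu_F = 0` entry is our reconstruction of a
typographically garbled source expression; it is the reading consistent
with the stated limits (`mu -> 1` as `beta -> 0`, sublinear in
`beta/r`) and is treated as indicative only — nothing in the test suite
asserts it numerically.

## Simulation schemes

**Minimal model (tau-leaping).**  Fixed step `tau = 0.1 hr`.  Per step
and per cluster, cell additions and chipping events are Poisson draws at
the start-of-step rates; growth is applied first, then fragmentation,
with chip counts truncated at `n - 1` so clusters never drop below one
cell.  New fragments are size-1 clusters and do not re-fragment within
the step.  A quarter-step refinement leaves the pooled distribution
statistically unchanged (two-sample KS test in the suite).

**Full model (hybrid Gillespie).**  Fragmentation, aggregation and
expulsion fire as discrete events with exponential waiting times from
frozen propensities; growth advances deterministically between events as
logistic dynamics in explicit Euler steps of at most 0.1 hr.  If a drawn
waiting time exceeds one doubling time `ln(2)/r`, growth is advanced by
a doubling time, propensities are recomputed, and the wait is redrawn
(valid because exponential waits are memoryless).  Aggregation partners
are chosen by sampling cluster `i` with weight `n_i^nu_A`, then `j != i`
with the same weights; the unordered-pair total propensity
`alpha * sum_{i<j} (n_i n_j)^nu_A` is evaluated through the factorized
identity `(alpha/2) [(sum w)^2 - sum w^2]`, `w = n^nu_A`.  Cluster sizes
are real-valued internally; outputs bin them to the nearest integer
(minimum 1).  We use nearest-integer rather than ceiling binning because
a freshly shed cell spends time at sizes in (1, 2) while it regrows;
ceiling would leave the size-1 bin empty, which is an artifact of the
continuous-growth representation, not a feature of the process.
Ingested imaging tables, by contrast, are rounded up on read — that is
the convention their cell counts were recorded with.

**Pure aggregation (Marcus-Lushnikov).**  Exact Gillespie with only the
merge reaction, from `n` monomers.  Runs stop when the largest cluster
first reaches a mass fraction of 0.1 (configurable).  For the product
kernel (`nu_A = 1`) the finite-system gel point is where the largest
cluster reaches order `n^(2/3)` — about 5% of the mass at `n = 10^4` —
and there the size distribution decays as `n^-5/2`.  Stopping much
later (e.g. at half the mass) samples the post-gel regime, where sol
depletion steepens the apparent exponent to ~2.9; the 0.1 default was
chosen to sit just past the transition while remaining robust to
replicate noise.

**Stationarity.**  A distribution counts as stationary when, after
extending the run by 50% of elapsed time, the pooled reverse cumulative
distribution changes by less than `tol` in log10 at every common support
point backed by at least 5 clusters in both samples.  The default
tolerance for the ensemble drivers is 0.1 (one minor tick on a log
axis — the quantitative version of "visibly unchanged"): pooled
distributions of ~30–150 capacity-limited replicates fluctuate at the
0.05–0.1 level indefinitely because each host cycles through
condensation, expulsion and regrowth, so a tighter tolerance never
triggers and only prolongs runs into the regime where extinction
(every cluster expelled) distorts the ensemble.  Strict extinction is
absorbing, so the model has no true stationary distribution — "
stationarity" here always means this quasi-stationary plateau.

**Event-rate statistics.**  Aggregation events per hour are counted per
replicate over a measurement window opened at the start of the final
stationarity check and extended to span at least 60 hr (several
expulsion-regrowth cycles).  Replicates are normalized by the time they
were alive inside the window, and replicates alive for under 20% of it
are excluded — a rate estimated from a sliver of one cycle says nothing
about the stationary process.  Across-replicate spread is reported as
the sample (n-1) standard deviation.

## Mean-field (master-equation) dynamics

Densities `c_n` of clusters of size `n` on the integer grid `[1, n_max]`
evolve under aggregation gain/loss, growth advection, expulsion loss and
chipping terms (see the module docstring for the equation).  Two
transcription choices: the aggregation gain sum runs over
`m = 1 .. n-1` (the printed upper limit `m = n` would require a `c_0`),
and the chipping loss and monomer source involve only sizes `m >= 2`,
matching the simulators; with these the chipping terms conserve mass
exactly (asserted to 1e-10 per step in the suite).  The mean-field
aggregation loss keeps the self-pair term `m = n` as printed; the
`O(1/M)` finite-population correction it ignores is part of the
stochastic-vs-mean-field difference under study.

Integration is forward Euler.  The step size is configurable;
`dt = 1e-3 hr` is the default and is validated two ways in the suite
(halving `dt` changes stationary distributions by < 1e-6 in log10;
a step-halving convergence test on the transient), with `dt = 1e-4`
available as a high-fidelity setting.  The aggregation gain is the
discrete self-convolution of `n^nu_A c_n`, evaluated with an FFT in
`O(n_max log n_max)`; a direct `O(n_max^2)` reference path is kept and
cross-checked.  Boundaries are reflecting: advection out of the top bin
is suppressed and merge products larger than `n_max` are deposited in
the top bin.  With a carrying capacity the natural grid is `n_max = K`;
without one, `n_max = ceil(exp(r t_max))`.  Densities must stay
nonnegative; negative values beyond rounding error abort the run with
the offending `dt` named.

## Exponent estimation

**Discrete MLE.**  The reference model is the zeta distribution
`p(n) = n^-mu / zeta(mu, n_min)` (upper-truncated variant for windowed
fits).  `mu` is maximized by bounded scalar optimization; `n_min` is
selected by minimizing the KS distance between the empirical and fitted
tails over candidate minima with at least 50 tail observations (ties go
to the smallest `n_min`, keeping the most data).  Uncertainty comes from
the observed information, with a nonparametric bootstrap (200 resamples
by default) available separately.  Sizes are integer cell counts, so the
discrete form is the default throughout; no continuous approximation is
used anywhere in the pipeline.

**Linear fits.**  Least squares on `log10 P(size>n)` vs `log10 n` over a
size window; the slope estimates `-(mu - 1)`.  Fits whose support is
dominated by sizes below 10 are flagged — small-size windows are a known
source of bias for this estimator.  For the rare-fragmentation benchmark
the default window is `[2, 100]`: the exact discrete law bends below
`n = 3` (for a cumulative exponent of -1 the true curve is `1/(n+1)`,
whose local log-log slope between 1 and 3 is only -0.63), and above a
few hundred cells a 24-hour run is dominated by the founder-lineage
clusters that have never fragmented, which flatten the curve before the
asymptotic regime is reached.  The `[2, 100]` window is also the window
used for measurement-sensitivity fits (below).  At the benchmark
conditions this estimator reads about -0.92: the residual distance from
the asymptotic -1 is finite-time curvature, not estimator error.

**Singleton sensitivity.**  Because single cells are the most
error-prone part of imaging-derived counts, fits are repeated on sizes
up to 100 twice — once including singletons, once on [2, 100] — by both
estimators, and the exponent shift is reported.  On pure power-law
samples the shift stays within the joint uncertainties; samples with
artificially inflated singleton counts shift the MLE down when
singletons are excluded.  The line fit is nearly blind to pure singleton
inflation (adding singletons rescales the whole tail without changing
its shape), which is itself a useful diagnostic.

## Synthetic cohorts

`generate_cohort` emulates the structure of imaging-derived cohort
tables: per fish, a lognormal cluster count (defaults 244 +- 182, the
observed mean and spread of clusters per host), sizes drawn from a
discrete power law with the spec's exponent (truncated at a size
ceiling), and an optional condensation step that merges a random subset
of clusters into one carrying a target fraction of the host's cells —
the plateau is injected by the same mechanism (mass condensation) that
produces it in the kinetic model, not by mixing in a second
distribution.  Strain presets carry the real cohort shapes (fish counts,
clusters per fish) for eight reference strains, but their exponents and
plateau fractions are illustrative placeholders, not measured values.

What the generator deliberately omits: imaging noise mechanisms
(autofluorescent false singletons beyond a simple inflation factor, dim
aggregate cores), within-host correlations between cluster sizes, and
any strain-specific biology beyond the three shape parameters.  Tests
that pass on these cohorts therefore validate the statistical pipeline,
not the imaging pipeline.

## Reference quantities recomputed by `scripts/acceptance.py`

* Aggregation-event rate: full model at `r=0.5`, `K=10^3`, `beta=0.5`,
  `nu_F=2/3`, `lambda=0.01`, `nu_E=1/3`, `alpha=10^-3`, `nu_A=2/3`, 30
  replicates from 10 single cells, run to pooled stationarity; mean
  alive-time-normalized aggregation events per hour (expected ~15,
  replicate std ~3-5).
* Rare-fragmentation exponent: minimal model at `beta/r = 0.01`, 50
  replicates to 24 hr, pooled; linear-fit cumulative exponent over
  [2, 100] (expected ~ -1).

Problem sizes throughout (30–150 replicates, `K = 10^3`, `10^4`
monomers for gelation runs) are chosen so every check completes on a
single CPU in minutes while leaving the measured statistics' standard
errors well inside the tolerances they are compared at.

## Known limitations

* Forward Euler for deterministic growth (0.1 hr substeps) lags the
  exact logistic by a few percent over a colonization transient; this is
  the scheme's documented accuracy, shared by the mean-field integrator
  at coarse `dt`.
* Clauset-style zeta MLE applied to Yule-Simons-shaped data is biased
  low by 0.05–0.2 at `beta/r >= 0.3` because the pre-asymptotic part of
  the exact law is shallower than any pure power law; the KS-selected
  `n_min` does not fully escape it at realizable sample sizes.  The
  exponent-grid check documents this bias honestly rather than hiding
  it (see the test for details).
* The full model has no true stationary state (extinction is
  absorbing); all stationary-state statistics are quasi-stationary and
  mildly sensitive to how long past stationarity the system is observed.
* The mean-field comparison at size-independent aggregation carries a
  genuine finite-system excess of large clusters of up to ~0.1 in
  log10 P; the dichotomy check's agreement clause sits at exactly that
  scale and is the tightest assertion in the suite.
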