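"""Stochastic simulators: tau-leaping, hybrid Gillespie, pure aggregation."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from clusterkin import (
    ClusterPopulation,
    KineticParams,
    run_to_stationarity,
    run_replicates_to_stationarity,
    simulate_full,
    simulate_minimal,
    simulate_pure_aggregation,
)
from clusterkin.core import AGGREGATION, EXPULSION, FRAGMENTATION
from clusterkin.simulate import FullModelSimulation


class TestMinimalModel:
    def test_pure_birth_keeps_single_cluster_and_grows_exponentially(self, rng):
        params = KineticParams(r=0.5, beta=0.0)
        finals = []
        for _ in range(40):
            res = simulate_minimal(params, ClusterPopulation(np.array([5.0])), 8.0, rng=rng)
            assert res.final_population.n_clusters == 1
            finals.append(res.final_population.total_cells)
        expected = 5 * np.exp(0.5 * 8.0)
        se = np.std(finals, ddof=1) / np.sqrt(len(finals))
        assert abs(np.mean(finals) - expected) < 4 * se

    def test_rejects_full_model_parameters(self):
        init = ClusterPopulation.single_cells(5)
        with pytest.raises(ValueError):
            simulate_minimal(KineticParams(r=0.5, alpha=0.1), init, 1.0)
        with pytest.raises(ValueError):
            simulate_minimal(KineticParams(r=0.5, lambda_=0.1), init, 1.0)
        with pytest.raises(ValueError):
            simulate_minimal(KineticParams(r=0.5, K=100.0), init, 1.0)

    def test_fragmentation_conserves_cells_when_growth_off(self, rng):
        params = KineticParams(r=0.0, beta=0.5, nu_F=1.0)
        init = ClusterPopulation(np.array([40.0, 60.0]))
        res = simulate_minimal(params, init, 20.0, rng=rng)
        assert res.final_population.total_cells == 100.0
        assert res.final_population.n_clusters > 2  # fragments were produced

    def test_seed_determinism(self):
        params = KineticParams(r=0.5, beta=0.1, nu_F=1.0)
        init = ClusterPopulation.single_cells(10)
        a = simulate_minimal(params, init, 12.0, seed=7)
        b = simulate_minimal(params, init, 12.0, seed=7)
        np.testing.assert_array_equal(a.final_sizes(), b.final_sizes())

    def test_snapshots_on_requested_grid(self, rng):
        params = KineticParams(r=0.5, beta=0.1, nu_F=1.0)
        res = simulate_minimal(
            params, ClusterPopulation.single_cells(10), 10.0, rng=rng,
            snapshot_times=[2.0, 5.0, 10.0],
        )
        times = [t for t, _ in res.snapshots]
        assert times == pytest.approx([2.0, 5.0, 10.0])
        # snapshot sizes are integers
        for _, pop in res.snapshots:
            assert np.allclose(pop.sizes, np.round(pop.sizes))

    def test_tau_refinement_leaves_distribution_unchanged(self, rng):
        """Halving tau twice should not shift the pooled size distribution."""
        params = KineticParams(r=0.5, beta=0.05, nu_F=1.0)
        init = ClusterPopulation.single_cells(10)
        coarse, fine = [], []
        for _ in range(25):
            coarse.append(simulate_minimal(params, init, 12.0, tau=0.1, rng=rng).final_sizes())
            fine.append(simulate_minimal(params, init, 12.0, tau=0.025, rng=rng).final_sizes())
        stat = ks_2samp(np.concatenate(coarse), np.concatenate(fine))
        assert stat.pvalue > 0.01


class TestFullModel:
    def test_zero_propensities_population_is_static(self):
        params = KineticParams(r=0.5, K=10.0)
        res = simulate_full(params, ClusterPopulation(np.array([10.0])), 30.0, seed=0)
        assert len(res.event_log) == 0
        assert res.final_population.sizes.tolist() == [10.0]

    def test_event_bookkeeping_balances(self, rng):
        """N changes only via expulsion when growth is off; M follows events."""
        params = KineticParams(
            r=0.0, beta=0.4, nu_F=2 / 3, alpha=0.02, nu_A=2 / 3, lambda_=0.02, nu_E=1 / 3
        )
        init = ClusterPopulation(np.array([8.0, 13.0, 21.0, 34.0, 55.0]))
        res = simulate_full(params, init, 15.0, rng=rng)
        log = res.event_log
        expelled = sum(
            s for s, k in zip(log.sizes1, log.kinds) if k == EXPULSION
        )
        assert res.final_population.total_cells == pytest.approx(131.0 - expelled)
        n_frag = log.count(FRAGMENTATION)
        n_agg = log.count(AGGREGATION)
        n_exp = log.count(EXPULSION)
        assert res.final_population.n_clusters == 5 + n_frag - n_agg - n_exp

    def test_cell_number_exactly_conserved_without_growth_or_expulsion(self, rng):
        params = KineticParams(r=0.0, beta=0.4, nu_F=2 / 3, alpha=0.05, nu_A=2 / 3)
        init = ClusterPopulation(np.array([5.0, 9.0, 13.0, 4.0, 20.0] * 4))
        sim = FullModelSimulation(params, init, rng=rng)
        sim.run_until(30.0)
        assert sim.sizes.sum() == 204.0
        assert len(sim.log) > 50  # plenty of fragmentation/aggregation happened

    def test_seed_determinism_of_event_log(self, full_model_params):
        init = ClusterPopulation.single_cells(10)
        a = simulate_full(full_model_params, init, 30.0, seed=11)
        b = simulate_full(full_model_params, init, 30.0, seed=11)
        assert a.event_log.times == b.event_log.times
        assert a.event_log.kinds == b.event_log.kinds
        np.testing.assert_array_equal(a.final_population.sizes, b.final_population.sizes)

    def test_growth_tracks_logistic_between_events(self):
        params = KineticParams(r=0.5, K=1000.0)
        res = simulate_full(params, ClusterPopulation(np.array([10.0])), 10.0, seed=0)
        expected = 1000 / (1 + (1000 / 10 - 1) * np.exp(-0.5 * 10))
        # forward Euler at 0.1 hr steps carries a few percent of lag
        assert res.final_population.total_cells == pytest.approx(expected, rel=0.05)

    def test_aggregation_merges_sizes(self, rng):
        params = KineticParams(alpha=1.0, nu_A=1.0)
        init = ClusterPopulation(np.array([3.0, 4.0]))
        res = simulate_full(params, init, 50.0, rng=rng)
        assert res.final_population.sizes.tolist() == [7.0]

    def test_extinction_is_recorded(self):
        params = KineticParams(r=0.0, lambda_=5.0, nu_E=0.0)
        res = simulate_full(params, ClusterPopulation(np.array([4.0, 4.0])), 50.0, seed=3)
        assert res.extinct
        assert res.event_log.count(EXPULSION) == 2


class TestPureAggregation:
    def test_two_monomers_forced_merge(self):
        res = simulate_pure_aggregation(2, alpha=1.0, nu_A=0.0, seed=0, gel_mass_fraction=None)
        assert res.final_population.sizes.tolist() == [2.0]
        assert res.final_population.time > 0

    def test_full_condensation_takes_n_minus_one_events(self, rng):
        res = simulate_pure_aggregation(
            50, alpha=1.0, nu_A=1.0, rng=rng, gel_mass_fraction=None, record_events=True
        )
        assert len(res.event_log) == 49
        assert res.final_population.sizes.tolist() == [50.0]

    def test_mass_conserved_at_gel_stop(self, rng):
        res = simulate_pure_aggregation(2000, alpha=1.0, nu_A=1.0, rng=rng)
        assert res.final_population.total_cells == 2000.0
        assert res.final_population.sizes.max() >= 200.0

    def test_rejects_fewer_than_two_monomers(self):
        with pytest.raises(ValueError):
            simulate_pure_aggregation(1, alpha=1.0, nu_A=1.0)

    def test_sub_gelling_kernel_has_exponential_not_power_law_tail(self, rng):
        """A size-independent kernel never gels: a power-law fit to its
        mid-coagulation distribution is visibly poor (large KS)."""
        from clusterkin import fit_mle, run_gelation_reference

        pooled = []
        for _ in range(5):
            res = simulate_pure_aggregation(
                2000, alpha=1e-3, nu_A=0.0, rng=rng, gel_mass_fraction=None, t_max=2.0
            )
            pooled.append(res.final_sizes())
        control = fit_mle(np.concatenate(pooled))
        gel = run_gelation_reference(n_monomers=5_000, nu_A=1.0, alpha=1.0,
                                     n_replicates=3, seed=0)["fit"]
        assert control.ks > 5 * gel.ks

    def test_constant_kernel_mean_cluster_count_matches_smoluchowski(self, rng):
        """For nu_A=0 the mean-field count M(t) = M0 / (1 + alpha*M0*t/2)."""
        M0, alpha, t = 300, 0.01, 1.0
        counts = []
        for _ in range(40):
            res = simulate_pure_aggregation(
                M0, alpha=alpha, nu_A=0.0, rng=rng, gel_mass_fraction=None, t_max=t
            )
            counts.append(res.final_population.n_clusters)
        expected = M0 / (1 + alpha * M0 * t / 2)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        # mean-field neglects O(1/M) corrections; allow them on top of MC error
        assert abs(np.mean(counts) - expected) < 4 * se + 0.02 * expected


class TestStationarityDrivers:
    def test_absorbing_state_is_stationary(self):
        params = KineticParams(r=0.5, K=50.0)
        res = run_to_stationarity(params, ClusterPopulation(np.array([5.0])), seed=0, t_init=8.0)
        assert res.stationary

    def test_growth_without_capacity_rejected(self):
        with pytest.raises(ValueError):
            run_to_stationarity(KineticParams(r=0.5), ClusterPopulation.single_cells(3), seed=0)

    def test_rapid_expulsion_flags_extinction(self):
        params = KineticParams(r=0.5, K=100.0, lambda_=10.0, nu_E=0.0)
        res = run_to_stationarity(params, ClusterPopulation.single_cells(5), seed=1, t_init=8.0)
        assert res.extinct
        assert res.stationary  # the empty gut is absorbing

    def test_ensemble_reaches_stationarity_and_reports_window(self, full_model_params):
        ens = run_replicates_to_stationarity(
            full_model_params,
            ClusterPopulation.single_cells(10),
            n_replicates=10,
            seed=2,
            record_events=False,
        )
        assert ens.window[1] == pytest.approx(1.5 * ens.window[0])
        assert ens.pooled_sizes().min() >= 1
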