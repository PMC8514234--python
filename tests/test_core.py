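"""Domain types and reaction propensities."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clusterkin import (
    ClusterPopulation,
    EventLog,
    KineticParams,
    expulsion_rates,
    fragmentation_rates,
    growth_rates,
    total_aggregation_propensity,
)
from clusterkin.core import AGGREGATION, FRAGMENTATION, aggregation_pair_propensity_bruteforce


class TestKineticParams:
    def test_json_round_trip_is_lossless(self, tmp_path, full_model_params):
        path = tmp_path / "params.json"
        full_model_params.to_json(path)
        assert KineticParams.from_json(path) == full_model_params
        # unbounded K serializes as null
        p = KineticParams(r=0.5)
        p.to_json(path)
        assert json.loads(path.read_text())["K"] is None
        assert KineticParams.from_json(path) == p

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"r": -0.1},
            {"beta": -1.0},
            {"nu_F": -0.5},
            {"lambda_": -1e-9},
            {"K": 0.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            KineticParams(**kwargs)

    def test_lambda_key_in_dict(self):
        d = KineticParams(lambda_=0.25).to_dict()
        assert d["lambda"] == 0.25 and "lambda_" not in d


class TestClusterPopulation:
    def test_counts_recomputed_from_sizes(self, small_population):
        assert small_population.total_cells == 19.0
        assert small_population.n_clusters == 5
        grown = ClusterPopulation(small_population.sizes * 2)
        assert grown.total_cells == 38.0

    def test_sizes_below_one_rejected(self):
        with pytest.raises(ValueError):
            ClusterPopulation(np.array([0.5, 2.0]))

    def test_integer_binning_keeps_fresh_fragments_in_size_one_bin(self):
        pop = ClusterPopulation(np.array([1.0, 1.3, 1.8, 2.6]))
        assert pop.as_integer_sizes().tolist() == [1, 1, 2, 3]


class TestEventLog:
    def test_times_must_be_nondecreasing(self):
        log = EventLog()
        log.append(1.0, FRAGMENTATION, 5.0)
        with pytest.raises(ValueError):
            log.append(0.5, FRAGMENTATION, 5.0)

    def test_aggregation_needs_two_participants(self):
        log = EventLog()
        with pytest.raises(ValueError):
            log.append(1.0, AGGREGATION, 5.0)
        log.append(1.0, AGGREGATION, 5.0, 3.0)
        assert log.count(AGGREGATION) == 1


class TestPropensities:
    def test_growth_rate_examples(self):
        one = ClusterPopulation(np.array([10.0]))
        assert growth_rates(one, KineticParams(r=0.5))[0] == pytest.approx(5.0)
        assert growth_rates(one, KineticParams(r=0.5, K=10.0))[0] == 0.0
        two = ClusterPopulation(np.array([2.0, 3.0]))
        np.testing.assert_allclose(
            growth_rates(two, KineticParams(r=0.5, K=10.0)), [0.5, 0.75]
        )

    def test_fragmentation_rate_examples(self):
        p = KineticParams(beta=0.4, nu_F=0.0)
        assert fragmentation_rates(ClusterPopulation(np.array([1.0])), p)[0] == 0.0
        assert fragmentation_rates(ClusterPopulation(np.array([8.0])), p)[0] == pytest.approx(0.4)
        p = KineticParams(beta=0.2, nu_F=2 / 3)
        assert fragmentation_rates(ClusterPopulation(np.array([8.0])), p)[0] == pytest.approx(0.8)

    def test_fractional_sizes_below_two_cannot_fragment(self):
        p = KineticParams(beta=1.0, nu_F=1.0)
        rates = fragmentation_rates(ClusterPopulation(np.array([1.0, 1.9, 2.0])), p)
        assert rates[0] == 0.0 and rates[1] == 0.0 and rates[2] > 0.0

    def test_aggregation_propensity_examples(self):
        assert total_aggregation_propensity(
            ClusterPopulation(np.array([7.0])), KineticParams(alpha=1.0, nu_A=1.0)
        ) == 0.0
        assert total_aggregation_propensity(
            ClusterPopulation(np.array([1.0, 2.0, 3.0])), KineticParams(alpha=1.0, nu_A=1.0)
        ) == pytest.approx(11.0)
        assert total_aggregation_propensity(
            ClusterPopulation(np.array([4.0, 4.0])), KineticParams(alpha=0.01, nu_A=2 / 3)
        ) == pytest.approx(0.01 * 16 ** (2 / 3))

    def test_expulsion_rate_examples(self):
        assert expulsion_rates(
            ClusterPopulation(np.array([1000.0])), KineticParams(lambda_=0.01, nu_E=1 / 3)
        )[0] == pytest.approx(0.1)
        assert expulsion_rates(
            ClusterPopulation(np.array([8.0])), KineticParams(lambda_=0.01, nu_E=1.0)
        )[0] == pytest.approx(0.08)
        assert not expulsion_rates(
            ClusterPopulation(np.array([3.0, 9.0])), KineticParams(lambda_=0.0)
        ).any()

    def test_pair_sum_identity_on_random_populations(self, rng):
        """Closed-form total aggregation rate equals brute-force pair sum."""
        for _ in range(100):
            m = rng.integers(2, 30)
            sizes = rng.uniform(1.0, 500.0, size=m)
            p = KineticParams(alpha=rng.uniform(0.01, 2.0), nu_A=rng.uniform(0.0, 1.5))
            pop = ClusterPopulation(sizes)
            fast = total_aggregation_propensity(pop, p)
            slow = aggregation_pair_propensity_bruteforce(pop, p)
            assert fast == pytest.approx(slow, rel=1e-12)

    @given(
        sizes=st.lists(st.floats(1.0, 1e4), min_size=2, max_size=15),
        nu=st.floats(0.0, 1.5),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pair_sum_identity_property(self, sizes, nu):
        p = KineticParams(alpha=1.0, nu_A=nu)
        pop = ClusterPopulation(np.array(sizes))
        assert total_aggregation_propensity(pop, p) == pytest.approx(
            aggregation_pair_propensity_bruteforce(pop, p), rel=1e-9
        )

    def test_propensities_scale_linearly_in_rate_coefficients(self, small_population):
        base = KineticParams(r=0.3, beta=0.2, nu_F=2 / 3, alpha=0.05, nu_A=0.5, lambda_=0.01, nu_E=1.0)
        scaled = KineticParams(
            r=0.9, beta=0.6, nu_F=2 / 3, alpha=0.15, nu_A=0.5, lambda_=0.03, nu_E=1.0
        )
        np.testing.assert_allclose(
            growth_rates(small_population, scaled), 3 * growth_rates(small_population, base)
        )
        np.testing.assert_allclose(
            fragmentation_rates(small_population, scaled),
            3 * fragmentation_rates(small_population, base),
        )
        assert total_aggregation_propensity(small_population, scaled) == pytest.approx(
            3 * total_aggregation_propensity(small_population, base)
        )
        np.testing.assert_allclose(
            expulsion_rates(small_population, scaled),
            3 * expulsion_rates(small_population, base),
        )

    def test_growth_and_fragmentation_halt_at_capacity(self):
        pop = ClusterPopulation(np.array([4.0, 6.0]))  # N = K
        p = KineticParams(r=0.5, K=10.0, beta=0.3, nu_F=1.0)
        assert not growth_rates(pop, p).any()
        assert not fragmentation_rates(pop, p).any()
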