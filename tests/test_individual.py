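import numpy as np
import pytest

from dpa import (
    IndividualConfig,
    InvalidInputError,
    LatencyTable,
    PairedOrderStatistics,
    compare_individual_estimates,
    compute_survival_curve,
    ip_dpa_group,
    ip_dpa_participant,
    iteration_individual_divergence,
    pair_iteration,
)


def naive_individual_divergence(s, f, run_length):
    """Independent oracle: pure-python scan for the first qualifying run."""
    n = len(s)
    for i in range(n - run_length + 1):
        if all(s[i + k] > f[i + k] for k in range(run_length)):
            return (s[i] + f[i]) / 2.0
    return None


class TestPairIteration:
    def test_point_mass_pools(self, rng):
        pairs = pair_iteration([300.0], [100.0], resample_n=50, rng=rng)
        assert np.all(pairs.slow_sorted == 300.0)
        assert np.all(pairs.fast_sorted == 100.0)
        assert pairs.n == 50

    def test_survival_decrement_is_minimal(self, rng):
        pairs = pair_iteration([300.0], [100.0], resample_n=1200, rng=rng)
        steps = np.diff(pairs.survival_percent)
        np.testing.assert_allclose(steps, -1.0 / 1200.0 * 100.0)
        assert pairs.survival_percent[0] == pytest.approx(100.0 - 100.0 / 1200.0)

    def test_sortedness_on_random_input(self, skewed_pool_factory, rng):
        pairs = pair_iteration(
            skewed_pool_factory(), skewed_pool_factory(), resample_n=500, rng=rng
        )
        assert np.all(np.diff(pairs.slow_sorted) >= 0)
        assert np.all(np.diff(pairs.fast_sorted) >= 0)

    def test_empty_pool_names_participant(self, rng):
        with pytest.raises(InvalidInputError, match="p3"):
            pair_iteration([], [100.0], resample_n=10, rng=rng, participant="p3")

    def test_rank_survival_matches_strict_exceedance(self):
        # distinct integer values: survival attached to bin i equals the
        # strict-exceedance survival of the set evaluated at s_i
        values = np.array([110.0, 150.0, 200.0, 260.0, 330.0])
        pairs = PairedOrderStatistics(slow_sorted=values, fast_sorted=values - 5.0)
        curve = compute_survival_curve(values, t_max=400)
        for i, v in enumerate(values):
            assert pairs.survival_percent[i] == pytest.approx(curve.at(int(v)))


class TestIterationIndividualDivergence:
    def test_point_mass_pair_value(self, rng):
        pairs = pair_iteration([300.0], [100.0], resample_n=200, rng=rng)
        assert iteration_individual_divergence(pairs, run_length=100) == 200.0

    def test_identical_sequences_never_diverge(self):
        values = np.linspace(100, 400, 1200)
        pairs = PairedOrderStatistics(slow_sorted=values, fast_sorted=values.copy())
        assert iteration_individual_divergence(pairs, run_length=1) is None

    def test_run_of_99_is_too_short(self):
        f = np.arange(1200, dtype=float)
        s = f.copy()
        s[500:599] += 0.5  # positive diff exactly on bins 500..598
        pairs = PairedOrderStatistics(slow_sorted=s, fast_sorted=f)
        assert iteration_individual_divergence(pairs, run_length=100) is None
        assert iteration_individual_divergence(pairs, run_length=99) == pytest.approx(500.25)

    def test_truncated_run_at_grid_end_does_not_qualify(self):
        f = np.arange(200, dtype=float)
        s = f.copy()
        s[150:] += 0.5  # run of 50 touching the end
        pairs = PairedOrderStatistics(slow_sorted=s, fast_sorted=f)
        assert iteration_individual_divergence(pairs, run_length=51) is None
        assert iteration_individual_divergence(pairs, run_length=50) == pytest.approx(150.25)

    @pytest.mark.parametrize("run_length", [1, 5, 30])
    def test_matches_naive_oracle(self, skewed_pool_factory, rng, run_length):
        for _ in range(20):
            pairs = pair_iteration(
                skewed_pool_factory(20), skewed_pool_factory(20), resample_n=150, rng=rng
            )
            got = iteration_individual_divergence(pairs, run_length=run_length)
            want = naive_individual_divergence(
                pairs.slow_sorted, pairs.fast_sorted, run_length
            )
            assert got == want


class TestIpDpaParticipant:
    def test_point_mass_estimate(self):
        res = ip_dpa_participant(
            [300.0], [100.0], IndividualConfig(n_iterations=50, seed=0)
        )
        assert res.estimate == 200.0
        assert res.detection_rate == 1.0
        assert res.reliable

    def test_identical_pools_mostly_unreliable(self, skewed_pool_factory):
        unreliable = 0
        for i in range(20):
            pool = skewed_pool_factory()
            res = ip_dpa_participant(
                pool, pool.copy(), IndividualConfig(n_iterations=100, seed=i)
            )
            unreliable += not res.reliable
        assert unreliable >= 15

    def test_empty_pool_rejected(self):
        with pytest.raises(InvalidInputError, match="slow"):
            ip_dpa_participant([], [100.0], IndividualConfig(n_iterations=5))

    def test_estimate_none_iff_no_detection(self):
        pool = np.full(5, 250.0)
        res = ip_dpa_participant(
            pool, pool.copy(), IndividualConfig(n_iterations=20, seed=1)
        )
        assert res.estimate is None
        assert res.detection_rate == 0.0
        assert not res.reliable

    def test_scale_equivariance(self, skewed_pool_factory):
        slow = skewed_pool_factory(40, loc=230.0)
        fast = skewed_pool_factory(40, loc=190.0)
        cfg = IndividualConfig(n_iterations=50, resample_n=400, run_length=40, seed=6)
        base = ip_dpa_participant(slow, fast, cfg)
        shifted = ip_dpa_participant(slow + 37.0, fast + 37.0, cfg)
        assert base.detection_rate == shifted.detection_rate
        np.testing.assert_allclose(
            shifted.iteration_values, base.iteration_values + 37.0
        )

    def test_recovery_of_injected_divergence(self, rng):
        # Simulation-2 style participant: 60 obs, divergence injected at 150
        from dpa.synthetic import ExGaussianParams, make_artificial_slow, sample_exgaussian

        fast = sample_exgaussian(60, ExGaussianParams(), rng)
        slow = make_artificial_slow(fast, 150.0, 50.0, 0.5, rng)
        res = ip_dpa_participant(slow, fast, IndividualConfig(n_iterations=300, seed=2))
        assert res.reliable
        assert 140 <= res.estimate <= 180


class TestIpDpaGroup:
    def test_all_point_mass_participants(self, point_mass_table):
        res = ip_dpa_group(point_mass_table, IndividualConfig(n_iterations=30, seed=0))
        assert res.group_mean == 200.0
        assert res.group_sd == 0.0
        assert res.n_excluded == 0

    def test_mixed_null_half_excluded(self, skewed_pool_factory):
        cells = {}
        for i in range(4):  # point-mass effect participants
            cells[(f"e{i}", "slow")] = np.full(10, 300.0)
            cells[(f"e{i}", "fast")] = np.full(10, 100.0)
        for i in range(4):  # identical-pool null participants
            pool = skewed_pool_factory()
            cells[(f"n{i}", "slow")] = pool
            cells[(f"n{i}", "fast")] = pool.copy()
        res = ip_dpa_group(LatencyTable(cells), IndividualConfig(n_iterations=100, seed=3))
        excluded_ids = {
            p.participant_id for p in res.per_participant if not p.reliable
        }
        assert excluded_ids <= {"n0", "n1", "n2", "n3"}
        assert res.n_excluded >= 3

    def test_invariant_to_input_order(self, skewed_pool_factory):
        cells = {}
        for i in range(3):
            cells[(f"p{i}", "slow")] = skewed_pool_factory(30, loc=230.0)
            cells[(f"p{i}", "fast")] = skewed_pool_factory(30, loc=190.0)
        cfg = IndividualConfig(n_iterations=40, resample_n=300, run_length=30, seed=5)
        forward = ip_dpa_group(LatencyTable(cells), cfg)
        reversed_cells = dict(reversed(list(cells.items())))
        backward = ip_dpa_group(LatencyTable(reversed_cells), cfg)
        for a, b in zip(forward.per_participant, backward.per_participant):
            assert a.participant_id == b.participant_id
            assert a.estimate == b.estimate
            np.testing.assert_array_equal(a.iteration_values, b.iteration_values)

    def test_zero_reliable_participants(self, caplog):
        pool = np.full(5, 250.0)
        table = LatencyTable({("a", "slow"): pool, ("a", "fast"): pool.copy()})
        with caplog.at_level("WARNING", logger="dpa.individual"):
            res = ip_dpa_group(table, IndividualConfig(n_iterations=10, seed=0))
        assert res.group_mean is None
        assert res.group_sd is None
        assert res.n_excluded == 1


class TestCompareIndividualEstimates:
    def test_equal_vectors_give_zero_t(self):
        t, df, p = compare_individual_estimates([100, 120, 140], [100, 120, 140])
        assert t == 0.0
        assert df == 2.0

    def test_location_shift_positive_t(self, rng):
        b = rng.normal(150, 20, 25)
        a = b + 24.0 + rng.normal(0, 5, 25)
        t, df, p = compare_individual_estimates(a, b, paired=True)
        assert t > 0
        assert df == 24.0

    def test_hand_computed_three_pair_case(self):
        # differences {10, 20, 30}: t = 20 / (10/sqrt(3)), df = 2
        t, df, p = compare_individual_estimates([10.0, 20.0, 30.0], [0.0, 0.0, 0.0])
        assert t == pytest.approx(20.0 / (10.0 / np.sqrt(3.0)))
        assert df == 2.0
        assert 0 < p < 0.1

    def test_mapping_alignment_on_shared_keys(self):
        a = {"p1": 100.0, "p2": 150.0, "p3": 120.0, "only_a": 1.0}
        b = {"p1": 90.0, "p2": 140.0, "p3": 115.0, "only_b": 2.0}
        t, df, p = compare_individual_estimates(a, b, paired=True)
        assert df == 2.0
        assert t > 0

    def test_welch_unpaired(self, rng):
        a = rng.normal(160, 10, 20)
        b = rng.normal(130, 30, 12)
        t, df, p = compare_individual_estimates(a, b, paired=False)
        assert t > 0
        assert df != 30.0  # Welch df, not pooled

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InvalidInputError):
            compare_individual_estimates([100.0], [90.0], paired=True)
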