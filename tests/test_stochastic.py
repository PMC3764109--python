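"""Stochastic engine: binomial partitioning, conservation, termination,
size distributions and reproducibility of the seeded substreams."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hourglass import (
    DivisionParams,
    RunawayGrowthError,
    SizeDistribution,
    batch_final_stats,
    grow_stochastic,
    molecule_threshold,
    partition_molecules,
    simulate_size_distribution,
)
from hourglass.rng import seed_sequence, substream


class TestPartitionMolecules:
    def test_zero_probability_sends_all_to_other_side(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert partition_molecules(10, 0.0, rng) == (0, 10)

    @settings(max_examples=50, deadline=None)
    @given(m=st.integers(0, 10_000), p=st.floats(0.0, 1.0))
    def test_conservation(self, m, p):
        a, b = partition_molecules(m, p, np.random.default_rng(1))
        assert a + b == m
        assert a >= 0 and b >= 0

    def test_binomial_moments(self):
        rng = np.random.default_rng(42)
        draws = np.array([partition_molecules(10_000, 0.5, rng)[0] for _ in range(4000)])
        # Bin(10000, 0.5): mean 5000, var 2500 -> SE of mean ~ 0.79
        assert abs(draws.mean() - 5000) < 4 * np.sqrt(2500 / 4000)
        assert abs(draws.var() - 2500) < 0.1 * 2500

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            partition_molecules(-1, 0.5, np.random.default_rng(0))


class TestMoleculeThreshold:
    def test_decimal_product_snapped_to_integer(self):
        # 0.0025 * 10000 = 25.000000000000004 in floats
        assert molecule_threshold(0.0025, 10_000) == 25.0

    def test_non_integer_products_left_alone(self):
        assert molecule_threshold(0.33, 10) == pytest.approx(3.3)


class TestGrowStochastic:
    def test_symmetric_high_threshold_always_two_cells(self):
        # a daughter reaching 6000 of Binomial(10000, 0.5) is a ~20-sigma event
        for seed in range(5):
            tree = grow_stochastic(DivisionParams(0.5, 0.6), 10_000, seed=seed)
            assert tree.final_size == 2

    def test_single_molecule_can_never_terminate(self):
        with pytest.raises(RunawayGrowthError, match="runaway"):
            grow_stochastic(DivisionParams(0.3, 0.5), 1, seed=0)

    def test_leaf_molecules_sum_to_n0(self):
        tree = grow_stochastic(DivisionParams(0.3, 0.01), 500, seed=3)
        assert sum(int(n.content) for n in tree.leaves()) == 500

    def test_division_conserves_molecules_exactly(self):
        tree = grow_stochastic(DivisionParams(0.25, 0.05), 200, seed=7)
        for node in tree.nodes:
            if node.divided:
                a, b = (int(tree.nodes[c].content) for c in node.children)
                assert a + b == int(node.content)

    def test_zero_molecule_daughters_count_as_cells(self):
        tree = grow_stochastic(DivisionParams(0.1, 0.9), 10, seed=1)
        assert tree.final_size == len(tree.leaves())


class TestSizeDistribution:
    def test_counts_sum_to_reps_and_confidence_definition(self):
        dist = simulate_size_distribution(
            DivisionParams(0.4, 0.2), 100, reps=40, seed=5
        )
        assert sum(dist.counts.values()) == dist.reps == 40
        assert dist.confidence == dist.counts[dist.mode] / dist.reps
        assert all(c <= dist.counts[dist.mode] for c in dist.counts.values())

    def test_single_replicate_has_full_confidence(self):
        dist = simulate_size_distribution(DivisionParams(0.4, 0.3), 100, reps=1, seed=0)
        assert dist.confidence == 1.0

    def test_high_threshold_mode_two_full_confidence(self):
        dist = simulate_size_distribution(
            DivisionParams(0.5, 0.6), 10_000, reps=50, seed=2
        )
        assert dist.mode == 2 and dist.confidence == 1.0

    def test_mode_ties_break_toward_smallest_size(self):
        dist = SizeDistribution.from_sizes([4, 4, 2, 2, 3])
        assert dist.mode == 2

    def test_runaway_replicate_reports_its_index(self):
        with pytest.raises(RunawayGrowthError, match="replicate 0"):
            simulate_size_distribution(DivisionParams(0.5, 0.5), 1, reps=3, seed=0)


class TestReproducibility:
    def test_same_seed_same_distribution(self):
        a = simulate_size_distribution(DivisionParams(0.3, 0.1), 300, reps=25, seed=9)
        b = simulate_size_distribution(DivisionParams(0.3, 0.1), 300, reps=25, seed=9)
        assert a == b

    def test_single_replicate_reproducible_in_isolation(self):
        params, n0, seed = DivisionParams(0.3, 0.1), 300, 9
        full = simulate_size_distribution(params, n0, reps=10, seed=seed)
        root = seed_sequence(seed)
        sizes = []
        for k in range(10):
            rng = np.random.default_rng(substream(root, k))
            nf, _, _ = batch_final_stats(params, n0, 1, rng)
            sizes.append(int(nf[0]))
        assert SizeDistribution.from_sizes(sizes) == full

    def test_batched_stream_is_deterministic(self):
        params = DivisionParams(0.3, 0.1)
        a = simulate_size_distribution(params, 300, reps=25, seed=4, stream="batched")
        b = simulate_size_distribution(params, 300, reps=25, seed=4, stream="batched")
        assert a == b

    def test_unknown_stream_layout_rejected(self):
        with pytest.raises(ValueError, match="stream"):
            simulate_size_distribution(DivisionParams(0.3, 0.1), 300, reps=2, seed=0, stream="nope")


class TestBatchKernel:
    def test_matches_model_for_deterministic_limit(self):
        # huge n0 relative noise ~ 0: modes equal the deterministic sizes
        sizes, linear, duration = batch_final_stats(
            DivisionParams(0.5, 0.3), 10_000, 50, np.random.default_rng(0)
        )
        assert np.all(sizes == 4)
        assert np.all(duration == 2)
        assert not linear.any()  # [1, 2, 4] doubles at step 2

    def test_linear_flag_tracks_one_division_per_iteration(self):
        sizes, linear, duration = batch_final_stats(
            DivisionParams(0.1, 0.5), 10_000, 20, np.random.default_rng(1)
        )
        # chain lineage: linear, duration = N_f - 1
        assert np.all(linear)
        assert np.all(duration == sizes - 1)
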