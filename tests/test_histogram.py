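import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppsaxs import (
    AccumulatorBank,
    ParticleCloud,
    compact_encode,
    histogram_on_compact,
    merge_partials,
    pair_histogram_bruteforce,
    pair_histogram_chunked,
    read_histogram_tsv,
    rebin,
    write_histogram_tsv,
)


class TestBruteForce:
    def test_single_pair_accumulates_weight_product(self):
        cloud = ParticleCloud([[0, 0, 0], [5, 0, 0]], [2.0, 3.0])
        hist = pair_histogram_bruteforce(cloud)
        assert hist.values[5] == 6.0
        assert np.count_nonzero(hist.values) == 1
        assert hist.total_pairs == 1

    def test_single_particle_has_no_pairs(self):
        hist = pair_histogram_bruteforce(ParticleCloud([[1, 2, 3]], [4.0]))
        assert hist.total_pairs == 0
        assert not hist.values.any()

    def test_three_particle_hand_computation(self):
        """Distances 5, 7 and sqrt(74) = 8.60 pm land in bins 5, 7 and 8."""
        cloud = ParticleCloud([[0, 0, 0], [3, 4, 0], [0, 0, 7]], [1.0, 1.0, 1.0])
        hist = pair_histogram_bruteforce(cloud)
        nonzero = {k: v for k, v in enumerate(hist.values) if v}
        assert nonzero == {5: 1.0, 7: 1.0, 8: 1.0}

    def test_left_closed_bin_convention(self):
        cloud = ParticleCloud([[0, 0, 0], [10, 0, 0]], [1.0, 1.0])
        hist = pair_histogram_bruteforce(cloud, bin_width=5.0)
        assert hist.values[2] == 1.0  # d = 10 opens bin [10, 15)

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            pair_histogram_bruteforce(ParticleCloud([[0, 0, 0]], [1.0]), 0.0)


class TestChunkedEngine:
    @pytest.mark.parametrize("n_partials", [1, 8, 16, 32])
    @pytest.mark.parametrize("n", [101, 500])
    def test_matches_bruteforce_exactly_on_integer_clouds(
        self, make_cloud, n_partials, n
    ):
        """Lane count and the dynamic-unroll remainder never change the result.

        Integer coordinates and integer weights make float64 accumulation
        exact and order-independent, so equality is element-wise exact.
        """
        cloud = make_cloud(n, seed=n, integer_coords=True, integer_weights=True)
        oracle = pair_histogram_bruteforce(cloud)
        got = pair_histogram_chunked(cloud, 1.0, AccumulatorBank(n_partials))
        assert np.array_equal(got.values, oracle.values)

    @pytest.mark.parametrize("block", [8, 37, 65_536])
    def test_block_size_is_a_memory_knob_only(self, make_cloud, block):
        cloud = make_cloud(150, seed=3, integer_coords=True, integer_weights=True)
        ref = pair_histogram_chunked(cloud, 1.0, AccumulatorBank(8), block=65_536)
        got = pair_histogram_chunked(cloud, 1.0, AccumulatorBank(8), block=block)
        assert np.array_equal(got.values, ref.values)

    def test_float_clouds_match_oracle_to_1e9_relative(self, make_cloud):
        cloud = make_cloud(400, seed=5)
        oracle = pair_histogram_bruteforce(cloud)
        got = pair_histogram_chunked(cloud, 1.0, AccumulatorBank(16))
        scale = np.abs(oracle.values).max()
        assert np.abs(got.values - oracle.values).max() <= 1e-9 * scale

    def test_block_smaller_than_lane_count_rejected(self, make_cloud):
        with pytest.raises(ValueError):
            pair_histogram_chunked(make_cloud(10), 1.0, AccumulatorBank(8), block=4)

    def test_permutation_invariance(self, make_cloud):
        cloud = make_cloud(200, seed=6, integer_coords=True, integer_weights=True)
        perm = np.random.default_rng(0).permutation(len(cloud))
        shuffled = ParticleCloud(cloud.positions[perm], cloud.weights[perm])
        a = pair_histogram_chunked(cloud, 1.0, AccumulatorBank(8))
        b = pair_histogram_chunked(shuffled, 1.0, AccumulatorBank(8))
        assert np.array_equal(a.values, b.values)

    def test_doubling_coordinates_doubles_bin_indices(self, make_cloud):
        cloud = make_cloud(100, seed=7, integer_coords=True, integer_weights=True)
        doubled = ParticleCloud(2.0 * cloud.positions, cloud.weights)
        h1 = pair_histogram_chunked(cloud, 1.0, AccumulatorBank(4))
        h2 = pair_histogram_chunked(doubled, 1.0, AccumulatorBank(4))
        # bin k of the original maps to 2k (sqrt rounding can nudge to 2k+1)
        for k in np.flatnonzero(h1.values):
            assert h2.values[2 * k] + h2.values[2 * k + 1] == pytest.approx(
                h1.values[k]
            )

    @given(st.integers(0, 2**31 - 1), st.integers(2, 40))
    def test_mass_conservation_property(self, seed, n):
        """sum(values) = ((sum w)^2 - sum w^2)/2 whatever the geometry."""
        rng = np.random.default_rng(seed)
        cloud = ParticleCloud(
            rng.uniform(-5_000, 5_000, (n, 3)), rng.uniform(-1, 1, n)
        )
        hist = pair_histogram_chunked(cloud, 1.0, AccumulatorBank(8))
        assert hist.values.sum() == pytest.approx(hist.expected_mass, rel=1e-9, abs=1e-12)


class TestMergePartials:
    def test_single_partial_unchanged(self):
        bank = AccumulatorBank(1, bin_width=1.0, n_particles=3)
        bank.partials = np.array([[1.0, 2.0, 0.5]])
        assert np.array_equal(merge_partials(bank).values, [1.0, 2.0, 0.5])

    def test_merge_is_commutative_and_linear(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 10))
        bank_ab = AccumulatorBank(2, bin_width=1.0)
        bank_ab.partials = np.stack([a, b])
        bank_ba = AccumulatorBank(2, bin_width=1.0)
        bank_ba.partials = np.stack([b, a])
        merged = merge_partials(bank_ab).values
        assert np.array_equal(merged, merge_partials(bank_ba).values)
        assert merged.sum() == pytest.approx(a.sum() + b.sum())

    def test_unallocated_or_misshapen_bank_rejected(self):
        with pytest.raises(ValueError):
            merge_partials(AccumulatorBank(2))
        bank = AccumulatorBank(2, bin_width=1.0)
        bank.partials = np.zeros(5)
        with pytest.raises(ValueError):
            merge_partials(bank)

    def test_lane_count_must_be_positive(self):
        with pytest.raises(ValueError):
            AccumulatorBank(0)


class TestCompactPath:
    def test_identical_to_float_path_on_integer_clouds(self, make_cloud):
        cloud = make_cloud(300, seed=8, integer_coords=True, integer_weights=True)
        hist_f = pair_histogram_chunked(cloud, 1.0, AccumulatorBank(8))
        hist_c = histogram_on_compact(compact_encode(cloud), 1.0, AccumulatorBank(8))
        n = min(len(hist_f.values), len(hist_c.values))
        assert np.array_equal(hist_f.values[:n], hist_c.values[:n])
        assert not hist_f.values[n:].any() and not hist_c.values[n:].any()

    def test_mass_identity_independent_of_binning(self, make_cloud):
        cloud = make_cloud(300, seed=9)
        hist = histogram_on_compact(compact_encode(cloud), 1.0, AccumulatorBank(8))
        assert hist.values.sum() == pytest.approx(hist.expected_mass, rel=1e-9)


class TestRebin:
    def test_rebin_equals_direct_coarse_binning(self, make_cloud):
        cloud = make_cloud(200, seed=10, integer_coords=True, integer_weights=True)
        fine = pair_histogram_bruteforce(cloud, 1.0)
        coarse = pair_histogram_bruteforce(cloud, 100.0)
        regrouped = rebin(fine, 100)
        n = min(len(coarse.values), len(regrouped.values))
        assert np.array_equal(regrouped.values[:n], coarse.values[:n])

    def test_invalid_factor(self, make_cloud):
        hist = pair_histogram_bruteforce(make_cloud(5))
        with pytest.raises(ValueError):
            rebin(hist, 0)


class TestHistogramTSV:
    def test_bit_exact_roundtrip(self, make_cloud, tmp_path):
        hist = pair_histogram_bruteforce(make_cloud(100, seed=12))
        path = tmp_path / "hist.tsv"
        write_histogram_tsv(hist, path)
        back = read_histogram_tsv(path)
        assert np.array_equal(back.values, hist.values)
        assert back.bin_width == hist.bin_width
        assert back.n_particles == hist.n_particles
        assert back.sum_w == hist.sum_w
        assert back.sum_w2 == hist.sum_w2
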