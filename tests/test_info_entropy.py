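"""Discretization, entropies and mutual information."""

import numpy as np
import pytest
from sklearn.metrics import mutual_info_score

from hydrorqa import (
    DiscretizedSeries,
    discretize,
    entropy,
    info_metrics,
    joint_entropy,
    mutual_information,
    series_mutual_information,
)


class TestDiscretize:
    @pytest.mark.parametrize(
        "values,bins,expected",
        [
            ([0, 1, 2, 3], 2, [0, 0, 1, 1]),
            ([0.0, 0.5, 1.0], 2, [0, 1, 1]),  # interior edge goes to upper bin
            ([10.0, 20.0, 30.0], 3, [0, 1, 2]),
        ],
    )
    def test_equal_width_assignment(self, values, bins, expected):
        d = discretize(np.asarray(values, dtype=float), bins)
        np.testing.assert_array_equal(d.symbols, expected)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            discretize(np.full(10, 3.3), 4)

    def test_symbols_stay_in_range(self, rng):
        d = discretize(rng.normal(size=1000), 16)
        assert d.symbols.min() >= 0 and d.symbols.max() <= 15


class TestEntropyIdentities:
    def test_uniform_four_symbols_two_bits(self):
        d = DiscretizedSeries(np.repeat(np.arange(4), 25), 4, np.arange(5.0))
        assert entropy(d) == pytest.approx(2.0, abs=1e-12)

    def test_single_symbol_zero_bits(self):
        d = DiscretizedSeries(np.zeros(50, dtype=int), 4, np.arange(5.0))
        assert entropy(d) == 0.0

    def test_half_quarter_quarter_is_one_point_five_bits(self):
        d = DiscretizedSeries(np.array([0, 0, 1, 2]), 3, np.arange(4.0))
        assert entropy(d) == pytest.approx(1.5, abs=1e-12)

    def test_joint_of_identical_equals_marginal(self, rng):
        d = discretize(rng.normal(size=500), 8)
        assert joint_entropy(d, d) == pytest.approx(entropy(d), abs=1e-12)

    def test_joint_of_independent_uniform_pairs(self):
        # all four (x, y) combinations equally frequent
        dx = DiscretizedSeries(np.array([0, 0, 1, 1]), 2, np.arange(3.0))
        dy = DiscretizedSeries(np.array([0, 1, 0, 1]), 2, np.arange(3.0))
        assert joint_entropy(dx, dy) == pytest.approx(2.0, abs=1e-12)

    def test_joint_matches_contingency_double_loop(self, rng):
        dx = discretize(rng.normal(size=300), 6)
        dy = discretize(rng.normal(size=300), 5)
        brute = 0.0
        for x in range(6):
            for y in range(5):
                p = np.mean((dx.symbols == x) & (dy.symbols == y))
                if p > 0:
                    brute -= p * np.log2(p)
        assert joint_entropy(dx, dy) == pytest.approx(brute, abs=1e-12)

    def test_length_mismatch_rejected(self, rng):
        dx = discretize(rng.normal(size=100), 4)
        dy = discretize(rng.normal(size=99), 4)
        with pytest.raises(ValueError, match="length mismatch"):
            joint_entropy(dx, dy)


class TestMutualInformation:
    def test_self_information_equals_entropy(self, rng):
        d = discretize(rng.normal(size=400), 8)
        assert mutual_information(d, d) == pytest.approx(entropy(d), abs=1e-12)

    def test_exact_product_distribution_gives_zero(self):
        # joint counts exactly factorize -> MI identically 0
        dx = DiscretizedSeries(np.array([0, 0, 1, 1]), 2, np.arange(3.0))
        dy = DiscretizedSeries(np.array([0, 1, 0, 1]), 2, np.arange(3.0))
        assert mutual_information(dx, dy) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_is_exact(self, rng):
        dx = discretize(rng.normal(size=600), 9)
        dy = discretize(rng.normal(size=600), 7)
        assert mutual_information(dx, dy) == mutual_information(dy, dx)

    def test_matches_sklearn_contingency_estimate(self, rng):
        x, y = rng.normal(size=800), rng.normal(size=800)
        y += 0.5 * x
        dx, dy = discretize(x, 12), discretize(y, 12)
        ours = mutual_information(dx, dy)
        theirs = mutual_info_score(dx.symbols, dy.symbols) / np.log(2)
        assert ours == pytest.approx(theirs, rel=1e-10)

    def test_monotone_relabeling_invariance(self, rng):
        dx = discretize(rng.normal(size=500), 8)
        dy = discretize(rng.normal(size=500), 8)
        relabeled = DiscretizedSeries(7 - dx.symbols, 8, dx.bin_edges)
        assert mutual_information(dx, dy) == pytest.approx(
            mutual_information(relabeled, dy), abs=1e-12
        )

    def test_iid_independent_mi_within_finite_sample_bias(self, rng):
        x, y = rng.normal(size=5000), rng.normal(size=5000)
        mi = series_mutual_information(x, y, n_bins=8)
        # expected chi-square bias is (B-1)^2 / (2 N ln 2) ~ 0.007 bits
        assert mi < 0.05

    def test_shuffling_destroys_coupling(self, rng):
        x = rng.normal(size=2000)
        y = x + 0.3 * rng.normal(size=2000)
        coupled = series_mutual_information(x, y, 8)
        shuffled = series_mutual_information(x, rng.permutation(y), 8)
        assert shuffled < coupled

    def test_info_metrics_identity_holds(self, rng):
        dx = discretize(rng.normal(size=300), 6)
        dy = discretize(rng.normal(size=300), 6)
        m = info_metrics(dx, dy)
        assert m.mi == pytest.approx(m.h_x + m.h_y - m.h_xy, abs=1e-12)
        assert m.mi <= min(m.h_x, m.h_y) + 1e-9
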