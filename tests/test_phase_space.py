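"""Embedding, AMI delay and FNN dimension selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrorqa import (
    EmbeddingParams,
    TimeSeries,
    ami_curve,
    ami_delay,
    embed,
    fnn_dimension,
    fnn_fractions,
    resolve_best_match,
)


def series(values, **kw):
    return TimeSeries(np.asarray(values, dtype=float), **kw)


def henon_x(n=2000, a=1.4, b=0.3):
    x, y = 0.1, 0.1
    out = np.empty(n + 100)
    for i in range(n + 100):
        out[i] = x
        x, y = 1 - a * x * x + y, b * x
    return out[100:]


class TestEmbed:
    @pytest.mark.parametrize(
        "values,dim,delay,expected",
        [
            ([1, 2, 3, 4, 5], 2, 1, [[1, 2], [2, 3], [3, 4], [4, 5]]),
            ([1, 2, 3, 4, 5, 6], 3, 2, [[1, 3, 5], [2, 4, 6]]),
            ([4, 7, 1, 9], 1, 3, [[4], [7], [1], [9]]),
        ],
    )
    def test_delay_matrix(self, values, dim, delay, expected):
        traj = embed(series(values), EmbeddingParams(dim, delay))
        np.testing.assert_array_equal(traj.points, np.asarray(expected, dtype=float))

    def test_dimension_one_is_lossless(self):
        v = np.linspace(-2, 5, 37)
        traj = embed(series(v), EmbeddingParams(1, 1))
        np.testing.assert_array_equal(traj.points[:, 0], v)

    def test_infeasible_params_error_names_max_dimension(self):
        with pytest.raises(ValueError, match="maximal feasible dimension .* is 3"):
            embed(series(range(5)), EmbeddingParams(4, 2))

    @given(
        n=st.integers(10, 200),
        dim=st.integers(1, 6),
        delay=st.integers(1, 8),
    )
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_row_count_identity(self, n, dim, delay):
        """N + (n-1)*t always reassembles the input length."""
        if (dim - 1) * delay >= n:
            return
        traj = embed(series(np.arange(n)), EmbeddingParams(dim, delay))
        assert len(traj) + (dim - 1) * delay == n


class TestBestMatch:
    def test_keeps_larger_dimension_and_smaller_delay(self):
        got = resolve_best_match(EmbeddingParams(6, 9), EmbeddingParams(8, 28))
        assert (got.dimension, got.delay) == (8, 9)
        got = resolve_best_match(EmbeddingParams(6, 9), EmbeddingParams(17, 24))
        assert (got.dimension, got.delay) == (17, 9)

    @given(
        na=st.integers(1, 50), ta=st.integers(1, 60),
        nb=st.integers(1, 50), tb=st.integers(1, 60),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_commutative_and_idempotent(self, na, ta, nb, tb):
        a, b = EmbeddingParams(na, ta), EmbeddingParams(nb, tb)
        assert resolve_best_match(a, b) == resolve_best_match(b, a)
        assert resolve_best_match(a, a) == a


class TestAmiDelay:
    def test_sine_quarter_period(self):
        t = np.arange(4000)
        got = ami_delay(series(np.sin(2 * np.pi * t / 100)), max_delay=60)
        assert abs(got - 25) <= 3

    def test_amplitude_invariance(self):
        t = np.arange(4000)
        v = np.sin(2 * np.pi * t / 100)
        assert ami_delay(series(v), 60) == ami_delay(series(7.3 * v), 60)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ami_delay(series(np.ones(500)), 20)

    def test_too_short_error_names_required_length(self):
        with pytest.raises(ValueError, match="requires at least 121 samples"):
            ami_delay(series(np.sin(np.arange(100))), max_delay=60)

    def test_fallback_when_no_minimum(self, caplog):
        # quarter period far beyond the search range: AMI only decays
        t = np.arange(2000)
        v = np.sin(2 * np.pi * t / 400)
        v += np.random.default_rng(0).normal(0, 0.2, t.size)
        with caplog.at_level("WARNING"):
            got = ami_delay(series(v, station="S", factor="slow"), max_delay=20)
        assert got == 20
        assert any("no local AMI minimum" in r.message for r in caplog.records)

    def test_curve_is_positive_and_finite(self):
        v = np.sin(np.arange(500) / 7.0)
        curve = ami_curve(series(v), 30)
        assert np.all(np.isfinite(curve)) and np.all(curve >= 0)


class TestFnnDimension:
    def test_henon_needs_two_dimensions(self):
        s = series(henon_x(), station="H", factor="x")
        fractions = fnn_fractions(s, delay=1, max_dim=4)
        assert fractions[0] > 0.1 and fractions[1] < 0.01
        assert fnn_dimension(s, delay=1, max_dim=10) == 2

    def test_white_noise_never_converges(self, rng, caplog):
        s = series(rng.normal(size=2000), station="W", factor="n")
        with caplog.at_level("WARNING"):
            got = fnn_dimension(s, delay=1, max_dim=6)
        assert got == 6
        assert any("using max_dim" in r.message for r in caplog.records)

    def test_linear_ramp_is_one_dimensional(self):
        s = series(np.arange(500, dtype=float))
        assert fnn_fractions(s, delay=1, max_dim=2)[0] == 0.0
        assert fnn_dimension(s, delay=1, max_dim=5) == 1

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            fnn_dimension(series(range(20)), delay=5, max_dim=6)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fnn_dimension(series(np.zeros(100)), delay=1)


class TestTimeSeries:
    def test_standardized_zero_mean_unit_sd(self, rng):
        s = series(rng.normal(3.0, 2.5, 400)).standardized()
        assert abs(s.values.mean()) < 1e-12
        assert abs(s.values.std() - 1) < 1e-12

    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            series([1.0, np.nan, 2.0])

    def test_truncated_keeps_metadata(self):
        s = series(np.arange(10), station="ST1", factor="pH").truncated(5)
        assert len(s) == 5 and s.station == "ST1" and s.factor == "pH"
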