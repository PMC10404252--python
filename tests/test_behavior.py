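"""Behavioral statistics: preference indices against hand-worked values,
binomial valence calls against exact tail summation, resampling stability,
and the POR detection rule on constructed traces."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from valencemap import behavior
from valencemap.datasets import PORMatrix, PORTrace


def matrix(rows):
    arr = np.asarray(rows)
    return PORMatrix(arr, [f"o{i}" for i in range(arr.shape[1])])


class TestScores:
    def test_all_ones(self):
        s = behavior.compute_scores(matrix(np.ones((4, 3), dtype=int)))
        assert (s.norm_score == 1.0).all()
        assert (s.preference_index == 0.0).all()

    def test_hand_worked_example(self):
        s = behavior.compute_scores(matrix([[1, 0, 0], [1, 1, 0], [1, 0, 1]]))
        assert list(s.total) == [3, 1, 1]
        np.testing.assert_allclose(s.norm_score, [1.0, 1 / 3, 1 / 3])
        np.testing.assert_allclose(s.preference_index, [2 / 3, 0.0, 0.0])

    def test_median_odor_has_zero_index(self):
        rng = np.random.default_rng(0)
        m = matrix((rng.random((9, 5)) < 0.5).astype(int))
        s = behavior.compute_scores(m)
        assert np.isclose(np.median(s.preference_index), 0.0)
        assert ((s.norm_score >= 0) & (s.norm_score <= 1)).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            PORMatrix(np.empty((0, 0)), [])


def exact_tails(total, n, p):
    """Independent oracle: exact binomial tail sums via math.comb."""
    pmf = [math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(n + 1)]
    return sum(pmf[total:]), sum(pmf[: total + 1])


class TestValenceCalls:
    def test_median_total_is_neutral(self):
        # every column identical -> all totals at the median expectation
        m = matrix(np.tile([[1], [0], [1], [0]], (1, 4)))
        calls = behavior.classify_valence(m)
        assert all(c.valence_class == "neutral" for c in calls)

    def test_examples_against_exact_summation(self):
        n, p0 = 26, 0.4
        up, _ = exact_tails(18, n, p0)
        assert up < 0.1
        _, low = exact_tails(0, n, p0)
        assert low < 0.1
        rows = np.zeros((n, 2), dtype=int)
        rows[:18, 0] = 1  # total 18 vs total 0
        calls = behavior.classify_valence(PORMatrix(rows, ["a", "b"]), null_probability=p0)
        assert calls[0].valence_class == "appetitive"
        assert calls[1].valence_class == "unappetitive"
        assert np.isclose(calls[0].p_value, up)

    @given(
        n=st.integers(2, 12),
        total=st.integers(0, 12),
        p0=st.floats(0.05, 0.95),
        alpha=st.floats(0.01, 0.3),
    )
    @settings(deadline=None, max_examples=60)
    def test_agrees_with_enumeration(self, n, total, p0, alpha):
        total = min(total, n)
        rows = np.zeros((n, 1), dtype=int)
        rows[:total] = 1
        (call,) = behavior.classify_valence(
            PORMatrix(rows, ["x"]), alpha=alpha, null_probability=p0
        )
        up, low = exact_tails(total, n, p0)
        if up < alpha:
            assert call.valence_class == "appetitive"
        elif low < alpha:
            assert call.valence_class == "unappetitive"
        else:
            assert call.valence_class == "neutral"


class TestResampling:
    def test_full_sample_returns_exactly_one(self):
        rng = np.random.default_rng(1)
        m = matrix((rng.random((10, 6)) < 0.4).astype(int))
        mean, sem = behavior.monte_carlo_locust_subsample(m, n=10, n_sims=25, seed=0)
        assert mean == 1.0 and sem == 0.0

    def test_nondecreasing_in_subset_size(self):
        # averaged over seeds, stability grows with subset size
        curves = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            m = matrix((rng.random((20, 8)) < rng.random(8)).astype(int))
            curve = [
                behavior.monte_carlo_locust_subsample(m, n, n_sims=30, seed=seed)[0]
                for n in (3, 10, 20)
            ]
            curves.append(curve)
        mean_curve = np.nanmean(curves, axis=0)
        assert mean_curve[0] < mean_curve[1] < mean_curve[2]

    def test_invalid_subset_size(self):
        m = matrix(np.ones((4, 3), dtype=int))
        with pytest.raises(ValueError):
            behavior.monte_carlo_locust_subsample(m, 0)


def make_trace(values, onset=60, offset=180, fps=30.0):
    return PORTrace(np.asarray(values, dtype=float), onset, offset, fps=fps)


class TestDetection:
    def test_constant_trace_is_negative(self):
        assert not behavior.detect_por_response(make_trace(np.full(300, 2.0)))

    @pytest.mark.parametrize(
        "duration_frames,expected", [(36, True), (24, False)]  # 1.2 s vs 0.8 s
    )
    def test_frame_count_rule(self, duration_frames, expected):
        rng = np.random.default_rng(0)
        base = 0.5 + 0.05 * rng.standard_normal(300)  # small but nonzero baseline s.d.
        sd = base[:60].std()
        trace = base.copy()
        trace[70 : 70 + duration_frames] = base[:60].mean() + 8 * sd + 2.0
        assert behavior.detect_por_response(make_trace(trace)) is expected

    def test_absolute_separation_gate(self):
        rng = np.random.default_rng(1)
        base = 0.5 + 0.01 * rng.standard_normal(300)
        trace = base.copy()
        trace[70:110] = 1.4  # far above 6.5 s.d. but below the 1.5-unit gate
        assert not behavior.detect_por_response(make_trace(trace))
        trace[70:110] = 1.6
        assert behavior.detect_por_response(make_trace(trace))

    def test_scaling_invariance_only_without_gate(self):
        rng = np.random.default_rng(2)
        base = 0.5 + 0.05 * rng.standard_normal(300)
        trace = base.copy()
        trace[70:110] = 5.0
        small = make_trace(trace * 0.1)
        assert behavior.detect_por_response(small, separation_gate=0.0)
        assert not behavior.detect_por_response(small)  # gate is absolute

    def test_contiguity_flag(self):
        rng = np.random.default_rng(3)
        base = 0.5 + 0.05 * rng.standard_normal(300)
        trace = base.copy()
        trace[70:180:2] = 5.0  # 55 hit frames, never 30 in a row
        assert behavior.detect_por_response(make_trace(trace))
        assert not behavior.detect_por_response(make_trace(trace), contiguous=True)

    def test_requires_two_second_baseline(self):
        with pytest.raises(ValueError):
            behavior.detect_por_response(make_trace(np.ones(200), onset=30, offset=100))


class TestNormalization:
    def test_affine_map(self):
        t = make_trace(np.linspace(2, 10, 300))
        (out,), flat = behavior.normalize_trace_set([t])
        assert not flat
        assert out.separation.min() == 0.0 and out.separation.max() == 1.0
        assert np.isclose(out.separation[149], 0.5, atol=0.01)

    def test_already_unit_range_unchanged(self):
        t = make_trace(np.linspace(0, 1, 300))
        (out,), _ = behavior.normalize_trace_set([t])
        np.testing.assert_allclose(out.separation, t.separation)

    @given(offset=st.floats(0.0, 50.0))
    @settings(deadline=None, max_examples=20)
    def test_offset_invariance(self, offset):
        rng = np.random.default_rng(4)
        vals = rng.random(300) * 3
        (a,), _ = behavior.normalize_trace_set([make_trace(vals)])
        (b,), _ = behavior.normalize_trace_set([make_trace(vals + offset)])
        np.testing.assert_allclose(a.separation, b.separation, atol=1e-12)

    def test_flat_set_flagged(self):
        (out,), flat = behavior.normalize_trace_set([make_trace(np.full(300, 2.0))])
        assert flat and not out.separation.any()


class TestLinearTrend:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = behavior.linear_trend(x, 2.5 * x - 1.0)
        assert np.isclose(res["r_squared"], 1.0)
        assert np.isclose(res["slope"], 2.5)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        x, y = rng.random(10), rng.random(10)
        res = behavior.linear_trend(x, y)
        A = np.vstack([x, np.ones_like(x)]).T
        slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
        assert abs(res["slope"] - slope) < 1e-10
        assert abs(res["intercept"] - intercept) < 1e-10

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            behavior.linear_trend(np.ones(5), np.arange(5.0))
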