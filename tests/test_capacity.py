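import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

import ipcap
from ipcap.capacity import (
    CapacityEstimator,
    TargetFunction,
    build_target,
    capacity_score,
    cutoff_threshold,
    explore_capacities,
    legendre,
)
from ipcap.signals import make_step_signal
from ipcap.systems import delay_line_states


def legendre_sum_form(d, s):
    """Independent oracle: P_d via the binomial-square sum expansion."""
    s = np.asarray(s, dtype=float)
    total = np.zeros_like(s)
    for j in range(d + 1):
        total += comb(d, j) ** 2 * (s - 1.0) ** (d - j) * (s + 1.0) ** j
    return total / 2**d


class TestLegendre:
    def test_degree_zero_is_one(self):
        assert legendre(0, 0.73) == 1.0

    def test_degree_one_is_identity(self):
        assert legendre(1, 0.3) == pytest.approx(0.3)

    def test_value_one_at_right_endpoint(self):
        for d in range(11):
            assert legendre(d, 1.0) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=40)
    @given(d=st.integers(0, 8), s=st.floats(-1.0, 1.0, allow_nan=False))
    def test_matches_sum_form(self, d, s):
        assert legendre(d, s) == pytest.approx(legendre_sum_form(d, s), abs=1e-9)

    def test_empirical_orthogonality(self):
        u = make_step_signal(200_000, 1.0, seed=17).values
        for a, b in [(1, 2), (1, 3), (2, 3), (2, 4)]:
            inner = np.mean(legendre(a, u) * legendre(b, u))
            assert abs(inner) < 5.0 / np.sqrt(u.size)


class TestTargetFunction:
    def test_canonical_form_enforced(self):
        with pytest.raises(ValueError):
            TargetFunction((1, 0))
        with pytest.raises(ValueError):
            TargetFunction(())

    def test_degree_and_delay(self):
        tf = TargetFunction((2, 1, 0, 4))
        assert tf.total_degree == 7
        assert tf.max_delay == 3
        assert tf.n_factors == 3

    def test_label_roundtrip(self):
        tf = TargetFunction((0, 3, 1))
        assert TargetFunction.from_label(tf.label()) == tf

    def test_shift(self):
        assert TargetFunction((2,)).shifted(2).degrees == (0, 0, 2)


class TestBuildTarget:
    def test_product_example(self):
        u = make_step_signal(500, 1.0, seed=3)
        w = 10
        y = build_target((2, 1, 0, 4), u, washout=w)
        v = u.values
        expected = (
            legendre(2, v[w:]) * legendre(1, v[w - 1 : -1]) * legendre(4, v[w - 3 : -3])
        )
        np.testing.assert_allclose(y, expected)

    def test_degree_one_is_input(self):
        u = make_step_signal(100, 1.0, seed=3)
        np.testing.assert_allclose(build_target((1,), u, washout=0), u.values)

    def test_pure_delay(self):
        u = make_step_signal(100, 1.0, seed=3)
        m = 4
        y = build_target((0,) * m + (1,), u, washout=m)
        np.testing.assert_allclose(y, u.values[: 100 - m])

    def test_delay_beyond_washout_rejected(self):
        u = make_step_signal(100, 1.0, seed=3)
        with pytest.raises(ValueError):
            build_target((0, 0, 1), u, washout=1)


class TestCapacityScore:
    def test_state_column_is_fully_reconstructable(self):
        u = make_step_signal(2000, 1.0, seed=5)
        X = delay_line_states(4, u)
        assert capacity_score(X[:, 2], X) == pytest.approx(1.0)

    def test_delay_line_exact_memory(self):
        u = make_step_signal(5000, 1.0, seed=5)
        X = delay_line_states(3, u)[10:]
        y1 = build_target((0, 1), u, washout=10)
        assert capacity_score(y1, X) == pytest.approx(1.0, abs=1e-9)
        y5 = build_target((0, 0, 0, 0, 0, 1), u, washout=10)
        assert capacity_score(y5, X) < cutoff_threshold(3, 4990)

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError):
            capacity_score(np.ones(50), np.random.default_rng(0).normal(size=(50, 3)))


class TestCutoff:
    def test_zero_factor_disables_filtering(self):
        assert cutoff_threshold(50, 1000, factor=0.0) == 0.0

    def test_monotonicity(self):
        assert cutoff_threshold(60, 1000) > cutoff_threshold(50, 1000)
        assert cutoff_threshold(50, 2000) < cutoff_threshold(50, 1000)

    def test_lower_tail_reading_is_tiny(self):
        # the literal lower-quantile reading filters essentially nothing
        assert cutoff_threshold(50, 1000, tail="lower") < cutoff_threshold(50, 1000) / 4


class TestExploration:
    def test_delay_line_profile(self):
        u = make_step_signal(30_000, 1.0, seed=21)
        X = delay_line_states(5, u)
        table = explore_capacities(X, u)
        assert table.total_capacity == pytest.approx(5.0, rel=0.02)
        assert table.max_degree == 1
        assert table.max_delay == 4
        prof = table.profile(by="delay")
        for d in range(5):
            assert prof.loc[d] == pytest.approx(1.0, abs=0.01)

    def test_memoryless_quadratic_system(self):
        # x(k) = u(k)^2 carries P_2 exactly and is uncorrelated with P_1
        u = make_step_signal(20_000, 1.0, seed=23)
        X = (u.values**2)[:, None]
        table = explore_capacities(X, u)
        assert table.capacity_at((2,)) == pytest.approx(1.0, abs=1e-6)
        assert table.capacity_at((1,)) == 0.0
        assert table.max_degree == 2

    def test_profile_partitions_total(self):
        u = make_step_signal(20_000, 1.0, seed=25)
        X = delay_line_states(4, u)
        table = explore_capacities(X, u)
        assert table.profile(by="delay").sum() == pytest.approx(table.total_capacity)
        assert table.profile(by="degree").sum() == pytest.approx(table.total_capacity)
        pivot = table.profile(by="delay", stratify=True)
        assert pivot.to_numpy().sum() == pytest.approx(table.total_capacity)

    def test_invariance_under_invertible_mixing(self):
        # Eq-style capacity depends only on the column space of the states
        u = make_step_signal(8000, 1.0, seed=27)
        X = delay_line_states(4, u)
        rng = np.random.default_rng(0)
        M = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        t1 = explore_capacities(X, u)
        t2 = explore_capacities(X @ M, u)
        assert t2.total_capacity == pytest.approx(t1.total_capacity, abs=1e-6)
        merged = t1.records.merge(t2.records, on="target", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["raw_a"], merged["raw_b"], atol=1e-8)

    def test_rank_deficient_states_warn_but_proceed(self):
        u = make_step_signal(5000, 1.0, seed=29)
        X = delay_line_states(3, u)
        X = np.hstack([X, X[:, :1]])  # duplicated column
        with pytest.warns(UserWarning, match="rank deficient"):
            table = explore_capacities(X, u)
        assert table.total_capacity == pytest.approx(3.0, rel=0.02)

    def test_evaluate_fixed_targets(self):
        u = make_step_signal(5000, 1.0, seed=31)
        X = delay_line_states(3, u)
        est = CapacityEstimator()
        table = est.evaluate(X, u, [(1,), (0, 1), (2,), (0, 0, 0, 0, 1)])
        assert table.capacity_at((0, 1)) == pytest.approx(1.0)
        assert table.capacity_at((2,)) == 0.0
        assert table.capacity_at((0, 0, 0, 0, 1)) == 0.0


class TestSerialization:
    def test_csv_and_json(self, tmp_path):
        u = make_step_signal(5000, 1.0, seed=33)
        table = explore_capacities(delay_line_states(3, u), u)
        table.to_csv(tmp_path / "caps.csv")
        import pandas as pd

        back = pd.read_csv(tmp_path / "caps.csv")
        assert back["capacity"].sum() == pytest.approx(table.total_capacity)
        import json

        payload = json.loads(table.to_json())
        assert payload["N"] == 3
        assert payload["total_capacity"] == pytest.approx(table.total_capacity)
        assert payload["cutoff"] == pytest.approx(table.cutoff)
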