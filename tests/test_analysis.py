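"""Statistics tests: group summaries, paired tests, Holm, power."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sqmsim import (
    cohens_d_ci,
    dominance_summary,
    holm_adjust,
    min_n_for_power,
    paired_test,
    power_paired_t,
)


def _table(values, condition="V"):
    return pd.DataFrame(
        {
            "observer_id": [f"O{i}" for i in range(len(values))],
            "condition": condition,
            "dominance": values,
        }
    )


class TestDominanceSummary:
    def test_two_observer_hand_computation(self):
        out = dominance_summary(_table([40.0, 60.0]))
        assert out["mean_dominance"].item() == pytest.approx(50.0)
        assert out["sem"].item() == pytest.approx(10.0)  # sd=sqrt(200), /sqrt(2)

    def test_unanimous_cohort(self):
        out = dominance_summary(_table([100.0] * 5))
        assert out["mean_dominance"].item() == 100.0
        assert out["sem"].item() == 0.0

    def test_reference_flip_identity(self):
        vals = np.array([55.0, 72.0, 61.0, 48.0])
        a = dominance_summary(_table(vals))
        b = dominance_summary(_table(100.0 - vals))
        assert b["mean_dominance"].item() == pytest.approx(
            100.0 - a["mean_dominance"].item()
        )
        assert b["sem"].item() == pytest.approx(a["sem"].item())

    def test_groups_by_condition_and_report(self):
        df = pd.concat(
            [_table([40.0, 60.0], "V").assign(report="naive"),
             _table([20.0, 30.0], "V-AV14").assign(report="naive")]
        )
        out = dominance_summary(df)
        assert len(out) == 2
        assert set(out["condition"]) == {"V", "V-AV14"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dominance_summary(_table([]))


class TestPairedTest:
    def test_identical_samples(self):
        r = paired_test([50.0, 60.0, 70.0], [50.0, 60.0, 70.0])
        assert r.t_statistic == 0.0 and r.cohens_d == 0.0
        assert r.p_value == 1.0 and not r.degenerate

    def test_constant_shift_is_degenerate(self):
        r = paired_test([51.0, 61.0], [50.0, 60.0])
        assert r.degenerate and r.p_value is None

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        a = rng.normal(60, 10, 9)
        b = rng.normal(50, 10, 9)
        r = paired_test(a, b)
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert r.t_statistic == pytest.approx(t_ref)
        assert r.p_value == pytest.approx(p_ref)
        assert r.df == 8

    def test_effect_size_convention_d_equals_t_over_sqrt_n(self):
        # the reported d=0.15 alongside t(9)=0.47 implies d = t/sqrt(n)
        rng = np.random.default_rng(1)
        a = rng.normal(55, 8, 10)
        b = rng.normal(52, 8, 10)
        r = paired_test(a, b)
        assert r.cohens_d == pytest.approx(r.t_statistic / math.sqrt(10))

    def test_ci_brackets_d_and_is_ordered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(60, 5, 8)
        b = rng.normal(50, 5, 8)
        r = paired_test(a, b)
        lo, hi = r.ci95
        assert lo < r.cohens_d < hi

    def test_null_ci_symmetric(self):
        lo, hi = cohens_d_ci(0.0, 10)
        assert lo == pytest.approx(-hi, abs=1e-6)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_test([1.0, 2.0], [1.0])

    def test_type_i_error_near_alpha(self):
        # simulated null: both samples from one distribution
        rng = np.random.default_rng(3)
        n_rep, n = 10_000, 10
        diffs = rng.normal(0.0, 1.0, size=(n_rep, n))
        t = diffs.mean(axis=1) / (diffs.std(axis=1, ddof=1) / math.sqrt(n))
        p = 2 * stats.t.sf(np.abs(t), n - 1)
        rate = (p < 0.05).mean()
        se = math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3 * se


class TestHolm:
    def test_two_p_values(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.3]) == pytest.approx([0.3])

    def test_against_step_down_definition(self):
        # direct step-down computation as independent oracle
        p = np.array([0.04, 0.001, 0.03, 0.2])
        order = np.argsort(p)
        m = len(p)
        stepped = np.maximum.accumulate(
            [(m - i) * p[order[i]] for i in range(m)]
        ).clip(max=1.0)
        expected = np.empty(m)
        expected[order] = stepped
        assert holm_adjust(p) == pytest.approx(expected)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8)
    )
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance_and_bounds(self, p):
        adj = holm_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)
        perm = np.random.default_rng(0).permutation(len(p))
        adj_perm = holm_adjust(np.asarray(p)[perm])
        assert adj_perm == pytest.approx(adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])


class TestPower:
    def test_printed_power_value(self):
        # d=1.47, n=8, two-sided alpha=.05 -> 94.3%
        assert power_paired_t(1.47, 8) == pytest.approx(0.943, abs=0.005)

    def test_min_n_for_90_percent_power_at_d2(self):
        assert min_n_for_power(2.0, 0.90) == 5

    def test_huge_effect_needs_minimum_two(self):
        assert min_n_for_power(50.0, 0.90) == 2

    def test_null_effect_power_equals_alpha(self):
        assert power_paired_t(0.0, 12, alpha=0.05) == pytest.approx(0.05, abs=1e-9)

    def test_minimality_contract(self):
        for d, target in [(0.9, 0.8), (1.2, 0.95), (2.0, 0.9)]:
            n = min_n_for_power(d, target)
            assert power_paired_t(d, n) >= target
            if n > 2:
                assert power_paired_t(d, n - 1) < target

    def test_monotone_in_n_and_d(self):
        powers_n = [power_paired_t(1.0, n) for n in range(3, 15)]
        assert np.all(np.diff(powers_n) > 0)
        powers_d = [power_paired_t(d, 8) for d in (0.3, 0.6, 1.0, 1.5, 2.0)]
        assert np.all(np.diff(powers_d) > 0)

    def test_one_sided_exceeds_two_sided(self):
        assert power_paired_t(1.0, 8, tails="one") > power_paired_t(1.0, 8)

    def test_against_monte_carlo_oracle(self):
        # simulated rejection rate of the paired t-test at (d, n)
        d, n, n_rep = 0.8, 10, 10_000
        rng = np.random.default_rng(7)
        x = rng.normal(d, 1.0, size=(n_rep, n))
        t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / math.sqrt(n))
        crit = stats.t.ppf(0.975, n - 1)
        rate = (np.abs(t) > crit).mean()
        expected = power_paired_t(d, n)
        se = math.sqrt(expected * (1 - expected) / n_rep)
        assert abs(rate - expected) < 3 * se

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            power_paired_t(1.0, 1)
        with pytest.raises(ValueError):
            min_n_for_power(-1.0, 0.9)
        with pytest.raises(ValueError):
            min_n_for_power(1.0, 0.01)
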