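"""Two-sample tests, Fisher exact, BH-FDR and the comparison battery."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mal_profiler.cohort_stats import (
    ComparisonSpec,
    bh_fdr,
    compare_groups,
    default_battery,
    fisher_exact_2x2,
    two_sample_t,
)
from mal_profiler.errors import ConfigurationError, InsufficientDataError, ValidationError


def fisher_enumeration(table) -> float:
    """Oracle: full hypergeometric enumeration with fixed margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = comb(n, c1)
    obs = comb(r1, a) * comb(r2, c) / denom
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = comb(r1, x) * comb(r2, c1 - x) / denom
        if p <= obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def bh_step_up(p):
    """Oracle: direct step-up formula p_(i)·m/i with monotone enforcement."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return np.clip(adjusted, 0, 1)


class TestTwoSampleT:
    def test_identical_samples_give_null_result(self):
        stat, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_pooled_variant_matches_hand_computation(self):
        # mean difference -3, pooled SE sqrt(2/3), t(4) tail
        stat, p = two_sample_t([1, 2, 3], [4, 5, 6], welch=False)
        assert stat == pytest.approx(-3.6742346, abs=1e-6)
        assert p == pytest.approx(0.0213116, abs=1e-6)

    def test_zero_variance_both_groups_yields_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="zero variance"):
            stat, p = two_sample_t([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert p == 1.0

    def test_insufficient_data_error(self):
        with pytest.raises(InsufficientDataError):
            two_sample_t([1.0], [1.0, 2.0])

    @given(
        x=st.lists(st.floats(-50, 50), min_size=3, max_size=12),
        y=st.lists(st.floats(-50, 50), min_size=3, max_size=12),
        shift=st.floats(-100, 100),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_swap_and_shift_invariance(self, x, y, shift):
        # skip near-degenerate variances where float cancellation flips the
        # zero-variance handling between the raw and shifted samples
        if np.var(x) < 1e-3 or np.var(y) < 1e-3:
            return
        _, p = two_sample_t(x, y)
        _, p_swapped = two_sample_t(y, x)
        _, p_shifted = two_sample_t([v + shift for v in x], [v + shift for v in y])
        assert p == pytest.approx(p_swapped, rel=1e-9)
        assert p == pytest.approx(p_shifted, rel=1e-6)


class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_perfect_association_matches_enumeration(self):
        p = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)
        assert p == pytest.approx(fisher_enumeration([[10, 0], [0, 10]]), rel=1e-9)

    def test_degenerate_margin(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[1, -2], [3, 4]])

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_matches_enumeration_and_symmetries(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_2x2([[a, b], [c, d]])
        assert p == pytest.approx(fisher_enumeration([[a, b], [c, d]]), rel=1e-7, abs=1e-12)
        assert p == pytest.approx(fisher_exact_2x2([[a, c], [b, d]]), rel=1e-7)
        assert p == pytest.approx(fisher_exact_2x2([[d, c], [b, a]]), rel=1e-7)


class TestBhFdr:
    @pytest.mark.parametrize(
        "p_in, expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_worked_examples(self, p_in, expected):
        assert bh_fdr(p_in) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_matches_step_up_oracle(self, p):
        adjusted = bh_fdr(p)
        assert adjusted == pytest.approx(bh_step_up(p), rel=1e-9, abs=1e-12)
        assert np.all(adjusted >= np.asarray(p) - 1e-12)
        # re-adjustment can only move values further toward 1 (the
        # adjustment is not idempotent: e.g. [1.0, 0.25] -> [1.0, 0.5])
        assert np.all(bh_fdr(adjusted) >= adjusted - 1e-12)

    @given(
        p=st.lists(st.floats(0, 1), min_size=2, max_size=20),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_permutation_equivariance(self, p, seed):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(p))
        direct = np.asarray(bh_fdr(p))[perm]
        permuted = bh_fdr(list(np.asarray(p)[perm]))
        assert permuted == pytest.approx(direct, rel=1e-9, abs=1e-12)


class TestCompareGroups:
    @staticmethod
    def _toy_cohort(seed=0, n=200):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "mal": np.repeat([False, True], n // 2),
                "age": rng.normal(60, 10, n),
                "af": rng.integers(0, 2, n),
            }
        )

    def test_single_variable_battery_has_equal_raw_and_adjusted_p(self):
        cohort = self._toy_cohort()
        result = compare_groups(cohort, [ComparisonSpec("age")])
        assert len(result) == 1
        assert result.loc[0, "p_fdr"] == pytest.approx(result.loc[0, "p_raw"])

    def test_unknown_variable_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="nonexistent"):
            compare_groups(self._toy_cohort(), [ComparisonSpec("nonexistent")])

    def test_planted_binary_difference_detected(self):
        rng = np.random.default_rng(5)
        n = 500
        cohort = pd.DataFrame(
            {
                "mal": np.repeat([False, True], n),
                "flag": np.concatenate(
                    [rng.random(n) < 0.10, rng.random(n) < 0.30]
                ).astype(int),
                "noise": rng.normal(size=2 * n),
            }
        )
        result = compare_groups(
            cohort, [ComparisonSpec("flag", "binary"), ComparisonSpec("noise")]
        )
        row = result.set_index("variable").loc["flag"]
        assert row["significant"]
        assert row["test"] == "fisher_exact"

    def test_per_variable_complete_case_n(self):
        cohort = self._toy_cohort()
        cohort.loc[:49, "age"] = np.nan
        result = compare_groups(cohort, [ComparisonSpec("age")])
        assert result.loc[0, "n_single"] + result.loc[0, "n_multiple"] == 150

    def test_default_battery_runs_on_generated_cohort(self):
        from mal_profiler.constellation import label_cohort
        from mal_profiler.synthetic import GeneratorConfig, generate_cohort

        cohort = label_cohort(generate_cohort(GeneratorConfig(n_patients=600, seed=3)))
        result = compare_groups(cohort, default_battery())
        assert len(result) == 16
        assert (result["p_fdr"] >= result["p_raw"] - 1e-12).all()
        assert (result["significant"] == (result["p_fdr"] < 0.05)).all()
        # the small-vessel etiology gap (26% vs 4%) is planted by design
        # and large enough to survive FDR at this sample size
        assert result.set_index("variable").loc["etiology_small_vessel", "significant"]
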