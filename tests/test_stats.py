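"""Normality gate, Wilcoxon layer and cohort summary tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from oculodyn.exceptions import DegenerateInputError, InvalidParameterError, TooShortError
from oculodyn.stats_report import (
    Comparison,
    benjamini_hochberg,
    build_summary_tables,
    session_significance,
    shapiro_wilk,
    wilcoxon_signed_rank,
)


def enumerate_wilcoxon_p(diffs):
    """Independent oracle: two-sided exact p by iterating all 2^n sign
    assignments of the absolute-difference ranks."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = [
        np.sum(np.array(signs) * ranks)
        for signs in itertools.product([0, 1], repeat=len(d))
    ]
    w_all = np.array(w_all)
    p_low = np.mean(w_all <= w_obs + 1e-12)
    p_high = np.mean(w_all >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_low, p_high))


class TestShapiroWilk:
    def test_normal_sample_passes(self):
        x = np.random.default_rng(0).normal(size=50)
        assert shapiro_wilk(x) > 0.05

    def test_uniform_sample_mostly_fails(self):
        """Power against a uniform alternative at n=50: the reference
        implementation rejects ~81 of these 100 seeds."""
        rejections = 0
        for seed in range(100):
            x = np.random.default_rng(seed).uniform(size=50)
            if shapiro_wilk(x) < 0.05:
                rejections += 1
        assert rejections >= 70

    def test_degenerate_and_out_of_range(self):
        with pytest.raises(DegenerateInputError):
            shapiro_wilk(np.ones(10))
        with pytest.raises(InvalidParameterError):
            shapiro_wilk(np.arange(2.0))


class TestWilcoxon:
    def test_all_positive_five_differences(self):
        """d = {1..5} all positive: W+ = 15, the extreme of 2^5 = 32 equally
        likely assignments, two-sided p = 2/32 = 0.0625."""
        res = wilcoxon_signed_rank(np.arange(1.0, 6.0) + 10.0, np.full(5, 10.0))
        assert res.p_value == pytest.approx(0.0625)
        assert res.method == "exact"

    def test_identical_samples_degenerate(self):
        a = np.arange(8.0)
        res = wilcoxon_signed_rank(a, a)
        assert res.p_value == 1.0 and res.degenerate

    def test_sign_flip_symmetry(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        assert wilcoxon_signed_rank(a, b).p_value == pytest.approx(
            wilcoxon_signed_rank(b, a).p_value
        )

    @given(st.integers(0, 10_000))
    def test_exact_p_matches_full_enumeration(self, seed):
        """Exact DP distribution equals brute-force enumeration over all
        sign assignments, for n <= 12 including ties."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        d = rng.integers(-5, 6, size=n).astype(float)
        if np.all(d == 0) or np.count_nonzero(d) < 5:
            return
        res = wilcoxon_signed_rank(d + 100.0, np.full(n, 100.0))
        assert res.p_value == pytest.approx(enumerate_wilcoxon_p(d), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(10):
            a = rng.normal(size=14)
            b = rng.normal(size=14)
            ours = wilcoxon_signed_rank(a, b).p_value
            ref = scipy.stats.wilcoxon(a, b, method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_large_n_uses_corrected_normal_approximation(self, rng):
        a = rng.normal(size=60)
        b = rng.normal(size=60) + 0.3
        res = wilcoxon_signed_rank(a, b)
        assert res.method == "approx"
        ref = scipy.stats.wilcoxon(
            a - b, zero_method="wilcox", correction=True, method="approx"
        ).pvalue
        assert res.p_value == pytest.approx(float(ref))

    def test_too_few_nonzero_differences(self):
        with pytest.raises(TooShortError):
            wilcoxon_signed_rank(np.array([1.0, 2, 3, 3, 3]), np.array([2.0, 3, 4, 3, 3]))


def _null_table(n_sessions, n_fix=29, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sessions):
        for f in range(n_fix):
            for condition in ("BNR", "ANR"):
                rows.append(
                    dict(
                        session_id=f"r{s:03d}",
                        fixation_id=f,
                        condition=condition,
                        measure="D2",
                        scope=2999,
                        value=rng.normal(),
                    )
                )
    return pd.DataFrame(rows)


BNR_VS_ANR = Comparison("condition", "BNR", "ANR", fixed=(("measure", "D2"), ("scope", 2999)))


class TestSessionSignificance:
    def test_null_cohort_false_positive_rate(self):
        """With both conditions drawn from the same distribution the
        session-level rejection rate sits near alpha."""
        res = session_significance(_null_table(200, seed=3), BNR_VS_ANR, alpha=0.05)
        assert 0.5 <= res.percent_significant <= 12.0

    def test_injected_shift_detected_everywhere(self):
        table = _null_table(10, seed=4)
        table.loc[table["condition"] == "ANR", "value"] += 5.0
        res = session_significance(table, BNR_VS_ANR, alpha=0.05)
        assert res.percent_significant == 100.0

    def test_single_session_percent_is_zero_or_hundred(self):
        res = session_significance(_null_table(1, seed=5), BNR_VS_ANR)
        assert res.percent_significant in (0.0, 100.0)

    def test_invariant_to_session_order(self):
        table = _null_table(20, seed=6)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = session_significance(table, BNR_VS_ANR).percent_significant
        b = session_significance(shuffled, BNR_VS_ANR).percent_significant
        assert a == b

    def test_histogram_bins_are_0p05_wide(self):
        res = session_significance(_null_table(30, seed=7), BNR_VS_ANR)
        assert len(res.histogram_counts) == 20
        assert res.histogram_counts.sum() == len(res.p_values)

    def test_short_sessions_excluded_and_listed(self):
        table = _null_table(3, n_fix=3, seed=8)
        res = session_significance(table, BNR_VS_ANR)
        assert len(res.excluded_sessions) == 3
        assert np.isnan(res.percent_significant)


def _cohort_table(n_sessions=2, seed=0, constant=None):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sessions):
        for f in range(29):
            for condition in ("BNR", "ANR"):
                for scope in (1000, 1500, 2999):
                    v = constant if constant is not None else abs(rng.normal(0.3, 0.1))
                    rows.append(
                        dict(session_id=f"r{s}", fixation_id=f, condition=condition,
                             measure="D2", scope=scope, value=v)
                    )
                for scope in ("<1...700>", "<700...1500>", "<1500...2999>"):
                    v = constant if constant is not None else abs(rng.normal(0.06, 0.02))
                    rows.append(
                        dict(session_id=f"r{s}", fixation_id=f, condition=condition,
                             measure="K2", scope=scope, value=v)
                    )
    return pd.DataFrame(rows)


class TestSummaryTables:
    def test_structure_mirrors_cohort_design(self):
        tables = build_summary_tables(_cohort_table())
        d2 = tables["d2_means"]
        assert list(d2.columns) == [1000, 1500, 2999]
        assert len(d2.index) == 3  # BNR, ANR, significance row
        k2 = tables["k2_means"]
        assert list(k2.columns) == ["<1...700>", "<700...1500>", "<1500...2999>"]
        assert tables["d2_length_significance"].shape == (2, 3)
        assert tables["k2_window_significance"].shape == (2, 3)

    def test_constant_inputs_have_zero_spread(self):
        tables = build_summary_tables(_cohort_table(constant=0.25))
        cell = tables["d2_means"].loc["BNR mean (stdev)", 1000]
        assert cell == "0.2500(0.0000)"

    def test_d2_bound_violation_flagged(self):
        table = _cohort_table()
        table.loc[
            (table["measure"] == "D2") & (table["scope"] == 1000), "value"
        ] = 6.5  # above 2 log10(1000) = 6
        tables = build_summary_tables(table)
        assert any("bound" in f for f in tables["flags"]["flag"])


def test_benjamini_hochberg_monotone():
    p = np.array([0.001, 0.01, 0.02, 0.8])
    q = benjamini_hochberg(p)
    assert np.all(q >= p) and np.all(q <= 1)
    assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)
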