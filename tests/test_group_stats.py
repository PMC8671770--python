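"""Group summaries, ANOVA (raw and summary routes), effect sizes, Tukey-Kramer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edmood.errors import UndefinedStatisticError
from edmood.group_stats import (
    anova_from_raw,
    anova_from_summary,
    ci95_from_summary,
    classify_effect,
    summarize_group,
    summarize_groups,
    tukey_pattern,
)

from conftest import (
    ANXIETY_SUMMARY,
    BINGE_SUMMARY,
    EATING_CONCERN_SUMMARY,
    EXERCISE_SUMMARY,
    SHAPE_CONCERN_SUMMARY,
    WEIGHT_CONCERN_SUMMARY,
)


class TestSummaries:
    def test_identical_values_collapse_ci(self):
        s = summarize_groups([[4.0] * 8])[0]
        assert s.mean == 4.0 and s.sd == 0.0 and s.ci95 == (4.0, 4.0)

    @pytest.mark.parametrize(
        "n, mean, sd, lo, hi",
        [(609, 1.84, 1.45, 1.73, 1.96), (245, 18.89, 1.92, 18.65, 19.13)],
    )
    def test_reproduces_published_intervals(self, n, mean, sd, lo, hi):
        # one unit in the printed last digit: the inputs are rounded summaries
        got = ci95_from_summary(n, mean, sd)
        assert got[0] == pytest.approx(lo, abs=0.01)
        assert got[1] == pytest.approx(hi, abs=0.01)

    def test_raw_group_summary_uses_sample_sd(self):
        x = [1.0, 2.0, 3.0, 4.0]
        s = summarize_groups([x])[0]
        assert s.sd == pytest.approx(np.std(x, ddof=1))
        assert s.ci95[0] < s.mean < s.ci95[1]

    def test_single_value_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_group(1, 3.0, 0.0)


class TestAnova:
    def test_equal_means_give_zero_f(self):
        r = anova_from_summary([(10, 5.0, 1.0), (12, 5.0, 2.0)])
        assert r.f_stat == 0.0 and r.partial_eta_sq == 0.0

    def test_published_anxiety_row_effect_size(self):
        r = anova_from_summary(ANXIETY_SUMMARY)
        assert r.partial_eta_sq == pytest.approx(0.935, abs=0.005)
        assert r.df_between == 3 and r.df_within == 1788
        assert r.effect_class == "large"

    def test_published_eating_concern_row(self):
        r = anova_from_summary(EATING_CONCERN_SUMMARY)
        assert r.f_stat == pytest.approx(141.37, abs=1.5)
        assert r.partial_eta_sq == pytest.approx(0.192, abs=0.005)

    def test_zero_within_variance_gives_infinite_f(self):
        r = anova_from_summary([(5, 1.0, 0.0), (5, 2.0, 0.0)])
        assert np.isinf(r.f_stat) and r.p_value == 0.0

    def test_all_constant_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            anova_from_summary([(5, 1.0, 0.0), (5, 1.0, 0.0)])

    def test_raw_route_matches_summary_route_exactly(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            groups = [
                rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), rng.integers(2, 30))
                for _ in range(rng.integers(2, 6))
            ]
            a = anova_from_raw(groups)
            b = anova_from_summary(
                [(len(g), g.mean(), g.std(ddof=1)) for g in groups]
            )
            assert a.f_stat == pytest.approx(b.f_stat, rel=1e-12)
            assert a.partial_eta_sq == pytest.approx(b.partial_eta_sq, rel=1e-12)

    def test_large_shift_yields_large_effect_class(self):
        rng = np.random.default_rng(6)
        g1 = rng.normal(0, 1, 5000)
        g2 = rng.normal(10, 1, 5000)
        assert anova_from_raw([g1, g2]).effect_class == "large"

    @given(a=st.floats(0.1, 5), b=st.floats(-10, 10))
    @settings(derandomize=True, max_examples=25)
    def test_f_and_eta_invariant_under_affine_map(self, a, b):
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1.0, 20) for m in (0.0, 1.0, 3.0)]
        r1 = anova_from_raw(groups)
        r2 = anova_from_raw([a * g + b for g in groups])
        assert r1.f_stat == pytest.approx(r2.f_stat, rel=1e-9)
        assert r1.partial_eta_sq == pytest.approx(r2.partial_eta_sq, rel=1e-9)

    def test_monte_carlo_anxiety_eta_near_analytic(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(m, sd, n) for n, m, sd in ANXIETY_SUMMARY]
        r = anova_from_raw(groups)
        assert r.partial_eta_sq == pytest.approx(0.935, abs=0.01)


class TestTukey:
    def test_identical_groups_produce_no_letters(self):
        p = tukey_pattern([(20, 1.0, 0.5), (20, 1.0, 0.5)])
        assert p.significant_pairs == ""

    def test_published_shape_concern_all_pairs_differ(self):
        assert tukey_pattern(SHAPE_CONCERN_SUMMARY).significant_pairs == "abcdef"

    def test_published_exercise_row_flags_b_and_d(self):
        letters = tukey_pattern(EXERCISE_SUMMARY).significant_pairs
        assert "b" in letters and "d" in letters

    def test_binge_row_recomputation_from_printed_summaries(self):
        # the printed letter column claims all six pairs differ, but from the
        # printed n/mean/SD the 3v4 contrast is far from significant
        # (q ~ 1.75); the recomputed pattern is abcde
        p = tukey_pattern(BINGE_SUMMARY)
        assert p.significant_pairs == "abcde"
        assert p.p_values[(3, 4)] > 0.05

    def test_adjusted_p_decreases_with_mean_gap(self):
        base = [(30, 0.0, 1.0), (30, 0.5, 1.0)]
        p_small = tukey_pattern(base).p_values[(1, 2)]
        p_big = tukey_pattern([(30, 0.0, 1.0), (30, 1.5, 1.0)]).p_values[(1, 2)]
        assert p_big < p_small

    def test_letter_map_is_lexicographic(self):
        p = tukey_pattern(WEIGHT_CONCERN_SUMMARY)
        assert p.letter_map["a"] == (1, 2)
        assert p.letter_map["f"] == (3, 4)

    def test_zero_within_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            tukey_pattern([(5, 1.0, 0.0), (5, 2.0, 0.0)])


@pytest.mark.parametrize(
    "eta, expected",
    [
        (0.0, "below_small"),
        (0.009, "below_small"),
        (0.01, "small"),
        (0.049, "small"),
        (0.051, "small"),
        (0.06, "medium"),
        (0.127, "medium"),
        (0.139, "medium"),
        (0.14, "large"),
        (0.935, "large"),
        (1.0, "large"),
    ],
)
def test_effect_size_bands(eta, expected):
    assert classify_effect(eta) == expected


def test_effect_size_out_of_range_rejected():
    with pytest.raises(ValueError):
        classify_effect(1.2)
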