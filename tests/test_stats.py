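"""Group summaries, ANOVA and t-test arithmetic against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cytoploid import (
    ValidationError,
    anova_from_components,
    extract_first_level,
    extract_min_genome,
    one_way_anova,
    summarize_groups,
    two_sample_t,
)


def _classified(rows):
    return pd.DataFrame(rows, columns=["species", "area_um2", "cx", "phase"])


class TestSummaries:
    def test_two_point_summary(self):
        df = pd.DataFrame({"area_um2": [0.4, 0.6], "species": ["a", "a"]})
        (s,) = summarize_groups(df, "species")
        assert s.n == 2
        assert s.mean == pytest.approx(0.5)
        assert s.sd == pytest.approx(0.14142, abs=1e-4)

    def test_monte_carlo_class_mean(self, gamete_sample):
        g1 = gamete_sample[gamete_sample["true_class"] == 0]
        (s,) = summarize_groups(g1, "species")
        se = 0.08 / np.sqrt(s.n)
        assert abs(s.mean - 0.5) < 3 * se

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            summarize_groups(pd.DataFrame({"area_um2": []}), "species")


class TestExtraction:
    def test_g1_subset_is_lowest_class(self):
        df = _classified([
            ("x", 1.0, 4, "G1"), ("x", 1.1, 4, "G1"), ("x", 2.0, 8, "G2"),
            ("y", 0.5, 2, "G1"),
        ])
        out = extract_min_genome(df)
        assert len(out["x"]) == 2 and len(out["y"]) == 1

    def test_first_level_includes_replicated_class(self):
        df = _classified([
            ("x", 1.0, 4, "G1"), ("x", 2.0, 8, "G2"), ("x", 4.1, 16, "endo"),
        ])
        out = extract_first_level(df)
        assert len(out["x"]) == 2

    def test_single_class_population_is_all_g1(self):
        df = _classified([("x", 1.0, 4, "G1"), ("x", 1.2, 4, "G1")])
        assert len(extract_min_genome(df)["x"]) == 2

    def test_missing_phases_rejected(self):
        df = pd.DataFrame({"species": ["x"], "area_um2": [1.0]})
        with pytest.raises(ValidationError):
            extract_min_genome(df)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.F == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # SS_b = 3*(2-3.5)^2 + 3*(5-3.5)^2 = 13.5; SS_w = 2+2 = 4
        res = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert res.F == pytest.approx(13.5)
        assert res.ss_between == pytest.approx(13.5)
        assert res.ss_within == pytest.approx(4.0)
        assert res.df_between == 1 and res.df_within == 4

    def test_matches_scipy_oracle(self, rng):
        groups = [rng.normal(loc, 1.0, size=n)
                  for loc, n in [(0.0, 30), (0.5, 45), (0.2, 25)]]
        res = one_way_anova(groups)
        f, p = sps.f_oneway(*groups)
        assert res.F == pytest.approx(f, rel=1e-9)
        assert res.p == pytest.approx(p, rel=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_sum_of_squares_identity(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 5)
        groups = [rng.normal(rng.uniform(0, 3), rng.uniform(0.1, 2),
                             size=rng.integers(2, 40)) for _ in range(k)]
        res = one_way_anova(groups)
        assert res.ss_total == pytest.approx(
            res.ss_between + res.ss_within, rel=1e-9)
        assert res.df_total == res.df_between + res.df_within

    def test_needs_two_groups(self):
        with pytest.raises(ValidationError):
            one_way_anova([[1.0, 2.0]])

    def test_table_reconstruction_from_components(self):
        """Published ANOVA tables follow arithmetically from their SS/df."""
        g1 = anova_from_components(93.7443, 3, 131.887, 2546)
        assert g1.ms_between == pytest.approx(31.2481, abs=1e-4)
        assert round(g1.F, 2) == 603.23
        assert g1.p < 1e-4
        full = anova_from_components(126.513, 3, 775.6, 3152)
        assert round(full.F, 2) == 171.38
        assert full.df_total == 3155


class TestTTest:
    def test_identical_samples(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_zero_variance_equal_means(self):
        res = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_pooled_df_arithmetic(self, rng):
        a, b = rng.normal(0.52, 0.2, 810), rng.normal(1.1, 0.4, 427)
        res = two_sample_t(a, b)
        assert res.df == 810 + 427 - 2 == 1235

    def test_matches_direct_formula_and_scipy(self, rng):
        a, b = rng.normal(0, 1, 9), rng.normal(0.4, 1.3, 14)
        res = two_sample_t(a, b)
        sp2 = ((8 * a.var(ddof=1)) + 13 * b.var(ddof=1)) / 21
        t_direct = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 9 + 1 / 14))
        assert res.t == pytest.approx(t_direct, abs=1e-12)
        t_sp, p_sp = sps.ttest_ind(a, b)
        assert res.t == pytest.approx(t_sp, rel=1e-9)
        assert res.p == pytest.approx(p_sp, rel=1e-9)

    def test_welch_variant(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 3.0, 12)
        res = two_sample_t(a, b, pooled=False)
        t_sp, p_sp = sps.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(t_sp, rel=1e-9)
        assert res.p == pytest.approx(p_sp, rel=1e-9)
        assert not res.pooled

    def test_f_equals_t_squared_for_two_groups(self, rng):
        a, b = rng.normal(0, 1, 25), rng.normal(0.7, 1.1, 31)
        f = one_way_anova([a, b]).F
        t = two_sample_t(a, b).t
        assert f == pytest.approx(t ** 2, rel=1e-9)

    def test_small_samples_rejected(self):
        with pytest.raises(ValidationError):
            two_sample_t([1.0], [2.0, 3.0])
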