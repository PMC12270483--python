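"""First-principles statistics against hand computations and library oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lhpulse import (
    ParameterError,
    ValidationError,
    one_way_anova,
    sidak_adjust,
    t_test_unpaired,
    two_way_anova,
)


class TestTTest:
    def test_identical_samples(self):
        res = t_test_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_formula_small_samples(self):
        # pooled variance 1, se = sqrt(2/3), t = -1/sqrt(2/3)
        res = t_test_unpaired([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.224744871, abs=1e-8)
        assert res.df == (4.0,)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
        a = t_test_unpaired(x, y)
        b = t_test_unpaired(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    @pytest.mark.parametrize("welch", [False, True])
    def test_matches_scipy(self, welch):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(0, 1, int(rng.integers(3, 12)))
            y = rng.normal(0.3, 1.5, int(rng.integers(3, 12)))
            ours = t_test_unpaired(x, y, welch=welch)
            ref = sps.ttest_ind(x, y, equal_var=not welch)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_sample_size_checked(self):
        with pytest.raises(ParameterError):
            t_test_unpaired([1.0], [1.0, 2.0])


class TestOneWayAnova:
    def test_two_groups_reproduce_pooled_t(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 7), rng.normal(1, 1, 9)
        t = t_test_unpaired(x, y)
        f = one_way_anova({"a": x, "b": y})
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert f.p_value == pytest.approx(t.p_value, rel=1e-10)

    def test_manual_sum_of_squares_3x3(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [4.0, 5.0, 6.0]}
        # Hand decomposition: grand mean 10/3; group means 2, 3, 5
        # SS_between = 3[(2-10/3)^2+(3-10/3)^2+(5-10/3)^2] = 14
        # SS_within = 6 (each group contributes 2); F = (14/2)/(6/6) = 7
        res = one_way_anova(groups)
        assert res.statistic == pytest.approx(7.0, abs=1e-12)
        assert res.df == (2.0, 6.0)
        ref = sps.f_oneway(*groups.values())
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_zero_within_variance_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            one_way_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})

    def test_fisher_lsd_is_unadjusted_pairwise(self):
        rng = np.random.default_rng(2)
        groups = {g: rng.normal(m, 1, 6) for g, m in
                  zip("abc", [0.0, 0.1, 2.0])}
        res = one_way_anova(groups, posthoc="fisher_lsd")
        assert res.posthoc is not None and len(res.posthoc) == 3
        # LSD p equals a t test using MS_within with N-k df; recompute one pair
        pooled = np.concatenate(list(groups.values()))
        ms_w = sum(np.sum((v - np.mean(v)) ** 2) for v in groups.values()) / (
            len(pooled) - 3)
        diff = np.mean(groups["a"]) - np.mean(groups["b"])
        t = diff / math.sqrt(ms_w * (2 / 6))
        p = 2 * sps.t.sf(abs(t), len(pooled) - 3)
        row = res.posthoc.set_index("pair").loc["a vs b"]
        assert row["p"] == pytest.approx(p, rel=1e-10)

    def test_lsd_letters_separate_significant_groups(self):
        rng = np.random.default_rng(4)
        groups = {"low": rng.normal(0, 0.3, 8),
                  "mid": rng.normal(0.2, 0.3, 8),
                  "high": rng.normal(5.0, 0.3, 8)}
        res = one_way_anova(groups, posthoc="fisher_lsd")
        letters = res.letters
        sig = {tuple(sorted(p.split(" vs "))): s for p, s in
               zip(res.posthoc["pair"], res.posthoc["significant"])}
        for (g1, g2), is_sig in sig.items():
            shared = set(letters[g1]) & set(letters[g2])
            assert is_sig == (not shared)


class TestTwoWayAnova:
    @staticmethod
    def _balanced_2x2():
        # cell means: a1b1=1, a1b2=3, a2b1=2, a2b2=8 with +/-0.5 replicates
        rows = []
        for la, lb, mean in [("a1", "b1", 1.0), ("a1", "b2", 3.0),
                             ("a2", "b1", 2.0), ("a2", "b2", 8.0)]:
            for d in (-0.5, 0.5):
                rows.append({"y": mean + d, "A": la, "B": lb})
        return pd.DataFrame(rows)

    def test_2x2_interaction_matches_manual_cell_mean_computation(self):
        df = self._balanced_2x2()
        res = two_way_anova(df, "y", "A", "B")
        # manual: interaction contrast (1-3-2+8)/4 = 1 per cell, SS_AB = n*sum
        # = 2 * 4 * 1^2 = 8; MS_err = (8 * 0.25)/4 = 0.5; F = 8/0.5 = 16
        inter = res.effects.set_index("effect").loc["A x B"]
        assert inter["ss"] == pytest.approx(8.0, abs=1e-10)
        assert inter["F"] == pytest.approx(16.0, abs=1e-10)
        assert res.df == (1.0, 4.0)

    def test_balanced_matches_statsmodels(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        rows = []
        for la in ("a1", "a2", "a3"):
            for lb in ("b1", "b2"):
                for _ in range(5):
                    rows.append({"y": rng.normal(hash((la, lb)) % 5, 1.0),
                                 "A": la, "B": lb})
        df = pd.DataFrame(rows)
        ours = two_way_anova(df, "y", "A", "B")
        fit = smf.ols("y ~ C(A) * C(B)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        ours_tbl = ours.effects.set_index("effect")
        assert ours_tbl.loc["A", "F"] == pytest.approx(ref.loc["C(A)", "F"], rel=1e-8)
        assert ours_tbl.loc["B", "F"] == pytest.approx(ref.loc["C(B)", "F"], rel=1e-8)
        assert ours_tbl.loc["A x B", "F"] == pytest.approx(
            ref.loc["C(A):C(B)", "F"], rel=1e-8)

    def test_null_data_gives_large_p(self):
        rng = np.random.default_rng(11)
        rows = [{"y": 1.0 + rng.normal(0, 0.1), "A": la, "B": lb}
                for la in ("a1", "a2") for lb in ("b1", "b2") for _ in range(8)]
        res = two_way_anova(pd.DataFrame(rows), "y", "A", "B")
        assert (res.effects["p"] > 0.05).all()

    def test_empty_cell_named_in_error(self):
        df = self._balanced_2x2()
        df = df[~((df.A == "a2") & (df.B == "b2"))]
        with pytest.raises(ValidationError, match="a2"):
            two_way_anova(df, "y", "A", "B")

    def test_sidak_posthoc_bounds(self):
        df = self._balanced_2x2()
        res = two_way_anova(df, "y", "A", "B", posthoc="sidak")
        assert res.posthoc is not None
        assert ((res.posthoc["p_adj"] >= 0) & (res.posthoc["p_adj"] <= 1)).all()

    def test_tukey_posthoc_uses_studentized_range(self):
        df = self._balanced_2x2()
        res = two_way_anova(df, "y", "A", "B", posthoc="tukey")
        row = res.posthoc.iloc[0]
        # recompute: q = |diff| / sqrt(MS_err/2 * (1/n1 + 1/n2))
        assert row["p_adj"] == pytest.approx(
            float(sps.studentized_range.sf(row["statistic"], 2, 4)), rel=1e-10)


class TestSidak:
    def test_m_one_is_identity(self):
        assert sidak_adjust(0.037, 1) == pytest.approx(0.037)

    @pytest.mark.parametrize("p", [0.001, 0.01, 0.2, 0.8])
    @pytest.mark.parametrize("m", [1, 2, 6])
    def test_adjusted_at_least_raw_and_in_unit_interval(self, p, m):
        adj = sidak_adjust(p, m)
        assert adj >= p - 1e-15
        assert 0.0 <= adj <= 1.0
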