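"""Unit and property tests for the first-principles statistics machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctamem.stats_core import (ANOVATable, IncompleteDesignError,
                               InsufficientDataError, bonferroni_adjust,
                               mixed_anova_2x2plus, paired_t_test,
                               two_way_anova_fixed, unpaired_t_test)


# ---------------------------------------------------------------------------
# t-tests

class TestUnpairedT:
    def test_identical_groups_give_zero_statistic_p_one(self):
        r = unpaired_t_test([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0
        assert r.p == 1.0

    def test_matches_scipy_pooled_and_welch(self, rng):
        from scipy import stats
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 2, 11)
        for ev in (True, False):
            mine = unpaired_t_test(x, y, equal_variance=ev)
            ref = stats.ttest_ind(x, y, equal_var=ev)
            assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert mine.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_pooled_df_is_integer_sum(self):
        r = unpaired_t_test([1.0, 2, 3, 4, 5, 6], [2.0, 3, 4, 5, 6, 8])
        assert r.df == 10  # the n=6/6 design reports t(10)

    def test_sign_follows_group_order(self):
        r = unpaired_t_test([1.0, 2], [5.0, 6])
        assert r.statistic < 0
        r2 = unpaired_t_test([5.0, 6], [1.0, 2])
        assert r2.statistic == pytest.approx(-r.statistic)

    def test_too_short_series_raises(self):
        with pytest.raises(InsufficientDataError):
            unpaired_t_test([1.0], [1.0, 2.0])

    def test_zero_variance_equal_means_degenerate(self):
        r = unpaired_t_test([2.0, 2, 2], [2.0, 2, 2])
        assert r.degenerate and r.statistic == 0.0 and r.p == 1.0

    def test_paired_matches_scipy(self, rng):
        from scipy import stats
        x, y = rng.normal(0, 1, 9), rng.normal(0.3, 1, 9)
        mine = paired_t_test(x, y)
        ref = stats.ttest_rel(x, y)
        assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-12)


# ---------------------------------------------------------------------------
# split-plot (mixed) ANOVA

def _mixed_table(values_by_subject):
    rows = []
    for (group, subject), vals in values_by_subject.items():
        for level, v in zip(("training", "test"), vals):
            rows.append((subject, group, level, float(v)))
    return pd.DataFrame(rows, columns=["subject", "group", "level", "value"])


#: 2 groups x 2 sessions x 3 subjects; SS decomposition worked by hand
HAND_FIXTURE = {
    ("A", "a1"): (5, 1), ("A", "a2"): (6, 2), ("A", "a3"): (7, 4),
    ("B", "b1"): (5, 4), ("B", "b2"): (7, 5), ("B", "b3"): (6, 6),
}
HAND_EXPECTED = {
    "group": dict(SS=16 / 3, F=16 / 7),
    "subjects-within-groups": dict(SS=28 / 3),
    "level": dict(SS=49 / 3, F=49.0),
    "group:level": dict(SS=16 / 3, F=16.0),
    "residual": dict(SS=4 / 3),
}


class TestMixedAnova:
    def test_matches_hand_decomposition(self):
        tab = mixed_anova_2x2plus(_mixed_table(HAND_FIXTURE))
        for effect, exp in HAND_EXPECTED.items():
            assert tab[effect]["SS"] == pytest.approx(exp["SS"], rel=1e-10)
            if "F" in exp:
                assert tab[effect]["F"] == pytest.approx(exp["F"], rel=1e-10)

    def test_constant_data_degenerate_f_zero(self):
        tab = mixed_anova_2x2plus(_mixed_table(
            {("A", "a1"): (3, 3), ("A", "a2"): (3, 3),
             ("B", "b1"): (3, 3), ("B", "b2"): (3, 3)}))
        assert tab.degenerate
        for eff in ("group", "level", "group:level"):
            assert tab[eff]["F"] == 0.0 and tab[eff]["p"] == 1.0

    def test_matches_pingouin_unbalanced_groups(self, rng):
        """The study's own designs have unequal group sizes (e.g. 6 vs 7)."""
        import pingouin as pg
        rows = []
        for g, n in [("GFP", 6), ("Cre", 7)]:
            for s in range(n):
                for lv in ("training", "test"):
                    rows.append((f"{g}{s}", g, lv,
                                 rng.normal((lv == "test") * (g == "GFP"), 1)))
        df = pd.DataFrame(rows, columns=["subject", "group", "level", "value"])
        mine = mixed_anova_2x2plus(df)
        ref = pg.mixed_anova(data=df, dv="value", within="level",
                             subject="subject", between="group")
        ref = ref.set_index("Source")
        assert mine["group"]["F"] == pytest.approx(ref.loc["group", "F"],
                                                   rel=1e-9)
        assert mine["level"]["F"] == pytest.approx(ref.loc["level", "F"],
                                                   rel=1e-9)
        assert mine["group:level"]["F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9)
        assert mine["group"]["p"] == pytest.approx(ref.loc["group", "p_unc"],
                                                   rel=1e-9)

    def test_missing_cell_rejected(self):
        df = _mixed_table(HAND_FIXTURE).iloc[:-1]
        with pytest.raises(IncompleteDesignError):
            mixed_anova_2x2plus(df)

    def test_single_subject_per_group_rejected(self):
        df = _mixed_table({("A", "a1"): (1, 2), ("B", "b1"): (3, 4)})
        with pytest.raises(IncompleteDesignError):
            mixed_anova_2x2plus(df)

    def test_group_f_equals_squared_pooled_t_on_subject_means(self, rng):
        """With the within-factor collapsed (averaged out), the between test
        reduces to a one-way comparison: F_group == t^2 on subject means."""
        vals = {("A", f"a{i}"): rng.normal(0, 1, 2) for i in range(5)}
        vals.update({("B", f"b{i}"): rng.normal(1, 1, 2) for i in range(5)})
        tab = mixed_anova_2x2plus(_mixed_table(vals))
        means_a = [np.mean(v) for (g, _), v in vals.items() if g == "A"]
        means_b = [np.mean(v) for (g, _), v in vals.items() if g == "B"]
        t = unpaired_t_test(means_a, means_b)
        assert tab["group"]["F"] == pytest.approx(t.statistic ** 2, rel=1e-9)
        assert tab["group"]["p"] == pytest.approx(t.p, rel=1e-9)

    def test_type_i_error_calibrated_under_null(self):
        """Empirical alpha at 0.05 within 2 binomial SD over 1000 replicates."""
        rng = np.random.default_rng(77)
        n_rep = 1000
        hits = {"group": 0, "level": 0, "group:level": 0}
        for _ in range(n_rep):
            vals = {("A", f"a{i}"): rng.normal(0, 1, 2) for i in range(4)}
            vals.update({("B", f"b{i}"): rng.normal(0, 1, 2) for i in range(4)})
            tab = mixed_anova_2x2plus(_mixed_table(vals))
            for eff in hits:
                hits[eff] += tab[eff]["p"] < 0.05
        band = 2 * np.sqrt(0.05 * 0.95 / n_rep)
        for eff, k in hits.items():
            assert abs(k / n_rep - 0.05) < band, (eff, k / n_rep)


# ---------------------------------------------------------------------------
# fixed two-way ANOVA

class TestTwoWayFixed:
    def test_row_only_structure_zeroes_b_and_interaction(self):
        rows = [(a, b, 1.0 if a == "x" else 4.0)
                for a in "xy" for b in "uv" for _ in range(3)]
        tab = two_way_anova_fixed(pd.DataFrame(
            rows, columns=["factorA", "factorB", "value"]))
        assert tab["factorB"]["F"] == 0.0
        assert tab["factorA:factorB"]["F"] == 0.0
        assert tab["factorA"]["p"] < 1e-6

    def test_matches_least_squares_projection_oracle(self, rng):
        """Balanced 2x3 integer fixture vs explicit normal-equations fits."""
        rows = []
        for ai, a in enumerate("xy"):
            for bi, b in enumerate("uvw"):
                for r in range(3):
                    rows.append((a, b, float(rng.integers(0, 10))))
        df = pd.DataFrame(rows, columns=["factorA", "factorB", "value"])
        tab = two_way_anova_fixed(df)

        y = df["value"].to_numpy()
        a = pd.get_dummies(df["factorA"]).to_numpy(float)
        b = pd.get_dummies(df["factorB"]).to_numpy(float)
        ab = pd.get_dummies(df["factorA"] + df["factorB"]).to_numpy(float)

        def rss(x):
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            return float(((y - x @ beta) ** 2).sum())

        one = np.ones((len(y), 1))
        ss_a = rss(one) - rss(np.hstack([one, a]))
        ss_b = rss(np.hstack([one, a])) - rss(np.hstack([one, a, b]))
        ss_i = rss(np.hstack([one, a, b])) - rss(ab)
        assert tab["factorA"]["SS"] == pytest.approx(ss_a, abs=1e-9)
        assert tab["factorB"]["SS"] == pytest.approx(ss_b, abs=1e-9)
        assert tab["factorA:factorB"]["SS"] == pytest.approx(ss_i, abs=1e-9)

    def test_empty_cell_rejected(self):
        df = pd.DataFrame([("x", "u", 1.0), ("x", "v", 2.0), ("y", "u", 3.0)],
                          columns=["factorA", "factorB", "value"])
        with pytest.raises(IncompleteDesignError):
            two_way_anova_fixed(df)


# ---------------------------------------------------------------------------
# Bonferroni

class TestBonferroni:
    def test_family_of_one_unchanged(self):
        assert bonferroni_adjust([0.01]) == pytest.approx([0.01])

    def test_closed_form_with_cap(self):
        out = bonferroni_adjust([0.3, 0.02, 0.5, 0.04])
        assert out == pytest.approx([1.0, 0.08, 1.0, 0.16])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.5, 1.2])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    def test_monotone_never_below_input_capped(self, ps):
        out = bonferroni_adjust(ps)
        assert np.all(out >= np.asarray(ps) - 1e-15)
        assert np.all(out <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(out[order]) >= -1e-15)


def test_anova_table_serialization_roundtrip(tmp_path):
    tab = mixed_anova_2x2plus(_mixed_table(HAND_FIXTURE))
    path = tmp_path / "anova.tsv"
    tab.to_tsv(path)
    back = pd.read_csv(path, sep="\t")
    assert list(back.columns) == ["effect", "SS", "df", "MS", "F", "p"]
    assert len(back) == len(tab.effects)
    d = tab.to_dict()
    assert d["effects"]["group"]["df"] == 1.0
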