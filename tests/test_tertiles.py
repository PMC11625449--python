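"""Tertile assignment, ANOVA, Scheffé groupings — all against brute force."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fatexchange.tertiles import (
    InsufficientSampleError,
    TertileAssignment,
    anova_oneway,
    assign_tertiles,
    compact_letters,
    compare_tertiles,
    scheffe_pairwise,
)


class TestAssignTertiles:
    def test_ranks_force_split(self):
        a = assign_tertiles({f"p{i}": float(i) for i in range(1, 7)})
        assert a.members("low") == ["p1", "p2"]
        assert a.members("medium") == ["p3", "p4"]
        assert a.members("high") == ["p5", "p6"]
        assert a.cut_points == (2.0, 4.0)

    def test_group_sizes_for_600(self):
        rng = np.random.default_rng(0)
        a = assign_tertiles({f"p{i:03d}": v for i, v in enumerate(rng.normal(14, 2.5, 600))})
        assert a.sizes() == {"low": 200, "medium": 200, "high": 200}

    def test_sizes_differ_by_at_most_remainder(self):
        a = assign_tertiles({f"p{i}": float(i) for i in range(7)})
        sizes = sorted(a.sizes().values())
        assert max(sizes) - min(sizes) <= 7 % 3

    def test_all_ties_split_stably_with_warning(self):
        with pytest.warns(UserWarning, match="tied"):
            a = assign_tertiles({f"p{i}": 5.0 for i in range(6)})
        assert a.members("low") == ["p0", "p1"]
        assert a.members("high") == ["p4", "p5"]

    def test_low_members_never_exceed_high_members(self, baseline_intakes):
        sfa = {p: it.pct_te["sfa_g"] for p, it in baseline_intakes.items()}
        a = assign_tertiles(sfa)
        assert max(sfa[p] for p in a.members("low")) <= min(sfa[p] for p in a.members("high"))

    @given(st.lists(st.floats(0, 30, allow_nan=False), min_size=3, max_size=40))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_order_invariance(self, values):
        s = {f"p{i:02d}": v for i, v in enumerate(values)}
        forward = assign_tertiles(s)
        shuffled = dict(reversed(list(s.items())))
        backward = assign_tertiles(shuffled)
        assert forward.labels.sort_index().equals(backward.labels.sort_index())

    def test_too_small_sample(self):
        with pytest.raises(InsufficientSampleError):
            assign_tertiles({"a": 1.0, "b": 2.0})


def brute_force_anova(groups):
    """Sums of squares written out longhand."""
    allv = [x for g in groups for x in g]
    grand = sum(allv) / len(allv)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((x - sum(g) / len(g)) ** 2 for g in groups for x in g)
    dfb, dfw = len(groups) - 1, len(allv) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


class TestAnova:
    def test_hand_example(self):
        """Groups {1,2,3},{2,3,4},{3,4,5}: SSB = 6, SSW = 6, F = 3 on (2, 6) df."""
        F, p, dfb, dfw = anova_oneway([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert F == pytest.approx(3.0)
        assert (dfb, dfw) == (2, 6)
        assert p == pytest.approx(float(stats.f.sf(3.0, 2, 6)))

    def test_identical_groups_give_F_zero(self):
        F, p, *_ = anova_oneway([[1, 2, 3]] * 3)
        assert F == 0.0

    def test_degenerate_equal_constant_groups(self):
        F, p, *_ = anova_oneway([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert (F, p) == (0.0, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(rng.uniform(-1, 1), 1.0, size=rng.integers(4, 12)) for _ in range(3)]
        F, p, *_ = anova_oneway(groups)
        assert F == pytest.approx(brute_force_anova([g.tolist() for g in groups]), rel=1e-10)
        sp = stats.f_oneway(*groups)
        assert F == pytest.approx(sp.statistic, rel=1e-10)
        assert p == pytest.approx(sp.pvalue, rel=1e-9)


def brute_force_scheffe(groups, alpha=0.05):
    """Direct criterion: contrast MS against (k-1) F_crit MSW (1/ni + 1/nj)."""
    k = len(groups)
    N = sum(len(g) for g in groups)
    msw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups) / (N - k)
    fc = stats.f.isf(alpha, k - 1, N - k)
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            lhs = (np.mean(groups[i]) - np.mean(groups[j])) ** 2
            rhs = (k - 1) * fc * msw * (1 / len(groups[i]) + 1 / len(groups[j]))
            out[(i, j)] = lhs > rhs
    return out


class TestScheffe:
    @pytest.mark.parametrize("seed", range(8))
    def test_pairwise_matches_direct_criterion(self, seed):
        rng = np.random.default_rng(seed)
        shift = rng.uniform(0, 3)
        groups = [rng.normal(m * shift, 1.0, size=rng.integers(5, 15)) for m in range(3)]
        assert scheffe_pairwise(groups) == brute_force_scheffe(groups)

    def test_separated_plus_overlapping_letters(self):
        rng = np.random.default_rng(3)
        lo = rng.normal(0.0, 0.5, 20)
        mid = rng.normal(0.6, 0.5, 20)
        hi = rng.normal(5.0, 0.5, 20)
        groups = [lo, mid, hi]
        diff = scheffe_pairwise(groups)
        letters = compact_letters([g.mean() for g in groups], diff)
        # letters consistent with pairwise outcomes: shared letter iff not different
        for (i, j), d in diff.items():
            shared = set(letters[i]) & set(letters[j])
            assert bool(shared) == (not d)

    def test_identical_groups_share_one_letter(self):
        groups = [[1.0, 2.0, 3.0]] * 3
        letters = compact_letters([2.0, 2.0, 2.0], scheffe_pairwise(groups))
        assert letters == ["a", "a", "a"]


class TestCompareTertiles:
    def test_report_structure_and_letter_consistency(self, baseline_intakes, composition):
        from fatexchange.intake import participant_category_share

        sfa = {p: it.pct_te["sfa_g"] for p, it in baseline_intakes.items()}
        assignment = assign_tertiles(sfa)
        shares = participant_category_share(baseline_intakes, "sfa_g", composition.categories())
        report = compare_tertiles(shares, assignment)
        assert report.family_size == shares.shape[1]
        t = report.table
        assert (t["p_adj"] >= t["p"] - 1e-15).all()
        assert (t["p_adj"] <= 1.0).all()
        # recompute one category's F by brute force
        cat = "whole milk"
        groups = [shares.loc[assignment.members(x), cat].tolist() for x in ("low", "medium", "high")]
        assert t.loc[cat, "F"] == pytest.approx(brute_force_anova(groups), rel=1e-10)
        # letters consistent with the Scheffé criterion for every category
        for cat in t.index:
            groups = [shares.loc[assignment.members(x), cat].to_numpy() for x in ("low", "medium", "high")]
            diff = brute_force_scheffe(groups)
            letters = [t.loc[cat, f"{x}_letter"] for x in ("low", "medium", "high")]
            for (i, j), d in diff.items():
                assert bool(set(letters[i]) & set(letters[j])) == (not d)

    def test_whole_milk_contribution_rises_with_sfa_tertile(self, baseline_intakes, composition):
        """The structural gradient: dairy determinants rise from low to high consumers."""
        from fatexchange.intake import participant_category_share

        sfa = {p: it.pct_te["sfa_g"] for p, it in baseline_intakes.items()}
        assignment = assign_tertiles(sfa)
        shares = participant_category_share(baseline_intakes, "sfa_g", composition.categories())
        report = compare_tertiles(shares, assignment)
        for cat in ("whole milk", "butter"):
            row = report.table.loc[cat]
            assert row["low_mean"] < row["medium_mean"] < row["high_mean"]

    def test_tertile_with_too_few_members_is_error(self):
        values = pd.DataFrame({"c": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        labels = pd.Series({"a": "low", "b": "medium", "c": "high"}, name="tertile")
        assignment = TertileAssignment(labels=labels, cut_points=(1.0, 2.0))
        with pytest.raises(InsufficientSampleError):
            compare_tertiles(values, assignment)
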