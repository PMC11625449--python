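"""Intake accounting: daily means, %TE, category partition, contributions."""

import numpy as np
import pandas as pd
import pytest

from fatexchange.food_model import CompositionTable, DiaryEntry, FoodCategory, FoodItem
from fatexchange.intake import (
    category_contribution,
    cohort_intakes,
    mean_daily_intake,
    participant_category_share,
)
from fatexchange.nutrients import NutrientVector


@pytest.fixture()
def milk_and_bread():
    dairy = FoodCategory(1, "whole milk")
    bread = FoodCategory(12, "bread and rolls")
    milk = FoodItem(
        "M1", "milk", dairy,
        NutrientVector(energy_kcal=64, total_fat_g=3.5, sfa_g=2.3, protein_g=3.4,
                       carbohydrate_g=4.7, total_sugar_g=4.7),
    )
    loaf = FoodItem(
        "B1", "bread", bread,
        NutrientVector(energy_kcal=220, total_fat_g=2.0, sfa_g=0.5, protein_g=8.0,
                       carbohydrate_g=46.0, total_sugar_g=3.0),
    )
    return CompositionTable([milk, loaf])


def test_milk_hand_arithmetic(milk_and_bread):
    """Four 200 g servings of 3.5 g fat/100 g milk over 4 days -> 7.0 g fat/d."""
    entries = [DiaryEntry("kid", d, d == 4, "M1", 200.0) for d in (1, 2, 3, 4)]
    intake = mean_daily_intake("kid", entries, milk_and_bread)
    assert intake.daily.total_fat_g == pytest.approx(7.0)
    assert intake.n_days == 4
    # %TE from own energy: 7 g x 9 kcal/g / 128 kcal x 100
    assert intake.pct_te["total_fat_g"] == pytest.approx(7.0 * 9 / 128.0 * 100)


def test_empty_diary_is_zero_with_warning(milk_and_bread):
    with pytest.warns(UserWarning, match="empty diary"):
        intake = mean_daily_intake("kid", [], milk_and_bread)
    assert intake.daily.as_array().sum() == 0.0
    assert all(v == 0.0 for v in intake.pct_te.values())


def test_partition_identity_two_categories(milk_and_bread):
    entries = [
        DiaryEntry("kid", 1, True, "M1", 150.0),
        DiaryEntry("kid", 1, True, "B1", 80.0),
        DiaryEntry("kid", 2, False, "M1", 250.0),
    ]
    intake = mean_daily_intake("kid", entries, milk_and_bread)
    total = sum((v.as_array() for v in intake.by_category.values()))
    np.testing.assert_allclose(total, intake.daily.as_array(), rtol=1e-12)


def test_partition_identity_full_cohort(baseline_intakes):
    """Category subtotals partition the daily total for every participant."""
    for it in baseline_intakes.values():
        total = sum((v.as_array() for v in it.by_category.values()))
        np.testing.assert_allclose(total, it.daily.as_array(), rtol=1e-9)


def test_days_divisor_is_distinct_recorded_days(milk_and_bread):
    entries = [DiaryEntry("kid", 1, True, "M1", 100.0), DiaryEntry("kid", 2, False, "M1", 100.0)]
    intake = mean_daily_intake("kid", entries, milk_and_bread)
    assert intake.n_days == 2
    assert intake.daily.total_fat_g == pytest.approx(2 * 100 * 3.5 / 100 / 2)


def test_scale_equivariance(milk_and_bread):
    """Doubling every amount doubles g/d but leaves %TE and shares unchanged."""
    entries = [
        DiaryEntry("kid", 1, True, "M1", 150.0),
        DiaryEntry("kid", 1, True, "B1", 80.0),
    ]
    doubled = [DiaryEntry(e.participant_id, e.day, e.is_weekend, e.food_code, 2 * e.amount_g)
               for e in entries]
    a = mean_daily_intake("kid", entries, milk_and_bread)
    b = mean_daily_intake("kid", doubled, milk_and_bread)
    np.testing.assert_allclose(b.daily.as_array(), 2 * a.daily.as_array(), rtol=1e-12)
    for nut in a.pct_te:
        assert b.pct_te[nut] == pytest.approx(a.pct_te[nut], rel=1e-12)


class TestCategoryContribution:
    def test_population_proportion_hand_value(self, milk_and_bread):
        """Two equal-weight participants with category SFA {2, 4} of totals {10, 10} -> 30 %."""
        # grams chosen so milk (2.3 g SFA/100 g) supplies {2, 4} g of {10, 10} g totals
        d1 = [DiaryEntry("p1", 1, True, "M1", 2 / 2.3 * 100), DiaryEntry("p1", 1, True, "B1", 8 / 0.5 * 100)]
        d2 = [DiaryEntry("p2", 1, True, "M1", 4 / 2.3 * 100), DiaryEntry("p2", 1, True, "B1", 6 / 0.5 * 100)]
        intakes = cohort_intakes({"p1": d1, "p2": d2}, milk_and_bread)
        tab = category_contribution(intakes, "sfa_g", method="population_proportion")
        assert tab.rows["whole milk"] == pytest.approx(30.0)
        assert tab.total() == pytest.approx(100.0, abs=1e-6)

    def test_single_category_is_100(self, milk_and_bread):
        intakes = cohort_intakes({"p": [DiaryEntry("p", 1, True, "M1", 100.0)]}, milk_and_bread)
        tab = category_contribution(intakes, "sfa_g")
        assert tab.rows["whole milk"] == pytest.approx(100.0)

    def test_methods_agree_for_identical_diets(self, milk_and_bread):
        entries = [DiaryEntry("x", 1, True, "M1", 120.0), DiaryEntry("x", 1, True, "B1", 60.0)]
        diaries = {
            pid: [DiaryEntry(pid, e.day, e.is_weekend, e.food_code, e.amount_g) for e in entries]
            for pid in ("p1", "p2", "p3")
        }
        intakes = cohort_intakes(diaries, milk_and_bread)
        a = category_contribution(intakes, "sfa_g", method="population_proportion")
        b = category_contribution(intakes, "sfa_g", method="mean_of_ratios")
        np.testing.assert_allclose(a.rows.to_numpy(), b.rows.to_numpy(), rtol=1e-12)

    def test_rows_sum_to_100_both_methods(self, baseline_intakes, composition):
        for method in ("population_proportion", "mean_of_ratios"):
            tab = category_contribution(
                baseline_intakes, "sfa_g", method=method, all_categories=composition.categories()
            )
            assert tab.total() == pytest.approx(100.0, abs=1e-6)

    def test_all_zero_denominator_is_error(self, milk_and_bread):
        intakes = cohort_intakes({"p": [DiaryEntry("p", 1, True, "B1", 50.0)]}, milk_and_bread)
        with pytest.raises(ValueError, match="undefined"):
            category_contribution(intakes, "epa_g")

    def test_weights_shift_population_proportion(self, milk_and_bread):
        d1 = [DiaryEntry("p1", 1, True, "M1", 100.0)]
        d2 = [DiaryEntry("p2", 1, True, "B1", 100.0)]
        intakes = cohort_intakes({"p1": d1, "p2": d2}, milk_and_bread)
        even = category_contribution(intakes, "sfa_g", weights={"p1": 1, "p2": 1})
        skew = category_contribution(intakes, "sfa_g", weights={"p1": 3, "p2": 1})
        assert skew.rows["whole milk"] > even.rows["whole milk"]


def test_participant_share_rows_sum_to_100(baseline_intakes, composition):
    shares = participant_category_share(baseline_intakes, "sfa_g", composition.categories())
    np.testing.assert_allclose(shares.sum(axis=1).to_numpy(), 100.0, rtol=1e-9)
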