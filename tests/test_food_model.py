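"""Domain types, CSV schemas, and validation behaviour."""

import numpy as np
import pandas as pd
import pytest

from fatexchange.food_model import (
    DiaryEntry,
    SchemaError,
    ValidationError,
    diaries_to_frame,
    load_taxonomy,
    read_composition,
    read_diaries,
    read_roster,
    write_composition,
    write_diaries,
    write_roster,
)
from fatexchange.nutrients import (
    NUTRIENT_FIELDS,
    NutrientValidationError,
    NutrientVector,
    percent_energy,
)


def test_taxonomy_has_26_unique_categories():
    tax = load_taxonomy()
    assert len(tax) == 26
    assert len({c.id for c in tax.values()}) == 26


class TestNutrientVector:
    def test_valid_vector_passes(self):
        NutrientVector(energy_kcal=100, total_fat_g=10, sfa_g=5, mufa_g=3, pufa_g=2).validate()

    def test_negative_value_rejected(self):
        with pytest.raises(NutrientValidationError, match="sfa_g"):
            NutrientVector(sfa_g=-0.1).validate()

    def test_fatty_acid_classes_cannot_exceed_total_fat(self):
        # 5 % rounding headroom: 10.4 g over 10 g passes, 10.6 g fails
        NutrientVector(total_fat_g=10, sfa_g=10.4).validate()
        with pytest.raises(NutrientValidationError, match="total fat"):
            NutrientVector(total_fat_g=10, sfa_g=10.6).validate()

    def test_n3_subfractions_bounded(self):
        with pytest.raises(NutrientValidationError, match="EPA\\+DHA"):
            NutrientVector(total_fat_g=5, pufa_g=1, n3_g=0.1, epa_g=0.2, dha_g=0.2).validate()

    def test_arithmetic_is_componentwise(self):
        a = NutrientVector(energy_kcal=10, sfa_g=1)
        b = NutrientVector(energy_kcal=5, protein_g=2)
        c = a + 2 * b
        assert c.energy_kcal == 20 and c.sfa_g == 1 and c.protein_g == 4


class TestPercentEnergy:
    def test_hand_value(self):
        assert percent_energy(50.0, 1800.0, 9.0) == pytest.approx(25.0)

    def test_zero_grams(self):
        assert percent_energy(0.0, 1500.0, 9.0) == 0.0

    def test_saturation_at_100(self):
        assert percent_energy(200.0, 1800.0, 9.0) == pytest.approx(100.0)

    def test_nonpositive_energy_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            percent_energy(10.0, 0.0, 9.0)


class TestCompositionIO:
    def test_round_trip(self, composition, tmp_path):
        path = tmp_path / "comp.csv"
        write_composition(composition, path)
        back = read_composition(path)
        assert len(back) == len(composition)
        for food in composition:
            other = back[food.food_code]
            assert other.description == food.description
            assert other.category == food.category
            np.testing.assert_allclose(
                other.per_100g.as_array(), food.per_100g.as_array(), rtol=0, atol=0
            )

    def test_missing_column_names_the_column(self, composition, tmp_path):
        path = tmp_path / "comp.csv"
        df = composition.to_frame().drop(columns=["sfa_g"])
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="sfa_g"):
            read_composition(path)

    def test_invalid_row_reported_with_row_number(self, composition, tmp_path):
        path = tmp_path / "comp.csv"
        df = composition.to_frame()
        df.loc[2, "sfa_g"] = df.loc[2, "total_fat_g"] * 1.2  # beyond rounding headroom
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="row 3"):
            read_composition(path)

    def test_duplicate_food_code_rejected(self, composition, tmp_path):
        path = tmp_path / "comp.csv"
        df = composition.to_frame()
        pd.concat([df, df.iloc[[0]]]).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="duplicate food_code"):
            read_composition(path)


class TestDiaryIO:
    def test_round_trip_preserves_entry_multiset(self, full_cohort, composition, tmp_path):
        path = tmp_path / "diaries.csv"
        write_diaries(full_cohort.diaries, path)
        back = read_diaries(path, composition)
        orig = sorted(
            (e.participant_id, e.day, e.is_weekend, e.food_code, e.amount_g)
            for es in full_cohort.diaries.values()
            for e in es
        )
        got = sorted(
            (e.participant_id, e.day, e.is_weekend, e.food_code, e.amount_g)
            for es in back.values()
            for e in es
        )
        assert got == orig

    def test_four_days_with_weekend_accepted(self, composition, tmp_path):
        code = next(iter(composition)).food_code
        rows = [("kid", d, d == 4, code, 100.0) for d in (1, 2, 3, 4)]
        path = tmp_path / "d.csv"
        diaries_to_frame({"kid": [DiaryEntry(*r) for r in rows]}).to_csv(path, index=False)
        out = read_diaries(path, composition, strict=True)
        assert {e.day for e in out["kid"]} == {1, 2, 3, 4}

    def test_unknown_food_code_is_resolution_error(self, composition, tmp_path):
        path = tmp_path / "d.csv"
        pd.DataFrame(
            [("kid", 1, True, "NOPE", 100.0)],
            columns=["participant_id", "day", "is_weekend", "food_code", "amount_g"],
        ).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="NOPE"):
            read_diaries(path, composition)

    def test_missing_weekend_day_strict_vs_lenient(self, composition, tmp_path):
        code = next(iter(composition)).food_code
        path = tmp_path / "d.csv"
        pd.DataFrame(
            [("kid", d, False, code, 50.0) for d in (1, 2, 3, 4)],
            columns=["participant_id", "day", "is_weekend", "food_code", "amount_g"],
        ).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="weekend"):
            read_diaries(path, composition, strict=True)
        with pytest.warns(UserWarning, match="weekend"):
            read_diaries(path, composition, strict=False)

    def test_nonpositive_amount_rejected(self, composition, tmp_path):
        code = next(iter(composition)).food_code
        path = tmp_path / "d.csv"
        pd.DataFrame(
            [("kid", 1, True, code, 0.0)],
            columns=["participant_id", "day", "is_weekend", "food_code", "amount_g"],
        ).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="amount_g"):
            read_diaries(path, composition)


def test_roster_round_trip_and_validation(full_cohort, tmp_path):
    path = tmp_path / "roster.csv"
    write_roster(full_cohort.roster, path)
    back = read_roster(path)
    assert back == full_cohort.roster
    df = pd.read_csv(path)
    df.loc[0, "age_y"] = 17.0
    df.to_csv(path, index=False)
    with pytest.raises(ValidationError, match="age"):
        read_roster(path)
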