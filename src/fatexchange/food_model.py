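"""Domain types and CSV I/O for composition tables, diaries, and rosters.

Three plain-CSV schemas (UTF-8, "." decimal separator):

* composition: ``food_code, description, category`` then one column per
  :data:`~fatexchange.nutrients.NUTRIENT_FIELDS` entry (per 100 g).
* diary: ``participant_id, day, is_weekend, food_code, amount_g`` — one
  row per consumption event of a consecutive 4-day semi-weighed diary.
* roster: ``participant_id, age_y, sex, weight``.

Foods are aggregated into a 26-category taxonomy keyed on predominant fat
profile / food-based dietary guidelines; the default taxonomy ships as a
package data file and can be overridden.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .nutrients import NUTRIENT_FIELDS, NutrientVector, NutrientValidationError

N_CATEGORIES = 26

COMPOSITION_COLUMNS = ("food_code", "description", "category", *NUTRIENT_FIELDS)
DIARY_COLUMNS = ("participant_id", "day", "is_weekend", "food_code", "amount_g")
ROSTER_COLUMNS = ("participant_id", "age_y", "sex", "weight")

AGE_RANGE_Y = (5.0, 12.0)
DIARY_DAYS = (1, 2, 3, 4)


class SchemaError(ValueError):
    """A CSV file does not match its documented schema."""


class ValidationError(ValueError):
    """A row violates a stated invariant."""


@dataclass(frozen=True, slots=True)
class FoodCategory:
    """One of the 26 food categories (id 1-26, unique name)."""

    id: int
    name: str


@dataclass(frozen=True, slots=True)
class FoodItem:
    food_code: str
    description: str
    category: FoodCategory
    per_100g: NutrientVector


@dataclass(frozen=True, slots=True)
class DiaryEntry:
    """One consumption event: who ate what, on which diary day, how much."""

    participant_id: str
    day: int
    is_weekend: bool
    food_code: str
    amount_g: float


@dataclass(frozen=True, slots=True)
class Participant:
    participant_id: str
    age_y: float
    sex: str  # "male" | "female"
    weight: float = 1.0


def load_taxonomy(path: str | Path | None = None) -> dict[str, FoodCategory]:
    """Load the category taxonomy (name -> FoodCategory).

    With no ``path`` the packaged 26-category default is used.  The
    taxonomy must contain exactly 26 uniquely named entries.
    """
    if path is None:
        ref = importlib.resources.files("fatexchange").joinpath("data/categories.csv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    missing = {"id", "name"} - set(df.columns)
    if missing:
        raise SchemaError(f"taxonomy file missing column(s): {sorted(missing)}")
    if len(df) != N_CATEGORIES:
        raise ValidationError(f"taxonomy must have exactly {N_CATEGORIES} categories, got {len(df)}")
    if df["name"].duplicated().any():
        dupes = df.loc[df["name"].duplicated(), "name"].tolist()
        raise ValidationError(f"duplicate category names: {dupes}")
    return {str(r["name"]): FoodCategory(int(r["id"]), str(r["name"])) for _, r in df.iterrows()}


class CompositionTable:
    """A food composition table: unique food codes with per-100 g nutrients."""

    def __init__(self, items: Iterable[FoodItem]):
        self._items: dict[str, FoodItem] = {}
        for item in items:
            if item.food_code in self._items:
                raise ValidationError(f"duplicate food_code {item.food_code!r}")
            self._items[item.food_code] = item

    def __len__(self) -> int:
        return len(self._items)

    def __contains__(self, food_code: str) -> bool:
        return food_code in self._items

    def __getitem__(self, food_code: str) -> FoodItem:
        try:
            return self._items[food_code]
        except KeyError:
            raise KeyError(f"unknown food_code {food_code!r}") from None

    def __iter__(self):
        return iter(self._items.values())

    def items_in_category(self, category_name: str) -> list[FoodItem]:
        return [f for f in self if f.category.name == category_name]

    def find_by_description(self, description: str) -> FoodItem:
        """Exact (case-insensitive) description lookup; error if not unique."""
        hits = [f for f in self if f.description.lower() == description.lower()]
        if len(hits) != 1:
            raise KeyError(f"description {description!r} matched {len(hits)} foods (need exactly 1)")
        return hits[0]

    def categories(self) -> list[FoodCategory]:
        seen: dict[int, FoodCategory] = {}
        for f in self:
            seen.setdefault(f.category.id, f.category)
        return [seen[k] for k in sorted(seen)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self:
            row: dict = {
                "food_code": f.food_code,
                "description": f.description,
                "category": f.category.name,
            }
            arr = f.per_100g.as_array()
            row.update(dict(zip(NUTRIENT_FIELDS, arr.tolist())))
            rows.append(row)
        return pd.DataFrame(rows, columns=list(COMPOSITION_COLUMNS))


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} CSV missing column(s): {missing}")


def read_composition(
    path: str | Path,
    taxonomy: Mapping[str, FoodCategory] | None = None,
) -> CompositionTable:
    """Read and validate a composition CSV.

    Every row's nutrient vector must satisfy the physical invariants
    (non-negativity; fatty-acid classes bounded by total fat to rounding
    tolerance).  Rows failing validation are reported with their 1-based
    data row number.
    """
    taxonomy = taxonomy if taxonomy is not None else load_taxonomy()
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, COMPOSITION_COLUMNS, "composition")
    items = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        cat_name = str(row.category)
        if cat_name not in taxonomy:
            raise ValidationError(f"composition row {i}: unknown category {cat_name!r}")
        vec = NutrientVector(**{f: float(getattr(row, f)) for f in NUTRIENT_FIELDS})
        try:
            vec.validate(context=f"composition row {i}, food {row.food_code!r}")
        except NutrientValidationError as e:
            raise ValidationError(str(e)) from e
        items.append(FoodItem(str(row.food_code), str(row.description), taxonomy[cat_name], vec))
    return CompositionTable(items)


def write_composition(table: CompositionTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_roster(path: str | Path) -> dict[str, Participant]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ROSTER_COLUMNS[:3], "roster")
    if "weight" not in df.columns:
        df = df.assign(weight=1.0)
    roster: dict[str, Participant] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        pid = str(row.participant_id)
        if pid in roster:
            raise ValidationError(f"roster row {i}: duplicate participant_id {pid!r}")
        age, w, sex = float(row.age_y), float(row.weight), str(row.sex)
        if not (AGE_RANGE_Y[0] <= age <= AGE_RANGE_Y[1]):
            raise ValidationError(f"roster row {i}: age {age} y outside {AGE_RANGE_Y}")
        if sex not in ("male", "female"):
            raise ValidationError(f"roster row {i}: sex must be 'male' or 'female', got {sex!r}")
        if w <= 0:
            raise ValidationError(f"roster row {i}: survey weight must be > 0, got {w}")
        roster[pid] = Participant(pid, age, sex, w)
    return roster


def write_roster(roster: Mapping[str, Participant], path: str | Path) -> None:
    pd.DataFrame(
        [(p.participant_id, p.age_y, p.sex, p.weight) for p in roster.values()],
        columns=list(ROSTER_COLUMNS),
    ).to_csv(path, index=False)


def read_diaries(
    path: str | Path,
    composition: CompositionTable,
    strict: bool = True,
) -> dict[str, list[DiaryEntry]]:
    """Read diary CSV and group entries by participant.

    Each participant must record at most the four consecutive diary days;
    an absent weekend day is an error in strict mode and a warning
    otherwise.  Every food code must resolve in ``composition``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, DIARY_COLUMNS, "diary")
    diaries: dict[str, list[DiaryEntry]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        day = int(row.day)
        if day not in DIARY_DAYS:
            raise ValidationError(f"diary row {i}: day {day} outside {DIARY_DAYS}")
        amount = float(row.amount_g)
        if amount <= 0:
            raise ValidationError(f"diary row {i}: amount_g must be > 0, got {amount}")
        code = str(row.food_code)
        if code not in composition:
            raise ValidationError(f"diary row {i}: food_code {code!r} not in composition table")
        entry = DiaryEntry(str(row.participant_id), day, bool(row.is_weekend), code, amount)
        diaries.setdefault(entry.participant_id, []).append(entry)
    for pid, entries in diaries.items():
        days = {e.day for e in entries}
        if len(days) > len(DIARY_DAYS):
            raise ValidationError(f"participant {pid!r}: {len(days)} distinct days recorded (max 4)")
        weekend_flags = {e.day: e.is_weekend for e in entries}
        if len({d for d, wk in weekend_flags.items() if wk}) == 0:
            msg = f"participant {pid!r}: diary has no weekend day"
            if strict:
                raise ValidationError(msg)
            warnings.warn(msg, stacklevel=2)
        for d in days:
            flags = {e.is_weekend for e in entries if e.day == d}
            if len(flags) > 1:
                raise ValidationError(f"participant {pid!r} day {d}: inconsistent weekend flag")
    return diaries


def diaries_to_frame(diaries: Mapping[str, list[DiaryEntry]]) -> pd.DataFrame:
    rows = [
        (e.participant_id, e.day, e.is_weekend, e.food_code, e.amount_g)
        for entries in diaries.values()
        for e in entries
    ]
    return pd.DataFrame(rows, columns=list(DIARY_COLUMNS))


def write_diaries(diaries: Mapping[str, list[DiaryEntry]], path: str | Path) -> None:
    diaries_to_frame(diaries).to_csv(path, index=False)
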