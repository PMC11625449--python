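"""Per-participant mean daily intakes and food-category contributions.

A participant's mean daily intake is the diary total of ``amount_g/100 x
per-100 g nutrients`` divided by the number of distinct recorded days
(normally 4).  Percent-of-total-energy (%TE) values use each
participant's own energy intake; population %TE means are means of the
individual %TE values.

Category contributions are computed either by the population-proportion
method (ratio of weighted sums — the convention of the Irish national
surveys) or as the weighted mean of per-participant category shares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .food_model import CompositionTable, DiaryEntry, FoodCategory
from .nutrients import (
    ENERGY_FACTORS_KCAL_PER_G,
    NUTRIENT_FIELDS,
    NutrientVector,
    percent_energy,
)

#: Nutrients reported on the %TE scale (everything with an energy factor).
PCT_TE_NUTRIENTS = tuple(ENERGY_FACTORS_KCAL_PER_G)


@dataclass(frozen=True)
class ParticipantIntake:
    """Mean daily intakes for one participant.

    ``daily`` holds per-day means in canonical units; ``pct_te`` maps each
    energy-bearing nutrient to its share of the participant's energy;
    ``by_category`` partitions ``daily`` by food category.
    """

    participant_id: str
    daily: NutrientVector
    pct_te: dict[str, float]
    epa_dha_mg: float
    by_category: dict[FoodCategory, NutrientVector]
    n_days: int


def mean_daily_intake(
    participant_id: str,
    entries: Iterable[DiaryEntry],
    composition: CompositionTable,
) -> ParticipantIntake:
    """Compute one participant's mean daily intake and category subtotals.

    An empty diary yields an all-zero intake with a warning (%TE values
    are then zero by convention, not an error).
    """
    entries = list(entries)
    if not entries:
        warnings.warn(f"participant {participant_id!r}: empty diary, intake is zero", stacklevel=2)
        zero = NutrientVector()
        return ParticipantIntake(participant_id, zero, {n: 0.0 for n in PCT_TE_NUTRIENTS}, 0.0, {}, 0)
    n_days = len({e.day for e in entries})
    by_cat: dict[FoodCategory, np.ndarray] = {}
    for e in entries:
        food = composition[e.food_code]
        contrib = food.per_100g.as_array() * (e.amount_g / 100.0)
        acc = by_cat.setdefault(food.category, np.zeros(len(NUTRIENT_FIELDS)))
        acc += contrib
    total = sum(by_cat.values()) / n_days
    daily = NutrientVector.from_array(total)
    idx = {f: k for k, f in enumerate(NUTRIENT_FIELDS)}
    energy = daily.energy_kcal
    if energy > 0:
        pct_te = {
            n: percent_energy(total[idx[n]], energy, ENERGY_FACTORS_KCAL_PER_G[n])
            for n in PCT_TE_NUTRIENTS
        }
    else:
        pct_te = {n: 0.0 for n in PCT_TE_NUTRIENTS}
    return ParticipantIntake(
        participant_id=participant_id,
        daily=daily,
        pct_te=pct_te,
        epa_dha_mg=(daily.epa_g + daily.dha_g) * 1000.0,
        by_category={c: NutrientVector.from_array(v / n_days) for c, v in by_cat.items()},
        n_days=n_days,
    )


def cohort_intakes(
    diaries: Mapping[str, list[DiaryEntry]],
    composition: CompositionTable,
) -> dict[str, ParticipantIntake]:
    return {pid: mean_daily_intake(pid, entries, composition) for pid, entries in diaries.items()}


def intakes_to_frame(intakes: Mapping[str, ParticipantIntake]) -> pd.DataFrame:
    """One row per participant: daily g/d-scale values, %TE values, EPA+DHA mg/d."""
    rows = []
    for pid, it in intakes.items():
        row: dict = {"participant_id": pid, "n_days": it.n_days}
        row.update(dict(zip(NUTRIENT_FIELDS, it.daily.as_array().tolist())))
        row.update({f"pct_te_{n.removesuffix('_g')}": v for n, v in it.pct_te.items()})
        row["epa_dha_mg"] = it.epa_dha_mg
        rows.append(row)
    return pd.DataFrame(rows).set_index("participant_id").sort_index()


def category_nutrient_frame(
    intakes: Mapping[str, ParticipantIntake],
    nutrient: str,
    all_categories: Iterable[FoodCategory] | None = None,
) -> pd.DataFrame:
    """Participants x categories matrix of per-day ``nutrient`` intakes (g/d scale)."""
    if nutrient not in NUTRIENT_FIELDS:
        raise KeyError(f"unknown nutrient {nutrient!r}")
    cats = sorted(
        {c for it in intakes.values() for c in it.by_category}
        | set(all_categories or []),
        key=lambda c: c.id,
    )
    data = {
        c.name: [it.by_category.get(c, NutrientVector()).__getattribute__(nutrient) for it in intakes.values()]
        for c in cats
    }
    return pd.DataFrame(data, index=pd.Index(list(intakes), name="participant_id"))


@dataclass(frozen=True)
class ContributionTable:
    """Percent contribution of each food category to a cohort nutrient intake."""

    nutrient: str
    method: str
    rows: pd.Series  # index: category name, values: percent

    def total(self) -> float:
        return float(self.rows.sum())


def category_contribution(
    intakes: Mapping[str, ParticipantIntake],
    nutrient: str,
    weights: Mapping[str, float] | None = None,
    method: str = "population_proportion",
    all_categories: Iterable[FoodCategory] | None = None,
) -> ContributionTable:
    """Percent contribution of every food category to cohort ``nutrient`` intake.

    ``population_proportion`` (default): 100 x sum_i w_i c_ik / sum_i w_i t_i,
    where c_ik is participant i's intake of the nutrient from category k
    and t_i their total.  ``mean_of_ratios``: the weighted mean of the
    per-participant category shares.  Both sum to 100 over categories.
    """
    if method not in ("population_proportion", "mean_of_ratios"):
        raise ValueError(f"unknown contribution method {method!r}")
    mat = category_nutrient_frame(intakes, nutrient, all_categories)
    w = pd.Series(
        [1.0 if weights is None else float(weights[pid]) for pid in mat.index], index=mat.index
    )
    totals = mat.sum(axis=1)
    if method == "population_proportion":
        denom = float((w * totals).sum())
        if denom <= 0:
            raise ValueError(f"contribution undefined: cohort total {nutrient} intake is zero")
        rows = mat.mul(w, axis=0).sum(axis=0) / denom * 100.0
    else:
        nonzero = totals > 0
        if not nonzero.any():
            raise ValueError(f"contribution undefined: cohort total {nutrient} intake is zero")
        shares = mat.loc[nonzero].div(totals[nonzero], axis=0)
        ww = w[nonzero]
        rows = shares.mul(ww, axis=0).sum(axis=0) / float(ww.sum()) * 100.0
    return ContributionTable(nutrient=nutrient, method=method, rows=rows)


def participant_category_share(
    intakes: Mapping[str, ParticipantIntake],
    nutrient: str,
    all_categories: Iterable[FoodCategory] | None = None,
) -> pd.DataFrame:
    """Per-participant percent of ``nutrient`` intake from each category."""
    mat = category_nutrient_frame(intakes, nutrient, all_categories)
    totals = mat.sum(axis=1)
    out = mat.div(totals.where(totals > 0), axis=0) * 100.0
    return out.fillna(0.0)


def participant_category_pct_te(
    intakes: Mapping[str, ParticipantIntake],
    nutrient: str,
    all_categories: Iterable[FoodCategory] | None = None,
) -> pd.DataFrame:
    """Per-participant %TE supplied by each category's ``nutrient`` intake.

    The alternative reading of a category-contribution table: each cell is
    the energy from the category's nutrient as a share of the
    participant's total energy.
    """
    factor = ENERGY_FACTORS_KCAL_PER_G[nutrient]
    mat = category_nutrient_frame(intakes, nutrient, all_categories)
    energy = pd.Series({pid: it.daily.energy_kcal for pid, it in intakes.items()})
    energy = energy.reindex(mat.index)
    out = mat.mul(factor).div(energy.where(energy > 0), axis=0) * 100.0
    return out.fillna(0.0)
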