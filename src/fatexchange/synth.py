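"""Seeded synthetic composition table and cohort diaries.

The national survey this analysis emulates (600 children aged 5-12, 300
boys and 300 girls, consecutive 4-day semi-weighed diaries with at least
one weekend day, foods aggregated into 26 categories) is not publicly
deposited, so this module generates a cohort with the statistical
structure the analysis assumes:

* a composition table with >= 2 foods in every category and a paired
  lower-SFA replacement for every exchangeable food (the spread pair is
  also higher-PUFA);
* diaries whose realised cohort mean SFA %TE is calibrated to the target
  (default 14.0, within 0.5), with a between-child gradient such that
  whole milk, cheese and butter consumption rises across SFA tertiles.

Generation is two-stage: the diary skeleton (event categories, portion
draws, daily energy targets) is drawn once from the seed; a single
"rich-food" logit *a* then decides, per event, whether the high-SFA or
the lighter variant of a category is eaten.  Realised mean SFA %TE is
monotone in *a*, so *a* is calibrated by bisection (bounded iterations,
fully deterministic).  Daily amounts are scaled so each day meets the
child's age-appropriate energy target, which makes %TE depend only on
the food mix, not portion scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .food_model import (
    CompositionTable,
    DiaryEntry,
    FoodItem,
    Participant,
    load_taxonomy,
)
from .nutrients import NutrientVector


class CalibrationError(RuntimeError):
    """The SFA %TE target is unattainable with this composition table."""


# --------------------------------------------------------------------------
# Composition table
# --------------------------------------------------------------------------

# (description, fat g/100g, (sfa, mufa, pufa, trans) fractions of fat,
#  protein, carbohydrate, sugar g/100g, vitamin E mg/100g,
#  n-3 share of PUFA, marine n-3 profile, "rich" flag)
# The rich flag marks the high-SFA variant inside a category; the cohort
# generator's calibrated logit chooses between rich and lighter variants.
_F = tuple[str, float, tuple[float, float, float, float], float, float, float, float, float, bool, bool]

_FOOD_SPECS: dict[str, list[_F]] = {
    "whole milk": [
        ("whole milk", 3.6, (0.63, 0.28, 0.03, 0.030), 3.4, 4.7, 4.7, 0.07, 0.08, False, True),
        ("whole milk, fortified", 3.5, (0.62, 0.28, 0.04, 0.030), 3.4, 4.8, 4.8, 0.50, 0.08, False, True),
    ],
    "low-fat, skimmed and fortified milks": [
        ("low-fat milk", 1.5, (0.62, 0.28, 0.04, 0.020), 3.5, 4.9, 4.9, 0.03, 0.08, False, False),
        ("skimmed milk", 0.3, (0.60, 0.25, 0.05, 0.020), 3.5, 5.0, 5.0, 0.01, 0.08, False, False),
        ("fortified low-fat milk", 1.6, (0.61, 0.28, 0.04, 0.020), 3.6, 4.9, 4.9, 1.00, 0.08, False, False),
    ],
    "cheeses": [
        ("cheddar cheese, full-fat", 34.4, (0.62, 0.27, 0.040, 0.035), 25.4, 0.1, 0.1, 0.70, 0.08, False, True),
        ("processed cheese, full-fat", 27.0, (0.61, 0.28, 0.040, 0.030), 20.8, 5.0, 5.0, 0.40, 0.08, False, True),
        ("cheddar cheese, reduced-fat", 15.8, (0.62, 0.27, 0.040, 0.030), 32.7, 0.1, 0.1, 0.30, 0.08, False, False),
        ("processed cheese slices, reduced-fat", 11.0, (0.60, 0.28, 0.050, 0.030), 24.0, 6.0, 6.0, 0.20, 0.08, False, False),
    ],
    "yogurts": [
        ("whole-milk yogurt", 3.0, (0.64, 0.27, 0.03, 0.030), 5.7, 7.8, 7.8, 0.05, 0.08, False, True),
        ("low-fat fruit yogurt", 1.1, (0.60, 0.27, 0.05, 0.020), 4.2, 13.7, 13.0, 0.02, 0.08, False, False),
    ],
    "butter": [
        ("butter, salted", 82.2, (0.63, 0.26, 0.034, 0.035), 0.6, 0.6, 0.6, 2.00, 0.08, False, True),
        ("butter spread, dairy fat", 75.0, (0.61, 0.27, 0.050, 0.030), 0.5, 0.8, 0.8, 1.80, 0.08, False, True),
    ],
    "spreading fats and oils": [
        ("high-PUFA sunflower spread", 59.0, (0.20, 0.24, 0.530, 0.005), 0.2, 0.5, 0.5, 20.00, 0.10, False, False),
        ("olive oil spread", 59.0, (0.24, 0.52, 0.210, 0.005), 0.2, 0.5, 0.5, 8.00, 0.08, False, False),
        ("vegetable oil", 99.9, (0.15, 0.25, 0.580, 0.005), 0.0, 0.0, 0.0, 15.00, 0.08, False, False),
    ],
    "fresh meat": [
        ("beef mince, fried", 15.0, (0.43, 0.47, 0.05, 0.040), 25.0, 0.0, 0.0, 0.20, 0.08, False, True),
        ("pork chop, fried", 12.0, (0.38, 0.45, 0.13, 0.010), 27.0, 0.0, 0.0, 0.10, 0.08, False, True),
        ("lamb chop, grilled", 14.0, (0.46, 0.41, 0.07, 0.050), 25.0, 0.0, 0.0, 0.15, 0.08, False, True),
        ("beef mince, lean, grilled", 5.5, (0.42, 0.46, 0.06, 0.040), 28.0, 0.0, 0.0, 0.20, 0.08, False, False),
        ("pork chop, lean, grilled", 4.5, (0.36, 0.44, 0.16, 0.010), 30.0, 0.0, 0.0, 0.10, 0.08, False, False),
    ],
    "processed meats": [
        ("pork sausages, fried", 22.0, (0.36, 0.45, 0.13, 0.010), 14.0, 9.0, 1.0, 0.10, 0.08, False, True),
        ("ham, standard", 5.0, (0.36, 0.46, 0.12, 0.010), 20.0, 1.0, 1.0, 0.05, 0.08, False, True),
        ("pork sausages, reduced-fat, grilled", 10.0, (0.35, 0.45, 0.14, 0.010), 16.0, 9.0, 1.0, 0.10, 0.08, False, False),
        ("ham, lean", 2.4, (0.35, 0.45, 0.13, 0.010), 21.0, 0.8, 0.8, 0.05, 0.08, False, False),
    ],
    "poultry": [
        ("roast chicken, with skin", 9.7, (0.28, 0.45, 0.24, 0.010), 27.0, 0.0, 0.0, 0.10, 0.08, False, True),
        ("chicken breast, grilled", 2.2, (0.28, 0.40, 0.27, 0.010), 32.0, 0.0, 0.0, 0.10, 0.08, False, False),
    ],
    "fish, fish products and fish dishes": [
        ("white fish fillet, baked", 1.2, (0.18, 0.25, 0.35, 0.000), 21.0, 0.0, 0.0, 0.40, 0.55, True, False),
        ("salmon, grilled", 13.0, (0.19, 0.40, 0.28, 0.000), 22.0, 0.0, 0.0, 1.90, 0.55, True, True),
        ("fish fingers, grilled", 9.0, (0.12, 0.35, 0.40, 0.010), 13.0, 17.0, 0.8, 0.60, 0.25, True, False),
    ],
    "eggs and egg dishes": [
        ("boiled egg", 9.0, (0.30, 0.42, 0.15, 0.000), 12.5, 0.0, 0.0, 1.10, 0.08, False, False),
        ("scrambled egg with milk", 11.0, (0.35, 0.40, 0.13, 0.010), 11.0, 1.5, 1.5, 1.00, 0.08, False, True),
    ],
    "bread and rolls": [
        ("white bread", 2.2, (0.23, 0.15, 0.50, 0.000), 8.5, 46.0, 3.5, 0.50, 0.08, False, False),
        ("wholemeal bread", 2.9, (0.19, 0.18, 0.52, 0.000), 9.5, 42.0, 2.8, 0.90, 0.08, False, False),
    ],
    "ready-to-eat breakfast cereals": [
        ("cornflakes", 0.7, (0.30, 0.20, 0.40, 0.000), 7.0, 84.0, 8.0, 0.40, 0.08, False, False),
        ("wheat biscuit breakfast cereal", 2.0, (0.25, 0.15, 0.50, 0.000), 11.5, 69.0, 4.4, 0.70, 0.08, False, False),
    ],
    "biscuits": [
        ("chocolate biscuit", 26.0, (0.55, 0.32, 0.080, 0.020), 5.7, 62.0, 43.0, 1.20, 0.08, False, True),
        ("cookies", 21.0, (0.50, 0.33, 0.120, 0.020), 5.5, 66.0, 36.0, 1.00, 0.08, False, True),
        ("plain biscuit, reduced-fat", 9.5, (0.28, 0.35, 0.300, 0.010), 7.0, 72.0, 20.0, 1.50, 0.08, False, False),
    ],
    "cakes and pastries": [
        ("fruit cake", 11.0, (0.40, 0.37, 0.150, 0.020), 4.0, 58.0, 40.0, 0.80, 0.08, False, False),
        ("croissant", 20.0, (0.55, 0.30, 0.080, 0.030), 8.0, 44.0, 8.0, 0.70, 0.08, False, True),
    ],
    "chocolate confectionery": [
        ("milk chocolate bar", 30.0, (0.60, 0.31, 0.040, 0.020), 7.0, 57.0, 56.0, 0.60, 0.08, False, True),
        ("chocolate-coated wafer bar", 26.0, (0.62, 0.28, 0.060, 0.010), 6.0, 62.0, 48.0, 0.60, 0.08, False, True),
    ],
    "sugar confectionery": [
        ("fruit gums", 0.2, (0.30, 0.30, 0.20, 0.000), 5.0, 77.0, 60.0, 0.00, 0.08, False, False),
        ("boiled sweets", 0.0, (0.00, 0.00, 0.00, 0.000), 0.0, 87.0, 70.0, 0.00, 0.08, False, False),
    ],
    "savoury snacks": [
        ("popcorn, butter-flavoured", 25.0, (0.44, 0.33, 0.180, 0.010), 9.0, 48.0, 2.0, 2.50, 0.08, False, True),
        ("cream crackers", 13.0, (0.42, 0.35, 0.180, 0.005), 9.5, 68.0, 1.5, 0.80, 0.08, False, True),
        ("rice cakes, flavoured", 8.0, (0.30, 0.35, 0.300, 0.000), 8.0, 78.0, 4.0, 0.60, 0.08, False, True),
        ("potato crisps", 31.0, (0.13, 0.40, 0.420, 0.000), 6.0, 53.0, 0.6, 5.50, 0.08, False, True),
        ("popcorn, plain, air-popped", 4.3, (0.14, 0.26, 0.500, 0.000), 12.0, 63.0, 1.0, 2.00, 0.08, False, False),
        ("cream crackers, reduced-fat", 6.0, (0.23, 0.35, 0.370, 0.000), 10.0, 72.0, 1.5, 0.70, 0.08, False, False),
        ("rice cakes, plain, lower-fat", 2.8, (0.20, 0.30, 0.420, 0.000), 8.5, 81.0, 0.8, 0.50, 0.08, False, False),
    ],
    "desserts and puddings": [
        ("dairy ice cream", 9.8, (0.62, 0.28, 0.040, 0.030), 3.5, 22.0, 21.0, 0.20, 0.08, False, True),
        ("custard", 4.2, (0.60, 0.28, 0.050, 0.030), 3.8, 16.0, 12.0, 0.10, 0.08, False, False),
    ],
    "potatoes boiled, baked and mashed": [
        ("boiled potatoes", 0.1, (0.25, 0.25, 0.40, 0.000), 1.8, 17.0, 0.7, 0.00, 0.08, False, False),
        ("mashed potato with butter and milk", 4.3, (0.58, 0.28, 0.060, 0.030), 1.9, 15.5, 1.2, 0.10, 0.08, False, True),
    ],
    "potatoes chipped, fried and roasted": [
        ("oven chips, baked", 4.2, (0.12, 0.46, 0.400, 0.000), 3.2, 30.0, 0.6, 0.80, 0.08, False, False),
        ("chips, fried in vegetable oil", 12.4, (0.12, 0.43, 0.420, 0.005), 3.9, 30.5, 0.7, 1.50, 0.08, False, True),
    ],
    "rice and pasta": [
        ("boiled white rice", 0.4, (0.30, 0.25, 0.35, 0.000), 2.6, 31.0, 0.1, 0.00, 0.08, False, False),
        ("boiled pasta", 0.7, (0.20, 0.15, 0.50, 0.000), 4.8, 31.0, 0.6, 0.00, 0.08, False, False),
    ],
    "fruit": [
        ("apple", 0.1, (0.20, 0.05, 0.45, 0.000), 0.4, 11.8, 11.8, 0.60, 0.08, False, False),
        ("banana", 0.3, (0.35, 0.05, 0.20, 0.000), 1.2, 23.0, 20.9, 0.30, 0.08, False, False),
    ],
    "vegetables": [
        ("carrots, boiled", 0.4, (0.20, 0.05, 0.50, 0.000), 0.6, 4.4, 4.2, 0.60, 0.08, False, False),
        ("peas, boiled", 0.9, (0.18, 0.10, 0.45, 0.000), 6.7, 10.0, 2.3, 0.20, 0.08, False, False),
    ],
    "non-alcoholic beverages": [
        ("orange juice", 0.1, (0.20, 0.20, 0.20, 0.000), 0.5, 8.8, 8.8, 0.20, 0.08, False, False),
        ("cola drink", 0.0, (0.00, 0.00, 0.00, 0.000), 0.0, 10.6, 10.6, 0.00, 0.08, False, False),
    ],
    "other foods": [
        ("tomato ketchup", 0.3, (0.20, 0.20, 0.40, 0.000), 1.2, 27.0, 23.0, 0.00, 0.08, False, False),
        ("vegetable soup", 1.8, (0.30, 0.35, 0.250, 0.005), 1.5, 7.0, 2.5, 0.40, 0.08, False, False),
    ],
}

#: Typical single-event portion medians (g) per category, before age scaling.
_PORTION_MEDIAN_G: dict[str, float] = {
    "whole milk": 190.0,
    "low-fat, skimmed and fortified milks": 190.0,
    "cheeses": 28.0,
    "yogurts": 125.0,
    "butter": 9.0,
    "spreading fats and oils": 9.0,
    "fresh meat": 85.0,
    "processed meats": 55.0,
    "poultry": 85.0,
    "fish, fish products and fish dishes": 75.0,
    "eggs and egg dishes": 55.0,
    "bread and rolls": 65.0,
    "ready-to-eat breakfast cereals": 30.0,
    "biscuits": 24.0,
    "cakes and pastries": 50.0,
    "chocolate confectionery": 28.0,
    "sugar confectionery": 25.0,
    "savoury snacks": 25.0,
    "desserts and puddings": 80.0,
    "potatoes boiled, baked and mashed": 120.0,
    "potatoes chipped, fried and roasted": 110.0,
    "rice and pasta": 140.0,
    "fruit": 100.0,
    "vegetables": 70.0,
    "non-alcoholic beverages": 240.0,
    "other foods": 40.0,
}

#: Base probability that an eating event falls in a category (normalised).
_BASE_CATEGORY_WEIGHT: dict[str, float] = {
    "whole milk": 0.060,
    "low-fat, skimmed and fortified milks": 0.040,
    "cheeses": 0.040,
    "yogurts": 0.040,
    "butter": 0.050,
    "spreading fats and oils": 0.035,
    "fresh meat": 0.050,
    "processed meats": 0.040,
    "poultry": 0.040,
    "fish, fish products and fish dishes": 0.020,
    "eggs and egg dishes": 0.020,
    "bread and rolls": 0.090,
    "ready-to-eat breakfast cereals": 0.060,
    "biscuits": 0.050,
    "cakes and pastries": 0.020,
    "chocolate confectionery": 0.040,
    "sugar confectionery": 0.020,
    "savoury snacks": 0.040,
    "desserts and puddings": 0.030,
    "potatoes boiled, baked and mashed": 0.040,
    "potatoes chipped, fried and roasted": 0.040,
    "rice and pasta": 0.050,
    "fruit": 0.080,
    "vegetables": 0.070,
    "non-alcoholic beverages": 0.100,
    "other foods": 0.020,
}

#: Loading of the latent fat-propensity z on category log-weights; positive
#: for the SFA-determinant categories, negative for their lighter
#: counterparts, producing the whole milk / cheese / butter tertile
#: gradient by construction.
_PROPENSITY_LOADING: dict[str, float] = {
    "whole milk": 0.28,
    "cheeses": 0.18,
    "butter": 0.25,
    "biscuits": 0.10,
    "processed meats": 0.10,
    "chocolate confectionery": 0.10,
    "low-fat, skimmed and fortified milks": -0.28,
    "spreading fats and oils": -0.10,
    "fruit": -0.07,
    "vegetables": -0.07,
    "fish, fish products and fish dishes": -0.07,
}


def generate_composition(seed: int = 0) -> CompositionTable:
    """Deterministic synthetic composition table, 26 categories, >= 2 foods each.

    Nutrient profiles are template values with +/-3 % seeded jitter (one
    factor for the fat block, one for the other macros), so the invariant
    structure — fatty-acid partition, every replacement strictly lower in
    SFA per 100 g, the spread pair strictly higher in PUFA — holds for
    every seed.
    """
    rng = np.random.default_rng(seed)
    taxonomy = load_taxonomy()
    items: list[FoodItem] = []
    code = 0
    for cat_name, foods in _FOOD_SPECS.items():
        category = taxonomy[cat_name]
        for (desc, fat, fr, prot, carb, sugar, ve, n3_share, marine, _rich) in foods:
            code += 1
            fat_jit = 1.0 + rng.uniform(-0.03, 0.03)
            macro_jit = 1.0 + rng.uniform(-0.03, 0.03)
            ve_jit = 1.0 + rng.uniform(-0.03, 0.03)
            f = fat * fat_jit
            sfa, mufa, pufa, trans = (x * f for x in fr)
            n3 = pufa * n3_share
            n6 = pufa - n3
            if marine:
                ala, epa, dha = 0.08 * n3, 0.42 * n3, 0.46 * n3
            else:
                ala, epa, dha = 0.92 * n3, 0.005 * n3, 0.005 * n3
            p, c, s = prot * macro_jit, carb * macro_jit, sugar * macro_jit
            vec = NutrientVector(
                energy_kcal=9.0 * f + 4.0 * p + 3.75 * c,
                total_fat_g=f,
                sfa_g=sfa,
                mufa_g=mufa,
                pufa_g=pufa,
                trans_g=trans,
                n6_g=n6,
                n3_g=n3,
                ala_g=ala,
                epa_g=epa,
                dha_g=dha,
                protein_g=p,
                carbohydrate_g=c,
                total_sugar_g=s,
                vitamin_e_mg=ve * ve_jit,
            )
            vec.validate(context=f"generated food {desc!r}")
            items.append(FoodItem(f"F{code:03d}", desc, category, vec))
    return CompositionTable(items)


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of the emulated survey."""

    n_children: int = 600
    sex_ratio: float = 0.5  # proportion male
    age_range: tuple[int, int] = (5, 12)
    n_days: int = 4
    target_sfa_pct_te: float = 14.0
    sfa_sd: float = 2.5  # %TE dispersion; default places tertile means near 11/14/17
    seed: int = 0
    weight_model: str | None = None  # None (all 1.0) or "social-class"

    def __post_init__(self):
        if self.n_children < 3:
            raise ValueError("n_children must be >= 3")
        if not (0.0 < self.sex_ratio < 1.0):
            raise ValueError("sex_ratio must be in (0, 1)")
        if not (0.0 < self.target_sfa_pct_te < 40.0):
            raise ValueError("target_sfa_pct_te must be in (0, 40)")


@dataclass(frozen=True)
class CalibrationInfo:
    rich_logit: float
    realised_mean_sfa_pct_te: float
    iterations: int


@dataclass(frozen=True)
class SyntheticCohort:
    spec: CohortSpec
    roster: dict[str, Participant] = field(repr=False)
    diaries: dict[str, list[DiaryEntry]] = field(repr=False)
    calibration: CalibrationInfo


def generate_cohort(spec: CohortSpec, composition: CompositionTable) -> SyntheticCohort:
    """Generate a roster and 4-day diaries matching the study conditions.

    Deterministic under ``spec.seed``; the realised cohort mean SFA %TE is
    within 0.05 of ``target_sfa_pct_te`` at the calibrated logit (the
    acceptance tolerance is 0.5).  Raises :class:`CalibrationError` if the
    target is outside the range the composition can reach.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_children
    n_days = spec.n_days
    disp = spec.sfa_sd / 2.5  # scale loadings relative to the default dispersion

    # --- roster -----------------------------------------------------------
    width = max(4, len(str(n)))
    pids = [f"P{i + 1:0{width}d}" for i in range(n)]
    n_male = round(n * spec.sex_ratio)
    sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(sexes)
    ages = rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=n).astype(float)
    if spec.weight_model is None:
        weights = np.ones(n)
    elif spec.weight_model == "social-class":
        weights = rng.choice([0.8, 1.0, 1.25], size=n, p=[0.3, 0.4, 0.3])
    else:
        raise ValueError(f"unknown weight_model {spec.weight_model!r}")
    z = rng.standard_normal(n)

    # --- food lookup tables ----------------------------------------------
    foods = list(composition)
    cat_names = list(_FOOD_SPECS)
    cat_index = {name: k for k, name in enumerate(cat_names)}
    food_cat = np.array([cat_index[f.category.name] for f in foods])
    rich_flags: dict[str, set[str]] = {
        c: {d for (d, *rest) in specs if rest[-1]} for c, specs in _FOOD_SPECS.items()
    }
    is_rich = np.array([f.description in rich_flags[f.category.name] for f in foods])
    energy_per_g = np.array([f.per_100g.energy_kcal for f in foods]) / 100.0
    sfa_per_g = np.array([f.per_100g.sfa_g for f in foods]) / 100.0
    rich_idx = [np.flatnonzero((food_cat == k) & is_rich) for k in range(len(cat_names))]
    lean_idx = [np.flatnonzero((food_cat == k) & ~is_rich) for k in range(len(cat_names))]
    all_idx = [np.flatnonzero(food_cat == k) for k in range(len(cat_names))]

    # --- diary skeleton (drawn once) --------------------------------------
    base_w = np.array([_BASE_CATEGORY_WEIGHT[c] for c in cat_names])
    beta = np.array([_PROPENSITY_LOADING.get(c, 0.0) for c in cat_names]) * disp
    logw = np.log(base_w)[None, :] + z[:, None] * beta[None, :]
    probs = np.exp(logw)
    probs /= probs.sum(axis=1, keepdims=True)
    cum = np.cumsum(probs, axis=1)

    events_per_day = rng.integers(9, 15, size=(n, n_days))
    child_of_event = np.repeat(np.arange(n), events_per_day.sum(axis=1))
    day_of_event = np.concatenate(
        [np.repeat(np.arange(1, n_days + 1), events_per_day[i]) for i in range(n)]
    )
    n_events = child_of_event.size
    u_cat = rng.random(n_events)
    event_cat = (u_cat[:, None] > cum[child_of_event]).sum(axis=1)
    u_rich = rng.random(n_events)
    u_which = rng.random(n_events)
    age_factor = (ages / 8.5) ** 0.7
    portions = _PORTION_MEDIAN_G_ARR(cat_names)[event_cat] * age_factor[child_of_event] * np.exp(
        rng.normal(0.0, 0.35, size=n_events)
    )
    energy_target = (1100.0 + 70.0 * ages) * np.exp(rng.normal(0.0, 0.10, size=n))
    day_jitter = np.exp(rng.normal(0.0, 0.05, size=(n, n_days)))
    day_energy_target = energy_target[:, None] * day_jitter  # kcal per child-day
    start_weekday = rng.integers(3, 7, size=n)  # Thu..Sun start guarantees a weekend day
    gamma = 0.30 * disp

    day_key = child_of_event * n_days + (day_of_event - 1)
    flat_day_target = day_energy_target.reshape(-1)

    def realise(a: float):
        """Pick foods at rich-logit ``a`` and scale amounts to the energy targets."""
        pi = 1.0 / (1.0 + np.exp(-(a + gamma * z)))
        pick_rich = u_rich < pi[child_of_event]
        food_idx = np.empty(n_events, dtype=int)
        for k in range(len(cat_names)):
            mask = event_cat == k
            if not mask.any():
                continue
            r_idx, l_idx = rich_idx[k], lean_idx[k]
            if len(r_idx) == 0 or len(l_idx) == 0:
                pool = all_idx[k]
                food_idx[mask] = pool[(u_which[mask] * len(pool)).astype(int)]
                continue
            m_rich = mask & pick_rich
            m_lean = mask & ~pick_rich
            food_idx[m_rich] = r_idx[(u_which[m_rich] * len(r_idx)).astype(int)]
            food_idx[m_lean] = l_idx[(u_which[m_lean] * len(l_idx)).astype(int)]
        raw_energy = np.bincount(day_key, weights=portions * energy_per_g[food_idx], minlength=n * n_days)
        scale = flat_day_target / raw_energy
        amounts = portions * scale[day_key]
        return food_idx, amounts

    def mean_sfa_pct_te(food_idx, amounts) -> float:
        sfa_d = np.bincount(child_of_event, weights=amounts * sfa_per_g[food_idx], minlength=n) / n_days
        energy_d = day_energy_target.mean(axis=1)
        return float((9.0 * sfa_d / energy_d * 100.0).mean())

    # --- monotone bisection on the rich-food logit -------------------------
    lo, hi = -8.0, 8.0
    f_lo = mean_sfa_pct_te(*realise(lo))
    f_hi = mean_sfa_pct_te(*realise(hi))
    target = spec.target_sfa_pct_te
    if not (f_lo - 0.05 <= target <= f_hi + 0.05):
        raise CalibrationError(
            f"target SFA {target} %TE outside attainable range [{f_lo:.2f}, {f_hi:.2f}]"
        )
    a, realised, iters = 0.0, None, 0
    for iters in range(1, 41):
        a = 0.5 * (lo + hi)
        food_idx, amounts = realise(a)
        realised = mean_sfa_pct_te(food_idx, amounts)
        if abs(realised - target) <= 0.05:
            break
        if realised < target:
            lo = a
        else:
            hi = a
    food_idx, amounts = realise(a)
    realised = mean_sfa_pct_te(food_idx, amounts)

    # --- materialise domain objects ----------------------------------------
    food_codes = np.array([f.food_code for f in foods])
    roster = {
        pid: Participant(pid, float(ages[i]), str(sexes[i]), float(weights[i]))
        for i, pid in enumerate(pids)
    }
    weekend = ((start_weekday[child_of_event] + day_of_event - 1) % 7) >= 5
    diaries: dict[str, list[DiaryEntry]] = {pid: [] for pid in pids}
    codes_ev = food_codes[food_idx]
    for i in range(n_events):
        pid = pids[child_of_event[i]]
        diaries[pid].append(
            DiaryEntry(pid, int(day_of_event[i]), bool(weekend[i]), str(codes_ev[i]), float(amounts[i]))
        )
    info = CalibrationInfo(rich_logit=float(a), realised_mean_sfa_pct_te=realised, iterations=iters)
    return SyntheticCohort(spec=spec, roster=roster, diaries=diaries, calibration=info)


def _PORTION_MEDIAN_G_ARR(cat_names: list[str]) -> np.ndarray:
    return np.array([_PORTION_MEDIAN_G[c] for c in cat_names])
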