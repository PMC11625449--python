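"""Nutrient vectors and energy-conversion conventions.

All quantities are stored per 100 g (composition tables) or per day
(intakes).  One canonical unit per dimension: energy in kcal, fatty acids
and macronutrients in g, vitamin E in mg.  EPA+DHA is converted to mg only
at reporting and compliance boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np

#: Ordered nutrient field names shared by composition tables and intakes.
NUTRIENT_FIELDS: tuple[str, ...] = (
    "energy_kcal",
    "total_fat_g",
    "sfa_g",
    "mufa_g",
    "pufa_g",
    "trans_g",
    "n6_g",
    "n3_g",
    "ala_g",
    "epa_g",
    "dha_g",
    "protein_g",
    "carbohydrate_g",
    "total_sugar_g",
    "vitamin_e_mg",
)

#: Energy-conversion (Atwater-type) factors in kcal/g, UK convention.
#: Fat classes all convert at 9 kcal/g; carbohydrate (and its sugar
#: subset) at 3.75 kcal/g as in the McCance & Widdowson lineage.
ENERGY_FACTORS_KCAL_PER_G: dict[str, float] = {
    "total_fat_g": 9.0,
    "sfa_g": 9.0,
    "mufa_g": 9.0,
    "pufa_g": 9.0,
    "trans_g": 9.0,
    "n6_g": 9.0,
    "n3_g": 9.0,
    "ala_g": 9.0,
    "epa_g": 9.0,
    "dha_g": 9.0,
    "protein_g": 4.0,
    "carbohydrate_g": 3.75,
    "total_sugar_g": 3.75,
}

#: Relative tolerance for fatty-acid partition invariants: the sum of
#: fatty-acid classes may exceed total fat by at most this fraction
#: (rounding in published composition data).
FAT_PARTITION_TOL = 0.05


class NutrientValidationError(ValueError):
    """A nutrient vector violates a physical invariant."""


@dataclass(frozen=True, slots=True)
class NutrientVector:
    """Energy plus the tracked fat fractions and macronutrients.

    Units: kcal for energy, g for fat classes / protein / carbohydrate /
    sugars, mg for vitamin E.  Semantics (per 100 g vs per day) are set by
    context.
    """

    energy_kcal: float = 0.0
    total_fat_g: float = 0.0
    sfa_g: float = 0.0
    mufa_g: float = 0.0
    pufa_g: float = 0.0
    trans_g: float = 0.0
    n6_g: float = 0.0
    n3_g: float = 0.0
    ala_g: float = 0.0
    epa_g: float = 0.0
    dha_g: float = 0.0
    protein_g: float = 0.0
    carbohydrate_g: float = 0.0
    total_sugar_g: float = 0.0
    vitamin_e_mg: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in NUTRIENT_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, values) -> "NutrientVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(NUTRIENT_FIELDS),):
            raise ValueError(f"expected {len(NUTRIENT_FIELDS)} values, got {values.shape}")
        return cls(**dict(zip(NUTRIENT_FIELDS, values.tolist())))

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector.from_array(self.as_array() + other.as_array())

    def __mul__(self, scalar: float) -> "NutrientVector":
        return NutrientVector.from_array(self.as_array() * float(scalar))

    __rmul__ = __mul__

    def validate(self, tol: float = FAT_PARTITION_TOL, context: str = "") -> None:
        """Raise :class:`NutrientValidationError` on a physical impossibility.

        Checks non-negativity, that the fatty-acid classes do not exceed
        total fat beyond rounding tolerance, and that the n-3 sub-fractions
        (ALA, EPA+DHA) do not exceed total n-3 beyond the same tolerance.
        """
        where = f" ({context})" if context else ""
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise NutrientValidationError(f"{f.name} = {v!r} must be finite and >= 0{where}")
        fa_sum = self.sfa_g + self.mufa_g + self.pufa_g + self.trans_g
        if fa_sum > self.total_fat_g * (1 + tol):
            raise NutrientValidationError(
                f"fatty-acid classes sum to {fa_sum:.4g} g > total fat "
                f"{self.total_fat_g:.4g} g x (1 + {tol}){where}"
            )
        if self.ala_g > self.n3_g * (1 + tol):
            raise NutrientValidationError(
                f"ALA {self.ala_g:.4g} g exceeds n-3 {self.n3_g:.4g} g{where}"
            )
        if self.epa_g + self.dha_g > self.n3_g * (1 + tol):
            raise NutrientValidationError(
                f"EPA+DHA {self.epa_g + self.dha_g:.4g} g exceeds n-3 {self.n3_g:.4g} g{where}"
            )


def percent_energy(
    nutrient_g: float,
    energy_kcal: float,
    kcal_per_g: float,
) -> float:
    """A nutrient's share of total energy (%TE).

    ``nutrient_g`` is a daily intake in grams, ``energy_kcal`` the daily
    energy intake, ``kcal_per_g`` the conversion factor (9 for fat
    classes, 4 for protein, 3.75 for carbohydrate).
    """
    if energy_kcal <= 0:
        raise ValueError(f"%TE undefined for energy {energy_kcal!r} kcal/d (must be > 0)")
    return nutrient_g * kcal_per_g / energy_kcal * 100.0
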