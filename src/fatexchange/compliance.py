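"""Compliance with dietary fat recommendations.

A recommendation is a bound on a nutrient expressed in %TE (fat classes)
or mg/d (EPA+DHA); compliance is the weighted share of participants whose
intake satisfies the bound, bounds inclusive as printed (SFA <= 10 %TE,
PUFA >= 6 %TE, EPA+DHA >= 250 mg/d).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .intake import ParticipantIntake


class RecommendationError(ValueError):
    pass


@dataclass(frozen=True)
class Recommendation:
    """A dietary reference bound: ``upper`` (<=), ``lower`` (>=) or
    ``range`` (both, inclusive) on a nutrient in %TE or mg/d."""

    nutrient: str  # NutrientVector fat field ("sfa_g", ...) or "epa_dha"
    unit: str  # "%TE" | "mg/d"
    bound: str  # "upper" | "lower" | "range"
    value: float | None = None
    low: float | None = None
    high: float | None = None
    source: str = ""
    assumed: bool = False  # True for implementer defaults not printed in guidelines

    def __post_init__(self):
        if self.bound in ("upper", "lower"):
            if self.value is None or self.value <= 0:
                raise RecommendationError(f"{self.bound} bound needs a positive threshold")
        elif self.bound == "range":
            if self.low is None or self.high is None or not (0 < self.low <= self.high):
                raise RecommendationError("range bounds must satisfy 0 < low <= high")
        else:
            raise RecommendationError(f"unknown bound type {self.bound!r}")

    def label(self) -> str:
        name = self.nutrient.removesuffix("_g")
        if self.bound == "upper":
            return f"{name} <= {self.value:g} {self.unit}"
        if self.bound == "lower":
            return f"{name} >= {self.value:g} {self.unit}"
        return f"{name} in [{self.low:g}, {self.high:g}] {self.unit}"

    def satisfied_by(self, measured: float) -> bool:
        if self.bound == "upper":
            return measured <= self.value
        if self.bound == "lower":
            return measured >= self.value
        return self.low <= measured <= self.high


def default_recommendation_set() -> list[Recommendation]:
    """EFSA/UK dietary fat recommendations.

    SFA <= 10 %TE, PUFA >= 6 %TE and EPA+DHA >= 250 mg/d are the
    guideline values; the total fat, MUFA and trans-fat thresholds are
    implementer defaults (``assumed=True``) since compliance with them is
    conventionally reported but their numeric cut-offs vary by authority.
    """
    return [
        Recommendation("total_fat_g", "%TE", "upper", value=35.0, source="UK", assumed=True),
        Recommendation("sfa_g", "%TE", "upper", value=10.0, source="UK/EFSA"),
        Recommendation("mufa_g", "%TE", "lower", value=10.0, source="implementer", assumed=True),
        Recommendation("pufa_g", "%TE", "lower", value=6.0, source="UK/EFSA"),
        Recommendation("trans_g", "%TE", "upper", value=2.0, source="implementer", assumed=True),
        Recommendation("epa_dha", "mg/d", "lower", value=250.0, source="EFSA"),
    ]


def _measure(intake: ParticipantIntake, rec: Recommendation) -> float:
    if rec.unit == "mg/d":
        if rec.nutrient != "epa_dha":
            raise RecommendationError(f"mg/d recommendations support only epa_dha, got {rec.nutrient!r}")
        return intake.epa_dha_mg
    if rec.unit == "%TE":
        if rec.nutrient not in intake.pct_te:
            raise RecommendationError(f"nutrient {rec.nutrient!r} has no %TE value")
        return intake.pct_te[rec.nutrient]
    raise RecommendationError(f"unknown unit {rec.unit!r}")


@dataclass(frozen=True)
class ComplianceResult:
    recommendation: Recommendation
    arm: str
    percent_compliant: float
    n: int


def assess_compliance(
    intakes: Mapping[str, ParticipantIntake],
    recommendations: Sequence[Recommendation],
    weights: Mapping[str, float] | None = None,
    arm: str = "baseline",
) -> list[ComplianceResult]:
    """Weighted percent of participants meeting each recommendation.

    percent = 100 x sum of weights of compliant participants / total
    weight; with equal weights this is the plain proportion.
    """
    if not intakes:
        raise ValueError("no intakes supplied")
    results = []
    pids = list(intakes)
    w = pd.Series([1.0 if weights is None else float(weights[p]) for p in pids], index=pids)
    total_w = float(w.sum())
    for rec in recommendations:
        ok = pd.Series(
            [rec.satisfied_by(_measure(intakes[p], rec)) for p in pids], index=pids
        )
        pct = float(w[ok].sum()) / total_w * 100.0
        results.append(ComplianceResult(rec, arm, pct, len(pids)))
    return results


def compliance_to_frame(results: Iterable[ComplianceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "recommendation": r.recommendation.label(),
                "source": r.recommendation.source,
                "assumed_threshold": r.recommendation.assumed,
                "arm": r.arm,
                "percent_compliant": r.percent_compliant,
                "n": r.n,
            }
            for r in results
        ]
    )


def write_recommendations(recs: Sequence[Recommendation], path: str | Path) -> None:
    payload = []
    for r in recs:
        item = {"nutrient": r.nutrient, "unit": r.unit, "bound": r.bound, "source": r.source,
                "assumed": r.assumed}
        if r.bound == "range":
            item.update(low=r.low, high=r.high)
        else:
            item["value"] = r.value
        payload.append(item)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_recommendations(path: str | Path) -> list[Recommendation]:
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, list):
        raise RecommendationError("recommendation file must be a YAML list")
    return [
        Recommendation(
            nutrient=str(item["nutrient"]),
            unit=str(item["unit"]),
            bound=str(item["bound"]),
            value=item.get("value"),
            low=item.get("low"),
            high=item.get("high"),
            source=str(item.get("source", "")),
            assumed=bool(item.get("assumed", False)),
        )
        for item in payload
    ]
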