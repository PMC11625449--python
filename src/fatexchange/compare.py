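"""Baseline-vs-modelled comparison statistics.

Paired-sample t tests per nutrient endpoint (participant-aligned),
Bonferroni adjustment across the family of endpoints, signed differences
in both unit systems (g/d and %TE, kcal/d for energy), and the percent
change in food-category contributions that drives the waterfall-style
contribution figures.  Relative changes are always computed from
unrounded inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intake import ParticipantIntake, intakes_to_frame
from .nutrients import NUTRIENT_FIELDS

#: Fat-profile endpoints of the main comparison (g/d and %TE panels).
FAT_PANEL = (
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
)

#: Macro-/micronutrient panel reported alongside the fat profile.
MACRO_PANEL = ("protein_g", "carbohydrate_g", "total_sugar_g", "vitamin_e_mg")


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    df: int
    flag: str = ""  # "", "no-change", "zero-variance"


def paired_t(baseline: Sequence[float], model: Sequence[float]) -> PairedTResult:
    """Two-sided paired-sample t test, participant-aligned.

    t = mean(d) / (sd(d)/sqrt(n)) with d = model - baseline on n-1 df.
    Zero-variance differences are flagged: identical arms give a
    "no-change" result (t = 0, p = 1); a constant nonzero shift gives
    p = 0 with a "zero-variance" flag.
    """
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(model, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("baseline and model must be equal-length 1-d vectors")
    n = x.size
    if n < 2:
        raise ValueError(f"paired t needs n >= 2, got {n}")
    d = y - x
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d[0] == 0.0:
            return PairedTResult(0.0, 1.0, n - 1, flag="no-change")
        return PairedTResult(float(np.sign(d[0]) * np.inf), 0.0, n - 1, flag="zero-variance")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return PairedTResult(float(t), p, n - 1)


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """p_adj = min(1, p * m); ``m`` defaults to the number of p-values.

    The family size may exceed the number supplied (a reported subset of
    a larger tested family) but never be smaller.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m_eff = p.size if m is None else int(m)
    if m_eff < p.size:
        raise ValueError(f"family size {m_eff} smaller than number of p-values {p.size}")
    return np.minimum(1.0, p * m_eff)


@dataclass(frozen=True)
class PctChange:
    """Relative change of a contribution; ``status`` is 'ok', 'new'
    (appeared from zero: relative change undefined), or 'both-zero'."""

    value: float | None
    status: str


def contribution_pct_change(baseline_contrib: float, model_contrib: float) -> PctChange:
    """(model - baseline) / baseline x 100, on unrounded inputs.

    A category removed entirely yields exactly -100; a category absent at
    baseline but present post-exchange is reported as 'new' rather than a
    number.
    """
    if baseline_contrib < 0:
        raise ValueError(f"baseline contribution must be >= 0, got {baseline_contrib}")
    if baseline_contrib == 0.0:
        return PctChange(None, "new") if model_contrib > 0 else PctChange(0.0, "both-zero")
    return PctChange((model_contrib - baseline_contrib) / baseline_contrib * 100.0, "ok")


@dataclass(frozen=True)
class PairedComparison:
    nutrient: str
    unit: str
    baseline_mean: float
    model_mean: float
    delta: float
    t: float
    p: float
    p_adj: float
    n: int
    flag: str = ""


def _aligned_frames(
    baseline: Mapping[str, ParticipantIntake], model: Mapping[str, ParticipantIntake]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    fb, fm = intakes_to_frame(baseline), intakes_to_frame(model)
    if set(fb.index) != set(fm.index):
        only_b = sorted(set(fb.index) - set(fm.index))
        only_m = sorted(set(fm.index) - set(fb.index))
        raise ValueError(
            f"arms are not participant-aligned (baseline-only: {only_b}, model-only: {only_m})"
        )
    return fb, fm.loc[fb.index]


def build_comparison_table(
    baseline: Mapping[str, ParticipantIntake],
    model: Mapping[str, ParticipantIntake],
    family_size: int | None = None,
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-endpoint paired comparison between arms.

    Emits energy (kcal/d), every fat endpoint in both g/d and %TE, and
    the macro/micronutrient panel (protein, carbohydrate, total sugar in
    g/d and %TE where defined; vitamin E in mg/d).  Bonferroni family
    defaults to the number of endpoint rows.  ``groups`` (participant ->
    stratum label, e.g. sex) adds a stratified copy of every row.
    """
    fb, fm = _aligned_frames(baseline, model)

    endpoints: list[tuple[str, str, str]] = [("energy", "kcal/d", "energy_kcal")]
    for nut in FAT_PANEL:
        endpoints.append((nut.removesuffix("_g"), "g/d", nut))
        endpoints.append((nut.removesuffix("_g"), "%TE", f"pct_te_{nut.removesuffix('_g')}"))
    for nut in MACRO_PANEL:
        if nut == "vitamin_e_mg":
            endpoints.append(("vitamin_e", "mg/d", nut))
            continue
        endpoints.append((nut.removesuffix("_g"), "g/d", nut))
        endpoints.append((nut.removesuffix("_g"), "%TE", f"pct_te_{nut.removesuffix('_g')}"))
    endpoints.append(("epa_dha", "mg/d", "epa_dha_mg"))

    strata: list[tuple[str, pd.Index]] = [("all", fb.index)]
    if groups is not None:
        g = pd.Series({pid: groups[pid] for pid in fb.index})
        strata += [(lvl, g.index[g == lvl]) for lvl in sorted(g.unique())]

    rows = []
    for stratum, idx in strata:
        results = []
        for name, unit, col in endpoints:
            x = fb.loc[idx, col].to_numpy(dtype=float)
            y = fm.loc[idx, col].to_numpy(dtype=float)
            res = paired_t(x, y)
            results.append((name, unit, x.mean(), y.mean(), res))
        m = family_size if family_size is not None else len(results)
        p_adj = bonferroni_adjust([r[4].p for r in results], m)
        for (name, unit, bmean, mmean, res), pa in zip(results, p_adj):
            rows.append(
                {
                    "group": stratum,
                    "nutrient": name,
                    "unit": unit,
                    "baseline_mean": bmean,
                    "model_mean": mmean,
                    "delta": mmean - bmean,
                    "t": res.t,
                    "p": res.p,
                    "p_adj": float(pa),
                    "n": len(idx),
                    "flag": res.flag,
                }
            )
    return pd.DataFrame(rows)


def contribution_change_table(
    baseline_rows: pd.Series, model_rows: pd.Series
) -> pd.DataFrame:
    """Per-category percent change in contribution between arms.

    Input series are category -> percent contribution (same nutrient,
    same method, both arms); output has unrounded baseline, model,
    pct_change, and a status column ('ok' / 'new' / 'both-zero').
    """
    cats = baseline_rows.index.union(model_rows.index)
    records = []
    for cat in cats:
        b = float(baseline_rows.get(cat, 0.0))
        m = float(model_rows.get(cat, 0.0))
        ch = contribution_pct_change(b, m)
        records.append(
            {
                "category": cat,
                "baseline_pct": b,
                "model_pct": m,
                "pct_change": np.nan if ch.value is None else ch.value,
                "status": ch.status,
            }
        )
    return pd.DataFrame(records).set_index("category")
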