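"""End-to-end orchestration: data in, report bundle out.

Stages map one-to-one onto the analysis: baseline intakes -> SFA tertile
report -> food exchanges -> baseline-vs-model comparison tables ->
contribution-change table -> compliance table, plus a run manifest with
the seed, a config hash, and package versions.  Any stage error aborts
the run, names the stage, and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .compare import build_comparison_table, contribution_change_table
from .compliance import (
    assess_compliance,
    compliance_to_frame,
    default_recommendation_set,
    read_recommendations,
)
from .exchange import apply_exchanges, default_rule_set, read_rules, write_rules
from .food_model import (
    read_composition,
    read_diaries,
    read_roster,
    write_composition,
    write_diaries,
    write_roster,
)
from .intake import category_contribution, cohort_intakes, intakes_to_frame, participant_category_share
from .tertiles import assign_tertiles, compare_tertiles

log = logging.getLogger("fatexchange")

ARTEFACTS = (
    "baseline_intakes.csv",
    "tertile_report.csv",
    "modelled_diaries.csv",
    "exchange_report.csv",
    "comparison_table.csv",
    "contribution_change.csv",
    "compliance.csv",
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run.

    Either the three real-data paths are set, or ``synthetic`` is true
    and a cohort is generated from ``seed`` / ``n_children``.
    """

    output_dir: str
    composition_path: str | None = None
    diaries_path: str | None = None
    roster_path: str | None = None
    synthetic: bool = False
    n_children: int = 600
    seed: int = 0
    rules_path: str | None = None  # None -> default SFA-replacement rule set
    recommendations_path: str | None = None  # None -> default EFSA/UK set
    contribution_method: str = "population_proportion"
    alpha: float = 0.05
    tertile_family_size: int | None = None
    comparison_family_size: int | None = None
    use_survey_weights: bool = True
    strict_diaries: bool = True

    def validate(self) -> None:
        real = all(p is not None for p in (self.composition_path, self.diaries_path, self.roster_path))
        if not (real or self.synthetic):
            raise ValueError("config must set the three data paths or synthetic=True")
        if real and self.synthetic:
            raise ValueError("config sets both real-data paths and synthetic=True")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    config: RunConfig
    manifest: dict
    artefacts: dict[str, Path] = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> RunResult:
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> Path:
        path = outdir / name
        df.to_csv(path, index=index)
        written.append(path)
        return path

    stage = "load"
    try:
        if config.synthetic:
            from .synth import CohortSpec, generate_composition, generate_cohort

            composition = generate_composition(config.seed)
            cohort = generate_cohort(
                CohortSpec(n_children=config.n_children, seed=config.seed), composition
            )
            roster, diaries = cohort.roster, cohort.diaries
            write_composition(composition, outdir / "composition.csv")
            write_roster(roster, outdir / "roster.csv")
            write_diaries(diaries, outdir / "diaries.csv")
            written += [outdir / "composition.csv", outdir / "roster.csv", outdir / "diaries.csv"]
        else:
            composition = read_composition(config.composition_path)
            roster = read_roster(config.roster_path)
            diaries = read_diaries(config.diaries_path, composition, strict=config.strict_diaries)
        weights = {p.participant_id: p.weight for p in roster.values()} if config.use_survey_weights else None
        log.info("load: %d foods, %d participants, %d diary entries",
                 len(composition), len(roster), sum(map(len, diaries.values())))

        stage = "baseline_intakes"
        baseline = cohort_intakes(diaries, composition)
        emit("baseline_intakes.csv", intakes_to_frame(baseline), index=True)

        stage = "tertiles"
        sfa_pct = {pid: it.pct_te["sfa_g"] for pid, it in baseline.items()}
        assignment = assign_tertiles(sfa_pct)
        shares = participant_category_share(baseline, "sfa_g", composition.categories())
        tert = compare_tertiles(shares, assignment, alpha=config.alpha,
                                family_size=config.tertile_family_size)
        emit("tertile_report.csv", tert.table, index=True)

        stage = "exchange"
        rules = read_rules(config.rules_path) if config.rules_path else default_rule_set(composition)
        modelled_diaries, report = apply_exchanges(diaries, rules, composition)
        emit("modelled_diaries.csv",
             pd.concat([pd.DataFrame(
                 [(e.participant_id, e.day, e.is_weekend, e.food_code, e.amount_g) for e in entries],
                 columns=["participant_id", "day", "is_weekend", "food_code", "amount_g"])
                 for entries in modelled_diaries.values()], ignore_index=True))
        emit("exchange_report.csv", report.to_frame())
        write_rules(rules, outdir / "rules.yaml")
        written.append(outdir / "rules.yaml")
        log.info("exchange: %d entries (%.0f g) exchanged across %d rules",
                 report.total_entries(), report.total_grams(), len(rules))

        stage = "comparison"
        modelled = cohort_intakes(modelled_diaries, composition)
        comparison = build_comparison_table(baseline, modelled,
                                            family_size=config.comparison_family_size)
        display = comparison.copy()
        for col in ("baseline_mean", "model_mean", "delta"):
            display[f"{col}_display"] = display[col].round(1)
        emit("comparison_table.csv", display)

        stage = "contribution_change"
        frames = []
        for nutrient in ("total_fat_g", "sfa_g"):
            b = category_contribution(baseline, nutrient, weights, config.contribution_method,
                                      composition.categories())
            m = category_contribution(modelled, nutrient, weights, config.contribution_method,
                                      composition.categories())
            tab = contribution_change_table(b.rows, m.rows)
            tab.insert(0, "nutrient", nutrient.removesuffix("_g"))
            frames.append(tab.reset_index())
        emit("contribution_change.csv", pd.concat(frames, ignore_index=True))

        stage = "compliance"
        recs = (read_recommendations(config.recommendations_path)
                if config.recommendations_path else default_recommendation_set())
        results = assess_compliance(baseline, recs, weights, arm="baseline")
        results += assess_compliance(modelled, recs, weights, arm="model")
        emit("compliance.csv", compliance_to_frame(results))

        stage = "manifest"
        manifest = {
            "package": "fatexchange",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.hash(),
            "config": asdict(config),
            "n_participants": len(roster),
            "n_diary_entries": int(sum(map(len, diaries.values()))),
            "entries_exchanged": report.total_entries(),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(outdir / "manifest.json")
    except Exception as e:
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError(stage, e) from e

    return RunResult(config=config, manifest=manifest,
                     artefacts={p.name: p for p in written})
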