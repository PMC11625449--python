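"""Gram-preserving food-exchange rules and their application to diaries.

Each rule selects foods by category plus an optional case-insensitive
description regex, and names a single replacement food.  Applying a rule
set swaps the food code of every matched diary entry for the replacement
while keeping participant, day, and amount unchanged — only the food
types change, never the amounts.  Rules are ordered; the first match
wins, and replacements are not re-matched (one pass), so a rule set whose
replacements are never selected is idempotent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .food_model import CompositionTable, DiaryEntry, FoodItem


class RuleConfigError(ValueError):
    """A rule references a food or category absent from the composition."""


@dataclass(frozen=True)
class ExchangeRule:
    """Replace foods in ``category`` (optionally narrowed by ``pattern``)
    with the food ``replacement_code``, gram for gram."""

    rule_id: str
    category: str
    replacement_code: str
    pattern: str | None = None

    def matches(self, food: FoodItem) -> bool:
        if food.category.name != self.category:
            return False
        if food.food_code == self.replacement_code:
            return False
        if self.pattern is None:
            return True
        return re.search(self.pattern, food.description, flags=re.IGNORECASE) is not None


@dataclass
class ExchangeReport:
    """Per-rule tallies of exchanged entries and grams."""

    entries_exchanged: dict[str, int] = field(default_factory=dict)
    grams_exchanged: dict[str, float] = field(default_factory=dict)
    unmatched_rules: list[str] = field(default_factory=list)

    def total_entries(self) -> int:
        return sum(self.entries_exchanged.values())

    def total_grams(self) -> float:
        return sum(self.grams_exchanged.values())

    def to_frame(self) -> pd.DataFrame:
        rules = sorted(set(self.entries_exchanged) | set(self.grams_exchanged))
        return pd.DataFrame(
            {
                "rule_id": rules,
                "entries_exchanged": [self.entries_exchanged.get(r, 0) for r in rules],
                "grams_exchanged": [self.grams_exchanged.get(r, 0.0) for r in rules],
            }
        )


def validate_rules(rules: Sequence[ExchangeRule], composition: CompositionTable) -> None:
    """Fail before any mutation if a rule is unusable against this table."""
    known_categories = {c.name for c in composition.categories()}
    missing = [r.rule_id for r in rules if r.replacement_code not in composition]
    if missing:
        raise RuleConfigError(f"replacement_code missing from composition for rule(s): {missing}")
    for r in rules:
        if r.category not in known_categories:
            raise RuleConfigError(f"rule {r.rule_id!r}: category {r.category!r} not in composition")
        if r.matches(composition[r.replacement_code]):
            raise RuleConfigError(f"rule {r.rule_id!r} selects its own replacement")


def apply_exchanges(
    diaries: Mapping[str, list[DiaryEntry]],
    rules: Sequence[ExchangeRule],
    composition: CompositionTable,
) -> tuple[dict[str, list[DiaryEntry]], ExchangeReport]:
    """Apply an ordered rule set to every diary entry (first match wins).

    Matched entries keep participant, day, and amount and swap their food
    code; unmatched entries pass through unchanged.  Replacement entries
    are not re-matched.
    """
    validate_rules(rules, composition)
    report = ExchangeReport(
        entries_exchanged={r.rule_id: 0 for r in rules},
        grams_exchanged={r.rule_id: 0.0 for r in rules},
    )
    # matching depends only on the food, not the entry: precompute per food code
    decision: dict[str, str | None] = {}
    rule_for: dict[str, str] = {}
    for food in composition:
        decision[food.food_code] = None
        for r in rules:
            if r.matches(food):
                decision[food.food_code] = r.replacement_code
                rule_for[food.food_code] = r.rule_id
                break
    modelled: dict[str, list[DiaryEntry]] = {}
    for pid, entries in diaries.items():
        out = []
        for e in entries:
            repl = decision[e.food_code]
            if repl is None:
                out.append(e)
            else:
                rid = rule_for[e.food_code]
                report.entries_exchanged[rid] += 1
                report.grams_exchanged[rid] += e.amount_g
                out.append(DiaryEntry(e.participant_id, e.day, e.is_weekend, repl, e.amount_g))
        modelled[pid] = out
    report.unmatched_rules = [r.rule_id for r in rules if report.entries_exchanged[r.rule_id] == 0]
    return modelled, report


# ---------------------------------------------------------------------------
# Default rule set: the SFA replacement model
# ---------------------------------------------------------------------------

#: The exchange map of the SFA replacement model, as
#: (rule-group, source category, source description, replacement description).
#: Whole milk and butter are exchanged category-wide; cheese, meats,
#: biscuits and the named snack foods (popcorn, cream crackers, rice
#: cakes only) are exchanged per source food so each keeps its identity
#: ("leaner cuts of the same product").
DEFAULT_EXCHANGE_MAP: tuple[tuple[str, str, str | None, str], ...] = (
    ("milk", "whole milk", None, "low-fat milk"),
    ("cheese", "cheeses", "cheddar cheese, full-fat", "cheddar cheese, reduced-fat"),
    ("cheese", "cheeses", "processed cheese, full-fat", "processed cheese slices, reduced-fat"),
    ("meat", "fresh meat", "beef mince, fried", "beef mince, lean, grilled"),
    ("meat", "fresh meat", "pork chop, fried", "pork chop, lean, grilled"),
    ("meat", "processed meats", "pork sausages, fried", "pork sausages, reduced-fat, grilled"),
    ("meat", "processed meats", "ham, standard", "ham, lean"),
    ("butter", "butter", None, "high-PUFA sunflower spread"),
    ("biscuits", "biscuits", "chocolate biscuit", "plain biscuit, reduced-fat"),
    ("biscuits", "biscuits", "cookies", "plain biscuit, reduced-fat"),
    ("snacks", "savoury snacks", "popcorn, butter-flavoured", "popcorn, plain, air-popped"),
    ("snacks", "savoury snacks", "cream crackers", "cream crackers, reduced-fat"),
    ("snacks", "savoury snacks", "rice cakes, flavoured", "rice cakes, plain, lower-fat"),
)


def default_rule_set(composition: CompositionTable) -> list[ExchangeRule]:
    """Build the default SFA-replacement rule set against a composition table.

    Replacement foods are resolved by description; a missing canonical
    replacement is a configuration error listing the absent foods.
    Per-source rules use an anchored, escaped description pattern so a
    replacement can never be re-selected (idempotence by construction).
    """
    rules: list[ExchangeRule] = []
    absent: list[str] = []
    counters: dict[str, int] = {}
    for group, category, source_desc, repl_desc in DEFAULT_EXCHANGE_MAP:
        try:
            repl = composition.find_by_description(repl_desc)
        except KeyError:
            absent.append(repl_desc)
            continue
        counters[group] = counters.get(group, 0) + 1
        pattern = None if source_desc is None else f"^{re.escape(source_desc)}$"
        rules.append(
            ExchangeRule(
                rule_id=f"{group}/{counters[group]}",
                category=category,
                pattern=pattern,
                replacement_code=repl.food_code,
            )
        )
    if absent:
        raise RuleConfigError(f"composition lacks canonical replacement food(s): {absent}")
    validate_rules(rules, composition)
    return rules


def write_rules(rules: Iterable[ExchangeRule], path: str | Path) -> None:
    payload = [
        {
            "rule_id": r.rule_id,
            "category": r.category,
            "pattern": r.pattern,
            "replacement_code": r.replacement_code,
        }
        for r in rules
    ]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_rules(path: str | Path) -> list[ExchangeRule]:
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, list):
        raise RuleConfigError("rule file must be a YAML list of rule mappings")
    rules = []
    for i, item in enumerate(payload):
        try:
            rules.append(
                ExchangeRule(
                    rule_id=str(item["rule_id"]),
                    category=str(item["category"]),
                    pattern=item.get("pattern"),
                    replacement_code=str(item["replacement_code"]),
                )
            )
        except KeyError as e:
            raise RuleConfigError(f"rule entry {i}: missing key {e}") from None
    return rules
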