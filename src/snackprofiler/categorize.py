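"""Rule-based assignment of products to the nine fruit-snack categories.

The study design distinguishes nine market categories — canned fruit, canned
fruit with juice, dried fruit, dried flavored fruit, formed fruit (leathers,
rolls, strips, twists, jerky), fruit chips, fruit-based bars, fruit purees
(pouches) and fruit-flavored snacks (gummy-style) — identifiable from product
name, description, package type and ingredient list.  Assignment here is an
ordered keyword rule set: an explicit, auditable surrogate for the manual
categorization such surveys perform.  Rules are evaluated most-specific
first; the first match wins, so classification is deterministic and
single-valued.  Products matching no rule are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from .gnpd_io import ProductRecord

CATEGORIES: tuple[str, ...] = (
    "canned_fruit",
    "canned_fruit_with_juice",
    "dried_fruit",
    "dried_flavored_fruit",
    "formed_fruit",
    "fruit_chips",
    "fruit_based_bar",
    "fruit_puree",
    "fruit_flavored_snack",
)

RULE_FIELDS = ("name", "description", "package_type", "ingredients")

#: vocabulary treated as "fruit" when judging ingredient-list complexity
_FRUIT_WORDS = frozenset(
    """apple apples apricot apricots banana bananas berry berries blueberry
    blueberries cherry cherries cranberry cranberries date dates fig figs
    grape grapes kiwi lemon lime mandarin mango mangoes melon orange oranges
    papaya peach peaches pear pears pineapple plum plums prune prunes raisin
    raisins raspberry raspberries strawberry strawberries fruit fruits juice
    puree purees concentrate concentrates pulp paste""".split()
)


@dataclass
class CategoryRule:
    """One classification rule.

    ``any_of`` is a list of keyword groups; the rule matches when *every*
    group has at least one whole-word hit in the searched fields (a single
    group therefore behaves as a plain any-of list).  ``min_leading_nonfruit``
    additionally requires that many non-fruit entries among the first five
    ingredients — used to split complex-recipe bars from all-fruit formed
    products that also carry "bar" in the name.
    """

    target: str
    any_of: list[list[str]]
    fields_searched: tuple[str, ...] = ("name", "description")
    priority: int = 0
    min_leading_nonfruit: int | None = None

    def __post_init__(self) -> None:
        if self.target not in CATEGORIES:
            raise ValueError(f"unknown category {self.target!r}")
        bad = set(self.fields_searched) - set(RULE_FIELDS)
        if bad:
            raise ValueError(f"unknown searchable fields: {sorted(bad)}")
        self._compiled = [
            [re.compile(r"\b" + re.escape(p.lower()) + r"\b") for p in group]
            for group in self.any_of
        ]

    def matches(self, record: ProductRecord) -> bool:
        text = " | ".join(str(getattr(record, f, "") or "") for f in self.fields_searched).lower()
        if not all(any(rx.search(text) for rx in group) for group in self._compiled):
            return False
        if self.min_leading_nonfruit is not None:
            if count_leading_nonfruit(record.ingredients) < self.min_leading_nonfruit:
                return False
        return True


def count_leading_nonfruit(ingredients: str, leading: int = 5) -> int:
    """Count non-fruit entries among the first ``leading`` ingredients."""
    entries = [e.strip().lower() for e in (ingredients or "").split(",") if e.strip()]
    n = 0
    for entry in entries[:leading]:
        words = re.findall(r"[a-z]+", entry)
        if words and not any(w in _FRUIT_WORDS for w in words):
            n += 1
    return n


def default_ruleset() -> list[CategoryRule]:
    """The shipped rule table, most specific first."""
    fruit = sorted(_FRUIT_WORDS)
    return [
        CategoryRule(
            "fruit_chips",
            any_of=[["chips", "chip", "crisps"], fruit],
            fields_searched=("name", "description"),
            priority=1,
        ),
        CategoryRule(
            "canned_fruit_with_juice",
            any_of=[["in juice", "in fruit juice", "in 100% juice", "in its own juice",
                     "juice-packed", "packed in juice", "in pear juice", "in white grape juice"]],
            fields_searched=("name", "description"),
            priority=2,
        ),
        CategoryRule(
            "canned_fruit",
            any_of=[["in syrup", "in light syrup", "in heavy syrup", "in water",
                     "in sweetener solution", "in salt water", "canned", "fruit cup",
                     "in sweetened solution"]],
            fields_searched=("name", "description"),
            priority=3,
        ),
        CategoryRule(
            "fruit_puree",
            any_of=[["puree", "pureed", "applesauce", "apple sauce", "smoothie"],
                    ["pouch", "pouches", "squeeze", "cup", "puree", "applesauce", "apple sauce"]],
            fields_searched=("name", "description", "package_type"),
            priority=4,
        ),
        CategoryRule(
            "fruit_based_bar",
            any_of=[["bar", "bars"], fruit],
            fields_searched=("name", "description"),
            priority=5,
            min_leading_nonfruit=2,
        ),
        CategoryRule(
            "formed_fruit",
            any_of=[["leather", "leathers", "roll", "rolls", "roll-ups", "strip",
                     "strips", "twist", "twists", "jerky", "bar", "bars"], fruit],
            fields_searched=("name", "description"),
            priority=6,
        ),
        CategoryRule(
            "dried_flavored_fruit",
            any_of=[["dried", "dry", "dehydrated", "freeze-dried"],
                    ["flavored", "flavoured", "sweetened", "yogurt", "coated",
                     "salted", "chili", "cinnamon", "honey", "infused"]],
            fields_searched=("name", "description"),
            priority=7,
        ),
        CategoryRule(
            "dried_fruit",
            any_of=[["dried", "dry", "dehydrated", "freeze-dried", "raisins", "prunes", "sun-dried"]],
            fields_searched=("name", "description"),
            priority=8,
        ),
        CategoryRule(
            "fruit_flavored_snack",
            any_of=[["gummies", "gummy", "fruit snacks", "fruit snack", "fruity snacks",
                     "fruit bites", "fruit shapes", "fruit chews"]],
            fields_searched=("name", "description"),
            priority=9,
        ),
    ]


def classify(record: ProductRecord, ruleset: Sequence[CategoryRule]) -> str | None:
    """First matching rule (ascending priority) wins; None means out of scope."""
    if not ruleset:
        raise ValueError("empty ruleset")
    for rule in sorted(ruleset, key=lambda r: r.priority):
        if rule.matches(record):
            return rule.target
    return None


@dataclass
class RulesetReport:
    unreachable_labels: list[str] = field(default_factory=list)
    duplicate_priorities: list[int] = field(default_factory=list)
    empty_pattern_rules: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.unreachable_labels or self.duplicate_priorities or self.empty_pattern_rules)


def validate_ruleset(ruleset: Sequence[CategoryRule]) -> RulesetReport:
    """Static checks: every label reachable, priorities unique, patterns non-empty.

    Duplicate priorities are fatal (classification order would be undefined).
    """
    report = RulesetReport()
    seen: dict[int, int] = {}
    for rule in ruleset:
        seen[rule.priority] = seen.get(rule.priority, 0) + 1
        if not rule.any_of or any(not group for group in rule.any_of):
            report.empty_pattern_rules.append(rule.target)
    report.duplicate_priorities = sorted(p for p, c in seen.items() if c > 1)
    covered = {rule.target for rule in ruleset}
    report.unreachable_labels = [c for c in CATEGORIES if c not in covered]
    if report.duplicate_priorities:
        raise ValueError(f"duplicate rule priorities: {report.duplicate_priorities}")
    return report


def classify_all(
    records: Sequence[ProductRecord],
    ruleset: Sequence[CategoryRule] | None = None,
) -> tuple[list[ProductRecord], list[ProductRecord]]:
    """Classify records in place; returns (classified, unclassified)."""
    ruleset = list(ruleset) if ruleset is not None else default_ruleset()
    validate_ruleset(ruleset)
    in_scope: list[ProductRecord] = []
    out_of_scope: list[ProductRecord] = []
    for r in records:
        label = classify(r, ruleset)
        r.category = label
        (in_scope if label is not None else out_of_scope).append(r)
    return in_scope, out_of_scope
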