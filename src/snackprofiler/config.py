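"""YAML configuration: daily values, RACC table, cleaning constants,
classification rules and generator settings in one overridable file.

Every section is optional; absent keys fall back to the shipped defaults,
so a config file only needs to state what it changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .categorize import CategoryRule, default_ruleset
from .cleaning import CleaningConfig
from .nrf_scoring import DEFAULT_DAILY_VALUES, DEFAULT_RACC_G
from .synthetic_data import SimConfig, default_config


@dataclass
class AppConfig:
    daily_values: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DAILY_VALUES))
    racc_g: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RACC_G))
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    ruleset: list[CategoryRule] = field(default_factory=default_ruleset)
    schema: dict[str, str] | None = None  # file column -> canonical field
    sim: SimConfig = field(default_factory=default_config)
    alpha: float = 0.05


def _rules_from_yaml(items: list[dict]) -> list[CategoryRule]:
    rules = []
    for item in items:
        any_of = item["any_of"]
        if any_of and isinstance(any_of[0], str):  # single-group shorthand
            any_of = [any_of]
        rules.append(
            CategoryRule(
                target=item["target"],
                any_of=[list(g) for g in any_of],
                fields_searched=tuple(item.get("fields_searched", ("name", "description"))),
                priority=int(item["priority"]),
                min_leading_nonfruit=item.get("min_leading_nonfruit"),
            )
        )
    return rules


def load_config(path: str | Path | None = None) -> AppConfig:
    """Build an :class:`AppConfig`, overlaying a YAML file on the defaults."""
    cfg = AppConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    cfg.daily_values.update(raw.get("daily_values", {}))
    cfg.racc_g.update(raw.get("racc_g", {}))
    if "cleaning" in raw:
        section = dict(raw["cleaning"])
        for key in ("required_nutrients", "duplicate_key", "dual_label_key", "second_pass_key"):
            if key in section:
                section[key] = tuple(section[key])
        cfg.cleaning = CleaningConfig(**section)
    if "ruleset" in raw:
        cfg.ruleset = _rules_from_yaml(raw["ruleset"])
    if "schema" in raw:
        cfg.schema = dict(raw["schema"])
    if "alpha" in raw:
        cfg.alpha = float(raw["alpha"])
    if "sim" in raw:
        section = dict(raw["sim"])
        cfg.sim = default_config(
            n_per_category=section.pop("n_per_category", None),
            seed=section.pop("seed", 0),
        )
        for key, value in section.items():
            if not hasattr(cfg.sim, key):
                raise KeyError(f"unknown sim setting {key!r}")
            setattr(cfg.sim, key, value)
        cfg.sim.validate()
    return cfg


def dump_default_config(path: str | Path) -> Path:
    """Write a template config with the shipped defaults spelled out."""
    data = {
        "daily_values": dict(DEFAULT_DAILY_VALUES),
        "racc_g": dict(DEFAULT_RACC_G),
        "cleaning": {
            "fiber_dv_g": 28.0,
            "protein_sub_g": 0.75,
            "satfat_sub_g": 0.1,
            "sodium_sub_mg": 5.0,
            "cholesterol_sub_mg": 5.0,
            "required_nutrients": ["added_sugar", "vitamin_d", "calcium", "iron"],
        },
        "alpha": 0.05,
        "sim": {"n_per_category": None, "seed": 0},
        "ruleset": [
            {
                "target": r.target,
                "priority": r.priority,
                "any_of": r.any_of,
                "fields_searched": list(r.fields_searched),
                **({"min_leading_nonfruit": r.min_leading_nonfruit} if r.min_leading_nonfruit else {}),
            }
            for r in default_ruleset()
        ],
    }
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path
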