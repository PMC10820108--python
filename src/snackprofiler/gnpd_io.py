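"""Reading and writing GNPD-style product-launch tables.

Market-intelligence exports of packaged-food launches arrive as one row per
product with a per-serving Nutrition Facts panel transcribed from the label.
Panel cells are frequently *coded* rather than numeric: labels print "<1" for
fiber below one gram, "<0.1 g" saturated fat, "<5 mg" sodium or cholesterol,
and newly mandated nutrients (added sugar, vitamin D, calcium, iron) are often
simply absent on products still carrying the pre-2016 label.  This module
preserves those codes losslessly as :class:`CodedValue` so the cleaning stage
can impute them by explicit, auditable rules instead of silently coercing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical per-serving panel nutrients and their units.  Amounts are stored
#: in these units regardless of how the source cell spelled them.
NUTRIENT_UNITS: dict[str, str] = {
    "energy": "kcal",
    "saturated_fat": "g",
    "trans_fat": "g",
    "cholesterol": "mg",
    "sodium": "mg",
    "total_sugar": "g",
    "added_sugar": "g",
    "fiber": "g",
    "protein": "g",
    "potassium": "mg",
    "vitamin_d": "mcg",
    "calcium": "mg",
    "iron": "mg",
}

NUTRIENTS: tuple[str, ...] = tuple(NUTRIENT_UNITS)

#: mass-unit conversion factors to grams
_MASS_TO_G = {"g": 1.0, "mg": 1e-3, "mcg": 1e-6, "µg": 1e-6, "ug": 1e-6}

#: 40 IU of vitamin D = 1 mcg (FDA label conversion)
_VITD_IU_PER_MCG = 40.0

_MISSING_SENTINELS = {"", "na", "n/a", "nan", "none", "-", "--", "—", "null"}


class ValueState(str, Enum):
    NUMERIC = "numeric"
    CENSORED_BELOW = "censored_below"
    MISSING = "missing"


@dataclass(frozen=True)
class CodedValue:
    """A label-panel cell: a number, a "<bound>" code, or missing.

    Equality compares ``state``/``value``/``bound`` only; ``raw_text`` is
    provenance and survives round-trips as whatever text was (re)serialized.
    """

    state: ValueState
    value: float | None = None
    bound: float | None = None
    raw_text: str = ""

    def __post_init__(self) -> None:
        if self.state is ValueState.NUMERIC:
            if self.value is None or self.value < 0:
                raise ValueError(f"numeric cell requires value >= 0, got {self.value!r}")
            if self.bound is not None:
                raise ValueError("numeric cell carries no bound")
        elif self.state is ValueState.CENSORED_BELOW:
            if self.bound is None or self.bound <= 0:
                raise ValueError(f"censored cell requires bound > 0, got {self.bound!r}")
            if self.value is not None:
                raise ValueError("censored cell carries no value")
        else:
            if self.value is not None or self.bound is not None:
                raise ValueError("missing cell carries neither value nor bound")

    # provenance-insensitive equality (round-trip identity on substance)
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodedValue):
            return NotImplemented
        return (self.state, self.value, self.bound) == (other.state, other.value, other.bound)

    def __hash__(self) -> int:
        return hash((self.state, self.value, self.bound))

    @classmethod
    def numeric(cls, value: float, raw_text: str = "") -> "CodedValue":
        return cls(ValueState.NUMERIC, value=float(value), raw_text=raw_text or format_number(value))

    @classmethod
    def censored(cls, bound: float, raw_text: str = "") -> "CodedValue":
        return cls(ValueState.CENSORED_BELOW, bound=float(bound), raw_text=raw_text or f"<{format_number(bound)}")

    @classmethod
    def missing(cls, raw_text: str = "") -> "CodedValue":
        return cls(ValueState.MISSING, raw_text=raw_text)

    @property
    def is_numeric(self) -> bool:
        return self.state is ValueState.NUMERIC

    @property
    def is_censored(self) -> bool:
        return self.state is ValueState.CENSORED_BELOW

    @property
    def is_missing(self) -> bool:
        return self.state is ValueState.MISSING


def format_number(x: float) -> str:
    """Compact decimal text: drop trailing zeros, keep full precision."""
    s = repr(float(x))
    if s.endswith(".0"):
        s = s[:-2]
    return s


def format_coded_cell(cv: CodedValue) -> str:
    """Canonical text for a coded cell (inverse of :func:`parse_coded_cell`)."""
    if cv.is_numeric:
        return format_number(cv.value)
    if cv.is_censored:
        return f"<{format_number(cv.bound)}"
    return ""


_CELL_RE = re.compile(
    r"^\s*(?P<lt><\s*)?(?P<num>(?:\d+(?:\.\d+)?|\.\d+)(?:[eE][+-]?\d+)?)\s*"
    r"(?P<unit>g|mg|mcg|µg|ug|kcal|cal|iu)?\s*$",
    re.IGNORECASE,
)


def _to_canonical_unit(x: float, unit: str | None, nutrient: str) -> float:
    canonical = NUTRIENT_UNITS[nutrient]
    if unit is None:
        return x
    unit = unit.lower()
    if canonical == "kcal":
        if unit in ("kcal", "cal"):
            return x
        raise ValueError(f"unit {unit!r} invalid for energy")
    if unit == "iu":
        if nutrient == "vitamin_d":
            return x / _VITD_IU_PER_MCG
        raise ValueError(f"IU only meaningful for vitamin D, not {nutrient}")
    if unit in _MASS_TO_G and canonical in _MASS_TO_G:
        return x * _MASS_TO_G[unit] / _MASS_TO_G[canonical]
    raise ValueError(f"cannot convert {unit!r} to {canonical!r}")


def parse_coded_cell(text: object, nutrient: str) -> CodedValue:
    """Parse one panel cell into a :class:`CodedValue` in canonical units.

    Parsing is total: any cell maps to exactly one state.  Unrecognized
    content degrades to *missing* with the original text retained and a
    warning logged, never an exception.
    """
    if nutrient not in NUTRIENT_UNITS:
        raise KeyError(f"unknown nutrient {nutrient!r}")
    raw = "" if text is None else str(text)
    stripped = raw.strip()
    if stripped.lower() in _MISSING_SENTINELS:
        return CodedValue.missing(raw)
    m = _CELL_RE.match(stripped)
    if m is None:
        logger.warning("unparseable %s cell %r -> treated as missing", nutrient, raw)
        return CodedValue.missing(raw)
    try:
        x = _to_canonical_unit(float(m.group("num")), m.group("unit"), nutrient)
    except ValueError as exc:
        logger.warning("cell %r for %s: %s -> treated as missing", raw, nutrient, exc)
        return CodedValue.missing(raw)
    if m.group("lt"):
        if x <= 0:
            logger.warning("censored cell %r with non-positive bound -> missing", raw)
            return CodedValue.missing(raw)
        return CodedValue.censored(x, raw)
    return CodedValue.numeric(x, raw)


@dataclass
class ProductRecord:
    """One packaged product: metadata plus a per-serving coded nutrient panel."""

    record_id: str
    name: str
    brand: str = ""
    description: str = ""
    launch_date: date | None = None
    storage_type: str = ""
    package_type: str = ""
    claims: list[str] = field(default_factory=list)
    ingredients: str = ""
    serving_size_text: str = ""
    serving_g: float | None = None
    panel: dict[str, CodedValue] = field(default_factory=dict)
    percent_dv: dict[str, float] = field(default_factory=dict)
    category: str | None = None  # assigned by the classifier

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        self.panel = dict(self.panel)
        self.claims = list(self.claims)
        self.percent_dv = dict(self.percent_dv)
        for nutrient in NUTRIENTS:
            self.panel.setdefault(nutrient, CodedValue.missing())
        unknown = set(self.panel) - set(NUTRIENTS)
        if unknown:
            raise ValueError(f"unknown panel nutrients: {sorted(unknown)}")

    def numeric(self, nutrient: str) -> float:
        """Numeric per-serving amount; raises if the cell is not numeric."""
        cv = self.panel[nutrient]
        if not cv.is_numeric:
            raise ValueError(f"{nutrient} of record {self.record_id} is {cv.state.value}, not numeric")
        return float(cv.value)

    def has_label(self) -> bool:
        """True if at least one panel cell carries information."""
        return any(not cv.is_missing for cv in self.panel.values())

    def copy(self) -> "ProductRecord":
        return replace(
            self,
            claims=list(self.claims),
            panel=dict(self.panel),
            percent_dv=dict(self.percent_dv),
        )


@dataclass
class LedgerStep:
    label: str
    n_removed: int
    n_remaining: int


class ExclusionLedger:
    """Ordered record of screening steps: label -> (n removed, n remaining).

    The four canonical screening steps are ``out_of_scope``,
    ``no_nutrition_label``, ``duplicate`` and ``missing_new_label_nutrients``;
    further labelled steps (e.g. unparseable serving size, non-positive
    energy) may follow.  Conservation — removals plus the final remainder
    equal the initial count — is enforced on every append.
    """

    CANONICAL_STEPS = (
        "out_of_scope",
        "no_nutrition_label",
        "duplicate",
        "missing_new_label_nutrients",
    )

    def __init__(self, initial_count: int):
        if initial_count < 0:
            raise ValueError("initial count must be >= 0")
        self.initial_count = int(initial_count)
        self.steps: list[LedgerStep] = []

    @property
    def n_remaining(self) -> int:
        return self.steps[-1].n_remaining if self.steps else self.initial_count

    def record(self, label: str, n_removed: int) -> None:
        if n_removed < 0 or n_removed > self.n_remaining:
            raise ValueError(f"invalid removal count {n_removed} at step {label!r}")
        self.steps.append(LedgerStep(label, int(n_removed), self.n_remaining - int(n_removed)))

    def check_conservation(self) -> None:
        total_removed = sum(s.n_removed for s in self.steps)
        if total_removed + self.n_remaining != self.initial_count:
            raise AssertionError("exclusion ledger does not conserve record counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.label, s.n_removed, s.n_remaining) for s in self.steps],
            columns=["step", "n_removed", "n_remaining"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def log_block(self) -> str:
        lines = [f"initial records: {self.initial_count}"]
        for s in self.steps:
            lines.append(f"  - {s.label}: removed {s.n_removed}, remaining {s.n_remaining}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# table I/O

_META_COLUMNS = (
    "record_id",
    "brand",
    "name",
    "description",
    "launch_date",
    "storage_type",
    "package_type",
    "claims",
    "ingredients",
    "serving_size_text",
    "serving_g",
)

_CLAIMS_SEP = "; "


def default_columns() -> list[str]:
    cols = list(_META_COLUMNS)
    cols += list(NUTRIENTS)
    cols += [f"pct_dv_{n}" for n in NUTRIENTS]
    return cols


def _parse_date(text: str) -> date | None:
    text = text.strip()
    if not text:
        return None
    # ISO-8601 only; other dialects are ambiguous and rejected
    m = re.match(r"^(\d{4})-(\d{2})-(\d{2})$", text)
    if m is None:
        raise ValueError(f"launch_date {text!r} is not ISO-8601 (YYYY-MM-DD)")
    return date(int(m.group(1)), int(m.group(2)), int(m.group(3)))


def read_products(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[ProductRecord]:
    """Read a delimiter-separated product table into :class:`ProductRecord` s.

    Parameters
    ----------
    path:
        CSV file with a header row (UTF-8).
    schema:
        Optional map *file column name -> canonical field name* for loading
        real exports whose headers differ from the canonical layout.  Columns
        not covered by the map are matched by canonical name.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: table has no data rows")
    if schema:
        df = df.rename(columns=dict(schema))
    for mandatory in ("record_id", "name"):
        if mandatory not in df.columns:
            raise ValueError(f"{path}: mandatory column {mandatory!r} absent")

    records: list[ProductRecord] = []
    for _, row in df.iterrows():
        get = lambda col: str(row[col]) if col in df.columns else ""
        serving_txt = get("serving_g").strip()
        try:
            serving_g = float(serving_txt) if serving_txt else None
        except ValueError:
            serving_g = None
        panel = {n: parse_coded_cell(get(n), n) for n in NUTRIENTS}
        pct_dv: dict[str, float] = {}
        for n in NUTRIENTS:
            cell = get(f"pct_dv_{n}").strip()
            if cell:
                try:
                    pct_dv[n] = float(cell.rstrip("%"))
                except ValueError:
                    logger.warning("unparseable %%DV cell %r for %s", cell, n)
        claims_txt = get("claims").strip()
        records.append(
            ProductRecord(
                record_id=get("record_id"),
                brand=get("brand"),
                name=get("name"),
                description=get("description"),
                launch_date=_parse_date(get("launch_date")),
                storage_type=get("storage_type"),
                package_type=get("package_type"),
                claims=claims_txt.split(_CLAIMS_SEP) if claims_txt else [],
                ingredients=get("ingredients"),
                serving_size_text=get("serving_size_text"),
                serving_g=serving_g,
                panel=panel,
                percent_dv=pct_dv,
            )
        )
    logger.info("read %d product records from %s", len(records), path)
    return records


def write_products(records: Sequence[ProductRecord], path: str | Path) -> Path:
    """Write records as CSV; inverse of :func:`read_products` field-for-field."""
    if not records:
        raise ValueError("refusing to write an empty product table")
    rows = []
    for r in records:
        row: dict[str, str] = {
            "record_id": r.record_id,
            "brand": r.brand,
            "name": r.name,
            "description": r.description,
            "launch_date": r.launch_date.isoformat() if r.launch_date else "",
            "storage_type": r.storage_type,
            "package_type": r.package_type,
            "claims": _CLAIMS_SEP.join(r.claims),
            "ingredients": r.ingredients,
            "serving_size_text": r.serving_size_text,
            "serving_g": format_number(r.serving_g) if r.serving_g is not None else "",
        }
        for n in NUTRIENTS:
            cv = r.panel[n]
            # keep original raw text for censored cells when it re-parses to
            # the same substance; otherwise serialize canonically
            if cv.raw_text and parse_coded_cell(cv.raw_text, n) == cv:
                row[n] = cv.raw_text
            else:
                row[n] = format_coded_cell(cv)
        for n, v in r.percent_dv.items():
            row[f"pct_dv_{n}"] = format_number(v)
        rows.append(row)
    df = pd.DataFrame(rows, columns=default_columns()).fillna("")
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def records_from_rows(rows: Iterable[Mapping[str, object]]) -> list[ProductRecord]:
    """Convenience constructor from dict rows with raw text panel cells."""
    out = []
    for row in rows:
        panel = {n: parse_coded_cell(row.get(n, ""), n) for n in NUTRIENTS}
        out.append(
            ProductRecord(
                record_id=str(row["record_id"]),
                name=str(row.get("name", "")),
                brand=str(row.get("brand", "")),
                description=str(row.get("description", "")),
                serving_g=row.get("serving_g"),  # type: ignore[arg-type]
                panel=panel,
            )
        )
    return out
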