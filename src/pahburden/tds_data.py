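"""Domain types and CSV I/O for total-diet-study (TDS) concentration and consumption data.

A TDS pairs two tables: a laboratory table of per-composite-sample analyte
concentrations (with left-censored non-detects carrying their limit of
detection), and a 24-hour-recall consumption survey of per-respondent food
amounts in g per kg body weight.  Both are validated against a food catalog.

Units are canonical and fixed here: concentrations and LODs are µg/kg food;
consumption amounts are g food per kg body weight per day.  The single
µg→mg conversion lives in :mod:`pahburden.exposure_sim`, nowhere else.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "AnalyteCode",
    "ANALYTES",
    "MIN_RESPONDENT_AGE",
    "FoodItem",
    "Catalog",
    "ConcentrationRecord",
    "ConsumptionEvent",
    "PersonDay",
    "FormatError",
    "ValidationError",
    "read_catalog",
    "write_catalog",
    "read_concentration_table",
    "write_concentration_table",
    "read_survey",
    "write_survey",
]

MIN_RESPONDENT_AGE = 18


class FormatError(ValueError):
    """A table is structurally malformed (e.g. a required column is missing)."""


class ValidationError(ValueError):
    """A structurally well-formed row violates a domain invariant."""


class AnalyteCode(str, enum.Enum):
    """The four EU marker PAHs whose sum defines PAH4."""

    BaA = "BaA"  # benz[a]anthracene
    BaP = "BaP"  # benzo[a]pyrene
    BbF = "BbF"  # benzo[b]fluoranthene
    Ch = "Ch"    # chrysene


ANALYTES: tuple[AnalyteCode, ...] = tuple(AnalyteCode)


@dataclass(frozen=True)
class FoodItem:
    """One food in the catalog, with its category and preparation method."""

    food_id: str
    name: str
    category: str
    cooking_method: str


@dataclass(frozen=True)
class ConsumptionEvent:
    """One food consumed on a person-day, in g food per kg body weight."""

    food_id: str
    amount: float

    def __post_init__(self) -> None:
        if not (self.amount >= 0):
            raise ValidationError(
                f"consumption amount must be >= 0, got {self.amount} "
                f"for food {self.food_id!r}"
            )


@dataclass(frozen=True)
class ConcentrationRecord:
    """One composite-sample × analyte measurement.

    ``detected`` distinguishes a quantified value from a left-censored
    non-detect; non-detects carry no value but always carry the LOD, so the
    substitution policy downstream is data-driven per record.
    """

    food_id: str
    sample_id: str
    analyte: AnalyteCode
    detected: bool
    value: Optional[float]
    lod: float

    def __post_init__(self) -> None:
        if self.detected:
            if self.value is None or not (self.value >= 0):
                raise ValidationError(
                    f"detected record ({self.food_id!r}, {self.sample_id!r}, "
                    f"{self.analyte.value}) needs value >= 0, got {self.value}"
                )
        elif self.value is not None:
            raise ValidationError(
                f"non-detect record ({self.food_id!r}, {self.sample_id!r}, "
                f"{self.analyte.value}) must not carry a value, got {self.value}"
            )
        if not (self.lod > 0):
            raise ValidationError(
                f"lod must be > 0, got {self.lod} for "
                f"({self.food_id!r}, {self.sample_id!r}, {self.analyte.value})"
            )


@dataclass(frozen=True)
class PersonDay:
    """One respondent's complete 24-hour dietary record.

    The Monte Carlo resampling unit: one person, one day, a list of
    (food, g/kg bw) events.  Zero-amount events are legal and retained.
    """

    respondent_id: str
    age: int
    events: tuple[ConsumptionEvent, ...]

    def __post_init__(self) -> None:
        if self.age < MIN_RESPONDENT_AGE:
            raise ValidationError(
                f"respondent {self.respondent_id!r}: age {self.age} below "
                f"survey minimum {MIN_RESPONDENT_AGE}"
            )
        object.__setattr__(self, "events", tuple(self.events))

    @property
    def total_amount(self) -> float:
        """Total g/kg bw consumed across all events."""
        return sum(e.amount for e in self.events)


class Catalog:
    """A food catalog with a fixed category vocabulary and unique food ids."""

    def __init__(self, items: Iterable[FoodItem]):
        items = list(items)
        by_id: dict[str, FoodItem] = {}
        for it in items:
            if it.food_id in by_id:
                raise ValidationError(f"duplicate food_id {it.food_id!r} in catalog")
            by_id[it.food_id] = it
        self.items: tuple[FoodItem, ...] = tuple(items)
        self._by_id = by_id
        self.categories: frozenset[str] = frozenset(it.category for it in items)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._by_id

    def __getitem__(self, food_id: str) -> FoodItem:
        try:
            return self._by_id[food_id]
        except KeyError:
            raise KeyError(f"unknown food_id {food_id!r}") from None

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Catalog) and self.items == other.items


# ---------------------------------------------------------------------------
# CSV I/O.  Comma-separated, UTF-8, mandatory header, decimal point.
# ---------------------------------------------------------------------------

_CATALOG_COLS = ["food_id", "name", "category", "cooking_method"]
_CONC_COLS = ["food_id", "sample_id", "analyte", "detected", "value", "lod"]
_SURVEY_COLS = ["respondent_id", "age", "food_id", "amount"]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; header was {list(df.columns)}")
    return df


def _parse_bool(raw: str, row: int, col: str) -> bool:
    low = raw.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValidationError(f"row {row}, field {col!r}: cannot parse boolean from {raw!r}")


def _parse_float(raw: str, row: int, col: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ValidationError(f"row {row}, field {col!r}: cannot parse number from {raw!r}") from None


def read_catalog(path: str | Path) -> Catalog:
    """Read a catalog CSV (food_id,name,category,cooking_method)."""
    df = _read_csv(path, _CATALOG_COLS)
    items = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        if not rec.food_id:
            raise ValidationError(f"row {i}, field 'food_id': empty")
        items.append(FoodItem(rec.food_id, rec.name, rec.category, rec.cooking_method))
    return Catalog(items)


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    pd.DataFrame(
        [(it.food_id, it.name, it.category, it.cooking_method) for it in catalog],
        columns=_CATALOG_COLS,
    ).to_csv(path, index=False)


def read_concentration_table(
    path: str | Path, catalog: Optional[Catalog] = None
) -> list[ConcentrationRecord]:
    """Read a laboratory concentration table.

    Columns: food_id,sample_id,analyte,detected,value,lod.  ``value`` must be
    empty exactly when ``detected`` is false.  Unknown analytes, and — when a
    catalog is given — unknown food_ids, are rejected with the offending row
    number.
    """
    df = _read_csv(path, _CONC_COLS)
    records = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        if catalog is not None and rec.food_id not in catalog:
            raise ValidationError(f"row {i}, field 'food_id': {rec.food_id!r} not in catalog")
        try:
            analyte = AnalyteCode(rec.analyte)
        except ValueError:
            raise ValidationError(
                f"row {i}, field 'analyte': {rec.analyte!r} not one of "
                f"{[a.value for a in ANALYTES]}"
            ) from None
        detected = _parse_bool(rec.detected, i, "detected")
        raw_value = rec.value.strip()
        if detected and raw_value == "":
            raise ValidationError(f"row {i}, field 'value': empty but detected=true")
        value = _parse_float(raw_value, i, "value") if detected else None
        if not detected and raw_value != "":
            raise ValidationError(
                f"row {i}, field 'value': non-detect row carries value {raw_value!r}"
            )
        lod = _parse_float(rec.lod, i, "lod")
        try:
            records.append(
                ConcentrationRecord(rec.food_id, rec.sample_id, analyte, detected, value, lod)
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    return records


def write_concentration_table(
    records: Iterable[ConcentrationRecord], path: str | Path
) -> None:
    rows = [
        (
            r.food_id,
            r.sample_id,
            r.analyte.value,
            "true" if r.detected else "false",
            "" if r.value is None else repr(r.value),
            repr(r.lod),
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=_CONC_COLS).to_csv(path, index=False)


def read_survey(path: str | Path, catalog: Optional[Catalog] = None) -> list[PersonDay]:
    """Read a consumption survey (respondent_id,age,food_id,amount).

    One row per consumption event; rows are grouped by respondent_id (in
    first-appearance order) into :class:`PersonDay` records.  Zero-amount
    rows are retained.
    """
    df = _read_csv(path, _SURVEY_COLS)
    order: list[str] = []
    ages: dict[str, int] = {}
    events: dict[str, list[ConsumptionEvent]] = {}
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        rid = rec.respondent_id
        if not rid:
            raise ValidationError(f"row {i}, field 'respondent_id': empty")
        age = int(_parse_float(rec.age, i, "age"))
        if age < MIN_RESPONDENT_AGE:
            raise ValidationError(
                f"row {i}, field 'age': {age} below survey minimum {MIN_RESPONDENT_AGE}"
            )
        if rid in ages and ages[rid] != age:
            raise ValidationError(f"row {i}, field 'age': inconsistent age for {rid!r}")
        if catalog is not None and rec.food_id not in catalog:
            raise ValidationError(f"row {i}, field 'food_id': {rec.food_id!r} not in catalog")
        amount = _parse_float(rec.amount, i, "amount")
        if amount < 0:
            raise ValidationError(f"row {i}, field 'amount': negative amount {amount}")
        if rid not in ages:
            order.append(rid)
            ages[rid] = age
            events[rid] = []
        events[rid].append(ConsumptionEvent(rec.food_id, amount))
    return [PersonDay(rid, ages[rid], tuple(events[rid])) for rid in order]


def write_survey(days: Iterable[PersonDay], path: str | Path) -> None:
    rows = [
        (d.respondent_id, d.age, e.food_id, repr(e.amount))
        for d in days
        for e in d.events
    ]
    pd.DataFrame(rows, columns=_SURVEY_COLS).to_csv(path, index=False)
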