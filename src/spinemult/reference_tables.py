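"""Sitting-height multiplier tables: types, the packaged reference table,
and lookup.

The multiplier method predicts the mature value of a body dimension from a
single current measurement: ``mature = current x M``, where ``M`` is the
ratio of the dimension at skeletal maturity to the same dimension at the
current age. This module houses the published sitting-height multiplier
table — one value of M per month of age and sex, from 3 months of age up to
skeletal maturity (18 y in boys, 16 y in girls, where M = 1 by definition)
— together with the :class:`MultiplierTable` container that also accepts
user-supplied tables (e.g. a cervical-spine table) with the same structure.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Iterator, Mapping, NamedTuple

from .errors import (
    DomainError,
    OverAgeError,
    TableIntegrityError,
    UnderAgeError,
)

__all__ = [
    "Sex",
    "AgeYM",
    "MultiplierTable",
    "LookupResult",
    "TableViolation",
    "load_packaged_table",
    "lookup_multiplier",
    "parse_decimal_age",
    "validate_table",
    "PACKAGED_PROVENANCE",
]

PACKAGED_PROVENANCE = "packaged sitting-height multiplier table"

_PACKAGED_RESOURCE = "sitting_height_multipliers.csv"


class Sex(str, Enum):
    """Biological sex as stratified in growth references."""

    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, value: "Sex | str") -> "Sex":
        if isinstance(value, Sex):
            return value
        try:
            return cls(value.strip().lower())
        except (ValueError, AttributeError):
            raise DomainError(f"unrecognized sex {value!r}; expected 'male' or 'female'")


@dataclass(frozen=True, order=True)
class AgeYM:
    """Chronological age expressed as whole years plus whole months,
    matching the ``Age (Years + Months)`` convention of the tables."""

    years: int
    months: int = 0

    def __post_init__(self) -> None:
        if self.years < 0:
            raise DomainError(f"years must be non-negative, got {self.years}")
        if not 0 <= self.months <= 11:
            raise DomainError(f"months must be in 0..11, got {self.months}")

    @property
    def total_months(self) -> int:
        return 12 * self.years + self.months

    @classmethod
    def from_total_months(cls, total_months: int) -> "AgeYM":
        if total_months < 0:
            raise DomainError(f"total months must be non-negative, got {total_months}")
        return cls(total_months // 12, total_months % 12)

    @classmethod
    def parse(cls, text: "AgeYM | str | float") -> "AgeYM":
        """Parse ``'Y+M'`` (table convention, e.g. ``'10+6'``), a bare
        integer year (``'10'``), or decimal years (``'10.5'``)."""
        if isinstance(text, AgeYM):
            return text
        if isinstance(text, (int, float)):
            return parse_decimal_age(float(text))
        text = text.strip()
        if "+" in text:
            y, _, m = text.partition("+")
            try:
                return cls(int(y), int(m))
            except ValueError:
                raise DomainError(f"cannot parse age {text!r}; expected 'Y+M'")
        try:
            return cls(int(text), 0)
        except ValueError:
            pass
        try:
            return parse_decimal_age(float(text))
        except ValueError:
            raise DomainError(f"cannot parse age {text!r}")

    def __str__(self) -> str:
        return f"{self.years}+{self.months}"


def parse_decimal_age(years: float) -> AgeYM:
    """Snap a decimal age in years to the monthly grid of the tables.

    The table is the authority and carries no sub-month resolution, so the
    age is rounded to the nearest whole month; an exact half-month tie
    rounds *down* (toward the younger age, i.e. the larger multiplier).
    """
    if years < 0:
        raise DomainError(f"age must be non-negative, got {years}")
    if not math.isfinite(years):
        raise DomainError(f"age must be finite, got {years}")
    months = round(years * 12, 9)  # shed float fuzz before the tie rule
    return AgeYM.from_total_months(int(math.ceil(months - 0.5)))


class LookupResult(NamedTuple):
    multiplier: float
    post_maturity: bool


class TableViolation(NamedTuple):
    """One structural defect found by :func:`validate_table`."""

    sex: Sex
    total_months: int | None
    message: str

    def __str__(self) -> str:
        where = "" if self.total_months is None else f" at {AgeYM.from_total_months(self.total_months)}"
        return f"[{self.sex.value}{where}] {self.message}"


@dataclass(frozen=True)
class MultiplierTable:
    """Per-sex map from age in total months to the multiplier M.

    Invariants (enforced by :func:`validate_table`, checked on the packaged
    fixture at load time): for each sex the entries form a contiguous
    monthly grid; M >= 1 everywhere; M is non-increasing with age; and M at
    the oldest tabulated age (skeletal maturity) is exactly 1.
    """

    entries: Mapping[Sex, Mapping[int, float]]
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        # normalize to plain dicts keyed by Sex with sorted integer ages
        norm: dict[Sex, dict[int, float]] = {}
        for sex, mapping in self.entries.items():
            sex = Sex.parse(sex)
            norm[sex] = {int(t): float(m) for t, m in sorted(mapping.items())}
        object.__setattr__(self, "entries", norm)

    def sexes(self) -> list[Sex]:
        return list(self.entries)

    def first_age(self, sex: Sex) -> int:
        """Youngest tabulated age, in total months."""
        return min(self._sex_entries(sex))

    def maturity_age(self, sex: Sex) -> int:
        """Oldest tabulated age (skeletal maturity), in total months."""
        return max(self._sex_entries(sex))

    def ages(self, sex: Sex) -> list[int]:
        return sorted(self._sex_entries(sex))

    def _sex_entries(self, sex: Sex) -> Mapping[int, float]:
        sex = Sex.parse(sex)
        try:
            return self.entries[sex]
        except KeyError:
            raise DomainError(f"table {self.provenance!r} has no entries for sex {sex.value!r}")

    def __contains__(self, key: tuple[Sex, int]) -> bool:
        sex, total_months = key
        return total_months in self.entries.get(Sex.parse(sex), {})

    def iter_cells(self) -> Iterator[tuple[Sex, int, float]]:
        for sex in self.entries:
            for t, m in self.entries[sex].items():
                yield sex, t, m


def lookup_multiplier(
    table: MultiplierTable,
    sex: Sex | str,
    age: AgeYM,
    clamp_post_maturity: bool = False,
) -> LookupResult:
    """Exact table lookup of the multiplier M for ``sex`` at ``age``.

    Ages beyond skeletal maturity raise :class:`OverAgeError` unless
    ``clamp_post_maturity`` is set, in which case M = 1.0 is returned with
    the ``post_maturity`` flag raised (no growth remains after maturity).
    Ages below the first tabulated month (the table prints no values at
    0+1 and 0+2 months) raise :class:`UnderAgeError`.
    """
    sex = Sex.parse(sex)
    entries = table._sex_entries(sex)
    t = age.total_months
    if t < min(entries):
        raise UnderAgeError(
            f"age {age} is below the first tabulated age "
            f"({AgeYM.from_total_months(min(entries))}) for {sex.value}"
        )
    if t > max(entries):
        if clamp_post_maturity:
            return LookupResult(1.0, True)
        raise OverAgeError(
            f"age {age} is beyond skeletal maturity "
            f"({AgeYM.from_total_months(max(entries))}) for {sex.value}; "
            "pass clamp_post_maturity=True to treat growth as complete"
        )
    return LookupResult(entries[t], False)


def validate_table(table: MultiplierTable) -> list[TableViolation]:
    """Check every structural invariant; return all violations found.

    An empty report means the table is valid. This never raises: it is the
    gatekeeper for user-supplied tables, where the caller decides whether a
    defect is fatal.
    """
    report: list[TableViolation] = []
    if not table.entries:
        report.append(TableViolation(Sex.MALE, None, "table has no entries for any sex"))
        return report
    for sex, entries in table.entries.items():
        if not entries:
            report.append(TableViolation(sex, None, "no entries"))
            continue
        ages = sorted(entries)
        for prev, cur in zip(ages, ages[1:]):
            if cur != prev + 1:
                report.append(
                    TableViolation(sex, cur, f"monthly grid gap: {prev} -> {cur} total months")
                )
        for t, m in entries.items():
            if not m >= 1.0:
                report.append(TableViolation(sex, t, f"multiplier {m} < 1"))
        for prev, cur in zip(ages, ages[1:]):
            if entries[cur] > entries[prev]:
                report.append(
                    TableViolation(
                        sex, cur, f"multiplier increases with age: {entries[prev]} -> {entries[cur]}"
                    )
                )
        if entries[ages[-1]] != 1.0:
            report.append(
                TableViolation(sex, ages[-1], f"multiplier at maturity is {entries[ages[-1]]}, expected exactly 1")
            )
    return report


def _read_table_rows(rows: Iterator[list[str]], provenance: str) -> MultiplierTable:
    """Shared CSV-dialect parser (header ``sex,age_years,age_months,multiplier``)."""
    from .errors import ParseError  # local import to keep module deps one-way

    header = next(rows, None)
    expected = ["sex", "age_years", "age_months", "multiplier"]
    if header is None or [h.strip() for h in header] != expected:
        raise ParseError(f"bad header {header!r}; expected {','.join(expected)}", line=1)
    entries: dict[Sex, dict[int, float]] = {}
    for lineno, row in enumerate(rows, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != 4:
            raise ParseError(f"expected 4 fields, got {len(row)}", line=lineno)
        try:
            sex = Sex.parse(row[0])
            age = AgeYM(int(row[1]), int(row[2]))
            m = float(row[3])
        except (DomainError, ValueError) as exc:
            raise ParseError(str(exc), line=lineno)
        per_sex = entries.setdefault(sex, {})
        if age.total_months in per_sex:
            raise ParseError(f"duplicate entry for {sex.value} at age {age}", line=lineno)
        per_sex[age.total_months] = m
    return MultiplierTable(entries=entries, provenance=provenance)


def load_packaged_table() -> MultiplierTable:
    """Load the published sitting-height multiplier table.

    Male entries run monthly from 0+3 to 18+0 (214 cells), female from 0+3
    to 16+0 (190 cells). The fixture is validated on every load; a corrupt
    installation raises :class:`TableIntegrityError` naming the first
    violated invariant rather than returning bad clinical numbers.
    """
    ref = resources.files("spinemult.data").joinpath(_PACKAGED_RESOURCE)
    with ref.open("r", encoding="utf-8") as fh:
        table = _read_table_rows(csv.reader(fh), provenance=PACKAGED_PROVENANCE)
    violations = validate_table(table)
    if violations:
        raise TableIntegrityError(f"packaged table is corrupt: {violations[0]}")
    expected_span = {Sex.MALE: (3, 216), Sex.FEMALE: (3, 192)}
    for sex, (lo, hi) in expected_span.items():
        if sex not in table.entries:
            raise TableIntegrityError(f"packaged table is corrupt: missing sex {sex.value}")
        if (table.first_age(sex), table.maturity_age(sex)) != (lo, hi):
            raise TableIntegrityError(
                f"packaged table is corrupt: {sex.value} span "
                f"{table.first_age(sex)}..{table.maturity_age(sex)} months, expected {lo}..{hi}"
            )
    return table
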