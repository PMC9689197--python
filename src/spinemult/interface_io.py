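"""CSV readers/writers for both file dialects, and report rendering.

Two dialects, both UTF-8 CSV with a mandatory header:

* multiplier table:  ``sex,age_years,age_months,multiplier``
* growth database:   ``sex,percentile,age_years,age_months,sitting_height_cm``

Derived multiplier sets serialize as
``sex,percentile,age_years,age_months,multiplier``.

Multipliers are written rounded half-even to 3 decimal places (the
precision of the published tables); lengths in cm render at 2 decimals.
Rendering is deterministic: identical inputs give byte-identical output.
"""

from __future__ import annotations

import csv
import io
import json
from pathlib import Path
from typing import Union

import pandas as pd

from .derivation import (
    ComparisonResult,
    GrowthDatabase,
    GrowthRecord,
    MultiplierSet,
    VariabilityReport,
)
from .errors import DomainError, ParseError, TableIntegrityError
from .predictor import PredictionResult
from .reference_tables import (
    AgeYM,
    MultiplierTable,
    Sex,
    validate_table,
    _read_table_rows,
)

__all__ = [
    "read_multiplier_table",
    "write_multiplier_table",
    "read_growth_database",
    "write_growth_database",
    "read_multiplier_set",
    "write_multiplier_set",
    "render_report",
    "render_table_text",
]

Renderable = Union[PredictionResult, VariabilityReport, ComparisonResult]


def read_multiplier_table(path: str | Path, *, validate: bool = True) -> MultiplierTable:
    """Read a multiplier table CSV; validates structure unless told not to.

    Raises :class:`TableIntegrityError` listing the violations when the
    table breaks an invariant (non-contiguous months, non-monotone values,
    maturity multiplier != 1, ...).
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        table = _read_table_rows(csv.reader(fh), provenance=str(path))
    if validate:
        violations = validate_table(table)
        if violations:
            detail = "; ".join(str(v) for v in violations[:5])
            raise TableIntegrityError(
                f"{path}: {len(violations)} invariant violation(s): {detail}"
            )
    return table


def write_multiplier_table(table: MultiplierTable, path: str | Path) -> None:
    """Write a table in the CSV dialect, multipliers rounded half-even to
    3 decimals. ``write ∘ read`` is the identity at that rounding."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sex", "age_years", "age_months", "multiplier"])
        for sex in sorted(table.entries, key=lambda s: s.value):
            for t, m in table.entries[sex].items():
                age = AgeYM.from_total_months(t)
                writer.writerow([sex.value, age.years, age.months, format(round(m, 3), ".3f")])


_DB_HEADER = ["sex", "percentile", "age_years", "age_months", "sitting_height_cm"]


def read_growth_database(
    path: str | Path,
    *,
    maturity_male: int = 216,
    maturity_female: int = 192,
    provenance: str | None = None,
) -> GrowthDatabase:
    """Read a growth database CSV; parse errors carry the line number.

    Maturity ages are in total months and default to those of the packaged
    sitting-height table (18 y boys, 16 y girls). Every (sex, percentile)
    curve must include a record at its maturity age.
    """
    path = Path(path)
    records: list[GrowthRecord] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        rows = csv.reader(fh)
        header = next(rows, None)
        if header is None or [h.strip() for h in header] != _DB_HEADER:
            raise ParseError(f"bad header {header!r}; expected {','.join(_DB_HEADER)}", line=1)
        seen: dict[tuple, int] = {}
        for lineno, row in enumerate(rows, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 5:
                raise ParseError(f"expected 5 fields, got {len(row)}", line=lineno)
            try:
                rec = GrowthRecord(
                    sex=Sex.parse(row[0]),
                    percentile=row[1].strip(),
                    age=AgeYM(int(row[2]), int(row[3])),
                    sitting_height=float(row[4]),
                )
            except (DomainError, ValueError) as exc:
                raise ParseError(str(exc), line=lineno)
            key = (rec.sex, rec.percentile, rec.age.total_months)
            if key in seen:
                raise ParseError(
                    f"duplicate record for ({rec.sex.value}, {rec.percentile}, {rec.age}); "
                    f"first seen on line {seen[key]}",
                    line=lineno,
                )
            seen[key] = lineno
            records.append(rec)
    return GrowthDatabase(
        records,
        maturity_age={Sex.MALE: maturity_male, Sex.FEMALE: maturity_female},
        provenance=provenance or str(path),
    )


def write_growth_database(db: GrowthDatabase, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DB_HEADER)
        for rec in db.records:
            writer.writerow(
                [
                    rec.sex.value,
                    rec.percentile,
                    rec.age.years,
                    rec.age.months,
                    format(rec.sitting_height, ".6g"),
                ]
            )


_MSET_HEADER = ["sex", "percentile", "age_years", "age_months", "multiplier"]


def write_multiplier_set(mset: MultiplierSet, path: str | Path, *, decimals: int = 3) -> None:
    """Serialize a derived multiplier set, rounded half-even to ``decimals``."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MSET_HEADER)
        for row in mset.frame.itertuples(index=False):
            age = AgeYM.from_total_months(int(row.total_months))
            writer.writerow(
                [row.sex, row.percentile, age.years, age.months,
                 format(round(row.multiplier, decimals), f".{decimals}f")]
            )


def read_multiplier_set(path: str | Path) -> MultiplierSet:
    path = Path(path)
    rows = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _MSET_HEADER:
            raise ParseError(f"bad header {header!r}; expected {','.join(_MSET_HEADER)}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 5:
                raise ParseError(f"expected 5 fields, got {len(row)}", line=lineno)
            try:
                sex = Sex.parse(row[0])
                age = AgeYM(int(row[2]), int(row[3]))
                m = float(row[4])
            except (DomainError, ValueError) as exc:
                raise ParseError(str(exc), line=lineno)
            rows.append((sex.value, row[1].strip(), age.total_months, m))
    frame = pd.DataFrame(rows, columns=["sex", "percentile", "total_months", "multiplier"])
    return MultiplierSet(frame=frame, provenance=str(path))


# ---------------------------------------------------------------------------
# rendering


def _fmt_cm(x: float) -> str:
    return f"{x:.2f}"


def _fmt_mult(x: float) -> str:
    return f"{x:.3f}"


def _prediction_payload(result: PredictionResult) -> dict:
    return {
        "formula": result.formula,
        "inputs": dict(result.inputs),
        "multiplier": round(result.multiplier_used, 6),
        "predicted_cm": round(result.predicted_value, 6),
        "post_maturity": result.post_maturity,
    }


def _variability_payload(report: VariabilityReport) -> dict:
    return {
        "report": "variability",
        "pooled": {
            "mean_variability": round(report.mean_variability, 6),
            "max_variability": round(report.max_variability, 6),
        },
        "per_sex": {
            sex.value: {
                "mean_variability": round(sv.mean_variability, 6),
                "max_variability": round(sv.max_variability, 6),
                "n_ages": len(sv.per_age),
            }
            for sex, sv in sorted(report.per_sex.items(), key=lambda kv: kv[0].value)
        },
    }


def _comparison_payload(result: ComparisonResult) -> dict:
    return {
        "report": "comparison",
        "degree": result.degree,
        "r_squared": round(result.r_squared, 6),
        "rmse": round(result.rmse, 6),
        "max_abs_difference": round(result.max_abs_difference, 6),
        "n_shared_ages": result.n_shared_ages,
    }


def render_report(result: Renderable, format: str = "text") -> str:
    """Render a result record as ``text``, ``json`` (one line), or ``csv``.

    Output is deterministic; JSON lines parse back to the same values.
    """
    if isinstance(result, PredictionResult):
        payload = _prediction_payload(result)
    elif isinstance(result, VariabilityReport):
        payload = _variability_payload(result)
    elif isinstance(result, ComparisonResult):
        payload = _comparison_payload(result)
    else:
        raise DomainError(f"cannot render object of type {type(result).__name__}")

    if format == "json":
        return json.dumps(payload, sort_keys=True)
    if format == "csv":
        flat = _flatten(payload)
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(flat.keys())
        writer.writerow(flat.values())
        return buf.getvalue().rstrip("\n")
    if format == "text":
        return _render_text(result, payload)
    raise DomainError(f"unknown output format {format!r}; expected text, json, or csv")


def _flatten(payload: dict, prefix: str = "") -> dict:
    out: dict = {}
    for k, v in payload.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, prefix=f"{key}."))
        else:
            out[key] = v
    return out


def _render_text(result: Renderable, payload: dict) -> str:
    lines: list[str] = []
    if isinstance(result, PredictionResult):
        lines.append(f"formula          : {result.formula}")
        for k, v in result.inputs.items():
            lines.append(f"  {k:<15}: {v}")
        if result.formula == "limb_lengthening_target":
            # fixed anatomical ratio, not an age-specific multiplier
            lines.append("target fraction  : 88.6% of predicted mature sitting height")
        elif result.formula == "mature_standing_height":
            lines.append("sitting fraction : 53% of mature standing height")
        else:
            lines.append(f"multiplier M     : {_fmt_mult(result.multiplier_used)}")
        lines.append(f"predicted        : {_fmt_cm(result.predicted_value)} cm")
        if result.post_maturity:
            lines.append("note             : age beyond skeletal maturity; growth complete (M = 1)")
    elif isinstance(result, VariabilityReport):
        lines.append("cross-percentile multiplier variability")
        for sex_value, stats in payload["per_sex"].items():
            lines.append(
                f"  {sex_value:<7}: mean ±{stats['mean_variability']:.3f}  "
                f"max ±{stats['max_variability']:.3f}  ({stats['n_ages']} ages)"
            )
        lines.append(
            f"  pooled : mean ±{payload['pooled']['mean_variability']:.3f}  "
            f"max ±{payload['pooled']['max_variability']:.3f}"
        )
    else:  # ComparisonResult
        lines.append("multiplier-set comparison (polynomial regression)")
        lines.append(f"  degree          : {result.degree}")
        lines.append(f"  shared ages     : {result.n_shared_ages}")
        lines.append(f"  R^2             : {result.r_squared:.4f}")
        lines.append(f"  RMSE            : {result.rmse:.4f}")
        lines.append(f"  max |mean diff| : {result.max_abs_difference:.4f}")
    return "\n".join(lines)


def render_table_text(table: MultiplierTable) -> str:
    """Human-readable reproduction of a multiplier table, in the printed
    layout: one row per month, boys and girls side by side."""
    months = sorted(
        {t for sex in table.entries for t in table.entries[sex]}
    )
    lines = ["Age (Years + Months)   Boys    Girls", "-" * 38]
    for t in months:
        age = AgeYM.from_total_months(t)
        cells = []
        for sex in (Sex.MALE, Sex.FEMALE):
            m = table.entries.get(sex, {}).get(t)
            cells.append("  -  " if m is None else _fmt_mult(m))
        lines.append(f"{str(age):>10}            {cells[0]:>6}  {cells[1]:>6}")
    return "\n".join(lines)
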