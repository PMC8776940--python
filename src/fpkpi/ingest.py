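"""Reading and writing service-statistics sheets and the MWRA reference.

The machine-readable dialect is strict: UTF-8 comma-separated files with a
single header row and one row per governorate. Row order in input files is
irrelevant — the fixed registry order is canonical on output — and every
validation failure is reported with the governorate and column concerned.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Mapping

from .schema import (
    AGE_BANDS,
    CLIENT_TYPES,
    METHOD_MIX_ORDER,
    METHODS,
    PARITY_BANDS,
    VISIT_REASONS,
    VISIT_TYPES,
    Governorate,
    MethodCategory,
    Period,
    ServiceCounts,
    ValidationError,
    canonical_governorate_name,
    standard_governorate_registry,
)

__all__ = [
    "QuarterlySheet",
    "MWRAReference",
    "SHEET_COLUMNS",
    "read_quarterly_sheet",
    "read_mwra_reference",
    "write_sheet",
    "write_annual_sheet",
    "write_mwra_reference",
]

log = logging.getLogger(__name__)

USER_COLUMNS = tuple(f"users_{m.value}" for m in METHOD_MIX_ORDER)
DISPENSED_COLUMNS = tuple(f"dispensed_{m.value}" for m in METHODS)

#: Canonical column order of a sheet CSV (plus optional leading row_type).
SHEET_COLUMNS: tuple[str, ...] = (
    ("governorate",)
    + AGE_BANDS
    + PARITY_BANDS
    + USER_COLUMNS
    + VISIT_TYPES
    + CLIENT_TYPES
    + VISIT_REASONS
    + DISPENSED_COLUMNS
    + ("ccr_reported",)
)


@dataclass(frozen=True)
class QuarterlySheet:
    period: Period
    rows: Mapping[Governorate, ServiceCounts]

    def __post_init__(self) -> None:
        registry = standard_governorate_registry()
        missing = [g.name for g in registry if g not in self.rows]
        if missing:
            raise ValidationError(f"sheet is missing governorates: {', '.join(missing)}")
        extra = [g.name for g in self.rows if g not in registry]
        if extra:
            raise ValidationError(f"sheet has unknown governorates: {', '.join(extra)}")


@dataclass(frozen=True)
class MWRAReference:
    """Annual denominators: married women of reproductive age and clinic
    counts per governorate. These are stocks, never summed over quarters."""

    year: int
    rows: Mapping[Governorate, tuple[int, int]]  # governorate -> (mwra, clinics)

    def __post_init__(self) -> None:
        registry = standard_governorate_registry()
        missing = [g.name for g in registry if g not in self.rows]
        if missing:
            raise ValidationError(f"reference is missing governorates: {', '.join(missing)}")
        for g, (mwra, clinics) in self.rows.items():
            if mwra < 0 or clinics < 0:
                raise ValidationError(f"{g.name}: negative MWRA or clinic count")

    @property
    def national_mwra(self) -> int:
        return sum(m for m, _ in self.rows.values())

    @property
    def national_clinics(self) -> int:
        return sum(c for _, c in self.rows.values())

    def region_totals(self) -> dict:
        out: dict = {}
        for g, (mwra, clinics) in self.rows.items():
            m, c = out.get(g.region, (0, 0))
            out[g.region] = (m + mwra, c + clinics)
        return out


def _parse_count(raw: str, governorate: str, column: str) -> int:
    try:
        value = int(raw)
    except (TypeError, ValueError):
        raise ValidationError(
            f"{governorate}, column {column!r}: not an integer: {raw!r}"
        ) from None
    if value < 0:
        raise ValidationError(f"{governorate}, column {column!r}: negative count {value}")
    return value


def _row_to_counts(row: Mapping[str, str], governorate: str) -> ServiceCounts:
    def block(cols: tuple[str, ...]) -> tuple[int, ...]:
        return tuple(_parse_count(row[c], governorate, c) for c in cols)

    dispensed: dict[MethodCategory, float] = {}
    for m, col in zip(METHODS, DISPENSED_COLUMNS):
        raw = (row.get(col) or "").strip()
        if raw:
            q = float(raw)
            if q < 0:
                raise ValidationError(f"{governorate}, column {col!r}: negative quantity {q}")
            if q:
                dispensed[m] = q
    raw_ccr = (row.get("ccr_reported") or "").strip()
    reported_ccr = float(raw_ccr) if raw_ccr else None
    try:
        return ServiceCounts(
            block(AGE_BANDS),
            block(PARITY_BANDS),
            block(USER_COLUMNS),
            block(VISIT_TYPES),
            block(CLIENT_TYPES),
            block(VISIT_REASONS),
            dispensed,
            reported_ccr,
        )
    except ValidationError as exc:
        raise ValidationError(f"{governorate}: {exc}") from None


def read_quarterly_sheet(path, period: Period, zero_fill: bool = False) -> QuarterlySheet:
    """Read and validate one governorate-per-row sheet.

    With ``zero_fill`` missing governorates are substituted with all-zero
    counts (logged); by default they are hard errors.
    """
    registry = standard_governorate_registry()
    by_name = {g.name: g for g in registry}
    rows: dict[Governorate, ServiceCounts] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file")
        missing_cols = [c for c in SHEET_COLUMNS[:-1] if c not in reader.fieldnames]
        if missing_cols:
            raise ValidationError(f"{path}: missing columns: {', '.join(missing_cols)}")
        for record in reader:
            if record.get("row_type", "governorate") not in ("", "governorate"):
                continue  # derived region/national rows of an annual sheet
            gov = by_name[canonical_governorate_name(record["governorate"])]
            if gov in rows:
                raise ValidationError(f"duplicated governorate: {gov.name}")
            rows[gov] = _row_to_counts(record, gov.name)
    missing = [g for g in registry if g not in rows]
    if missing and zero_fill:
        log.warning(
            "zero-filling %d missing governorate(s): %s",
            len(missing),
            ", ".join(g.name for g in missing),
        )
        for g in missing:
            rows[g] = ServiceCounts.zero()
    return QuarterlySheet(period=period, rows=rows)


def read_mwra_reference(path, year: int = 2014) -> MWRAReference:
    """Read the governorate -> (MWRA, clinics) reference CSV."""
    registry = standard_governorate_registry()
    by_name = {g.name: g for g in registry}
    rows: dict[Governorate, tuple[int, int]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file")
        for col in ("governorate", "mwra", "clinics"):
            if col not in reader.fieldnames:
                raise ValidationError(f"{path}: missing column {col!r}")
        for record in reader:
            gov = by_name[canonical_governorate_name(record["governorate"])]
            if gov in rows:
                raise ValidationError(f"duplicated governorate: {gov.name}")
            rows[gov] = (
                _parse_count(record["mwra"], gov.name, "mwra"),
                _parse_count(record["clinics"], gov.name, "clinics"),
            )
    return MWRAReference(year=year, rows=rows)


def _counts_to_row(gov_label: str, counts: ServiceCounts) -> list[str]:
    values: list[str] = [gov_label]
    for block in (
        counts.age_counts,
        counts.parity_counts,
        counts.method_user_counts,
        counts.visit_type_counts,
        counts.client_type_counts,
        counts.reason_counts,
    ):
        values.extend(str(v) for v in block)
    for m in METHODS:
        q = counts.dispensed_quantities.get(m, 0.0)
        values.append(repr(q) if q else "0")
    values.append("" if counts.reported_ccr is None else repr(counts.reported_ccr))
    return values


def write_sheet(sheet: QuarterlySheet, path) -> None:
    """Write a sheet in registry order; read-back reproduces it exactly."""
    registry = standard_governorate_registry()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SHEET_COLUMNS)
        for g in registry:
            writer.writerow(_counts_to_row(g.name, sheet.rows[g]))


def write_annual_sheet(annual, path) -> None:
    """Write an annual sheet with derived region and national rows.

    Rows carry a ``row_type`` column (governorate | region | national);
    governorate rows alone round-trip the underlying counts.
    """
    registry = standard_governorate_registry()
    header = ("row_type",) + SHEET_COLUMNS
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for region in dict.fromkeys(g.region for g in registry):
            for g in (g for g in registry if g.region == region):
                writer.writerow(["governorate"] + _counts_to_row(g.name, annual.rows[g]))
            writer.writerow(
                ["region"] + _counts_to_row(region.display_name, annual.region_rows[region])
            )
        writer.writerow(["national"] + _counts_to_row("Total Egypt", annual.national_row))


def write_mwra_reference(ref: MWRAReference, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["governorate", "mwra", "clinics"])
        for g in standard_governorate_registry():
            mwra, clinics = ref.rows[g]
            writer.writerow([g.name, mwra, clinics])
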