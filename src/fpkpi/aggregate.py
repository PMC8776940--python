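"""Merging quarterly sheets into annual sheets and regional/national rollups.

All rollups are exact elementwise integer sums of governorate counts —
never averages of percentages — so for every count variable the national
total equals the sum over regions equals the sum over governorates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .ingest import QuarterlySheet
from .schema import (
    Governorate,
    Region,
    ServiceCounts,
    ValidationError,
    standard_governorate_registry,
)

__all__ = ["AnnualSheet", "merge_quarters", "rollup"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnualSheet:
    year: int
    rows: Mapping[Governorate, ServiceCounts]
    region_rows: Mapping[Region, ServiceCounts]
    national_row: ServiceCounts
    partial_year: bool = False  # fewer than 4 quarters merged
    quarters: tuple[int, ...] = (1, 2, 3, 4)


def rollup(
    rows: Mapping[Governorate, ServiceCounts],
    registry: Sequence[Governorate] | None = None,
) -> tuple[dict[Region, ServiceCounts], ServiceCounts]:
    """Exact integer region and national sums of governorate rows."""
    if registry is None:
        registry = standard_governorate_registry()
    region_rows: dict[Region, ServiceCounts] = {}
    for g in registry:
        counts = rows[g]
        region_rows[g.region] = region_rows.get(g.region, ServiceCounts.zero()) + counts
    national = ServiceCounts.sum(region_rows.values())
    return region_rows, national


def merge_quarters(sheets: Sequence[QuarterlySheet]) -> AnnualSheet:
    """Sum 1-4 quarterly sheets of one year into an annual sheet.

    Counts and dispensed quantities add elementwise per governorate;
    region and national rows are recomputed from the merged governorate
    rows. Merging fewer than four quarters flags the result partial-year.
    """
    if not 1 <= len(sheets) <= 4:
        raise ValidationError(f"expected 1-4 quarterly sheets, got {len(sheets)}")
    years = {s.period.year for s in sheets}
    if len(years) != 1:
        raise ValidationError(f"mixed years in quarterly sheets: {sorted(years)}")
    quarters = [s.period.quarter for s in sheets]
    if any(q is None for q in quarters):
        raise ValidationError("annual sheets cannot be merged as quarters")
    if len(set(quarters)) != len(quarters):
        raise ValidationError(f"duplicate quarters: {sorted(quarters)}")
    # canonical quarter order makes the merge independent of input order
    # (float dispensed quantities are summed sequentially)
    sheets = sorted(sheets, key=lambda s: s.period.quarter)

    registry = standard_governorate_registry()
    rows = {g: ServiceCounts.sum(s.rows[g] for s in sheets) for g in registry}
    region_rows, national = rollup(rows, registry)
    year = sorted(years)[0]
    partial = len(sheets) < 4
    if partial:
        log.warning(
            "partial-year annual sheet: only quarter(s) %s of %d merged",
            sorted(quarters), year,
        )
    return AnnualSheet(
        year=year,
        rows=rows,
        region_rows=region_rows,
        national_row=national,
        partial_year=partial,
        quarters=tuple(sorted(quarters)),
    )
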