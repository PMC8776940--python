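"""Rank-ordering governorates on an indicator with traffic-light categories.

Governorates are sorted best-first (direction-aware) with competition
ranking — tied values share the best rank, ties broken for display by
fixed report position — and categorised into three groups by percentile
cut-points of the value distribution: best (green), prospective (yellow)
and unfavorable (red). The default scheme is tertiles with nearest-rank
percentiles; cut-points are computed on values, not ranks, so tied
governorates can never straddle a category boundary.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .kpi import Direction, KPIProfile
from .schema import Governorate, ValidationError

__all__ = [
    "Category",
    "CategoryScheme",
    "RankEntry",
    "RankTable",
    "rank_governorates",
    "rank_values",
    "categorize",
]

# Category ids double as chart colours.
class Category:
    BEST = "green"
    PROSPECTIVE = "yellow"
    UNFAVORABLE = "red"


@dataclass(frozen=True)
class CategoryScheme:
    """Percentile cut-points for the three-colour categorisation."""

    lower_centile: float = 100 / 3
    upper_centile: float = 200 / 3

    def __post_init__(self) -> None:
        if not (0 < self.lower_centile < 100 and 0 < self.upper_centile < 100):
            raise ValidationError("centiles must lie strictly between 0 and 100")
        if not self.lower_centile < self.upper_centile:
            raise ValidationError(
                f"lower centile ({self.lower_centile}) must be below "
                f"upper centile ({self.upper_centile})"
            )


@dataclass(frozen=True)
class RankEntry:
    governorate: Governorate
    value: float
    rank: int
    category: str | None = None


@dataclass(frozen=True)
class RankTable:
    indicator_id: str
    direction: Direction
    entries: tuple[RankEntry, ...]  # best-first

    def entry_for(self, governorate: Governorate) -> RankEntry:
        for e in self.entries:
            if e.governorate == governorate:
                return e
        raise KeyError(governorate.name)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["governorate", "value", "rank", "category"])
            for e in self.entries:
                writer.writerow([e.governorate.name, repr(e.value), e.rank, e.category or ""])


def _sort_key(direction: Direction):
    sign = -1.0 if direction is not Direction.LOWER_BETTER else 1.0

    def key(item: tuple[Governorate, float]):
        g, v = item
        return (sign * v, g.fixed_position)

    return key


def rank_values(
    values: Mapping[Governorate, float],
    indicator_id: str,
    direction: Direction = Direction.HIGHER_BETTER,
) -> RankTable:
    """Rank raw per-governorate values best-first with competition ties."""
    for g, v in values.items():
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValidationError(
                f"indicator {indicator_id!r} undefined for {g.name}; cannot rank"
            )
    ordered = sorted(values.items(), key=_sort_key(direction))
    entries: list[RankEntry] = []
    for i, (g, v) in enumerate(ordered):
        if i and v == entries[-1].value:
            rank = entries[-1].rank  # competition ranking: ties share best rank
        else:
            rank = i + 1
        entries.append(RankEntry(governorate=g, value=float(v), rank=rank))
    return RankTable(indicator_id=indicator_id, direction=direction, entries=tuple(entries))


def rank_governorates(
    profiles: Mapping[Governorate, KPIProfile],
    indicator_id: str,
    direction: Direction,
) -> RankTable:
    """Rank the 27 governorates on one indicator of their profiles."""
    values = {g: p.value(indicator_id) for g, p in profiles.items()}
    return rank_values(values, indicator_id, direction)


def _nearest_rank_percentile(sorted_values: Sequence[float], p: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th smallest value."""
    n = len(sorted_values)
    k = max(1, math.ceil(p / 100.0 * n))
    return sorted_values[min(k, n) - 1]


def categorize(table: RankTable, scheme: CategoryScheme | None = None) -> RankTable:
    """Assign green/yellow/red categories by percentile cut-points.

    Direction-adjusted: for higher-is-better indicators values at or above
    the upper cut are best and values at or below the lower cut are
    unfavorable; for lower-is-better the comparisons flip (the data do
    not). Degenerate all-equal distributions are all best by convention.
    """
    if scheme is None:
        scheme = CategoryScheme()
    values = sorted(e.value for e in table.entries)
    lower_cut = _nearest_rank_percentile(values, scheme.lower_centile)
    upper_cut = _nearest_rank_percentile(values, scheme.upper_centile)

    def category(v: float) -> str:
        if table.direction is Direction.LOWER_BETTER:
            if v <= lower_cut:
                return Category.BEST
            if v >= upper_cut:
                return Category.UNFAVORABLE
        else:
            if v >= upper_cut:
                return Category.BEST
            if v <= lower_cut:
                return Category.UNFAVORABLE
        return Category.PROSPECTIVE

    entries = tuple(replace(e, category=category(e.value)) for e in table.entries)
    return RankTable(indicator_id=table.indicator_id, direction=table.direction, entries=entries)
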