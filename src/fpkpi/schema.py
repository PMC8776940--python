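"""Fixed registries and domain types for Egypt's family-planning MIS.

The reporting unit is the governorate-period aggregate: 27 governorates
grouped into four regions (urban, lower Egypt, upper Egypt, frontier),
each governorate holding a fixed position in every report so that league
tables are comparable across quarters and years.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "Region",
    "REGIONS",
    "Governorate",
    "MethodCategory",
    "METHODS",
    "METHOD_MIX_ORDER",
    "Period",
    "ServiceCounts",
    "ValidationError",
    "standard_governorate_registry",
    "canonical_governorate_name",
    "total_clients",
    "export_registry_csv",
    "AGE_BANDS",
    "PARITY_BANDS",
    "VISIT_TYPES",
    "CLIENT_TYPES",
    "VISIT_REASONS",
]


class ValidationError(ValueError):
    """A sheet or count bundle violates a structural invariant."""


class Region(str, Enum):
    URBAN = "urban"
    LOWER_EGYPT = "lower_egypt"
    UPPER_EGYPT = "upper_egypt"
    FRONTIER = "frontier"

    @property
    def display_name(self) -> str:
        return _REGION_DISPLAY[self]


_REGION_DISPLAY = {
    Region.URBAN: "Urban Governorates",
    Region.LOWER_EGYPT: "Lower Egypt Governorates",
    Region.UPPER_EGYPT: "Upper Egypt Governorates",
    Region.FRONTIER: "Frontier Governorates",
}

REGIONS: tuple[Region, ...] = tuple(Region)


class MethodCategory(str, Enum):
    """Contraceptive method groups tracked by the MIS.

    Six groups carry current-user counts; sterilization is dispensable
    (it enters couple-years-of-protection arithmetic) but has no
    current-user column in the service-statistics sheet.
    """

    OC = "oc"
    IUD = "iud"
    CONDOM = "condom"
    INJECTABLE_3M = "injectable_3m"
    INJECTABLE_1M = "injectable_1m"
    IMPLANT = "implant"
    STERILIZATION = "sterilization"

    @property
    def in_method_mix(self) -> bool:
        return self is not MethodCategory.STERILIZATION


METHODS: tuple[MethodCategory, ...] = tuple(MethodCategory)

# Column order of the published method-mix table (current users only).
METHOD_MIX_ORDER: tuple[MethodCategory, ...] = (
    MethodCategory.OC,
    MethodCategory.IUD,
    MethodCategory.CONDOM,
    MethodCategory.INJECTABLE_3M,
    MethodCategory.IMPLANT,
    MethodCategory.INJECTABLE_1M,
)

AGE_BANDS = ("age_lt20", "age_20_24", "age_25_29", "age_30_34", "age_35_plus")
PARITY_BANDS = ("parity_0", "parity_1", "parity_2", "parity_3", "parity_4_plus")
VISIT_TYPES = ("visit_first", "visit_return")
CLIENT_TYPES = ("client_new", "client_continuing")
VISIT_REASONS = (
    "reason_get_method",
    "reason_counseling",
    "reason_rh_services",
    "reason_side_effects",
)


@dataclass(frozen=True, order=True)
class Period:
    """A reporting period: one of the four quarters, or the whole year."""

    year: int
    quarter: int | None = None  # None marks an annual period

    def __post_init__(self) -> None:
        if self.quarter is not None and self.quarter not in (1, 2, 3, 4):
            raise ValidationError(f"quarter must be 1-4 or None, got {self.quarter!r}")

    @property
    def is_annual(self) -> bool:
        return self.quarter is None

    def __str__(self) -> str:
        return f"{self.year}" if self.is_annual else f"{self.year}Q{self.quarter}"


@dataclass(frozen=True)
class Governorate:
    name: str
    region: Region
    fixed_position: int  # 1..27, constant across all reports

    def __str__(self) -> str:
        return self.name


# Fixed report order: urban, lower Egypt, upper Egypt, frontier; within a
# region, the order of the published 2014 annual tables.
_REGISTRY_SPEC: tuple[tuple[str, Region], ...] = (
    ("Cairo", Region.URBAN),
    ("Alexandria", Region.URBAN),
    ("Port-Said", Region.URBAN),
    ("Suez", Region.URBAN),
    ("Damietta", Region.LOWER_EGYPT),
    ("Kafr-Elsheikh", Region.LOWER_EGYPT),
    ("Gharbia", Region.LOWER_EGYPT),
    ("Dakahlia", Region.LOWER_EGYPT),
    ("Qalubia", Region.LOWER_EGYPT),
    ("Menofia", Region.LOWER_EGYPT),
    ("Behera", Region.LOWER_EGYPT),
    ("Ismailia", Region.LOWER_EGYPT),
    ("Sharkia", Region.LOWER_EGYPT),
    ("Aswan", Region.UPPER_EGYPT),
    ("Giza", Region.UPPER_EGYPT),
    ("Luxor", Region.UPPER_EGYPT),
    ("Quena", Region.UPPER_EGYPT),
    ("Fayoum", Region.UPPER_EGYPT),
    ("Beni-Suef", Region.UPPER_EGYPT),
    ("Souhag", Region.UPPER_EGYPT),
    ("Minia", Region.UPPER_EGYPT),
    ("Asuit", Region.UPPER_EGYPT),
    ("Red Sea", Region.FRONTIER),
    ("New Valley", Region.FRONTIER),
    ("Matrouh", Region.FRONTIER),
    ("N. Sinai", Region.FRONTIER),
    ("S. Sinai", Region.FRONTIER),
)

_REGISTRY: tuple[Governorate, ...] = tuple(
    Governorate(name=n, region=r, fixed_position=i + 1)
    for i, (n, r) in enumerate(_REGISTRY_SPEC)
)

# Spelling variants seen in circulating MIS tables. Canonicalisation is
# table-driven: unknown names are hard errors, never fuzzy-matched.
_ALIASES: dict[str, str] = {
    "menofeya": "Menofia",
    "menoufia": "Menofia",
    "kafr-elshieikh": "Kafr-Elsheikh",
    "kafr elsheikh": "Kafr-Elsheikh",
    "kafr el-sheikh": "Kafr-Elsheikh",
    "mynia": "Minia",
    "menia": "Minia",
    "quena": "Quena",
    "qena": "Quena",
    "assiut": "Asuit",
    "asyut": "Asuit",
    "sohag": "Souhag",
    "n saini": "N. Sinai",
    "n sinai": "N. Sinai",
    "north sinai": "N. Sinai",
    "s saini": "S. Sinai",
    "s sinai": "S. Sinai",
    "south sinai": "S. Sinai",
    "port said": "Port-Said",
    "beni suef": "Beni-Suef",
}


def _normalise(name: str) -> str:
    return re.sub(r"[\s._-]+", " ", name.strip().lower()).strip()


_CANONICAL_LOOKUP: dict[str, str] = {_normalise(g.name): g.name for g in _REGISTRY}
_CANONICAL_LOOKUP.update({_normalise(k): v for k, v in _ALIASES.items()})


def canonical_governorate_name(name: str) -> str:
    """Map a (possibly variant) governorate spelling to its canonical name.

    Raises :class:`ValidationError` for names not in the alias table.
    """
    key = _normalise(name)
    try:
        return _CANONICAL_LOOKUP[key]
    except KeyError:
        raise ValidationError(f"unknown governorate name: {name!r}") from None


def standard_governorate_registry() -> list[Governorate]:
    """The 27 governorates in fixed report order (positions 1..27)."""
    return list(_REGISTRY)


def governorate_by_name(name: str) -> Governorate:
    canonical = canonical_governorate_name(name)
    return _BY_NAME[canonical]


_BY_NAME: dict[str, Governorate] = {g.name: g for g in _REGISTRY}


def export_registry_csv(path) -> None:
    """Write the registry as CSV with columns name, region, fixed_position."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "region", "fixed_position"])
        for g in _REGISTRY:
            writer.writerow([g.name, g.region.value, g.fixed_position])


@dataclass(frozen=True)
class ServiceCounts:
    """One governorate-period bundle of the recorded count variables.

    ``age_counts``, ``parity_counts``, ``visit_type_counts``,
    ``client_type_counts`` and ``reason_counts`` each partition the same
    client total; ``method_user_counts`` (current users of the six
    recorded methods, in :data:`METHOD_MIX_ORDER`) may sum to less than
    the total, since non-users also attend for counseling or other
    reproductive-health services. ``dispensed_quantities`` are method
    units handed out (fractional allowed: bulk stock conversions), and
    ``reported_ccr`` carries a coverage figure precomputed upstream when
    the sheet has no dispensing data.
    """

    age_counts: tuple[int, int, int, int, int]
    parity_counts: tuple[int, int, int, int, int]
    method_user_counts: tuple[int, int, int, int, int, int]
    visit_type_counts: tuple[int, int]
    client_type_counts: tuple[int, int]
    reason_counts: tuple[int, int, int, int]
    dispensed_quantities: Mapping[MethodCategory, float] = field(default_factory=dict)
    reported_ccr: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "age_counts", tuple(self.age_counts))
        object.__setattr__(self, "parity_counts", tuple(self.parity_counts))
        object.__setattr__(self, "method_user_counts", tuple(self.method_user_counts))
        object.__setattr__(self, "visit_type_counts", tuple(self.visit_type_counts))
        object.__setattr__(self, "client_type_counts", tuple(self.client_type_counts))
        object.__setattr__(self, "reason_counts", tuple(self.reason_counts))
        # Zero entries are dropped so equality is independent of whether a
        # method was recorded explicitly as 0 or simply absent.
        object.__setattr__(
            self,
            "dispensed_quantities",
            {MethodCategory(k): float(v) for k, v in self.dispensed_quantities.items() if v},
        )
        self.validate()

    def validate(self) -> None:
        lengths = {
            "age_counts": (self.age_counts, 5),
            "parity_counts": (self.parity_counts, 5),
            "method_user_counts": (self.method_user_counts, 6),
            "visit_type_counts": (self.visit_type_counts, 2),
            "client_type_counts": (self.client_type_counts, 2),
            "reason_counts": (self.reason_counts, 4),
        }
        for name, (values, n) in lengths.items():
            if len(values) != n:
                raise ValidationError(f"{name} must have {n} entries, got {len(values)}")
            for i, v in enumerate(values):
                if int(v) != v:
                    raise ValidationError(f"{name}[{i}] must be an integer, got {v!r}")
                if v < 0:
                    raise ValidationError(f"{name}[{i}] is negative: {v}")
        total = sum(self.age_counts)
        for name in ("parity_counts", "visit_type_counts", "client_type_counts", "reason_counts"):
            s = sum(getattr(self, name))
            if s != total:
                raise ValidationError(
                    f"partition-sum mismatch: sum({name})={s} but sum(age_counts)={total}"
                )
        if sum(self.method_user_counts) > total:
            raise ValidationError(
                f"method users ({sum(self.method_user_counts)}) exceed total clients ({total})"
            )
        for m, q in self.dispensed_quantities.items():
            if not math.isfinite(q) or q < 0:
                raise ValidationError(f"dispensed quantity for {m.value} is invalid: {q}")
        if self.reported_ccr is not None and self.reported_ccr < 0:
            raise ValidationError(f"reported CCR is negative: {self.reported_ccr}")

    @property
    def total_clients(self) -> int:
        return sum(self.age_counts)

    @property
    def method_users_total(self) -> int:
        return sum(self.method_user_counts)

    @classmethod
    def zero(cls) -> "ServiceCounts":
        return cls((0,) * 5, (0,) * 5, (0,) * 6, (0, 0), (0, 0), (0,) * 4)

    def __add__(self, other: "ServiceCounts") -> "ServiceCounts":
        if not isinstance(other, ServiceCounts):
            return NotImplemented
        dispensed: dict[MethodCategory, float] = dict(self.dispensed_quantities)
        for m, q in other.dispensed_quantities.items():
            dispensed[m] = dispensed.get(m, 0.0) + q
        # Reported coverage is not additive without a denominator; drop it.
        return ServiceCounts(
            tuple(a + b for a, b in zip(self.age_counts, other.age_counts)),
            tuple(a + b for a, b in zip(self.parity_counts, other.parity_counts)),
            tuple(a + b for a, b in zip(self.method_user_counts, other.method_user_counts)),
            tuple(a + b for a, b in zip(self.visit_type_counts, other.visit_type_counts)),
            tuple(a + b for a, b in zip(self.client_type_counts, other.client_type_counts)),
            tuple(a + b for a, b in zip(self.reason_counts, other.reason_counts)),
            dispensed,
        )

    @staticmethod
    def sum(items: Iterable["ServiceCounts"]) -> "ServiceCounts":
        out = ServiceCounts.zero()
        for item in items:
            out = out + item
        return out


def total_clients(counts: ServiceCounts) -> int:
    """Total clients recorded in the bundle (the shared partition sum)."""
    counts.validate()
    return counts.total_clients
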