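"""The fifteen report indicators plus three contextual input indicators.

Every share is a ratio of summed counts (numerator / named denominator
x 100) — percentages are never averaged across units, so a region's
profile computed from summed counts equals the profile of its summed
numerators and denominators by construction.

Report indicators: percent of clients aged 35+, percent with fewer than
three children, the six-method mix of current users, percent first-visit
clients, percent new clients, the four reason-for-visit shares, and the
contraceptive coverage rate. Context indicators: the unit's share of
national MWRA, its share of national clinics, and clinics per 10,000 MWRA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Mapping

from . import cyp as _cyp
from .schema import METHOD_MIX_ORDER, ServiceCounts, ValidationError

__all__ = [
    "Direction",
    "IndicatorDefinition",
    "KPIProfile",
    "indicator_catalog",
    "compute_profile",
    "round_display",
]

log = logging.getLogger(__name__)


class Direction(str, Enum):
    HIGHER_BETTER = "higher_better"
    LOWER_BETTER = "lower_better"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class IndicatorDefinition:
    id: str
    label: str
    direction: Direction
    denominator: str  # total_clients | method_users | mwra | national_mwra | national_clinics


_CATALOG: tuple[IndicatorDefinition, ...] = (
    # Page 1: client profile and method mix (8 indicators)
    IndicatorDefinition("age_35_plus", "% clients aged 35+", Direction.NEUTRAL, "total_clients"),
    IndicatorDefinition(
        "under_3_children", "% clients with <3 children", Direction.NEUTRAL, "total_clients"
    ),
    IndicatorDefinition("mix_oc", "% OC users", Direction.NEUTRAL, "method_users"),
    IndicatorDefinition("mix_iud", "% IUD users", Direction.NEUTRAL, "method_users"),
    IndicatorDefinition("mix_condom", "% condom users", Direction.NEUTRAL, "method_users"),
    IndicatorDefinition(
        "mix_injectable_3m", "% 3-month injectable users", Direction.NEUTRAL, "method_users"
    ),
    IndicatorDefinition("mix_implant", "% implant users", Direction.NEUTRAL, "method_users"),
    IndicatorDefinition(
        "mix_injectable_1m", "% monthly injectable users", Direction.NEUTRAL, "method_users"
    ),
    # Page 2: demand-side performance and coverage (7 indicators)
    IndicatorDefinition(
        "first_visit", "% first-visit clients", Direction.HIGHER_BETTER, "total_clients"
    ),
    IndicatorDefinition(
        "new_clients", "% new clients", Direction.HIGHER_BETTER, "total_clients"
    ),
    IndicatorDefinition(
        "get_method", "% visits to get FP method", Direction.HIGHER_BETTER, "total_clients"
    ),
    IndicatorDefinition("counseling", "% counseling visits", Direction.NEUTRAL, "total_clients"),
    IndicatorDefinition("rh_services", "% RH-service visits", Direction.NEUTRAL, "total_clients"),
    IndicatorDefinition(
        "side_effects", "% side-effect management visits", Direction.NEUTRAL, "total_clients"
    ),
    IndicatorDefinition(
        "ccr", "contraceptive coverage rate (%)", Direction.HIGHER_BETTER, "mwra"
    ),
    # Context: programme inputs (3 indicators)
    IndicatorDefinition("mwra_share", "% of national MWRA", Direction.NEUTRAL, "national_mwra"),
    IndicatorDefinition(
        "clinic_share", "% of national FP clinics", Direction.NEUTRAL, "national_clinics"
    ),
    IndicatorDefinition(
        "clinics_per_10k_mwra", "FP clinics per 10,000 MWRA", Direction.NEUTRAL, "mwra"
    ),
)


def indicator_catalog() -> list[IndicatorDefinition]:
    """All 18 indicators in report order (page 1, page 2, context)."""
    return list(_CATALOG)


_MIX_IDS = tuple(f"mix_{m.value}" for m in METHOD_MIX_ORDER)
_REASON_IDS = ("get_method", "counseling", "rh_services", "side_effects")


@dataclass(frozen=True)
class KPIProfile:
    """Indicator values for one unit (governorate, region or nation).

    Undefined shares (zero denominator) are NaN — distinct from a true 0.
    ``ccr_as_reported`` flags a coverage rate taken from the sheet rather
    than recomputed from dispensed quantities.
    """

    pct_age_35_plus: float
    pct_under_3_children: float
    method_mix: tuple[float, float, float, float, float, float]  # METHOD_MIX_ORDER
    pct_first_visit: float
    pct_new_clients: float
    reason_shares: tuple[float, float, float, float]  # get, counseling, RH, side-effects
    ccr: float
    mwra_share: float
    clinic_share: float
    clinics_per_10k_mwra: float
    ccr_as_reported: bool = False

    def value(self, indicator_id: str) -> float:
        if indicator_id in _MIX_IDS:
            return self.method_mix[_MIX_IDS.index(indicator_id)]
        if indicator_id in _REASON_IDS:
            return self.reason_shares[_REASON_IDS.index(indicator_id)]
        simple = {
            "age_35_plus": self.pct_age_35_plus,
            "under_3_children": self.pct_under_3_children,
            "first_visit": self.pct_first_visit,
            "new_clients": self.pct_new_clients,
            "ccr": self.ccr,
            "mwra_share": self.mwra_share,
            "clinic_share": self.clinic_share,
            "clinics_per_10k_mwra": self.clinics_per_10k_mwra,
        }
        try:
            return simple[indicator_id]
        except KeyError:
            raise KeyError(f"unknown indicator id: {indicator_id!r}") from None

    def as_dict(self) -> dict[str, float]:
        return {d.id: self.value(d.id) for d in _CATALOG}


def round_display(value: float) -> float:
    """Display rounding used in the printed tables: half-up to integers for
    percents >= 10, one decimal place below 10. NaN passes through."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    d = Decimal(repr(float(value)))
    if abs(value) >= 10:
        return float(d.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return float(d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _share(numerator: float, denominator: float) -> float:
    if denominator == 0:
        return math.nan
    return 100.0 * numerator / denominator


def _resolve_ccr(
    counts: ServiceCounts, mwra: int, rules
) -> tuple[float, bool]:
    has_dispensed = bool(counts.dispensed_quantities)
    computed = (
        _cyp.ccr(_cyp.total_cyp(counts.dispensed_quantities, rules).total, mwra)
        if has_dispensed
        else None
    )
    if counts.reported_ccr is not None:
        if computed is not None:
            if abs(computed - counts.reported_ccr) > 0.5:
                log.warning(
                    "CCR mismatch: recomputed %.2f vs reported %.2f (>0.5 pp); "
                    "using recomputed value",
                    computed,
                    counts.reported_ccr,
                )
            return computed, False
        return counts.reported_ccr, True
    if computed is not None:
        return computed, False
    return math.nan, False


def compute_profile(
    counts: ServiceCounts,
    ref_row: tuple[int, int],
    national_ref: tuple[int, int],
    rules: Mapping | None = None,
    *,
    mix_over_all_clients: bool = False,
) -> KPIProfile:
    """Compute the full indicator profile for one unit.

    ``ref_row`` and ``national_ref`` are (MWRA, clinics) pairs for the
    unit and the nation. ``mix_over_all_clients`` switches the method-mix
    denominator from current users (the published table convention) to all
    clients (the published summary-figure convention).
    """
    mwra, clinics = ref_row
    national_mwra, national_clinics = national_ref
    if mwra <= 0:
        raise ValidationError(f"MWRA must be positive, got {mwra}")
    if rules is None:
        rules = _cyp.egypt_2014_rules()

    total = counts.total_clients
    users = counts.method_users_total
    mix_denom = total if mix_over_all_clients else users

    ccr_value, as_reported = _resolve_ccr(counts, mwra, rules)
    return KPIProfile(
        pct_age_35_plus=_share(counts.age_counts[4], total),
        pct_under_3_children=_share(sum(counts.parity_counts[:3]), total),
        method_mix=tuple(_share(u, mix_denom) for u in counts.method_user_counts),
        pct_first_visit=_share(counts.visit_type_counts[0], total),
        pct_new_clients=_share(counts.client_type_counts[0], total),
        reason_shares=tuple(_share(r, total) for r in counts.reason_counts),
        ccr=ccr_value,
        mwra_share=_share(mwra, national_mwra),
        clinic_share=_share(clinics, national_clinics),
        clinics_per_10k_mwra=10_000.0 * clinics / mwra,
        ccr_as_reported=as_reported,
    )
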