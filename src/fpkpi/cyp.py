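"""Couple-years of protection (CYP) and the contraceptive coverage rate.

CYP converts dispensed contraceptive quantities into the number of couples
protected from pregnancy for one year: resupply methods divide units by an
annual consumption factor (13 pill cycles, 100 condoms, 4 three-month
injectable vials per couple-year), while long-acting methods multiply units
by their average years of protection (IUD 3.2, implant 2, sterilization 10).

CCR = 100 x CYP dispensed in a period / MWRA in the catchment area — a
service-statistics proxy for contraceptive prevalence. It can exceed 100
where long-acting methods dominate.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

from .schema import MethodCategory, ValidationError

__all__ = [
    "ConversionMode",
    "ConversionRule",
    "CYPResult",
    "egypt_2014_rules",
    "load_rules_csv",
    "cyp_for_method",
    "total_cyp",
    "ccr",
]

log = logging.getLogger(__name__)


class ConversionMode(str, Enum):
    DIVIDE = "divide"  # factor = units per couple-year
    MULTIPLY = "multiply"  # factor = couple-years per unit


@dataclass(frozen=True)
class ConversionRule:
    method: MethodCategory
    mode: ConversionMode
    factor: float

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValidationError(f"conversion factor must be positive, got {self.factor}")

    def apply(self, quantity: float) -> float:
        if quantity < 0:
            raise ValidationError(f"dispensed quantity is negative: {quantity}")
        if self.mode is ConversionMode.DIVIDE:
            return quantity / self.factor
        return quantity * self.factor


RuleSet = Mapping[MethodCategory, ConversionRule]


def _as_ruleset(rules: Iterable[ConversionRule] | RuleSet) -> dict[MethodCategory, ConversionRule]:
    if isinstance(rules, Mapping):
        items = rules.values()
    else:
        items = rules
    out: dict[MethodCategory, ConversionRule] = {}
    for rule in items:
        if rule.method in out:
            raise ValidationError(f"duplicate conversion rule for {rule.method.value}")
        out[rule.method] = rule
    return out


def egypt_2014_rules() -> dict[MethodCategory, ConversionRule]:
    """Egypt's packaged conversion factors, one rule per method."""
    rules = (
        ConversionRule(MethodCategory.OC, ConversionMode.DIVIDE, 13.0),
        ConversionRule(MethodCategory.CONDOM, ConversionMode.DIVIDE, 100.0),
        ConversionRule(MethodCategory.IUD, ConversionMode.MULTIPLY, 3.2),
        ConversionRule(MethodCategory.INJECTABLE_3M, ConversionMode.DIVIDE, 4.0),
        ConversionRule(MethodCategory.INJECTABLE_1M, ConversionMode.DIVIDE, 13.0),
        ConversionRule(MethodCategory.IMPLANT, ConversionMode.MULTIPLY, 2.0),
        ConversionRule(MethodCategory.STERILIZATION, ConversionMode.MULTIPLY, 10.0),
    )
    return {r.method: r for r in rules}


def load_rules_csv(path) -> dict[MethodCategory, ConversionRule]:
    """Load conversion rules from a CSV with columns method, mode, factor.

    Lets another country's factors be swapped in without code changes.
    """
    out: dict[MethodCategory, ConversionRule] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            rule = ConversionRule(
                MethodCategory(row["method"].strip()),
                ConversionMode(row["mode"].strip()),
                float(row["factor"]),
            )
            if rule.method in out:
                raise ValidationError(f"duplicate rule for {rule.method.value} in {path}")
            out[rule.method] = rule
    if not out:
        raise ValidationError(f"no conversion rules found in {path}")
    return out


@dataclass(frozen=True)
class CYPResult:
    per_method: Mapping[MethodCategory, float]
    total: float


def cyp_for_method(
    method: MethodCategory,
    quantity: float,
    rules: Iterable[ConversionRule] | RuleSet,
) -> float:
    """Couple-years of protection for one method's dispensed quantity."""
    ruleset = _as_ruleset(rules)
    if method not in ruleset:
        raise ValidationError(f"no conversion rule for method {method!r}")
    return ruleset[method].apply(quantity)


def total_cyp(
    dispensed: Mapping[MethodCategory, float],
    rules: Iterable[ConversionRule] | RuleSet,
) -> CYPResult:
    """Per-method CYP and their sum for a dispensing record."""
    ruleset = _as_ruleset(rules)
    per_method = {
        MethodCategory(m): cyp_for_method(MethodCategory(m), q, ruleset)
        for m, q in dispensed.items()
    }
    return CYPResult(per_method=per_method, total=sum(per_method.values()))


def ccr(cyp_total: float, mwra: int) -> float:
    """Contraceptive coverage rate: percent of MWRA protected for one year."""
    if mwra <= 0:
        raise ValidationError(f"CCR undefined: MWRA must be positive, got {mwra}")
    if cyp_total < 0:
        raise ValidationError(f"CYP total is negative: {cyp_total}")
    return 100.0 * cyp_total / mwra
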