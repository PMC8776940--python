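"""Synthetic quarterly sheets and the packaged 2014 national fixture.

The generator emulates the statistical structure of governorate-quarter
service statistics: a Poisson client volume per governorate, multinomial
splits of that volume over the recorded partitions (age, parity, visit
type, client type, reason), a binomial current-user subset allocated over
the six-method mix, and Poisson dispensed quantities proportional to
users. The packaged fixture transcribes the published 2014 annual tables
(shares where only shares were printed, counts where counts were
printed), so every pipeline stage is testable without any download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .ingest import MWRAReference, QuarterlySheet
from .schema import (
    METHOD_MIX_ORDER,
    Governorate,
    MethodCategory,
    Period,
    ServiceCounts,
    ValidationError,
    standard_governorate_registry,
)

__all__ = [
    "GovernorateVolume",
    "GeneratorConfig",
    "generate_quarter",
    "default_egypt_config",
    "PaperFixture2014",
    "paper_fixture_2014",
    "NATIONAL_MWRA_2014",
    "NATIONAL_CLINICS_2014",
    "NATIONAL_CLIENTS_2014",
    "NATIONAL_METHOD_USERS_2014",
]

# National 2014 totals as printed in the annual tables.
NATIONAL_MWRA_2014 = 15_799_805
NATIONAL_CLINICS_2014 = 6_038
NATIONAL_CLIENTS_2014 = 13_846_714  # all clinic clients
NATIONAL_METHOD_USERS_2014 = 13_670_104  # clients currently using a method


def _check_simplex(name: str, p: tuple[float, ...], k: int) -> None:
    if len(p) != k:
        raise ValidationError(f"{name} must have {k} entries, got {len(p)}")
    if any(x < 0 for x in p):
        raise ValidationError(f"{name} has a negative entry")
    if abs(sum(p) - 1.0) > 1e-9:
        raise ValidationError(f"{name} must sum to 1 +- 1e-9, got {sum(p)!r}")


@dataclass(frozen=True)
class GovernorateVolume:
    mwra: int
    clinics: int
    expected_quarterly_clients: float


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling parameters for one synthetic reporting year.

    Proportions are national-level simplices applied to every
    governorate; volumes differ per governorate. ``dispensing_rates`` are
    expected units per current user of the method per quarter;
    sterilization (which has no current-user column) is driven by
    ``sterilization_rate_per_user`` applied to total method users.
    """

    seed: int
    volumes: Mapping[str, GovernorateVolume]  # canonical governorate name -> volume
    age: tuple[float, float, float, float, float]
    parity: tuple[float, float, float, float, float]
    method_mix: tuple[float, float, float, float, float, float]  # METHOD_MIX_ORDER
    reason: tuple[float, float, float, float]
    p_first_visit: float
    p_new_client: float
    p_method_user: float
    dispensing_rates: Mapping[MethodCategory, float] = field(default_factory=dict)
    sterilization_rate_per_user: float = 0.0

    def __post_init__(self) -> None:
        _check_simplex("age", self.age, 5)
        _check_simplex("parity", self.parity, 5)
        _check_simplex("method_mix", self.method_mix, 6)
        _check_simplex("reason", self.reason, 4)
        for name in ("p_first_visit", "p_new_client", "p_method_user"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {p}")
        registry_names = {g.name for g in standard_governorate_registry()}
        if set(self.volumes) != registry_names:
            raise ValidationError("volumes must cover exactly the 27 governorates")
        for m, r in self.dispensing_rates.items():
            if r < 0 or not math.isfinite(r):
                raise ValidationError(f"dispensing rate for {m} is invalid: {r}")

    def reference(self, year: int = 2014) -> MWRAReference:
        by_name = {g.name: g for g in standard_governorate_registry()}
        return MWRAReference(
            year=year,
            rows={by_name[n]: (v.mwra, v.clinics) for n, v in self.volumes.items()},
        )


def generate_quarter(config: GeneratorConfig, period: Period) -> QuarterlySheet:
    """Draw one quarterly sheet. Identical seed+config+period give an
    identical sheet; governorates are drawn in fixed registry order."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, period.year, period.quarter or 0])
    )
    rows: dict[Governorate, ServiceCounts] = {}
    for g in standard_governorate_registry():
        vol = config.volumes[g.name]
        n = int(rng.poisson(vol.expected_quarterly_clients))
        age = tuple(int(x) for x in rng.multinomial(n, config.age))
        parity = tuple(int(x) for x in rng.multinomial(n, config.parity))
        first = int(rng.binomial(n, config.p_first_visit))
        new = int(rng.binomial(n, config.p_new_client))
        reason = tuple(int(x) for x in rng.multinomial(n, config.reason))
        users = int(rng.binomial(n, config.p_method_user))
        by_method = tuple(int(x) for x in rng.multinomial(users, config.method_mix))
        dispensed: dict[MethodCategory, float] = {}
        for m, u in zip(METHOD_MIX_ORDER, by_method):
            rate = config.dispensing_rates.get(m, 0.0)
            if rate:
                q = float(rng.poisson(u * rate))
                if q:
                    dispensed[m] = q
        if config.sterilization_rate_per_user:
            q = float(rng.poisson(users * config.sterilization_rate_per_user))
            if q:
                dispensed[MethodCategory.STERILIZATION] = q
        rows[g] = ServiceCounts(
            age, parity, by_method, (first, n - first), (new, n - new), reason, dispensed
        )
    return QuarterlySheet(period=period, rows=rows)


# --- the 2014 national profile -------------------------------------------

# Interior age/parity proportions are not published; only the margins
# (35+ = 27.4%, <20 = 3.2%, 3+ children = 41.6%) are. The defaults below
# match those margins and interpolate the interior bands plausibly.
_AGE_2014 = (0.032, 0.190, 0.280, 0.224, 0.274)
_PARITY_2014 = (0.040, 0.200, 0.344, 0.240, 0.176)

_USERS_BY_METHOD_2014 = {
    MethodCategory.OC: 7_376_884,
    MethodCategory.IUD: 903_636,
    MethodCategory.CONDOM: 255_016,
    MethodCategory.INJECTABLE_3M: 4_228_168,
    MethodCategory.IMPLANT: 27_388,
    MethodCategory.INJECTABLE_1M: 879_012,
}

# Expected dispensed units per current user per quarter. Free parameters
# (the source tables print coverage, not stock); chosen so the implied
# national CCR sits mid-band (~33%) in the plausible 25-60% range.
_DISPENSING_2014 = {
    MethodCategory.OC: 4.0,
    MethodCategory.CONDOM: 30.0,
    MethodCategory.IUD: 0.5,
    MethodCategory.INJECTABLE_3M: 1.0,
    MethodCategory.INJECTABLE_1M: 4.0,
    MethodCategory.IMPLANT: 0.5,
}
_STERILIZATION_RATE_2014 = 0.0002


def default_egypt_config(seed: int = 0, volume_scale: float = 1.0) -> GeneratorConfig:
    """Generator config calibrated to the 2014 national profile.

    Volumes come from the packaged reference (15,799,805 MWRA; 6038
    clinics) with expected quarterly clients proportional to each
    governorate's published user volume. ``volume_scale`` shrinks client
    volumes uniformly for pilot-scale runs; denominators are untouched.
    """
    fixture = paper_fixture_2014()
    total_users = sum(_USERS_BY_METHOD_2014.values())
    mix = tuple(_USERS_BY_METHOD_2014[m] / total_users for m in METHOD_MIX_ORDER)
    clients_per_user = NATIONAL_CLIENTS_2014 / NATIONAL_METHOD_USERS_2014

    volumes: dict[str, GovernorateVolume] = {}
    for g in standard_governorate_registry():
        mwra, clinics = fixture.reference.rows[g]
        users_g = int(fixture.method_users.loc[g.name, "users_total"])
        volumes[g.name] = GovernorateVolume(
            mwra=mwra,
            clinics=clinics,
            expected_quarterly_clients=users_g * clients_per_user / 4.0 * volume_scale,
        )

    # Published reason shares exceed 100 when summed; keep the headline
    # get-method share (83%) and renormalise the other three into the
    # remaining 17%.
    other = (14.4, 5.6, 19.9)
    rest = tuple(0.17 * x / sum(other) for x in other)
    reason = (0.83,) + rest
    reason = tuple(x / sum(reason) for x in reason)

    return GeneratorConfig(
        seed=seed,
        volumes=volumes,
        age=_AGE_2014,
        parity=_PARITY_2014,
        method_mix=mix,
        reason=reason,
        p_first_visit=0.21,
        p_new_client=0.11,
        p_method_user=NATIONAL_METHOD_USERS_2014 / NATIONAL_CLIENTS_2014,
        dispensing_rates=dict(_DISPENSING_2014),
        sterilization_rate_per_user=_STERILIZATION_RATE_2014,
    )


# --- the packaged 2014 fixture -------------------------------------------


@dataclass(frozen=True)
class PaperFixture2014:
    """The published 2014 annual tables in machine-readable form.

    ``coverage``, ``method_users`` and ``visits_reasons`` are
    governorate-indexed frames of the printed cells (percent columns are
    share-only: they carry no count invariants). Regional and national
    printed rows are kept separately for cross-checks. ``reference``
    holds per-governorate MWRA/clinic integer counts reconstructed from
    the printed percent shares by largest-remainder apportionment against
    the printed national totals (share-derived, not printed directly).
    """

    reference: MWRAReference
    coverage: pd.DataFrame
    method_users: pd.DataFrame
    visits_reasons: pd.DataFrame
    coverage_regions: pd.DataFrame
    method_users_regions: pd.DataFrame
    visits_reasons_regions: pd.DataFrame
    national: dict

    def governorate_ccr(self) -> dict[Governorate, float]:
        by_name = {g.name: g for g in standard_governorate_registry()}
        return {by_name[n]: float(v) for n, v in self.coverage["ccr_pct"].items()}

    def _published_profile(self, users_row, visits_row, cov_row, extra=None):
        from .kpi import KPIProfile

        def f(row, col):
            try:
                v = float(row[col])
            except (KeyError, TypeError, ValueError):
                return math.nan
            return v

        extra = extra or {}
        return KPIProfile(
            pct_age_35_plus=extra.get("age_35_plus", math.nan),
            pct_under_3_children=extra.get("under_3_children", math.nan),
            method_mix=tuple(
                extra.get("method_mix", {}).get(m, f(users_row, f"{m.value}_pct"))
                for m in METHOD_MIX_ORDER
            ),
            pct_first_visit=f(visits_row, "first_visit_pct"),
            pct_new_clients=f(visits_row, "new_clients_pct"),
            reason_shares=(
                f(visits_row, "get_method_pct"),
                f(visits_row, "counseling_pct"),
                f(visits_row, "rh_services_pct"),
                f(visits_row, "side_effects_pct"),
            ),
            ccr=f(cov_row, "ccr_pct"),
            mwra_share=f(cov_row, "mwra_share_pct"),
            clinic_share=f(cov_row, "clinic_share_pct"),
            clinics_per_10k_mwra=f(cov_row, "clinics_per_10k_mwra"),
            ccr_as_reported=True,
        )

    def published_profiles(self):
        """Indicator profiles holding the printed 2014 cells verbatim.

        Cells the source tables do not print (per-governorate age and
        parity shares; Cairo's ambiguous reason cells) are NaN. The
        national method mix is derived from the printed national counts;
        the national age/parity headlines come from the printed summary
        (35+ = 27.4%, 3+ children = 41.6%).
        """
        from .report import ProfileSet

        governorates = {
            g: self._published_profile(
                self.method_users.loc[g.name],
                self.visits_reasons.loc[g.name],
                self.coverage.loc[g.name],
            )
            for g in standard_governorate_registry()
        }
        regions = {
            r: self._published_profile(
                self.method_users_regions.loc[r.display_name],
                self.visits_reasons_regions.loc[r.display_name],
                self.coverage_regions.loc[r.display_name],
            )
            for r in dict.fromkeys(g.region for g in standard_governorate_registry())
        }
        national_mix = {
            m: 100.0 * self.national["users_by_method"][m] / self.national["users_total"]
            for m in METHOD_MIX_ORDER
        }
        national = self._published_profile(
            {},
            {
                "first_visit_pct": self.national["first_visit_pct"],
                "new_clients_pct": self.national["new_clients_pct"],
                "get_method_pct": self.national["get_method_pct"],
                "counseling_pct": 14.4,
                "rh_services_pct": 5.6,
                "side_effects_pct": 19.9,
            },
            {
                "ccr_pct": self.national["ccr_pct"],
                "mwra_share_pct": 100.0,
                "clinic_share_pct": 100.0,
                "clinics_per_10k_mwra": self.national["clinics_per_10k_mwra"],
            },
            extra={
                "age_35_plus": 27.4,
                "under_3_children": 100.0 - 41.6,
                "method_mix": national_mix,
            },
        )
        return ProfileSet(governorates=governorates, regions=regions, national=national)

    def published_rank_tables(self, scheme=None):
        """Categorised league tables for the four chart indicators, built
        from the printed per-governorate cells. Governorates whose cell is
        unparsed (Cairo's ambiguous get-method) are omitted from that
        indicator's table rather than guessed."""
        from .kpi import Direction
        from .ranking import CategoryScheme, categorize, rank_values
        from .report import CHART_INDICATORS

        if scheme is None:
            scheme = CategoryScheme()
        profiles = self.published_profiles()
        tables = {}
        for ind in CHART_INDICATORS:
            values = {
                g: p.value(ind)
                for g, p in profiles.governorates.items()
                if not math.isnan(p.value(ind))
            }
            tables[ind] = categorize(
                rank_values(values, ind, Direction.HIGHER_BETTER), scheme
            )
        return tables

    def report_inputs(self, scheme=None):
        """(annual-sheet stub, profiles, rank tables) for rendering the
        published 2014 report. The stub carries metadata only: the report
        pages read profiles, which hold the printed cells."""
        from .aggregate import AnnualSheet, rollup

        registry = standard_governorate_registry()
        rows = {g: ServiceCounts.zero() for g in registry}
        region_rows, national_row = rollup(rows)
        stub = AnnualSheet(
            year=2014, rows=rows, region_rows=region_rows, national_row=national_row
        )
        return stub, self.published_profiles(), self.published_rank_tables(scheme)


def _load(name: str) -> pd.DataFrame:
    with resources.files("fpkpi.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def _split(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    gov = df[df.row_type == "governorate"].set_index("governorate").drop(columns="row_type")
    reg = df[df.row_type == "region"].set_index("governorate").drop(columns="row_type")
    nat = df[df.row_type == "national"].iloc[0]
    return gov, reg, nat


def _apportion(shares: list[float], total: int) -> list[int]:
    """Largest-remainder apportionment of integer ``total`` over shares."""
    weight = sum(shares)
    quotas = [s / weight * total for s in shares]
    counts = [math.floor(q) for q in quotas]
    remainder = total - sum(counts)
    order = sorted(range(len(shares)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def paper_fixture_2014() -> PaperFixture2014:
    """Load the packaged 2014 fixture (three tables + derived reference)."""
    cov, cov_reg, cov_nat = _split(_load("coverage_2014.csv"))
    users, users_reg, users_nat = _split(_load("method_users_2014.csv"))
    visits, visits_reg, visits_nat = _split(_load("visits_reasons_2014.csv"))

    registry = standard_governorate_registry()
    order = [g.name for g in registry]
    cov = cov.loc[order]
    users = users.loc[order]
    visits = visits.loc[order]

    national_mwra = int(cov_nat["mwra_count"])
    national_clinics = int(cov_nat["clinics_count"])
    mwra_counts = _apportion(list(cov["mwra_share_pct"]), national_mwra)
    clinic_counts = _apportion(list(cov["clinic_share_pct"]), national_clinics)
    reference = MWRAReference(
        year=2014,
        rows={g: (m, c) for g, m, c in zip(registry, mwra_counts, clinic_counts)},
    )

    national = {
        "mwra": national_mwra,
        "clinics": national_clinics,
        "clinics_per_10k_mwra": float(cov_nat["clinics_per_10k_mwra"]),
        "ccr_pct": float(cov_nat["ccr_pct"]),
        "users_total": int(users_nat["users_total"]),
        "users_by_method": {
            m: int(users_nat[f"{m.value}_count"]) for m in METHOD_MIX_ORDER
        },
        "total_clients": NATIONAL_CLIENTS_2014,
        "first_visit_pct": float(visits_nat["first_visit_pct"]),
        "new_clients_pct": float(visits_nat["new_clients_pct"]),
        "get_method_pct": float(visits_nat["get_method_pct"]),
    }
    return PaperFixture2014(
        reference=reference,
        coverage=cov,
        method_users=users,
        visits_reasons=visits,
        coverage_regions=cov_reg,
        method_users_regions=users_reg,
        visits_reasons_regions=visits_reg,
        national=national,
    )
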