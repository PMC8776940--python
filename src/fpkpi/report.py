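"""The three-page annual report and policy-brief scaffolds.

Page 1 is a 32-row table (27 governorates + 4 region rows + national) of
the eight client-profile indicators; page 2 the seven demand-side
indicators including the contraceptive coverage rate; page 3 four ranked
horizontal bar charts coloured by traffic-light category. Outputs are
diff-able text artifacts (CSV, SVG, HTML) and re-rendering identical
inputs is byte-identical.
"""

from __future__ import annotations

import html
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .aggregate import AnnualSheet
from .ingest import MWRAReference
from .kpi import (
    Direction,
    KPIProfile,
    compute_profile,
    indicator_catalog,
    round_display,
)
from .ranking import CategoryScheme, RankTable, categorize, rank_governorates
from .schema import (
    Governorate,
    Region,
    ValidationError,
    standard_governorate_registry,
)

__all__ = [
    "ProfileSet",
    "AnnualReport",
    "PolicyBrief",
    "CHART_INDICATORS",
    "PAGE1_INDICATORS",
    "PAGE2_INDICATORS",
    "compute_profiles",
    "build_rank_tables",
    "render_annual_report",
    "render_policy_brief",
    "export_profiles_csv",
]

PAGE1_INDICATORS = (
    "age_35_plus",
    "under_3_children",
    "mix_oc",
    "mix_iud",
    "mix_condom",
    "mix_injectable_3m",
    "mix_implant",
    "mix_injectable_1m",
)
PAGE2_INDICATORS = (
    "first_visit",
    "new_clients",
    "get_method",
    "counseling",
    "rh_services",
    "side_effects",
    "ccr",
)
#: The four colour-ranked page-3 charts.
CHART_INDICATORS = ("first_visit", "new_clients", "get_method", "ccr")

_LABELS = {d.id: d.label for d in indicator_catalog()}
_DIRECTIONS = {d.id: d.direction for d in indicator_catalog()}


@dataclass(frozen=True)
class ProfileSet:
    governorates: Mapping[Governorate, KPIProfile]
    regions: Mapping[Region, KPIProfile]
    national: KPIProfile


def compute_profiles(
    annual: AnnualSheet,
    reference: MWRAReference,
    rules=None,
    *,
    mix_over_all_clients: bool = False,
) -> ProfileSet:
    """Indicator profiles for every governorate, region and the nation.

    Regional and national profiles are computed from summed counts and
    summed denominators — never from averaged percentages.
    """
    national_ref = (reference.national_mwra, reference.national_clinics)
    region_refs = reference.region_totals()
    kwargs = dict(mix_over_all_clients=mix_over_all_clients)
    return ProfileSet(
        governorates={
            g: compute_profile(annual.rows[g], reference.rows[g], national_ref, rules, **kwargs)
            for g in standard_governorate_registry()
        },
        regions={
            r: compute_profile(annual.region_rows[r], region_refs[r], national_ref, rules, **kwargs)
            for r in annual.region_rows
        },
        national=compute_profile(annual.national_row, national_ref, national_ref, rules, **kwargs),
    )


def build_rank_tables(
    profiles: Mapping[Governorate, KPIProfile],
    scheme: CategoryScheme | None = None,
    indicator_ids: tuple[str, ...] = CHART_INDICATORS,
) -> dict[str, RankTable]:
    """Categorised rank tables for the chart indicators."""
    if scheme is None:
        scheme = CategoryScheme()
    return {
        ind: categorize(rank_governorates(profiles, ind, _DIRECTIONS[ind]), scheme)
        for ind in indicator_ids
    }


@dataclass(frozen=True)
class AnnualReport:
    page1_path: Path
    page2_path: Path
    chart_paths: Mapping[str, Path]
    html_path: Path
    metadata: dict


@dataclass(frozen=True)
class PolicyBrief:
    unit: str
    title: str
    introduction: str
    major_results: tuple[str, ...]
    recommendation: str

    def to_html(self) -> str:
        results = "".join(f"<li>{html.escape(r)}</li>" for r in self.major_results)
        if not results:
            results = "<li><em>No red-category indicators under the current scheme.</em></li>"
        return (
            "<article class='policy-brief'>"
            f"<h2>{html.escape(self.title)}</h2>"
            f"<h3>Introduction</h3><p>{html.escape(self.introduction)}</p>"
            f"<h3>Major Results</h3><ul>{results}</ul>"
            f"<h3>Recommendation</h3><p>{html.escape(self.recommendation)}</p>"
            "</article>"
        )


def _fmt(value: float) -> str:
    rounded = round_display(value)
    if math.isnan(rounded):
        return ""
    if rounded == int(rounded) and abs(value) >= 10:
        return str(int(rounded))
    return f"{rounded:.1f}"


def _unit_rows(profiles: ProfileSet):
    """Yield (label, profile) in fixed report order: each region's
    governorates followed by the region row, the national row last."""
    registry = standard_governorate_registry()
    for region in dict.fromkeys(g.region for g in registry):
        for g in (g for g in registry if g.region == region):
            yield g.name, profiles.governorates[g]
        yield region.display_name, profiles.regions[region]
    yield "Total Egypt", profiles.national


def _write_page_csv(profiles: ProfileSet, indicator_ids, path: Path) -> None:
    lines = ["unit," + ",".join(indicator_ids)]
    for label, profile in _unit_rows(profiles):
        lines.append(label + "," + ",".join(_fmt(profile.value(i)) for i in indicator_ids))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def export_profiles_csv(profiles: ProfileSet, path) -> None:
    """All 18 indicators, one row per unit, in catalog order (full precision)."""
    ids = [d.id for d in indicator_catalog()]
    lines = ["unit," + ",".join(ids)]
    for label, profile in _unit_rows(profiles):
        lines.append(
            label + "," + ",".join(repr(float(profile.value(i))) for i in ids)
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _render_chart(table: RankTable, path: Path) -> None:
    # Fixed hashsalt and no date metadata keep SVG output byte-identical
    # across re-renders of the same inputs.
    with plt.rc_context({"svg.hashsalt": "fpkpi"}):
        names = [e.governorate.name for e in table.entries]
        values = [e.value for e in table.entries]
        colors = [e.category or "grey" for e in table.entries]
        fig, ax = plt.subplots(figsize=(6.5, 7.0))
        y = range(len(names))
        ax.barh(y, values, color=colors, edgecolor="black", linewidth=0.3)
        ax.set_yticks(list(y), labels=names, fontsize=7)
        ax.invert_yaxis()  # best-first from the top
        ax.set_xlabel(_LABELS[table.indicator_id], fontsize=9)
        ax.set_title(f"Governorates ranked by {_LABELS[table.indicator_id]}", fontsize=10)
        fig.tight_layout()
        fig.savefig(path, format="svg", metadata={"Date": None})
        plt.close(fig)


def _page_table_html(path: Path, caption: str) -> str:
    rows = path.read_text(encoding="utf-8").strip().split("\n")
    out = [f"<table><caption>{html.escape(caption)}</caption>"]
    header = rows[0].split(",")
    out.append(
        "<tr>" + "".join(f"<th>{html.escape(_LABELS.get(c, c))}</th>" for c in header) + "</tr>"
    )
    for line in rows[1:]:
        cells = line.split(",")
        tag = "th" if cells[0].endswith("Governorates") or cells[0] == "Total Egypt" else "td"
        out.append("<tr>" + "".join(f"<{tag}>{html.escape(c)}</{tag}>" for c in cells) + "</tr>")
    out.append("</table>")
    return "".join(out)


def render_annual_report(
    annual: AnnualSheet,
    profiles: ProfileSet,
    rank_tables: Mapping[str, RankTable],
    scheme: CategoryScheme | None = None,
    out_dir=".",
) -> AnnualReport:
    """Persist the three-page report: two CSV tables, four SVG charts and
    one assembled HTML document. Deterministic for identical inputs."""
    if scheme is None:
        scheme = CategoryScheme()
    missing = [i for i in CHART_INDICATORS if i not in rank_tables]
    if missing:
        raise ValidationError(f"missing rank table(s): {', '.join(missing)}")
    for ind in CHART_INDICATORS:
        if not rank_tables[ind].entries:
            raise ValidationError(f"rank table for {ind!r} is empty")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    page1 = out / "page1_client_profile.csv"
    page2 = out / "page2_performance.csv"
    _write_page_csv(profiles, PAGE1_INDICATORS, page1)
    _write_page_csv(profiles, PAGE2_INDICATORS, page2)

    chart_paths: dict[str, Path] = {}
    for ind in CHART_INDICATORS:
        chart_paths[ind] = out / f"page3_{ind}.svg"
        _render_chart(rank_tables[ind], chart_paths[ind])

    year_label = f"{annual.year}" + (" (partial year)" if annual.partial_year else "")
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>FP annual report {html.escape(year_label)}</title>",
        "<style>table{border-collapse:collapse}td,th{border:1px solid #999;"
        "padding:2px 6px;font:12px sans-serif}caption{font:bold 13px sans-serif;"
        "margin:6px}</style></head><body>",
        f"<h1>Family planning annual report — {html.escape(year_label)}</h1>",
        "<h2>Page 1 — client profile and method mix</h2>",
        _page_table_html(page1, "Eight client-profile indicators"),
        "<h2>Page 2 — service performance and coverage</h2>",
        _page_table_html(page2, "Seven performance indicators"),
        "<h2>Page 3 — governorate league charts</h2>",
    ]
    for ind in CHART_INDICATORS:
        parts.append(chart_paths[ind].read_text(encoding="utf-8"))
    parts.append("</body></html>")
    html_path = out / "annual_report.html"
    html_path.write_text("".join(parts), encoding="utf-8")

    return AnnualReport(
        page1_path=page1,
        page2_path=page2,
        chart_paths=chart_paths,
        html_path=html_path,
        metadata={
            "year": annual.year,
            "partial_year": annual.partial_year,
            "quarters": list(annual.quarters),
            "scheme": {
                "lower_centile": scheme.lower_centile,
                "upper_centile": scheme.upper_centile,
            },
        },
    )


def render_policy_brief(
    unit: Governorate | str,
    profiles: ProfileSet,
    rank_tables: Mapping[str, RankTable],
) -> PolicyBrief:
    """Scaffold a policy brief for one governorate or the national level.

    The red-category indicators of the unit become candidate findings;
    the free-text sections stay as fill-in placeholders — interpretation
    is deliberately left to programme staff.
    """
    if isinstance(unit, Governorate):
        if unit not in profiles.governorates:
            raise ValidationError(f"no profile for unit {unit.name!r}")
        label = unit.name
        findings = []
        for ind, table in rank_tables.items():
            entry = table.entry_for(unit)
            if entry.category == "red":
                findings.append(
                    f"{_LABELS[ind]}: {_fmt(entry.value)} "
                    f"(rank {entry.rank} of {len(table.entries)}; unfavorable category)"
                )
    elif unit == "national":
        label = "Egypt (national)"
        findings = []  # the nation is not itself ranked
    else:
        raise ValidationError(f"unknown unit: {unit!r}")

    if findings:
        title = (
            f"[Suggested recommendation — rephrase]: strengthen the unfavorable "
            f"indicators identified for {label}"
        )
    else:
        title = f"[Suggested recommendation — rephrase]: sustain performance in {label}"
    return PolicyBrief(
        unit=label,
        title=title,
        introduction=(
            "[Fill in: topic importance, objectives, methodology, sources of "
            "data, and who conducted data management.]"
        ),
        major_results=tuple(findings),
        recommendation="[Fill in: recommendations derived from the key findings.]",
    )
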