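import math

import pytest

from fpkpi.kpi import round_display
from fpkpi.ranking import CategoryScheme
from fpkpi.report import (
    CHART_INDICATORS,
    PAGE1_INDICATORS,
    PAGE2_INDICATORS,
    build_rank_tables,
    compute_profiles,
    export_profiles_csv,
    render_annual_report,
    render_policy_brief,
)
from fpkpi.schema import ValidationError, standard_governorate_registry

# matplotlib's named colours as they appear in SVG fill styles
_FILL = {"green": "#008000", "yellow": "#ffff00", "red": "#ff0000"}


@pytest.fixture(scope="module")
def pilot_report(pilot_config, pilot_annual, tmp_path_factory):
    profiles = compute_profiles(pilot_annual, pilot_config.reference())
    tables = build_rank_tables(profiles.governorates)
    out = tmp_path_factory.mktemp("report")
    report = render_annual_report(pilot_annual, profiles, tables, out_dir=out)
    return profiles, tables, report


class TestAnnualReport:
    def test_three_page_artifacts_exist(self, pilot_report):
        _, _, report = pilot_report
        assert report.page1_path.exists() and report.page2_path.exists()
        assert set(report.chart_paths) == set(CHART_INDICATORS)
        assert report.html_path.exists()

    def test_page_tables_have_32_rows_in_fixed_order(self, pilot_report):
        _, _, report = pilot_report
        for path, ids in (
            (report.page1_path, PAGE1_INDICATORS),
            (report.page2_path, PAGE2_INDICATORS),
        ):
            lines = path.read_text().splitlines()
            assert lines[0] == "unit," + ",".join(ids)
            assert len(lines) == 1 + 27 + 4 + 1
            assert lines[1].split(",")[0] == "Cairo"
            assert lines[-1].split(",")[0] == "Total Egypt"

    def test_printed_cells_equal_rounded_profile_values(self, pilot_report):
        profiles, _, report = pilot_report
        lines = report.page2_path.read_text().splitlines()
        cairo = next(g for g in standard_governorate_registry() if g.name == "Cairo")
        cells = lines[1].split(",")
        expected = round_display(profiles.governorates[cairo].pct_first_visit)
        assert float(cells[1]) == expected

    def test_chart_bar_colours_match_rank_categories(self, pilot_report):
        _, tables, report = pilot_report
        for ind in CHART_INDICATORS:
            svg = report.chart_paths[ind].read_text()
            for color, fill in _FILL.items():
                expected = sum(e.category == color for e in tables[ind].entries)
                assert svg.count(f"fill: {fill}") >= expected

    def test_rerender_is_byte_identical(self, pilot_config, pilot_annual, tmp_path):
        profiles = compute_profiles(pilot_annual, pilot_config.reference())
        tables = build_rank_tables(profiles.governorates)
        a = render_annual_report(pilot_annual, profiles, tables, out_dir=tmp_path / "a")
        b = render_annual_report(pilot_annual, profiles, tables, out_dir=tmp_path / "b")
        assert a.html_path.read_bytes() == b.html_path.read_bytes()
        for ind in CHART_INDICATORS:
            assert a.chart_paths[ind].read_bytes() == b.chart_paths[ind].read_bytes()

    def test_missing_rank_table_is_an_error(self, pilot_config, pilot_annual, tmp_path):
        profiles = compute_profiles(pilot_annual, pilot_config.reference())
        tables = build_rank_tables(profiles.governorates)
        tables.pop("ccr")
        with pytest.raises(ValidationError, match="ccr"):
            render_annual_report(pilot_annual, profiles, tables, out_dir=tmp_path)

    def test_profiles_csv_has_all_18_indicators(self, pilot_report, tmp_path):
        profiles, _, _ = pilot_report
        path = tmp_path / "profiles.csv"
        export_profiles_csv(profiles, path)
        lines = path.read_text().splitlines()
        assert len(lines[0].split(",")) == 19
        assert len(lines) == 33


class TestPublishedFixtureReport:
    def test_page2_national_ccr_prints_37(self, fixture_2014, tmp_path):
        stub, profiles, tables = fixture_2014.report_inputs()
        report = render_annual_report(stub, profiles, tables, out_dir=tmp_path)
        rows = report.page2_path.read_text().splitlines()
        header = rows[0].split(",")
        national = rows[-1].split(",")
        assert national[header.index("ccr")] == "37"

    def test_ccr_chart_first_bar_is_behera(self, fixture_2014):
        tables = fixture_2014.published_rank_tables()
        assert tables["ccr"].entries[0].governorate.name == "Behera"
        assert tables["ccr"].entries[0].value == 57.0


class TestPolicyBrief:
    def test_four_sections_present_and_nonempty(self, pilot_report):
        profiles, tables, _ = pilot_report
        gov = standard_governorate_registry()[0]
        brief = render_policy_brief(gov, profiles, tables)
        assert brief.title and brief.introduction and brief.recommendation
        assert isinstance(brief.major_results, tuple)
        html = brief.to_html()
        for section in ("Introduction", "Major Results", "Recommendation"):
            assert section in html

    def test_red_indicators_become_candidate_findings(self, pilot_report):
        profiles, tables, _ = pilot_report
        for g in standard_governorate_registry():
            brief = render_policy_brief(g, profiles, tables)
            red = [ind for ind, t in tables.items() if t.entry_for(g).category == "red"]
            assert len(brief.major_results) == len(red)

    def test_all_green_unit_has_empty_findings_but_full_scaffold(self, pilot_report):
        profiles, tables, _ = pilot_report
        brief = render_policy_brief("national", profiles, tables)
        assert brief.major_results == ()
        assert "Recommendation" in brief.to_html()

    def test_unknown_unit_is_an_error(self, pilot_report):
        profiles, tables, _ = pilot_report
        with pytest.raises(ValidationError):
            render_policy_brief("atlantis", profiles, tables)
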