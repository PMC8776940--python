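import math
from dataclasses import replace

import numpy as np
import pytest

from fpkpi.aggregate import merge_quarters
from fpkpi.report import compute_profiles
from fpkpi.schema import (
    METHOD_MIX_ORDER,
    Period,
    ServiceCounts,
    ValidationError,
    standard_governorate_registry,
)
from fpkpi.synthetic import (
    NATIONAL_CLIENTS_2014,
    GeneratorConfig,
    GovernorateVolume,
    default_egypt_config,
    generate_quarter,
)


class TestGenerateQuarter:
    def test_same_seed_and_period_give_identical_sheets(self, pilot_config):
        a = generate_quarter(pilot_config, Period(2014, 3))
        b = generate_quarter(pilot_config, Period(2014, 3))
        assert a == b

    def test_different_quarters_differ(self, pilot_config):
        a = generate_quarter(pilot_config, Period(2014, 1))
        b = generate_quarter(pilot_config, Period(2014, 2))
        assert a.rows != b.rows

    def test_zero_expected_clients_give_all_zero_sheet(self, pilot_config):
        volumes = {
            n: GovernorateVolume(v.mwra, v.clinics, 0.0)
            for n, v in pilot_config.volumes.items()
        }
        config = replace(pilot_config, volumes=volumes)
        sheet = generate_quarter(config, Period(2014, 1))
        assert all(c == ServiceCounts.zero() for c in sheet.rows.values())

    def test_invalid_simplex_rejected(self, pilot_config):
        with pytest.raises(ValidationError, match="age"):
            replace(pilot_config, age=(0.5, 0.5, 0.5, 0.0, 0.0))

    def test_generated_totals_within_3_sigma_of_expectation(self, pilot_config):
        sheets = [generate_quarter(pilot_config, Period(2014, q)) for q in (1, 2, 3, 4)]
        total = sum(sum(c.total_clients for c in s.rows.values()) for s in sheets)
        expected = 4 * sum(v.expected_quarterly_clients for v in pilot_config.volumes.values())
        assert abs(total - expected) <= 3 * math.sqrt(expected)


class TestDefaultConfig:
    def test_denominators_match_published_national_totals(self, pilot_config):
        ref = pilot_config.reference()
        assert ref.national_mwra == 15_799_805
        assert ref.national_clinics == 6_038

    def test_simplices_and_probabilities_valid(self, pilot_config):
        for simplex in (pilot_config.age, pilot_config.parity,
                        pilot_config.method_mix, pilot_config.reason):
            assert abs(sum(simplex) - 1.0) < 1e-9
            assert all(p >= 0 for p in simplex)
        assert 0 < pilot_config.p_first_visit < 1
        assert 0 < pilot_config.p_method_user <= 1

    def test_full_scale_volume_matches_published_client_total(self):
        config = default_egypt_config(seed=0)
        annual_expected = 4 * sum(
            v.expected_quarterly_clients for v in config.volumes.values()
        )
        assert annual_expected == pytest.approx(NATIONAL_CLIENTS_2014, rel=1e-6)

    def test_pipeline_recovers_configured_proportions(self, pilot_config, pilot_annual):
        """End-to-end parameter recovery at pilot volume: the estimated
        method mix and headline shares track the configured simplices
        within multinomial sampling error."""
        profiles = compute_profiles(pilot_annual, pilot_config.reference())
        n_users = pilot_annual.national_row.method_users_total
        for i, p in enumerate(pilot_config.method_mix):
            est = profiles.national.method_mix[i] / 100.0
            se = math.sqrt(p * (1 - p) / n_users)
            assert abs(est - p) < 5 * se + 1e-12
        n = pilot_annual.national_row.total_clients
        p = pilot_config.p_first_visit
        assert abs(profiles.national.pct_first_visit / 100.0 - p) < 5 * math.sqrt(
            p * (1 - p) / n
        )


class TestPaperFixture:
    def test_published_user_counts(self, fixture_2014):
        users = fixture_2014.method_users
        behera = int(users.loc["Behera", "users_total"])
        assert behera == 1_098_520
        assert fixture_2014.national["users_total"] == 13_670_104

    def test_regional_user_totals_are_exact_sums(self, fixture_2014):
        registry = standard_governorate_registry()
        for region in dict.fromkeys(g.region for g in registry):
            members = [g.name for g in registry if g.region is region]
            printed = int(
                fixture_2014.method_users_regions.loc[region.display_name, "users_total"]
            )
            assert int(fixture_2014.method_users.loc[members, "users_total"].sum()) == printed

    def test_south_sinai_share_carries_corrected_typo_note(self, fixture_2014):
        row = fixture_2014.coverage.loc["S. Sinai"]
        assert row["mwra_share_pct"] == 0.1
        assert "o.1" in str(row["note"])

    def test_reference_apportionment_tracks_printed_shares(self, fixture_2014):
        ref = fixture_2014.reference
        for g in standard_governorate_registry():
            share = float(fixture_2014.coverage.loc[g.name, "mwra_share_pct"])
            mwra, clinics = ref.rows[g]
            assert 100.0 * mwra / ref.national_mwra == pytest.approx(
                share * 100 / fixture_2014.coverage["mwra_share_pct"].sum(), abs=0.01
            )
            assert clinics >= 0

    def test_published_profiles_expose_printed_cells(self, fixture_2014):
        profiles = fixture_2014.published_profiles()
        minia = next(g for g in standard_governorate_registry() if g.name == "Minia")
        cairo = next(g for g in standard_governorate_registry() if g.name == "Cairo")
        assert profiles.governorates[minia].reason_shares[0] == 97.0
        assert math.isnan(profiles.governorates[cairo].reason_shares[0])  # unparsed
        assert profiles.national.ccr == 37.0
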