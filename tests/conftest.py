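import pytest
from hypothesis import settings
from hypothesis import strategies as st

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

from fpkpi import Period, ServiceCounts, generate_quarter, paper_fixture_2014
from fpkpi.aggregate import merge_quarters
from fpkpi.schema import METHODS, MethodCategory
from fpkpi.synthetic import default_egypt_config


@pytest.fixture(scope="session")
def fixture_2014():
    return paper_fixture_2014()


@pytest.fixture(scope="session")
def pilot_config():
    """Default national conditions at pilot client volume (fast tests)."""
    return default_egypt_config(seed=20140, volume_scale=0.002)


@pytest.fixture(scope="session")
def pilot_annual(pilot_config):
    sheets = [generate_quarter(pilot_config, Period(2014, q)) for q in (1, 2, 3, 4)]
    return merge_quarters(sheets)


def _partition(draw, total: int, k: int) -> tuple[int, ...]:
    """A uniform-ish composition of `total` into k non-negative parts."""
    if k == 1:
        return (total,)
    cuts = sorted(
        draw(st.lists(st.integers(0, total), min_size=k - 1, max_size=k - 1))
    )
    parts = []
    prev = 0
    for c in cuts:
        parts.append(c - prev)
        prev = c
    parts.append(total - prev)
    return tuple(parts)


@st.composite
def service_counts(draw, max_total: int = 2000) -> ServiceCounts:
    total = draw(st.integers(0, max_total))
    users = draw(st.integers(0, total))
    dispensed = {
        m: draw(st.floats(0, 1e6, allow_nan=False, allow_infinity=False))
        for m in draw(st.sets(st.sampled_from(METHODS)))
    }
    return ServiceCounts(
        _partition(draw, total, 5),
        _partition(draw, total, 5),
        _partition(draw, users, 6),
        _partition(draw, total, 2),
        _partition(draw, total, 2),
        _partition(draw, total, 4),
        dispensed,
        draw(st.one_of(st.none(), st.floats(0, 200, allow_nan=False))),
    )


@st.composite
def quarterly_sheets(draw, max_total: int = 300):
    from fpkpi.ingest import QuarterlySheet
    from fpkpi.schema import standard_governorate_registry

    registry = standard_governorate_registry()
    rows = {g: draw(service_counts(max_total)) for g in registry}
    quarter = draw(st.sampled_from([1, 2, 3, 4]))
    return QuarterlySheet(period=Period(2014, quarter), rows=rows)


@st.composite
def dispensing_records(draw) -> dict[MethodCategory, float]:
    return {
        m: draw(st.floats(0, 1e7, allow_nan=False, allow_infinity=False))
        for m in draw(st.sets(st.sampled_from(METHODS)))
    }
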