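import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpkpi.kpi import Direction
from fpkpi.ranking import (
    Category,
    CategoryScheme,
    categorize,
    rank_values,
)
from fpkpi.schema import ValidationError, standard_governorate_registry

REGISTRY = standard_governorate_registry()


def _table(values, direction=Direction.HIGHER_BETTER):
    return rank_values(dict(zip(REGISTRY, values)), "test_indicator", direction)


def _oracle_ranks(values, direction):
    """Brute-force competition ranking: rank = 1 + number of strictly
    better values, computed per governorate by direct counting."""
    better = (lambda a, b: a > b) if direction is not Direction.LOWER_BETTER else (lambda a, b: a < b)
    return {
        g: 1 + sum(better(w, v) for w in values.values())
        for g, v in values.items()
    }


class TestRankValues:
    @settings(max_examples=60)
    @given(
        st.lists(st.integers(0, 50), min_size=27, max_size=27),
        st.sampled_from([Direction.HIGHER_BETTER, Direction.LOWER_BETTER]),
    )
    def test_matches_brute_force_sort_oracle(self, raw, direction):
        values = dict(zip(REGISTRY, map(float, raw)))
        table = _table(list(map(float, raw)), direction)
        oracle = _oracle_ranks(values, direction)
        assert {e.governorate: e.rank for e in table.entries} == oracle
        # best-first ordering, ties broken by fixed position
        for a, b in zip(table.entries, table.entries[1:]):
            assert a.rank <= b.rank
            if a.value == b.value:
                assert a.governorate.fixed_position < b.governorate.fixed_position

    def test_distinct_values_give_rank_permutation(self):
        rng = np.random.default_rng(5)
        values = rng.permutation(27).astype(float)
        table = _table(list(values))
        assert sorted(e.rank for e in table.entries) == list(range(1, 28))

    def test_total_tie_all_rank_one_in_registry_order(self):
        table = _table([7.0] * 27)
        assert all(e.rank == 1 for e in table.entries)
        assert [e.governorate for e in table.entries] == REGISTRY

    def test_lower_better_reverses_order_not_data(self):
        values = list(range(27))
        best_first = _table(list(map(float, values)), Direction.LOWER_BETTER)
        assert best_first.entries[0].value == 0.0
        assert best_first.entries[0].rank == 1

    def test_undefined_value_is_an_error(self):
        values = [1.0] * 27
        values[3] = float("nan")
        with pytest.raises(ValidationError, match="undefined"):
            _table(values)


class TestCategorize:
    def test_tertiles_split_1_to_27_into_9_9_9(self):
        # oracle: nearest-rank percentiles of 1..27 are the 9th and 19th
        # order statistics, i.e. cuts at 9 and 19
        table = categorize(_table([float(v) for v in range(1, 28)]),
                           CategoryScheme(33.3, 66.7))
        by_cat = {c: [e.value for e in table.entries if e.category == c]
                  for c in (Category.BEST, Category.PROSPECTIVE, Category.UNFAVORABLE)}
        assert sorted(by_cat[Category.BEST]) == [float(v) for v in range(19, 28)]
        assert sorted(by_cat[Category.PROSPECTIVE]) == [float(v) for v in range(10, 19)]
        assert sorted(by_cat[Category.UNFAVORABLE]) == [float(v) for v in range(1, 10)]

    def test_constant_values_all_best_by_convention(self):
        for direction in (Direction.HIGHER_BETTER, Direction.LOWER_BETTER):
            table = categorize(_table([5.0] * 27, direction))
            assert all(e.category == Category.BEST for e in table.entries)

    def test_degenerate_scheme_rejected(self):
        with pytest.raises(ValidationError):
            CategoryScheme(50.0, 50.0)
        with pytest.raises(ValidationError):
            CategoryScheme(0.0, 66.7)

    @settings(max_examples=60)
    @given(
        st.lists(st.integers(0, 30), min_size=27, max_size=27),
        st.sampled_from([Direction.HIGHER_BETTER, Direction.LOWER_BETTER]),
    )
    def test_partition_exhaustive_exclusive_and_monotone(self, raw, direction):
        table = categorize(_table(list(map(float, raw)), direction))
        cats = [e.category for e in table.entries]
        assert all(c in (Category.BEST, Category.PROSPECTIVE, Category.UNFAVORABLE) for c in cats)
        assert len(cats) == 27
        # monotone consistency: a strictly better value never gets a worse category
        order = {Category.BEST: 0, Category.PROSPECTIVE: 1, Category.UNFAVORABLE: 2}
        for a in table.entries:
            for b in table.entries:
                strictly_better = (
                    a.value > b.value
                    if direction is not Direction.LOWER_BETTER
                    else a.value < b.value
                )
                if strictly_better:
                    assert order[a.category] <= order[b.category]
        # ties never straddle categories
        for a in table.entries:
            for b in table.entries:
                if a.value == b.value:
                    assert a.category == b.category

    def test_rank_table_csv_export(self, tmp_path):
        table = categorize(_table([float(v) for v in range(27)]))
        path = tmp_path / "rank.csv"
        table.to_csv(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "governorate,value,rank,category"
        assert len(lines) == 28
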