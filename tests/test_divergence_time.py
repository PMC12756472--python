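import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phylogrid.divergence_time import (
    CellGenusCounts,
    GenusAgeTable,
    genus_crown_ages,
    mdt,
    mdt_bias_label,
    mdt_ses_suite,
    quartile_mean_ages,
    ses_mdt,
)
from phylogrid.errors import UndefinedResultError
from phylogrid.io_formats import GenusMap
from phylogrid.nullmodels import NullConfig


class TestGenusCrownAges:
    def test_crown_age_is_mrca_age(self, fixture_tree):
        gm = GenusMap({"A": "g1", "B": "g1", "C": "g2", "D": "g2"})
        table = genus_crown_ages(fixture_tree, gm)
        assert table.age("g1") == pytest.approx(1.0)
        assert table.age("g2") == pytest.approx(2.0)
        assert not table.monotypic

    def test_monotypic_falls_back_to_stem_age(self, fixture_tree):
        gm = GenusMap({"A": "gA", "B": "gB", "C": "gC", "D": "gD"})
        table = genus_crown_ages(fixture_tree, gm)
        assert table.age("gA") == pytest.approx(1.0)  # parent of A = (A,B) node
        assert table.age("gC") == pytest.approx(2.0)
        assert table.monotypic == frozenset({"gA", "gB", "gC", "gD"})

    def test_non_monophyletic_genus_uses_mrca(self, fixture_tree):
        gm = GenusMap({"A": "gx", "C": "gx", "B": "gB", "D": "gD"})
        table = genus_crown_ages(fixture_tree, gm)
        # A and C only meet at the root.
        assert table.age("gx") == pytest.approx(3.0)

    def test_genus_absent_from_tree_warns(self, fixture_tree):
        gm = GenusMap({"A": "g1", "B": "g1", "C": "g2", "D": "g2", "Z": "gz"})
        with pytest.warns(UserWarning, match="no tips"):
            table = genus_crown_ages(fixture_tree, gm)
        assert "gz" not in table.ages


class TestMdt:
    def test_single_genus(self):
        ages = GenusAgeTable({"g": 10.0})
        assert mdt(CellGenusCounts("c", {"g": 7}), ages) == pytest.approx(10.0)

    def test_equal_weights(self):
        ages = GenusAgeTable({"a": 10.0, "b": 30.0})
        assert mdt(CellGenusCounts("c", {"a": 1, "b": 1}), ages) == pytest.approx(20.0)

    def test_weighted_mean(self):
        ages = GenusAgeTable({"a": 10.0, "b": 20.0, "c": 30.0})
        cell = CellGenusCounts("c", {"a": 1, "b": 2, "c": 3})
        assert mdt(cell, ages) == pytest.approx((10 + 40 + 90) / 6)

    def test_empty_cell_rejected(self):
        with pytest.raises(UndefinedResultError):
            mdt(CellGenusCounts("c", {}), GenusAgeTable({"a": 1.0}))

    @given(
        ages=st.lists(st.floats(0.1, 300.0), min_size=2, max_size=10, unique=True),
        scale=st.integers(2, 9),
    )
    def test_invariant_under_count_scaling(self, ages, scale):
        table = GenusAgeTable({f"g{i}": a for i, a in enumerate(ages)})
        cell1 = CellGenusCounts("c", {f"g{i}": i + 1 for i in range(len(ages))})
        cellk = CellGenusCounts(
            "c", {f"g{i}": (i + 1) * scale for i in range(len(ages))}
        )
        assert mdt(cellk, table) == pytest.approx(mdt(cell1, table))

    @given(ages=st.lists(st.floats(0.1, 300.0), min_size=1, max_size=12))
    def test_equal_counts_give_unweighted_mean(self, ages):
        table = GenusAgeTable({f"g{i}": a for i, a in enumerate(ages)})
        cell = CellGenusCounts("c", {f"g{i}": 3 for i in range(len(ages))})
        assert mdt(cell, table) == pytest.approx(float(np.mean(ages)))
        assert min(ages) - 1e-9 <= mdt(cell, table) <= max(ages) + 1e-9


class TestQuartiles:
    def _cell(self, ages):
        table = GenusAgeTable({f"g{i}": a for i, a in enumerate(ages)})
        cell = CellGenusCounts("c", {f"g{i}": 1 for i in range(len(ages))})
        return cell, table

    def test_eight_genera(self):
        cell, table = self._cell([1, 2, 3, 4, 5, 6, 7, 8])
        q = quartile_mean_ages(cell, table)
        assert q.young_mean == pytest.approx(1.5)
        assert q.old_mean == pytest.approx(7.5)
        assert not q.flagged

    def test_four_genera(self):
        cell, table = self._cell([2, 4, 6, 8])
        q = quartile_mean_ages(cell, table)
        assert (q.young_mean, q.old_mean) == (pytest.approx(2), pytest.approx(8))

    def test_ceiling_rule_five_genera(self):
        cell, table = self._cell([1, 2, 3, 4, 10])
        q = quartile_mean_ages(cell, table)
        assert q.young_mean == pytest.approx(1.5)
        assert q.old_mean == pytest.approx(7.0)

    def test_small_cell_flagged(self):
        cell, table = self._cell([5, 15])
        q = quartile_mean_ages(cell, table)
        assert q.flagged
        assert q.young_mean == q.old_mean == pytest.approx(10.0)

    @given(ages=st.lists(st.floats(0.1, 300.0), min_size=4, max_size=20, unique=True))
    def test_young_below_old_and_within_range(self, ages):
        cell, table = self._cell(ages)
        q = quartile_mean_ages(cell, table)
        assert q.young_mean <= q.old_mean
        assert q.young_mean <= max(ages) and q.old_mean >= min(ages)


class TestSesMdt:
    def test_degenerate_equal_age_pool(self):
        table = GenusAgeTable({f"g{i}": 15.0 for i in range(8)})
        cell = CellGenusCounts("c", {"g0": 1, "g1": 2})
        res = ses_mdt(cell, table, NullConfig(n_reps=99, seed=1))
        assert not res.defined and not res.significant

    def test_oldest_quartile_cell_has_positive_ses(self):
        ages = {f"g{i:02d}": float(5 * (i + 1)) for i in range(12)}  # 5..60 Ma
        table = GenusAgeTable(ages)
        oldest = sorted(ages, key=ages.get)[-3:]
        cell = CellGenusCounts("c", {g: 1 for g in oldest})
        res = ses_mdt(cell, table, NullConfig(n_reps=999, seed=2))
        assert res.ses > 0

    def test_suite_shares_null_stream(self):
        ages = {f"g{i:02d}": float(i + 1) for i in range(20)}
        table = GenusAgeTable(ages)
        cell = CellGenusCounts("c", {g: 1 for g in list(ages)[:8]})
        config = NullConfig(n_reps=199, seed=4)
        suite1 = mdt_ses_suite(cell, table, config, np.random.default_rng(0))
        suite2 = mdt_ses_suite(cell, table, config, np.random.default_rng(0))
        assert suite1 == suite2
        assert suite1.mdt.ses == ses_mdt(cell, table, config, np.random.default_rng(0)).ses

    def test_bias_labels(self):
        ages = {f"g{i:02d}": float(i + 1) for i in range(40)}
        table = GenusAgeTable(ages)
        config = NullConfig(n_reps=999, seed=6)
        oldest = CellGenusCounts("c", {g: 1 for g in sorted(ages, key=ages.get)[-5:]})
        res = ses_mdt(oldest, table, config)
        assert mdt_bias_label(res) == "ancient-biased"
        youngest = CellGenusCounts("c", {g: 1 for g in sorted(ages, key=ages.get)[:5]})
        res = ses_mdt(youngest, table, config)
        assert mdt_bias_label(res) == "young-biased"
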