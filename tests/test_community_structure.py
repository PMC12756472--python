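import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phylogrid.community_structure import (
    classify,
    mntd,
    mpd,
    nri,
    nti,
    patristic_distances,
    structure_ses,
)
from phylogrid.errors import UndefinedResultError
from phylogrid.nullmodels import NullConfig, summarize_ses


def brute_force_patristic(tree, a, b):
    """Independent oracle: sum branch lengths along the a--b path."""
    dtree = tree.dendropy_tree
    label_of = lambda n: n.taxon.label if n.taxon is not None else n.label  # noqa: E731
    leaves = {label_of(l): l for l in dtree.leaf_node_iter()}

    def ancestors(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out

    pa = ancestors(leaves[a])
    pb = ancestors(leaves[b])
    common = next(n for n in pa if n in set(pb))
    dist = 0.0
    for path in (pa, pb):
        for node in path:
            if node is common:
                break
            dist += node.edge.length
    return dist


class TestPatristicDistances:
    def test_fixture_values(self, fixture_tree):
        dm = patristic_distances(fixture_tree)
        assert dm.distance("A", "B") == pytest.approx(2.0)
        assert dm.distance("A", "C") == pytest.approx(6.0)

    def test_symmetric_zero_diagonal(self, yule50):
        dm = patristic_distances(yule50)
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.allclose(np.diag(dm.matrix), 0.0)

    def test_matches_path_sum_oracle(self, six_tip_tree):
        dm = patristic_distances(six_tip_tree)
        for a, b in itertools.combinations(six_tip_tree.tip_labels, 2):
            assert dm.distance(a, b) == pytest.approx(
                brute_force_patristic(six_tip_tree, a, b), abs=1e-9
            )

    def test_cross_check_against_dendropy(self, yule50):
        dm = patristic_distances(yule50)
        pdm = yule50.dendropy_tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in yule50.dendropy_tree.taxon_namespace}
        rng = np.random.default_rng(4)
        labels = yule50.tip_labels
        for _ in range(100):
            a, b = rng.choice(len(labels), 2, replace=False)
            assert dm.matrix[a, b] == pytest.approx(
                pdm.patristic_distance(taxa[labels[a]], taxa[labels[b]]), abs=1e-9
            )


class TestMpdMntd:
    def test_pair_identity(self, fixture_tree):
        dm = patristic_distances(fixture_tree)
        assert mpd({"A", "B"}, dm) == pytest.approx(2.0)
        assert mntd({"A", "B"}, dm) == pytest.approx(2.0)

    def test_three_taxa(self, fixture_tree):
        dm = patristic_distances(fixture_tree)
        assert mpd({"A", "B", "C"}, dm) == pytest.approx((2 + 6 + 6) / 3)
        assert mntd({"A", "B", "C"}, dm) == pytest.approx((2 + 2 + 6) / 3)

    def test_four_taxa(self, fixture_tree):
        dm = patristic_distances(fixture_tree)
        assert mpd({"A", "B", "C", "D"}, dm) == pytest.approx(5.0)
        assert mntd({"A", "B", "C", "D"}, dm) == pytest.approx(3.0)

    def test_single_taxon_rejected(self, fixture_tree):
        dm = patristic_distances(fixture_tree)
        with pytest.raises(UndefinedResultError):
            mpd({"A"}, dm)
        with pytest.raises(UndefinedResultError):
            mntd({"A"}, dm)

    @given(data=st.data())
    def test_order_invariance_and_bounds(self, data, yule50):
        dm = patristic_distances(yule50)
        taxa = data.draw(
            st.sets(st.sampled_from(yule50.tip_labels), min_size=2, max_size=12)
        )
        perm = data.draw(st.permutations(sorted(taxa)))
        assert mpd(taxa, dm) == mpd(perm, dm)
        assert mntd(taxa, dm) == mntd(perm, dm)
        idx = dm.index_of(sorted(taxa))
        max_pair = dm.matrix[np.ix_(idx, idx)].max()
        assert mntd(taxa, dm) <= max_pair + 1e-9


class TestNriNti:
    def test_sister_pair_is_clustered(self, six_tip_tree):
        dm = patristic_distances(six_tip_tree)
        pool = sorted(six_tip_tree.tip_labels)
        config = NullConfig(n_reps=999, seed=1)
        res = nri({"A", "B"}, pool, dm, config)
        assert res.ses > 0

    def test_distant_pair_is_overdispersed(self, six_tip_tree):
        dm = patristic_distances(six_tip_tree)
        pool = sorted(six_tip_tree.tip_labels)
        config = NullConfig(n_reps=999, seed=1)
        res = nri({"A", "E"}, pool, dm, config)
        assert res.ses < 0

    def test_pair_nri_equals_nti_exactly(self, six_tip_tree):
        # MPD == MNTD for two taxa and the null draws are shared, so the
        # two indices must agree exactly, not just statistically.
        dm = patristic_distances(six_tip_tree)
        pool = sorted(six_tip_tree.tip_labels)
        config = NullConfig(n_reps=499, seed=7)
        for taxa in ({"A", "B"}, {"A", "E"}, {"C", "F"}):
            nri_res, nti_res = structure_ses(
                taxa, pool, dm, config, np.random.default_rng(11)
            )
            assert nri_res.ses == nti_res.ses

    def test_standalone_wrappers_match_suite(self, six_tip_tree):
        dm = patristic_distances(six_tip_tree)
        pool = sorted(six_tip_tree.tip_labels)
        config = NullConfig(n_reps=199, seed=2)
        pair = structure_ses({"A", "C", "E"}, pool, dm, config, np.random.default_rng(3))
        assert nri({"A", "C", "E"}, pool, dm, config, np.random.default_rng(3)) == pair[0]
        assert nti({"A", "C", "E"}, pool, dm, config, np.random.default_rng(3)) == pair[1]

    def test_full_pool_degenerate(self, six_tip_tree):
        dm = patristic_distances(six_tip_tree)
        pool = sorted(six_tip_tree.tip_labels)
        res = nri(set(pool), pool, dm, NullConfig(n_reps=99, seed=1))
        assert not res.defined


class TestClassify:
    def _res(self, ses):
        nulls = np.array([-1.0, 0.0, 1.0])
        return summarize_ses(-ses, nulls, sign=-1)  # reported value == ses

    def test_both_positive_significant(self):
        cls = classify(self._res(2.3), self._res(2.0), "c")
        assert cls.category == "both_positive"
        assert cls.nri_significant and cls.nti_significant
        assert cls.interpretation == "habitat_filtering"

    def test_mixed_signs_not_significant(self):
        cls = classify(self._res(-0.5), self._res(0.3), "c")
        assert cls.category == "nri_neg_nti_pos"
        assert not cls.nri_significant and not cls.nti_significant
        assert cls.interpretation == "random"

    def test_boundary_not_significant(self):
        cls = classify(self._res(-1.96), self._res(-1.96), "c")
        assert cls.category == "both_negative"
        assert not cls.nri_significant and not cls.nti_significant

    def test_both_negative_significant(self):
        cls = classify(self._res(-2.5), self._res(-2.1), "c")
        assert cls.interpretation == "competitive_exclusion"

    def test_undefined_inputs(self):
        nulls = np.full(5, 3.0)
        undef = summarize_ses(3.0, nulls)
        cls = classify(undef, undef, "c")
        assert cls.category == "undefined"
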