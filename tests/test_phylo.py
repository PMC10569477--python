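import dendropy
import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from degenmix.core import SequenceError, SequenceRecord
from degenmix.fixtures import FamilySpec, random_additive_tree, simulate_gene_family
from degenmix.phylo import (
    clade_recovery_fraction,
    nj_tree,
    pairwise_pdistance,
    rf_distance,
)

from tests_util import _GapRecord


def _recs(seqs):
    return [_GapRecord(id=f"s{i + 1}", seq=s) for i, s in enumerate(seqs)]


class TestPDistance:
    def test_identical_sequences(self):
        dm = pairwise_pdistance(_recs(["ACGT", "ACGT"]))
        assert dm["s1", "s2"] == 0.0

    def test_single_difference(self):
        dm = pairwise_pdistance(_recs(["AAAA", "AAAT"]))
        assert dm["s1", "s2"] == 0.25

    def test_gap_positions_excluded_pairwise(self):
        dm = pairwise_pdistance(_recs(["A-CG", "ATCG"]))
        assert dm["s1", "s2"] == 0.0

    def test_no_comparable_sites_is_an_error(self):
        with pytest.raises(SequenceError, match="s1.*s2"):
            pairwise_pdistance(_recs(["A---", "-TTT"]))


def _quartet_dm():
    # additive distances from the tree ((a:1,b:2):1,(c:3,d:4));
    return DistanceMatrix(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        ["a", "b", "c", "d"],
    )


class TestNJ:
    def test_recovers_quartet_topology_and_path_lengths(self):
        tree = nj_tree(_quartet_dm())
        truth = TreeNode.read(["((a:1,b:2):1,(c:3,d:4):0);"])
        assert rf_distance(tree, truth) == 0
        # additive input: patristic distances are reproduced exactly
        got = tree.tip_tip_distances()
        dm = _quartet_dm()
        for x in "abcd":
            for y in "abcd":
                if x != y:
                    assert got[x, y] == pytest.approx(dm[x, y])

    def test_three_taxa_star(self):
        dm = DistanceMatrix([[0, 2, 3], [2, 0, 5], [3, 5, 0]], list("abc"))
        tree = nj_tree(dm)
        assert sorted(t.name for t in tree.tips()) == ["a", "b", "c"]
        got = tree.tip_tip_distances()
        assert got["a", "b"] == pytest.approx(2.0)
        assert got["b", "c"] == pytest.approx(5.0)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(SequenceError):
            nj_tree(DistanceMatrix([[0, 1], [1, 0]], ["a", "b"]))

    def test_deterministic_under_input_permutation(self):
        _, dm = random_additive_tree(7, seed=9)
        ids = list(dm.ids)
        perm = [ids[i] for i in [3, 0, 6, 2, 5, 1, 4]]
        t1 = nj_tree(dm)
        t2 = nj_tree(dm.filter(perm))
        assert rf_distance(t1, t2) == 0
        assert str(t1) == str(t2)

    @pytest.mark.parametrize("seed", range(10))
    def test_consistency_on_additive_matrices(self, seed):
        n = 5 + seed % 5
        truth, dm = random_additive_tree(n, seed=seed)
        assert rf_distance(nj_tree(dm), truth) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_skbio_reference_nj(self, seed):
        _, dm = random_additive_tree(8, seed=50 + seed)
        assert rf_distance(nj_tree(dm), skbio_nj(dm)) == 0


def _dendropy_rf(newick_a, newick_b):
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)


class TestRF:
    def test_identical_trees(self):
        t = TreeNode.read(["((a,b),(c,d));"])
        u = TreeNode.read(["((a,b),(c,d));"])
        assert rf_distance(t, u) == 0

    def test_distinct_quartet_topologies(self):
        t = TreeNode.read(["((a,b),(c,d));"])
        u = TreeNode.read(["((a,c),(b,d));"])
        assert rf_distance(t, u) == 2

    def test_caterpillar_vs_balanced_matches_dendropy(self):
        cat = "(a,(b,(c,(d,(e,f)))));"
        bal = "((a,(b,c)),(d,(e,f)));"
        got = rf_distance(TreeNode.read([cat]), TreeNode.read([bal]))
        assert got == _dendropy_rf(cat, bal)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dendropy_on_random_trees(self, seed):
        ta, _ = random_additive_tree(7, seed=seed)
        tb, _ = random_additive_tree(7, seed=100 + seed)
        na, nb = str(ta), str(tb)
        assert rf_distance(ta, tb) == _dendropy_rf(na, nb)

    def test_metric_properties(self):
        trees = [random_additive_tree(6, seed=s)[0] for s in range(4)]
        for a in trees:
            assert rf_distance(a, a) == 0
        for a in trees:
            for b in trees:
                assert rf_distance(a, b) == rf_distance(b, a)
        for a in trees:
            for b in trees:
                for c in trees:
                    assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)

    def test_leaf_set_mismatch_is_an_error(self):
        t = TreeNode.read(["((a,b),(c,d));"])
        u = TreeNode.read(["((a,b),(c,e));"])
        with pytest.raises(SequenceError, match="only in"):
            rf_distance(t, u)


def test_amplicon_tree_recovers_clades_better_with_longer_fragments():
    """Clade recovery from p-distance NJ improves with fragment length."""
    clades = [[0, 1, 2], [3, 4, 5], [6, 7, 8], [9, 10, 11]]
    spec = FamilySpec(
        n_taxa=12,
        gene_length=900,
        conserved_blocks=[],
        background_divergence=0.4,
        clade_structure=clades,
        seed=7,
    )
    aln, _, tree = simulate_gene_family(spec)

    def recovery(n_cols):
        frags = [
            SequenceRecord(id=r.id, seq=r.seq[:n_cols]) for r in aln.records
        ]
        t = nj_tree(pairwise_pdistance(frags))
        return _clade_score(t, clades, aln)

    short, full = recovery(150), recovery(900)
    assert full >= short
    assert full >= 0.75


def _clade_score(tree, clades, aln):
    """Fraction of generating clades appearing as exact bipartitions."""
    from degenmix.phylo import _bipartitions

    bip = _bipartitions(tree)
    names = [r.id for r in aln.records]
    hits = 0
    for clade in clades:
        want = frozenset(names[i] for i in clade)
        comp = frozenset(names) - want
        if want in bip or comp in bip:
            hits += 1
    return hits / len(clades)
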