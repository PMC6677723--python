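"""Distance models, neighbor joining, bootstrap, rooting, and conserved
pol-region extraction, checked against closed forms and independent
oracles (exhaustive least-squares topology search, scikit-bio's NJ)."""

import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from conftest import dendropy_splits, least_squares_best_topology, topology_splits
from retronest import phylo
from retronest import synthetic_data as sd
from retronest.core_io import SequenceRecord
from retronest.phylo import DistanceMatrix, MsAlignment


def _mutant_alignment(n_taxa, ncols, rate, seed):
    rng = np.random.default_rng(seed)
    anc = sd.random_seq(ncols, rng)
    rows = [sd.mutate_seq(SequenceRecord("a", anc), rate, rng).seq for _ in range(n_taxa)]
    return MsAlignment([f"t{i}" for i in range(n_taxa)], rows)


class TestMlDistance:
    def test_identical_rows_zero(self):
        aln = MsAlignment(["a", "b"], ["ACGTACGT", "ACGTACGT"])
        assert phylo.ml_distance(aln).matrix[0, 1] == 0.0

    def test_jc69_matches_closed_form_on_counted_p(self):
        aln = _mutant_alignment(4, 3000, 0.04, seed=1)
        D = phylo.ml_distance(aln, model="JC69")
        for i in range(4):
            for j in range(i + 1, 4):
                p = sum(1 for x, y in zip(aln.seqs[i], aln.seqs[j]) if x != y) / 3000
                expected = -0.75 * math.log(1 - 4 * p / 3)
                assert abs(D.matrix[i, j] - expected) < 1e-9

    def test_jc69_hand_computed_value(self):
        # p = 0.10 -> d = -(3/4) ln(1 - 4*0.1/3) ~= 0.10732
        row_a = "A" * 100
        row_b = "C" * 10 + "A" * 90
        D = phylo.ml_distance(MsAlignment(["a", "b"], [row_a, row_b]))
        assert D.matrix[0, 1] == pytest.approx(0.1073256, abs=1e-6)

    def test_saturation_flagged_and_capped(self):
        row_a = "A" * 100
        row_b = "C" * 75 + "A" * 25  # p = 0.75: JC69 boundary
        D = phylo.ml_distance(MsAlignment(["a", "b"], [row_a, row_b]))
        assert D.matrix[0, 1] == phylo.SATURATION_CAP
        assert ("a", "b") in D.saturated

    def test_k80_transition_transversion_split(self):
        # 8% transitions (A<->G), 4% transversions (A<->C) over 1000 columns
        a = "A" * 1000
        b = "G" * 80 + "C" * 40 + "A" * 880
        D = phylo.ml_distance(MsAlignment(["a", "b"], [a, b]), model="K80")
        P, Q = 0.08, 0.04
        expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert D.matrix[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_gap_only_overlap_errors(self):
        aln = MsAlignment(["a", "b"], ["AC--", "--GT"])
        with pytest.raises(ValueError, match="no comparable columns"):
            phylo.ml_distance(aln)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
        tree = phylo.nj_tree(D)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_additive_matrix_recovery_with_ls_oracle(self):
        taxa = list("ABCDE")
        gen = phylo.random_tree(taxa, rng=7)
        D = phylo.tree_distance_matrix(gen)
        nj = phylo.nj_tree(D)
        # topology matches the generating tree ...
        assert dendropy_splits(nj) == dendropy_splits(gen) or _rf(nj, gen) == 0
        # ... and the exhaustive least-squares search agrees
        best_edges, sse = least_squares_best_topology(D)
        assert sse < 1e-18
        assert topology_splits(best_edges, taxa) == dendropy_splits_unrooted(nj, taxa)
        # path lengths reproduce the input matrix exactly
        D2 = phylo.tree_distance_matrix(nj)
        order = [D2.taxa.index(t) for t in D.taxa]
        assert np.abs(D.matrix - D2.matrix[np.ix_(order, order)]).max() < 1e-9

    def test_tie_broken_lexicographically(self):
        # all distances equal: every Q is tied; the first pair (A, B) joins
        D = DistanceMatrix(list("ABCD"), 2.0 * (1 - np.eye(4)))
        tree = phylo.nj_tree(D)
        splits = dendropy_splits_unrooted(tree, list("ABCD"))
        assert frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})}) in splits

    def test_non_symmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(list("ABC"), m)

    def test_fewer_than_three_taxa_rejected(self):
        D = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]]))
        with pytest.raises(ValueError, match="three taxa"):
            phylo.nj_tree(D)

    def test_recovery_property_over_random_trees(self):
        rng = np.random.default_rng(100)
        for _ in range(10):
            n = int(rng.integers(5, 9))
            taxa = [f"t{i}" for i in range(n)]
            gen = phylo.random_tree(taxa, rng)
            D = phylo.tree_distance_matrix(gen)
            nj = phylo.nj_tree(D)
            assert _rf(nj, gen) == 0
            D2 = phylo.tree_distance_matrix(nj)
            order = [D2.taxa.index(t) for t in D.taxa]
            assert np.abs(D.matrix - D2.matrix[np.ix_(order, order)]).max() < 1e-9

    def test_agrees_with_scikit_bio(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        gen = phylo.random_tree(list("ABCDEF"), rng=13)
        D = phylo.tree_distance_matrix(gen)
        ours = phylo.nj_tree(D)
        theirs = skbio_nj(SkbioDM(D.matrix, ids=D.taxa))
        theirs_dp = dendropy.Tree.get(data=str(theirs).replace("root", ""),
                                      schema="newick",
                                      taxon_namespace=ours.taxon_namespace)
        assert _rf(ours, theirs_dp) == 0


def _rf(t1, t2):
    tns = t1.taxon_namespace
    if t2.taxon_namespace is not tns:
        t2 = dendropy.Tree.get(data=t2.as_string(schema="newick"),
                               schema="newick", taxon_namespace=tns)
    t1b = t1.clone(depth=1)
    t1b.encode_bipartitions()
    t2.encode_bipartitions()
    return treecompare.symmetric_difference(t1b, t2)


def dendropy_splits_unrooted(tree, taxa):
    return dendropy_splits(tree)


class TestBootstrap:
    def test_clear_split_has_high_support(self):
        rng = np.random.default_rng(3)
        a = sd.random_seq(500, rng)
        b = sd.mutate_seq(SequenceRecord("x", a), 0.40, rng).seq
        aln = MsAlignment(
            ["a1", "a2", "b1", "b2"],
            [a,
             sd.mutate_seq(SequenceRecord("x", a), 0.02, rng).seq,
             b,
             sd.mutate_seq(SequenceRecord("x", b), 0.02, rng).seq])
        tree = phylo.bootstrap_support(aln, n_reps=200, seed=5)
        assert len(tree.bootstrap_supports) == 1
        assert list(tree.bootstrap_supports.values())[0] >= 99.0

    def test_single_replicate_support_in_zero_or_hundred(self):
        aln = _mutant_alignment(5, 300, 0.1, seed=9)
        tree = phylo.bootstrap_support(aln, n_reps=1, seed=2)
        assert set(tree.bootstrap_supports.values()) <= {0.0, 100.0}

    def test_deterministic_given_seed(self):
        aln = _mutant_alignment(5, 300, 0.1, seed=9)
        s1 = phylo.bootstrap_support(aln, n_reps=25, seed=4).bootstrap_supports
        s2 = phylo.bootstrap_support(aln, n_reps=25, seed=4).bootstrap_supports
        assert s1 == s2

    def test_star_alignment_reports_no_bipartition(self):
        aln = MsAlignment([f"t{i}" for i in range(5)], ["ACGTACGT"] * 5)
        tree = phylo.bootstrap_support(aln, n_reps=10, seed=1)
        assert tree.bootstrap_supports == {}

    def test_zero_replicates_rejected(self):
        aln = _mutant_alignment(4, 100, 0.1, seed=1)
        with pytest.raises(ValueError, match="n_reps"):
            phylo.bootstrap_support(aln, n_reps=0, seed=1)


class TestRooting:
    def test_three_taxon_outgroup_rooting(self):
        D = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
        tree = phylo.nj_tree(D)
        rooted = phylo.root_tree(tree, "A")
        children = rooted.seed_node.child_nodes()
        assert len(children) == 2
        sides = [{l.taxon.label for l in c.leaf_iter()} for c in children]
        assert {"A"} in sides

    def test_root_then_unroot_round_trip(self):
        gen = phylo.random_tree(list("ABCDE"), rng=21)
        D = phylo.tree_distance_matrix(gen)
        tree = phylo.nj_tree(D)
        rooted = phylo.root_tree(tree, "C")
        rooted.deroot()
        assert _rf(tree, rooted) == 0

    def test_ingroup_monophyly_preserved(self):
        tns_taxa = ["out", "i1", "i2", "i3", "i4"]
        gen = phylo.random_tree(tns_taxa, rng=33)
        D = phylo.tree_distance_matrix(gen)
        rooted = phylo.root_tree(phylo.nj_tree(D), "out")
        children = rooted.seed_node.child_nodes()
        sides = [{l.taxon.label for l in c.leaf_iter()} for c in children]
        assert {"out"} in sides
        assert {"i1", "i2", "i3", "i4"} in sides

    def test_unknown_outgroup_errors(self):
        gen = phylo.random_tree(list("ABC"), rng=2)
        tree = phylo.nj_tree(phylo.tree_distance_matrix(gen))
        with pytest.raises(ValueError, match="not among leaves"):
            phylo.root_tree(tree, "Z")


class TestConservedPolExtraction:
    def _anchor(self, seed=50):
        rng = np.random.default_rng(seed)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        return SequenceRecord(
            "anchor", "".join(np.array(list(aa))[rng.integers(0, 20, 300)]), "aa")

    def test_identity_alignment_extracts_anchor_subsequence(self):
        anchor = self._anchor()
        out = phylo.extract_conserved_pol(anchor, anchor)
        expected = "".join(anchor.seq[f - 1:l] for f, l in phylo.DEFAULT_POL_REGIONS)
        assert out.seq == expected

    def test_insertion_in_query_does_not_change_extraction(self):
        anchor = self._anchor()
        query = SequenceRecord("q", anchor.seq[:150] + "W" * 10 + anchor.seq[150:], "aa")
        out = phylo.extract_conserved_pol(query, anchor)
        expected = "".join(anchor.seq[f - 1:l] for f, l in phylo.DEFAULT_POL_REGIONS)
        assert out.seq == expected

    def test_short_query_skips_uncovered_region(self, caplog):
        anchor = self._anchor()
        query = SequenceRecord("q", anchor.seq[120:], "aa")
        with caplog.at_level("WARNING"):
            out = phylo.extract_conserved_pol(query, anchor)
        assert "skipped" in caplog.text
        covered = [(f, l) for f, l in phylo.DEFAULT_POL_REGIONS if f > 120]
        expected = "".join(anchor.seq[f - 1:l] for f, l in covered)
        assert out.seq == expected

    def test_region_outside_anchor_rejected(self):
        anchor = self._anchor()
        with pytest.raises(ValueError, match="outside anchor"):
            phylo.extract_conserved_pol(anchor, anchor, regions=[(250, 400)])


def test_center_star_alignment_round_trip():
    rng = np.random.default_rng(71)
    anc = sd.random_seq(300, rng)
    recs = [SequenceRecord(f"s{i}", sd.mutate_seq(
        SequenceRecord("a", anc), 0.03, rng).seq) for i in range(4)]
    aln = phylo.align_center_star(recs)
    assert len({len(s) for s in aln.seqs}) == 1
    # degapping returns the input sequences unchanged
    for rec, row in zip(recs, aln.seqs):
        assert row.replace("-", "") == rec.seq
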