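"""Alignment, distance, and tree construction against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbh3kit.align_phylo import (
    DistanceMatrix,
    distance_matrix,
    get_blosum62,
    global_align,
    midpoint_root,
    neighbor_joining,
    p_distance,
    progressive_msa,
)
from rbh3kit.formats import ProteinSequence
from rbh3kit.synthetic_data import simulate_tree
from rbh3kit.tree import Tree, parse_newick, write_newick

AA = "ACDEFGHIKLMNPQRSTVWY"
seq_text = st.text(alphabet=AA, min_size=1, max_size=7)


def brute_force_align_score(s1, s2, matrix, gap_open, gap_extend):
    """Exhaustive enumeration of every gapped alignment (affine cost)."""
    best = -math.inf

    def rec(i, j, last, acc):
        nonlocal best
        if i == len(s1) and j == len(s2):
            best = max(best, acc)
            return
        if i < len(s1) and j < len(s2):
            rec(i + 1, j + 1, "M", acc + matrix.score(s1[i], s2[j]))
        if i < len(s1):
            cost = gap_extend if last == "X" else gap_open + gap_extend
            rec(i + 1, j, "X", acc - cost)
        if j < len(s2):
            cost = gap_extend if last == "Y" else gap_open + gap_extend
            rec(i, j + 1, "Y", acc - cost)

    rec(0, 0, None, 0.0)
    return best


class TestScoring:
    @pytest.mark.parametrize("a,b,expected", [("D", "E", 2), ("A", "A", 4)])
    def test_canonical_blosum62_entries(self, blosum, a, b, expected):
        assert blosum.score(a, b) == expected

    def test_symmetry_over_full_alphabet(self, blosum):
        for a, b in itertools.combinations(AA, 2):
            assert blosum.score(a, b) == blosum.score(b, a)

    def test_x_scores_zero(self, blosum):
        assert all(blosum.score("X", aa) == 0 for aa in AA + "X")

    def test_unknown_residue_rejected(self, blosum):
        with pytest.raises(ValueError, match="unknown residue"):
            blosum.score("D", "B")


class TestGlobalAlign:
    def test_identity_alignment(self, blosum):
        pw = global_align("MKV", "MKV")
        assert pw.aligned1 == pw.aligned2 == "MKV"
        assert pw.score == sum(blosum.score(c, c) for c in "MKV")

    def test_single_terminal_gap_charged_open_plus_extend(self, blosum):
        pw = global_align("M", "MK", gap_open=10, gap_extend=1)
        assert pw.score == blosum.score("M", "M") - 11

    def test_rows_recover_inputs_and_no_gap_gap_column(self):
        pw = global_align("MKVLWA", "MVLW")
        assert pw.aligned1.replace("-", "") == "MKVLWA"
        assert pw.aligned2.replace("-", "") == "MVLW"
        assert all(c != ("-", "-") for c in zip(pw.aligned1, pw.aligned2))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "MK")

    @given(seq_text, seq_text)
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_enumeration(self, s1, s2):
        blosum = get_blosum62()
        expected = brute_force_align_score(s1, s2, blosum, 10.0, 1.0)
        assert global_align(s1, s2).score == expected


class TestPDistance:
    def test_identical_rows(self):
        assert p_distance("MKVL", "MKVL") == 0.0

    def test_gap_columns_excluded(self):
        assert p_distance("MK-V", "MR-V") == pytest.approx(1 - 2 / 3)

    def test_no_comparable_columns_degenerates_to_one(self):
        assert p_distance("M---", "-AAA") == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            p_distance("MK", "MKV")

    @given(st.text(alphabet=AA + "-", min_size=1, max_size=30).filter(
        lambda s: s.strip("-")), st.data())
    @settings(max_examples=50, deadline=None)
    def test_semimetric_properties(self, row, data):
        other = data.draw(
            st.text(alphabet=AA + "-", min_size=len(row), max_size=len(row))
        )
        assert p_distance(row, row) == 0.0
        d = p_distance(row, other)
        assert 0.0 <= d <= 1.0
        assert d == p_distance(other, row)


class TestDistanceMatrix:
    def test_identical_sequences_give_zeros(self):
        seqs = [ProteinSequence(f"s{i}", "MKVLW") for i in range(3)]
        dm = distance_matrix(seqs)
        assert np.allclose(dm.matrix, 0.0)

    def test_engineered_mismatch_counts(self):
        from rbh3kit.formats import Alignment

        rows = [
            ProteinSequence("a", "MKVL"),
            ProteinSequence("b", "MKVW"),  # 1/4 vs a
            ProteinSequence("c", "MRAW"),  # 3/4 vs a, 2/4 vs b
            ProteinSequence("d", "MKVL"),  # 0 vs a
        ]
        dm = distance_matrix(Alignment(rows))
        idx = {i: k for k, i in enumerate(dm.ids)}
        assert dm.matrix[idx["a"], idx["b"]] == pytest.approx(0.25)
        assert dm.matrix[idx["a"], idx["c"]] == pytest.approx(0.75)
        assert dm.matrix[idx["b"], idx["c"]] == pytest.approx(0.5)
        assert dm.matrix[idx["a"], idx["d"]] == 0.0

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            distance_matrix([ProteinSequence("a", "MK"), ProteinSequence("b", "MK")])


def _additive_matrix(tree: Tree) -> DistanceMatrix:
    labels = sorted(tree.leaf_labels())
    dists = tree.leaf_distances()
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            b = labels[j]
            D[i, j] = D[j, i] = dists[(a, b) if a < b else (b, a)]
    return DistanceMatrix(labels, D)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        t = neighbor_joining(DistanceMatrix(["a", "b", "c"], D))
        bl = {n.label: n.branch_length for n in t.leaves()}
        assert bl["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert bl["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert bl["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_exact_recovery_on_additive_matrices(self, n_taxa):
        """Four-point-condition oracle: patristic distances from a known
        tree must be reproduced exactly, topology and branch lengths."""
        for seed in range(10):
            true = simulate_tree(n_taxa, seed)
            recovered = neighbor_joining(_additive_matrix(true))
            assert recovered.bipartitions() == true.bipartitions()
            want = true.leaf_distances()
            got = recovered.leaf_distances()
            for pair, d in want.items():
                assert got[pair] == pytest.approx(d, abs=1e-9)

    def test_all_equal_distances_deterministic_tie_break(self):
        D = np.ones((4, 4)) - np.eye(4)
        ids = ["a", "b", "c", "d"]
        first = write_newick(neighbor_joining(DistanceMatrix(ids, D)))
        again = write_newick(neighbor_joining(DistanceMatrix(ids, D)))
        assert first == again
        # lowest-index pair (a, b) joined first
        t = neighbor_joining(DistanceMatrix(ids, D))
        assert t.bipartitions() == {frozenset({"a", "b"})}

    def test_invalid_matrices_rejected(self):
        bad = DistanceMatrix(["a", "b", "c"], np.array(
            [[0, 1, 2], [1, 0, 3], [2, 3.5, 0]]))
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(bad)
        neg = DistanceMatrix(["a", "b", "c"], np.array(
            [[0, -1, 2], [-1, 0, 3], [2, 3, 0]]))
        with pytest.raises(ValueError, match="negative"):
            neighbor_joining(neg)

    def test_agrees_with_skbio_topology(self, default_family):
        """Independent oracle: scikit-bio's NJ on the same p-distance
        matrix must give the same unrooted topology."""
        import skbio
        from skbio.tree import nj as skbio_nj

        aln, _ = default_family
        dm = distance_matrix(aln)
        ours = neighbor_joining(dm)
        sk_tree = skbio_nj(skbio.DistanceMatrix(dm.matrix, ids=dm.ids))
        names = set(dm.ids)
        sk_splits = set()
        for node in sk_tree.non_tips():
            clade = frozenset(t.name for t in node.tips())
            other = frozenset(names - clade)
            if len(clade) >= 2 and len(other) >= 2:
                sk_splits.add(min(clade, other, key=lambda s: (len(s), sorted(s))))
        assert ours.bipartitions() == sk_splits


class TestMidpointRoot:
    def test_two_leaf_closed_form(self):
        rooted = midpoint_root(parse_newick("(a:1,b:3);"))
        depths = {n.label: n.branch_length for n in rooted.leaves()}
        assert depths["a"] == pytest.approx(2.0)
        assert depths["b"] == pytest.approx(2.0)

    @pytest.mark.parametrize("n_taxa,seed", [(4, 0), (6, 3), (10, 7), (16, 11)])
    def test_root_bisects_diameter_path(self, n_taxa, seed):
        """All-pairs path-length oracle: the deepest two leaf depths from
        the root equal half the tree diameter."""
        tree = simulate_tree(n_taxa, seed)
        diameter = max(tree.leaf_distances().values())
        rooted = midpoint_root(tree)

        depths = {}

        def walk(node, acc):
            if node.is_leaf:
                depths[node.label] = acc
            for child in node.children:
                walk(child, acc + child.branch_length)

        walk(rooted.root, 0.0)
        deepest = sorted(depths.values())[-2:]
        assert deepest[0] == pytest.approx(diameter / 2, abs=1e-9)
        assert deepest[1] == pytest.approx(diameter / 2, abs=1e-9)
        # patristic distances are preserved by rerooting
        want = tree.leaf_distances()
        got = rooted.leaf_distances()
        for pair, d in want.items():
            assert got[pair] == pytest.approx(d, abs=1e-9)

    def test_balanced_tree_depths_unchanged(self):
        rooted = midpoint_root(parse_newick("((a:1,b:1):1,(c:1,d:1):1);"))
        depths = {n.label: None for n in rooted.leaves()}

        def walk(node, acc):
            if node.is_leaf:
                depths[node.label] = acc
            for child in node.children:
                walk(child, acc + child.branch_length)

        walk(rooted.root, 0.0)
        assert all(d == pytest.approx(2.0) for d in depths.values())

    def test_all_zero_lengths_deterministic(self):
        t1 = midpoint_root(parse_newick("(b:0,(a:0,c:0):0,d:0);"))
        t2 = midpoint_root(parse_newick("(b:0,(a:0,c:0):0,d:0);"))
        assert write_newick(t1) == write_newick(t2)


class TestProgressiveMSA:
    def _guide(self, seqs):
        return neighbor_joining(distance_matrix(seqs))

    def test_identical_sequences_align_gap_free(self):
        seqs = [ProteinSequence(f"s{i}", "MKVLWAD") for i in range(3)]
        msa = progressive_msa(seqs, self._guide(seqs))
        assert all(r.residues == "MKVLWAD" for r in msa.rows)

    def test_single_internal_deletion_becomes_one_gap_column(self):
        seqs = [
            ProteinSequence("a", "MKVWADLE"),
            ProteinSequence("b", "MKVWADLE"),
            ProteinSequence("c", "MKVADLE"),  # W deleted
        ]
        msa = progressive_msa(seqs, self._guide(seqs))
        assert msa.n_columns == 8
        assert msa.row("c").residues == "MKV-ADLE"

    def test_degapping_recovers_inputs(self, default_family):
        aln, _ = default_family
        seqs = [r.degapped() for r in aln.rows][:10]
        msa = progressive_msa(seqs, self._guide(seqs))
        by_id = {s.id: s.residues for s in seqs}
        for row in msa.rows:
            assert row.residues.replace("-", "") == by_id[row.id]

    def test_leaf_mismatch_rejected(self):
        seqs = [ProteinSequence(f"s{i}", "MKVL") for i in range(3)]
        guide = neighbor_joining(distance_matrix(
            [ProteinSequence(f"t{i}", "MKVL") for i in range(3)]))
        with pytest.raises(ValueError, match="leaves do not match"):
            progressive_msa(seqs, guide)
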