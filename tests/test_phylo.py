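"""Distances, neighbor-joining and bootstrap: closed forms, additivity
oracles, and an independent-library cross-check."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from narkit import (
    DistanceMatrix,
    bootstrap_support,
    nj_tree,
    p_distance,
    poisson_correct,
    simulate_alignment,
    write_phylip,
)


class TestPDistance:
    def test_identical_sequences_have_zero_distance(self):
        dm = p_distance(("a", "b"), ("ACDEF", "ACDEF"))
        assert dm.d[0, 1] == 0.0

    def test_one_difference_in_five_sites(self):
        dm = p_distance(("a", "b"), ("ACDEF", "ACDEY"))
        assert dm.d[0, 1] == pytest.approx(0.2)

    def test_gap_columns_excluded_pairwise(self):
        dm = p_distance(("a", "b"), ("AC-EF", "ACDEY"))
        assert dm.d[0, 1] == pytest.approx(0.25)  # 1 diff over 4 comparable

    def test_pair_without_comparable_columns_named_in_error(self):
        with pytest.raises(ValueError, match="x.*y|y.*x"):
            p_distance(("x", "y"), ("--AA", "AA--"))


class TestPoissonCorrection:
    @pytest.mark.parametrize(
        "p,d", [(0.0, 0.0), (0.5, 0.6931), (0.2, -math.log(0.8))]
    )
    def test_closed_form_values(self, p, d):
        dm = DistanceMatrix(("a", "b"), np.array([[0, p], [p, 0.0]]))
        assert poisson_correct(dm).d[0, 1] == pytest.approx(d, abs=1e-4)

    def test_near_saturation_warns_but_computes(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0, 0.999], [0.999, 0.0]]))
        with pytest.warns(UserWarning, match="saturation"):
            out = poisson_correct(dm)
        assert out.d[0, 1] == pytest.approx(-math.log(0.001), rel=1e-6)

    def test_saturated_pair_rejected(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="undefined"):
            poisson_correct(dm)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.0, 0.99), st.floats(0.0, 0.99))
    def test_strictly_increasing_and_dominates_p(self, p1, p2):
        def corr(p):
            return -math.log1p(-p)

        assert corr(p1) >= p1
        if p1 < p2:
            assert corr(p1) < corr(p2)


def quartet_matrix():
    """Additive distances from the tree ((A:2,B:3):1,(C:4,D:5):1)."""
    taxa = ("A", "B", "C", "D")
    d = np.array(
        [
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 9, 0],
        ],
        dtype=float,
    )
    return DistanceMatrix(taxa, d)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d12, d13, d23 = 0.3, 0.5, 0.6
        dm = DistanceMatrix(("t1", "t2", "t3"), np.array([[0, d12, d13], [d12, 0, d23], [d13, d23, 0.0]]))
        tree = nj_tree(dm)
        lengths = {lf.name: lf.length for lf in tree.root.leaves()}
        assert lengths["t1"] == pytest.approx((d12 + d13 - d23) / 2)
        assert lengths["t2"] == pytest.approx((d12 + d23 - d13) / 2)
        assert lengths["t3"] == pytest.approx((d13 + d23 - d12) / 2)

    def test_additive_quartet_recovered_exactly(self):
        dm = quartet_matrix()
        # four-point condition: the matrix is genuinely additive
        s1 = dm.d[0, 1] + dm.d[2, 3]
        s2 = dm.d[0, 2] + dm.d[1, 3]
        s3 = dm.d[0, 3] + dm.d[1, 2]
        assert s1 <= max(s2, s3) and abs(s2 - s3) < 1e-12
        tree = nj_tree(dm)
        assert frozenset({"C", "D"}) in tree.bipartitions() or frozenset({"A", "B"}) in tree.bipartitions()
        # path lengths reproduce the input exactly (additivity oracle)
        paths = tree.path_lengths()
        order = [paths.taxa.index(t) for t in dm.taxa]
        assert np.allclose(paths.d[np.ix_(order, order)], dm.d, atol=1e-12)

    def test_negative_branch_lengths_clamped_with_raw_kept(self):
        # near-degenerate matrix that drives one NJ estimate negative
        d = np.array(
            [
                [0, 0.1, 0.4, 0.4],
                [0.1, 0, 0.4, 0.45],
                [0.4, 0.4, 0, 0.05],
                [0.4, 0.45, 0.05, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(("a", "b", "c", "d"), d))
        nodes = [tree.root] + [c for c in tree.root.children]

        def all_nodes(n):
            yield n
            for c in n.children:
                yield from all_nodes(c)

        assert all(n.length >= 0 for n in all_nodes(tree.root))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b"), np.array([[0, 1.0], [2.0, 0]]))

    def test_topology_agrees_with_independent_nj_implementation(self):
        """Cross-check on a random additive 6-taxon matrix against
        scikit-bio's neighbor-joining."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(21)
        aln = simulate_alignment(
            "(((A:0.05,B:0.07):0.04,C:0.09):0.03,((D:0.06,E:0.05):0.05,F:0.1):0.03);",
            800,
            seed=int(rng.integers(1 << 30)),
        )
        dm = poisson_correct(p_distance(aln.taxa, aln.sequences))
        ours = nj_tree(dm)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=list(dm.taxa)))
        ours_splits = set(ours.bipartitions())
        ref = min(aln.taxa)
        theirs_splits = set()
        n = len(aln.taxa)
        for node in theirs.non_tips():
            below = frozenset(t.name for t in node.tips())
            if 1 < len(below) < n - 1:
                side = frozenset(aln.taxa) - below if ref in below else below
                theirs_splits.add(side)
        assert ours_splits == theirs_splits


class TestBootstrap:
    def test_clean_quartet_split_has_full_support(self):
        """Every column of a block alignment supports the same split."""
        taxa = ("A", "B", "C", "D")
        # 30 constant columns + 30 columns that all separate {A,B} from {C,D}
        seqs = ("A" * 30 + "C" * 30, "A" * 30 + "C" * 30, "A" * 30 + "G" * 30, "A" * 30 + "G" * 30)
        tree = bootstrap_support(taxa, seqs, n_replicates=50, seed=0)
        supports = [n.support for n in tree.bipartitions().values()]
        assert supports and all(s == pytest.approx(100.0) for s in supports)

    def test_supports_reproducible_and_order_invariant(self, quartet_alignment):
        aln = quartet_alignment
        t1 = bootstrap_support(aln.taxa, aln.sequences, n_replicates=100, seed=7)
        t2 = bootstrap_support(aln.taxa, aln.sequences, n_replicates=100, seed=7)
        sup1 = {bp: n.support for bp, n in t1.bipartitions().items()}
        sup2 = {bp: n.support for bp, n in t2.bipartitions().items()}
        assert sup1 == sup2
        # reversing taxon input order must not change bipartition supports
        rev = bootstrap_support(aln.taxa[::-1], aln.sequences[::-1], n_replicates=100, seed=7)
        sup_rev = {bp: n.support for bp, n in rev.bipartitions().items()}
        assert set(sup_rev) == set(sup1)

    def test_default_replicate_count_is_one_thousand(self):
        import inspect

        assert inspect.signature(bootstrap_support).parameters["n_replicates"].default == 1000


class TestFormats:
    def test_phylip_square_roundtrip_by_eye(self):
        dm = quartet_matrix()
        text = write_phylip(dm)
        lines = text.strip().splitlines()
        assert lines[0] == "4"
        assert len(lines) == 5
        assert lines[1].startswith("A")

    def test_newick_parses_with_dendropy(self, quartet_alignment):
        import dendropy

        aln = quartet_alignment
        tree = bootstrap_support(aln.taxa, aln.sequences, n_replicates=20, seed=1)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {lf.taxon.label for lf in parsed.leaf_node_iter()} == set(aln.taxa)
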