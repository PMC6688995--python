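"""JC69 distances, conserved-site selection and neighbor joining, with the
additive-matrix exactness oracle and independent cross-checks."""

import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxscan.genome_io import write_newick
from toxscan.phylogeny import (
    DistanceMatrix,
    Node,
    PhyloTree,
    SaturationError,
    jc69,
    mismatch_matrix,
    nj_tree,
    select_conserved_sites,
)


class TestJC69:
    def test_zero(self):
        assert jc69(0.0) == 0.0

    def test_closed_form_at_p_03(self):
        assert jc69(0.3) == pytest.approx(0.383119, abs=1e-6)
        assert jc69(0.3) == pytest.approx(-0.75 * math.log(0.6))

    def test_saturation(self):
        with pytest.raises(SaturationError, match="saturated"):
            jc69(0.75)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=0.7499))
    def test_correction_never_shrinks(self, p):
        assert jc69(p) >= p - 1e-12


class TestConservedSites:
    def test_gap_free_alignment_keeps_all(self):
        rows = {"a": "ACGTAC", "b": "ACGTAC"}
        assert select_conserved_sites(rows) == list(range(6))

    def test_gap_column_excluded(self):
        rows = {"a": "ACGTACGTAC", "b": "ACGTACG-AC"}
        sites = select_conserved_sites(rows)
        assert 7 not in sites and len(sites) == 9

    def test_ambiguity_code_excluded(self):
        rows = {"a": "ACNTAC", "b": "ACGTAC"}
        assert 2 not in select_conserved_sites(rows)

    def test_planted_gap_columns_counted_exactly(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        mat = rng.choice(bases, size=(5, 1000))
        gap_cols = rng.choice(1000, size=100, replace=False)
        mat[rng.integers(0, 5, size=100), gap_cols] = "-"
        rows = {f"t{i}": "".join(mat[i]) for i in range(5)}
        assert len(select_conserved_sites(rows)) == 900


class TestMismatchMatrix:
    def test_identical_rows_zero(self):
        dm = mismatch_matrix({"a": "ACGTAC", "b": "ACGTAC"})
        assert dm.values.max() == 0.0

    def test_30_of_100_mismatches(self):
        a = "A" * 100
        b = "C" * 30 + "A" * 70
        dm = mismatch_matrix({"a": a, "b": b})
        assert dm.get("a", "b") == pytest.approx(0.383119, abs=1e-6)

    def test_saturated_pair_named(self):
        a = "A" * 100
        b = "C" * 80 + "A" * 20
        with pytest.raises(SaturationError, match="'a'.*'b'"):
            mismatch_matrix({"a": a, "b": b})

    def test_zero_conserved_sites_rejected(self):
        with pytest.raises(ValueError, match="conserved"):
            mismatch_matrix({"a": "A-", "b": "-C"})


def random_tree(rng, n_taxa):
    """Random binary topology with uniform branch lengths; returns the
    PhyloTree (for its path metric) built over leaves T0..T{n-1}."""
    nodes = [Node(name=f"T{i}") for i in range(n_taxa)]
    lengths = {}
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = Node(children=[
            (nodes[i], float(rng.uniform(0.1, 1.0))),
            (nodes[j], float(rng.uniform(0.1, 1.0))),
        ])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [b]
    root = Node(children=[
        (nodes[0], float(rng.uniform(0.1, 1.0))),
        (nodes[1], float(rng.uniform(0.1, 1.0))),
    ])
    return PhyloTree(root=root, n_leaves=n_taxa)


def tree_to_matrix(tree):
    dists = tree.leaf_distances()
    taxa = tree.leaves()
    n = len(taxa)
    mat = np.zeros((n, n))
    for (a, b), d in dists.items():
        i, j = taxa.index(a), taxa.index(b)
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(taxa=taxa, values=mat)


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(taxa=["A", "B"], values=np.array([[0, 2.0], [2.0, 0]]))
        tree = nj_tree(dm)
        assert tree.leaf_distances()[("A", "B")] == pytest.approx(2.0)

    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            taxa=["A", "B", "C"],
            values=np.array([[0, 2.0, 4.0], [2.0, 0, 4.0], [4.0, 4.0, 0]]),
        )
        tree = nj_tree(dm)
        pendants = {c.name: bl for c, bl in tree.root.children}
        assert pendants == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_additive_matrices_recovered_exactly(self):
        """NJ inverts additive matrices: path lengths within 1e-9."""
        rng = np.random.default_rng(12)
        for trial in range(100):
            n = int(rng.integers(5, 9))
            true_tree = random_tree(rng, n)
            dm = tree_to_matrix(true_tree)
            est = nj_tree(dm)
            true_d = true_tree.leaf_distances()
            est_d = est.leaf_distances()
            for pair, d in true_d.items():
                assert abs(est_d[pair] - d) <= 1e-9, (trial, pair)

    def test_topology_matches_generating_tree(self, tmp_path):
        rng = np.random.default_rng(3)
        for trial in range(5):
            true_tree = random_tree(rng, 7)
            est = nj_tree(tree_to_matrix(true_tree))
            tns = dendropy.TaxonNamespace()
            t1 = dendropy.Tree.get(
                data=true_tree.to_newick(), schema="newick",
                taxon_namespace=tns,
            )
            t2 = dendropy.Tree.get(
                data=est.to_newick(), schema="newick", taxon_namespace=tns
            )
            t1.encode_bipartitions()
            t2.encode_bipartitions()
            rf = dendropy.calculate.treecompare.symmetric_difference(
                t1, t2, is_bipartitions_updated=True
            )
            assert rf == 0

    def test_agrees_with_independent_nj_implementation(self):
        """On a generic (tie-free) matrix our NJ topology matches scikit-bio's."""
        import skbio

        rng = np.random.default_rng(17)
        base = tree_to_matrix(random_tree(rng, 6))
        noise = rng.uniform(0, 0.05, size=base.values.shape)
        noisy = base.values + noise + noise.T
        np.fill_diagonal(noisy, 0.0)
        dm = DistanceMatrix(taxa=base.taxa, values=noisy)
        mine = nj_tree(dm)
        theirs = skbio.tree.nj(
            skbio.DistanceMatrix(noisy, ids=base.taxa), neg_as_zero=True
        )
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=mine.to_newick(), schema="newick",
                               taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=str(theirs), schema="newick",
                               taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_negative_branch_lengths_clamped(self):
        # triangle-violating distances force a negative pendant estimate
        values = np.array([
            [0.0, 1.0, 1.0],
            [1.0, 0.0, 3.0],
            [1.0, 3.0, 0.0],
        ])
        dm = DistanceMatrix(taxa=list("ABC"), values=values)
        with pytest.warns(UserWarning, match="clamped"):
            tree = nj_tree(dm)
        assert all(d >= 0 for d in tree.leaf_distances().values())

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(taxa=["A", "B"], values=np.array([[0, 1.0], [2.0, 0]]))

    def test_newick_round_trip_fixed_point(self, tmp_path):
        rng = np.random.default_rng(5)
        tree = nj_tree(tree_to_matrix(random_tree(rng, 6)))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        again = parsed.as_string(schema="newick")
        reparsed = dendropy.Tree.get(data=again, schema="newick")
        assert {l.taxon.label for l in reparsed.leaf_node_iter()} == set(
            tree.leaves()
        )
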