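"""Distances, neighbor joining, rooting, Newick round trips.

dendropy serves as the independent parser / topology oracle: random additive
trees are generated, their patristic distance matrices fed to our NJ, and
topologies compared by Robinson-Foulds distance.
"""

import dendropy
import numpy as np
import pytest

from geomine.candidate_selection import bar_heights
from geomine.phylogenetics import (
    distance_matrix,
    leaf_path_lengths,
    neighbor_joining,
    root_and_annotate,
    to_newick,
)
from geomine.sequence_mining import IdentityMatrix


def random_additive_tree(n_taxa, rng):
    """Random topology with positive branch lengths; returns (dendropy tree,
    taxon labels, patristic distance matrix)."""
    labels = [f"T{i}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(labels)
    # build a random binary topology by sequential leaf attachment
    newick = f"({labels[0]}:1,{labels[1]}:1)"
    tree = dendropy.Tree.get(data=newick + ";", schema="newick", taxon_namespace=ns)
    for label in labels[2:]:
        edges = [e for e in tree.preorder_edge_iter() if e.length is not None]
        edge = edges[rng.integers(0, len(edges))]
        # split the edge and hang the new leaf off the split point
        child = edge.head_node
        parent = edge.tail_node
        split = parent.new_child(edge_length=edge.length * rng.uniform(0.2, 0.8))
        parent.remove_child(child)
        split.add_child(child)
        child.edge.length = edge.length * rng.uniform(0.2, 0.8)
        leaf = split.new_child(taxon=ns.get_taxon(label),
                               edge_length=float(rng.uniform(0.2, 2.0)))
    tree.update_bipartitions(suppress_unifurcations=True)
    pdm = tree.phylogenetic_distance_matrix()
    d = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                d[i, j] = pdm.patristic_distance(ns.get_taxon(a), ns.get_taxon(b))
    return tree, labels, d


def rf_distance(newick_a, tree_b, ns):
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=ns)
    ta.encode_bipartitions()
    tree_b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tree_b)


class TestDistanceMatrix:
    def test_transform_and_involution(self):
        v = np.array([[1.0, 0.3, 0.0], [0.3, 1.0, 0.6], [0.0, 0.6, 1.0]])
        m = IdentityMatrix(ids=("a", "b", "c"), values=v)
        d = distance_matrix(m)
        assert d[0, 1] == pytest.approx(0.7)   # identity 0.3 -> distance 0.7
        assert d[0, 2] == pytest.approx(1.0)   # identity 0.0 -> distance 1.0
        assert np.allclose(np.diag(d), 0.0)    # identity 1.0 -> distance 0.0
        off = ~np.eye(3, dtype=bool)
        assert np.allclose((1.0 - d)[off], v[off])  # round trip


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        t = neighbor_joining(np.array([[0.0, 0.6], [0.6, 0.0]]), ["A", "B"])
        paths = leaf_path_lengths(t)
        assert paths[("A", "B")] == pytest.approx(0.6)
        assert to_newick(t, precision=2) == "(A:0.30,B:0.30);"

    def test_three_taxa_closed_form(self):
        d_ab, d_ac, d_bc = 5.0, 9.0, 10.0
        t = neighbor_joining(
            np.array([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]], float),
            ["A", "B", "C"])
        center = next(u for u in t.adjacency if u not in t.leaves)
        assert t.adjacency["A"][center] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert t.adjacency["B"][center] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert t.adjacency["C"][center] == pytest.approx((d_ac + d_bc - d_ab) / 2)

    def test_additive_six_taxon_recovery(self):
        rng = np.random.default_rng(42)
        gen_tree, labels, d = random_additive_tree(6, rng)
        t = neighbor_joining(d, labels)
        assert rf_distance(to_newick(t), gen_tree, gen_tree.taxon_namespace) == 0

    @pytest.mark.parametrize("trial", range(50))
    def test_additive_recovery_many_random_trees(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(4, 9))
        gen_tree, labels, d = random_additive_tree(n, rng)
        t = neighbor_joining(d, labels)
        assert rf_distance(to_newick(t), gen_tree, gen_tree.taxon_namespace) == 0
        # path lengths reproduce the additive input exactly
        paths = leaf_path_lengths(t)
        for i, a in enumerate(labels):
            for j in range(i + 1, n):
                key = tuple(sorted((a, labels[j])))
                assert paths[key] == pytest.approx(d[i, j], abs=1e-9)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(d, ["A", "B", "C"])

    def test_matches_scikit_bio_topology(self):
        """Dual-route check against an independent NJ implementation."""
        import skbio

        rng = np.random.default_rng(77)
        gen_tree, labels, d = random_additive_tree(7, rng)
        ours = to_newick(neighbor_joining(d, labels))
        dm = skbio.DistanceMatrix(d, ids=labels)
        theirs = skbio.tree.nj(dm)
        ns = gen_tree.taxon_namespace
        t_ours = dendropy.Tree.get(data=ours, schema="newick", taxon_namespace=ns)
        t_theirs = dendropy.Tree.get(data=str(theirs).strip(), schema="newick",
                                     taxon_namespace=ns)
        t_ours.encode_bipartitions()
        t_theirs.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t_ours, t_theirs) == 0


class TestRootAndAnnotate:
    def make_tree(self, seed=5, n=6):
        rng = np.random.default_rng(seed)
        _, labels, d = random_additive_tree(n, rng)
        return neighbor_joining(d, labels), labels

    def test_root_leaf_is_child_of_root(self):
        t, labels = self.make_tree()
        rooted = root_and_annotate(t, labels[0], {})
        assert rooted.root in rooted.adjacency[labels[0]]

    def test_total_length_conserved(self):
        t, labels = self.make_tree()
        rooted = root_and_annotate(t, labels[2], {})
        assert rooted.total_length == pytest.approx(t.total_length)

    def test_path_length_multiset_preserved(self):
        t, labels = self.make_tree(seed=9)
        before = leaf_path_lengths(t)
        rooted = root_and_annotate(t, labels[1], {})
        after = leaf_path_lengths(rooted)
        for key, val in before.items():
            assert after[key] == pytest.approx(val, abs=1e-12)

    def test_missing_annotations_default_zero(self):
        t, labels = self.make_tree()
        rooted = root_and_annotate(t, labels[0], {labels[1]: 0.8})
        assert rooted.annotations[labels[1]] == 0.8
        assert rooted.annotations[labels[0]] == 0.0

    def test_unknown_root_rejected(self):
        t, labels = self.make_tree()
        with pytest.raises(ValueError, match="unknown"):
            root_and_annotate(t, "nope", {})

    def test_max_bar_height_is_lowest_energy_candidate(self):
        """Cross-module: on noiseless scores the tallest bar marks the
        lowest-energy leaf."""
        from geomine.sequence_mining import identity_matrix
        from geomine.synthetic_data import (
            FamilySimSpec, ScoreSimSpec, simulate_family, simulate_scores)

        records, clade = simulate_family(FamilySimSpec(
            n_sequences=10, root_length=80, eukaryote_fraction=0.0, seed=21))
        cands = simulate_scores(records, clade, ScoreSimSpec(noise_sd=0.5, seed=21))
        heights = bar_heights([c.interface_energy for c in cands])
        annotations = {c.id: float(h) for c, h in zip(cands, heights)}
        m = identity_matrix(records)
        t = neighbor_joining(distance_matrix(m), list(m.ids))
        rooted = root_and_annotate(t, records[0].id, annotations)
        best = min(cands, key=lambda c: c.interface_energy)
        assert max(rooted.annotations, key=rooted.annotations.get) == best.id


class TestNewick:
    def test_round_trip_random_trees(self):
        for trial in range(20):
            rng = np.random.default_rng(300 + trial)
            gen_tree, labels, d = random_additive_tree(int(rng.integers(4, 8)), rng)
            t = neighbor_joining(d, labels)
            s = to_newick(t)
            parsed = dendropy.Tree.get(data=s, schema="newick",
                                       taxon_namespace=gen_tree.taxon_namespace)
            # topology and lengths survive the round trip
            pdm = parsed.phylogenetic_distance_matrix()
            paths = leaf_path_lengths(t)
            ns = gen_tree.taxon_namespace
            for (a, b), val in paths.items():
                got = pdm.patristic_distance(ns.get_taxon(a), ns.get_taxon(b))
                assert got == pytest.approx(val, abs=1e-5)

    def test_annotation_sidecar_empty_map(self, tmp_path):
        from geomine.phylogenetics import write_annotation_sidecar

        path = tmp_path / "ann.tsv"
        write_annotation_sidecar({}, path)
        assert path.read_text() == "id\theight\n"
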