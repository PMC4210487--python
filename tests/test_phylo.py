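"""Neighbor joining, bootstrap support, consensus and monophyly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dendropy

from seldscope import (
    DistanceMatrix,
    Msa,
    ValidationError,
    bootstrap_support,
    is_monophyletic,
    neighbor_joining,
    p_distance,
    read_newick,
    write_newick,
)
from seldscope.phylo import (
    UndefinedDistanceError,
    as_newick,
    bipartitions,
    read_phylip_matrix,
    write_phylip_matrix,
)


def patristic(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    return {
        (a.label, b.label): pdm.distance(a, b)
        for i, a in enumerate(taxa) for b in taxa[i + 1:]
    }


class TestPDistance:
    def test_identical_rows_zero(self):
        dm = p_distance(Msa({"a": "MKVW", "b": "MKVW"}))
        assert dm.d[0, 1] == 0.0

    def test_hand_counted_half(self):
        dm = p_distance(Msa({"a": "AAAA", "b": "AATT"}))
        assert dm.d[0, 1] == 0.5

    def test_pairwise_deletion(self):
        # comparable columns are 1 and 3: one match, one mismatch
        dm = p_distance(Msa({"a": "A-AA", "b": "AAT-"}))
        assert dm.d[0, 1] == 0.5

    def test_all_gap_pair_names_offenders(self):
        with pytest.raises(UndefinedDistanceError, match="a.*b"):
            p_distance(Msa({"a": "A--", "b": "-AA", "c": "AAA"}))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_matches_direct_recount(self, seed):
        rng = np.random.default_rng(seed)
        alphabet = "ACDG-"
        rows = {
            f"r{i}": "".join(alphabet[j] for j in rng.integers(0, 5, 20))
            for i in range(3)
        }
        try:
            dm = p_distance(Msa(rows))
        except UndefinedDistanceError:
            return
        ids = list(rows)
        for i in range(3):
            for j in range(i + 1, 3):
                a, b = rows[ids[i]], rows[ids[j]]
                pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
                expected = sum(x != y for x, y in pairs) / len(pairs)
                assert dm.d[i, j] == pytest.approx(expected)


def _random_additive(rng, n_taxa: int) -> tuple[DistanceMatrix, set[frozenset]]:
    """A random binary tree with positive branch lengths; returns its exact
    path-length matrix and its canonical non-trivial bipartitions."""
    labels = [f"t{i}" for i in range(n_taxa)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    # sequential random addition
    nodes = []
    for label in labels[:2]:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        node.edge.length = float(rng.uniform(0.1, 2.0))
        tree.seed_node.add_child(node)
        nodes.append(node)
    for label in labels[2:]:
        target = nodes[rng.integers(len(nodes))]
        parent = target.parent_node
        split = dendropy.Node()
        split.edge.length = float(rng.uniform(0.1, 2.0))
        parent.remove_child(target)
        parent.add_child(split)
        split.add_child(target)
        target.edge.length = float(rng.uniform(0.1, 2.0))
        leaf = dendropy.Node()
        leaf.taxon = taxa.get_taxon(label)
        leaf.edge.length = float(rng.uniform(0.1, 2.0))
        split.add_child(leaf)
        nodes.extend([leaf, split])
    tree.is_rooted = False
    dists = patristic(tree)
    d = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(labels):
        for j in range(i + 1, n_taxa):
            d[i, j] = d[j, i] = dists[tuple(sorted((a, labels[j])))]
    return DistanceMatrix(labels, d), set(bipartitions(tree))


class TestNeighborJoining:
    def test_known_quartet_recovered_exactly(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) -> additive matrix by hand
        ids = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 8, 9],
            [3, 0, 9, 10],
            [8, 9, 0, 9],
            [9, 10, 9, 0],
        ], dtype=float)
        tree = neighbor_joining(DistanceMatrix(ids, d))
        assert set(bipartitions(tree)) == {frozenset({"C", "D"})}
        dists = patristic(tree)
        for (a, b), expected in {("A", "B"): 3, ("A", "C"): 8, ("A", "D"): 9,
                                 ("B", "C"): 9, ("B", "D"): 10, ("C", "D"): 9}.items():
            assert dists[(a, b)] == pytest.approx(expected)

    def test_three_taxa_star_lengths(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValidationError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0., 1.], [1., 0.]])))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seed=st.integers(min_value=0, max_value=10**6),
        n=st.integers(min_value=4, max_value=8),
    )
    def test_additive_matrices_reproduce_generating_tree(self, seed, n):
        """On additive matrices NJ recovers the generating topology and the
        patristic distances equal the input exactly (within float error)."""
        dm, true_bps = _random_additive(np.random.default_rng(seed), n)
        tree = neighbor_joining(dm)
        assert set(bipartitions(tree)) == true_bps
        dists = patristic(tree)
        for i, a in enumerate(dm.ids):
            for j in range(i + 1, n):
                assert dists[(a, dm.ids[j])] == pytest.approx(dm.d[i, j], abs=1e-9)

    def test_taxon_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(17)
        dm, _ = _random_additive(rng, 6)
        perm = rng.permutation(len(dm.ids))
        dm_perm = DistanceMatrix([dm.ids[i] for i in perm],
                                 dm.d[np.ix_(perm, perm)])
        assert set(bipartitions(neighbor_joining(dm))) == \
            set(bipartitions(neighbor_joining(dm_perm)))

    def test_agrees_with_independent_nj_implementation(self):
        """Cross-check topology against scikit-bio's neighbor joining."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(23)
        n = 7
        ids = [f"t{i}" for i in range(n)]
        raw = rng.uniform(0.2, 1.0, size=(n, n))
        d = np.triu(raw, 1)
        d = d + d.T
        mine = neighbor_joining(DistanceMatrix(ids, d))
        other = skbio.tree.nj(skbio.DistanceMatrix(d, ids))
        all_leaves = frozenset(ids)
        ref = min(all_leaves)
        other_bps = set()
        for node in other.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= n - 2:
                other_bps.add(all_leaves - side if ref in side else side)
        assert set(bipartitions(mine)) == other_bps


def _two_clade_msa(n_cols: int = 120, seed: int = 9) -> Msa:
    """Alignment with saturated signal for two three-leaf clades."""
    rng = np.random.default_rng(seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    base = [aas[i] for i in rng.integers(0, 20, n_cols)]
    other = [aas[(aas.index(c) + 7) % 20] for c in base]
    rows = {}
    for i, name in enumerate(["A1", "A2", "A3"]):
        row = base.copy()
        row[i] = aas[(aas.index(row[i]) + 1) % 20]   # private substitution
        rows[name] = "".join(row)
    for i, name in enumerate(["B1", "B2", "B3"]):
        row = other.copy()
        row[i] = aas[(aas.index(row[i]) + 1) % 20]
        rows[name] = "".join(row)
    return Msa(rows)


class TestBootstrap:
    def test_saturated_signal_full_support(self):
        result = bootstrap_support(_two_clade_msa(), n_replicates=50, seed=3)
        split = frozenset({"B1", "B2", "B3"})
        assert result.supports[split] == 100.0
        consensus_bps = bipartitions(result.consensus)
        assert split in consensus_bps

    def test_supports_within_bounds_and_consensus_majority(self):
        result = bootstrap_support(_two_clade_msa(n_cols=30, seed=5),
                                   n_replicates=40, seed=11)
        assert all(0.0 <= s <= 100.0 for s in result.supports.values())
        for bp in bipartitions(result.consensus):
            assert result.supports[bp] > 50.0

    def test_single_replicate_binary_supports(self):
        result = bootstrap_support(_two_clade_msa(), n_replicates=1, seed=2)
        assert set(result.supports.values()) <= {0.0, 100.0}

    def test_fixed_seed_deterministic(self):
        a = bootstrap_support(_two_clade_msa(), n_replicates=20, seed=42)
        b = bootstrap_support(_two_clade_msa(), n_replicates=20, seed=42)
        assert as_newick(a.tree) == as_newick(b.tree)
        assert as_newick(a.consensus) == as_newick(b.consensus)
        assert a.supports == b.supports


class TestMonophyly:
    TREE = neighbor_joining(DistanceMatrix(
        ["A", "B", "C", "D"],
        np.array([[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float),
    ))

    def test_singleton_and_full_set_trivially_true(self):
        assert is_monophyletic(self.TREE, {"A"})
        assert is_monophyletic(self.TREE, {"A", "B", "C", "D"})

    def test_clade_and_non_clade(self):
        assert is_monophyletic(self.TREE, {"C", "D"})
        assert is_monophyletic(self.TREE, {"A", "B"})   # complement of a clade
        assert not is_monophyletic(self.TREE, {"A", "C"})

    def test_unknown_leaf_raises(self):
        with pytest.raises(KeyError):
            is_monophyletic(self.TREE, {"A", "Z"})

    def test_diverged_block_in_simulation(self):
        msa = _two_clade_msa()
        tree = neighbor_joining(p_distance(msa))
        assert is_monophyletic(tree, {"B1", "B2", "B3"})


class TestSerialization:
    def test_newick_round_trip(self, tmp_path):
        result = bootstrap_support(_two_clade_msa(), n_replicates=10, seed=1)
        path = tmp_path / "t.nwk"
        write_newick(result.tree, path)
        back = read_newick(path)
        assert set(bipartitions(back)) == set(bipartitions(result.tree))
        orig = {frozenset({l.taxon.label}): l.edge.length
                for l in result.tree.leaf_node_iter()}
        readback = {frozenset({l.taxon.label}): l.edge.length
                    for l in back.leaf_node_iter()}
        for key, length in orig.items():
            assert readback[key] == pytest.approx(length, abs=1e-9)

    def test_phylip_matrix_round_trip(self, tmp_path):
        dm, _ = _random_additive(np.random.default_rng(8), 5)
        path = tmp_path / "m.phy"
        write_phylip_matrix(dm, path)
        back = read_phylip_matrix(path)
        assert back.ids == dm.ids
        assert np.allclose(back.d, dm.d, atol=1e-6)
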