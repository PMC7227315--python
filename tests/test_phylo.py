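import itertools

import numpy as np
import pytest

from kinfam.align import Msa
from kinfam.phylo import (Node, PhyloTree, assign_subfamily, bootstrap_support,
                          from_newick, neighbor_joining, p_distance_matrix)


def _random_additive_tree(rng, n):
    """Random unrooted binary tree with positive branch lengths; returns
    (leaf names, distance matrix, bipartition set)."""
    nodes = [Node(name=f"t{i}") for i in range(n)]
    lengths = {}  # node id -> pendant length toward its parent join
    subtrees = list(nodes)
    lens = {id(nd): float(rng.uniform(0.1, 1.0)) for nd in subtrees}
    while len(subtrees) > 3:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        a, b = subtrees[j], subtrees[i]
        new = Node(children=[(subtrees[i], lens[id(subtrees[i])]),
                             (subtrees[j], lens[id(subtrees[j])])])
        del subtrees[j], subtrees[i]
        subtrees.append(new)
        lens[id(new)] = float(rng.uniform(0.1, 1.0))
    root = Node(children=[(s, lens[id(s)]) for s in subtrees])
    tree = PhyloTree(root=root, leaves=[f"t{i}" for i in range(n)])

    # leaf-to-leaf path lengths
    paths = {}

    def walk(node, dist_from_root):
        if node.is_leaf:
            paths[node.name] = dist_from_root
            return [node.name]
        below = []
        for child, bl in node.children:
            below.extend(walk(child, dist_from_root + bl))
        return below

    # distances via lowest common ancestor on the rooted representation
    depths = {}
    parent_sets = {}

    def walk2(node, depth, ancestors):
        if node.is_leaf:
            depths[node.name] = depth
            parent_sets[node.name] = ancestors
            return
        for child, bl in node.children:
            walk2(child, depth + bl, ancestors + [(id(node), depth)])

    walk2(root, 0.0, [])
    names = [f"t{i}" for i in range(n)]
    D = np.zeros((n, n))
    for a, b in itertools.combinations(names, 2):
        common = {nid: d for nid, d in parent_sets[a]}
        lca_depth = max(d for nid, d in parent_sets[b] if nid in common)
        d = depths[a] + depths[b] - 2 * lca_depth
        ia, ib = names.index(a), names.index(b)
        D[ia, ib] = D[ib, ia] = d
    _ = lengths, paths
    return names, D, tree.bipartitions()


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        """Additive AB|CD tree: pendants A=1, B=2, C=2, D=3, internal 1."""
        ids = ["A", "B", "C", "D"]
        D = np.array([
            [0, 3, 4, 5],
            [3, 0, 5, 6],
            [4, 5, 0, 5],
            [5, 6, 5, 0],
        ], dtype=float)
        tree = neighbor_joining(ids, D)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        # additive: tree path lengths reproduce the input distances
        dist = _tree_distances(tree)
        for i, j in itertools.combinations(range(4), 2):
            assert dist[(ids[i], ids[j])] == pytest.approx(D[i, j], abs=1e-9)

    def test_three_taxa_closed_form_limbs(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = neighbor_joining(["x", "y", "z"], D)
        limbs = {child.name: bl for child, bl in tree.root.children}
        assert limbs["x"] == pytest.approx(0.0)
        assert limbs["y"] == pytest.approx(2.0)
        assert limbs["z"] == pytest.approx(3.0)

    def test_taxon_order_permutation_invariance(self):
        rng = np.random.default_rng(0)
        names, D, splits = _random_additive_tree(rng, 8)
        perm = list(rng.permutation(8))
        tree1 = neighbor_joining(names, D)
        tree2 = neighbor_joining([names[i] for i in perm], D[np.ix_(perm, perm)])
        assert tree1.bipartitions() == tree2.bipartitions()
        assert tree1.total_length() == pytest.approx(tree2.total_length())

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_additive_matrices_recover_generating_topology(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            names, D, splits = _random_additive_tree(rng, n)
            tree = neighbor_joining(names, D)
            assert tree.bipartitions() == splits
            dist = _tree_distances(tree)
            for i, j in itertools.combinations(range(n), 2):
                key = tuple(sorted((names[i], names[j])))
                assert dist[key] == pytest.approx(D[i, j], abs=1e-9)

    def test_agrees_with_dendropy_on_random_matrix(self):
        """Independent implementation cross-check on a non-additive matrix."""
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(42)
        n = 7
        names = [f"t{i}" for i in range(n)]
        D = rng.uniform(0.2, 1.0, size=(n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        mine = neighbor_joining(names, D)

        csv = "," + ",".join(names) + "\n" + "\n".join(
            names[i] + "," + ",".join(str(D[i, j]) for j in range(n))
            for i in range(n))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv))
        dtree = pdm.nj_tree()
        theirs = set()
        taxa = frozenset(names)
        ref = min(names)
        for edge in dtree.preorder_edge_iter():
            below = frozenset(lf.taxon.label for lf in edge.head_node.leaf_iter())
            if 1 < len(below) < n - 1:
                theirs.add(below if ref not in below else taxa - below)
        assert mine.bipartitions() == theirs

    def test_small_or_nan_input_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(["a", "b"], np.zeros((2, 2)))
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError):
            neighbor_joining(["a", "b", "c"], D)


def _tree_distances(tree):
    dist = {}

    def walk(node):
        if node.is_leaf:
            return {node.name: 0.0}
        below = {}
        for child, bl in node.children:
            sub = walk(child)
            for k in sub:
                sub[k] += bl
            for a in below:
                for b in sub:
                    dist[tuple(sorted((a, b)))] = below[a] + sub[b]
            below.update(sub)
        return below

    walk(tree.root)
    return dist


class TestPDistance:
    def test_examples_and_symmetry(self):
        msa = Msa(ids=["a", "b", "c"], rows=["AAAA", "AATT", "AAAA"])
        ids, D = p_distance_matrix(msa)
        assert D[0, 1] == pytest.approx(0.5)
        assert D[0, 2] == 0.0
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)

    def test_gap_columns_excluded_pairwise(self):
        msa = Msa(ids=["a", "b"], rows=["AA--", "AATT"])
        _, D = p_distance_matrix(msa)
        assert D[0, 1] == 0.0  # only 2 shared columns, both match

    def test_disjoint_gap_patterns_rejected(self):
        msa = Msa(ids=["a", "b"], rows=["AA--", "--TT"])
        with pytest.raises(ValueError):
            p_distance_matrix(msa)


class TestBootstrap:
    def _clean_clade_msa(self):
        """A and B united by 50 identical private columns; C, D, E far."""
        rng = np.random.default_rng(3)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        block = "".join(alphabet[i] for i in rng.integers(0, 20, size=50))
        rows = {
            "A": block + "A" * 10,
            "B": block + "C" * 10,
            "C": "".join(alphabet[i] for i in rng.integers(0, 20, size=60)),
            "D": "".join(alphabet[i] for i in rng.integers(0, 20, size=60)),
            "E": "".join(alphabet[i] for i in rng.integers(0, 20, size=60)),
        }
        return Msa(ids=list(rows), rows=list(rows.values()))

    def test_clean_clade_supported_at_100(self):
        msa = self._clean_clade_msa()
        tree = bootstrap_support(msa, n_replicates=100, seed=5)
        assert tree.support({"A", "B"}) == 100.0

    def test_seeded_determinism(self):
        msa = self._clean_clade_msa()
        t1 = bootstrap_support(msa, n_replicates=50, seed=9)
        t2 = bootstrap_support(msa, n_replicates=50, seed=9)
        assert t1.supports == t2.supports
        assert t1.to_newick() == t2.to_newick()

    def test_single_replicate_supports_are_zero_or_hundred(self):
        msa = self._clean_clade_msa()
        tree = bootstrap_support(msa, n_replicates=1, seed=2)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_fewer_than_four_rows_returns_empty_supports(self):
        msa = Msa(ids=["a", "b", "c"], rows=["AAAA", "AATT", "TTTT"])
        tree = bootstrap_support(msa, n_replicates=10, seed=1)
        assert tree.supports == {}


class TestNewick:
    def test_round_trip_preserves_topology_lengths_and_supports(self):
        rng = np.random.default_rng(17)
        names, D, _ = _random_additive_tree(rng, 9)
        tree = neighbor_joining(names, D)
        tree.supports = {s: 87.0 for s in tree.bipartitions()}
        back = from_newick(tree.to_newick())
        assert back.bipartitions() == tree.bipartitions()
        assert back.supports == tree.supports
        assert back.to_newick() == tree.to_newick()


class TestAssignSubfamily:
    def test_query_in_single_label_clade_gets_label(self):
        # ((q,a1),(a2,(b1,b2))) with labels a=RAF, b=MEKK
        q = Node(name="q")
        a1, a2 = Node(name="a1"), Node(name="a2")
        b1, b2 = Node(name="b1"), Node(name="b2")
        inner_b = Node(children=[(b1, 1.0), (b2, 1.0)])
        left = Node(children=[(q, 1.0), (a1, 1.0)])
        right = Node(children=[(a2, 1.0), (inner_b, 1.0)])
        tree = PhyloTree(root=Node(children=[(left, 1.0), (right, 1.0)]),
                         leaves=["q", "a1", "a2", "b1", "b2"])
        labels = assign_subfamily(tree, {"a1": "RAF", "a2": "RAF",
                                         "b1": "MEKK", "b2": "MEKK"})
        assert labels["q"] == "RAF"

    def test_star_topology_mixed_anchors_unassigned(self):
        leaves = [Node(name=n) for n in ["q", "r", "m"]]
        tree = PhyloTree(root=Node(children=[(lf, 1.0) for lf in leaves]),
                         leaves=["q", "r", "m"])
        labels = assign_subfamily(tree, {"r": "RAF", "m": "MEKK"})
        assert labels["q"] == "unassigned"

    def test_missing_anchors_rejected(self):
        leaves = [Node(name=n) for n in ["q", "r"]]
        tree = PhyloTree(root=Node(children=[(lf, 1.0) for lf in leaves]),
                         leaves=["q", "r"])
        with pytest.raises(ValueError):
            assign_subfamily(tree, {"zz": "RAF"})

    def test_full_family_labels_match_truth(self, sim_truth, sim_report):
        truth_labels = {g: info["subfamily"]
                        for g, info in sim_truth.genes.items()
                        if info["is_family"]}
        assert sim_report["subfamily_assignments"] == truth_labels
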