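"""Distance-based phylogeny: p-distances, neighbor joining, bootstrap.

The tree produced is unrooted (stored with an arbitrary trifurcating root,
the standard representation). Negative NJ branch lengths are clamped to
zero and the deficit recorded on the tree, never silently. Bootstrap
supports are percentages of column-resampled replicates whose NJ tree
contains each internal bipartition of the original tree, annotated onto
the original tree rather than a consensus.

Subfamily assignment anchors the tree with labelled reference proteins:
each query receives the label of the smallest clade (either side of any
edge) that contains it together with anchors of a single label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import Msa


@dataclass
class Node:
    name: str | None = None
    children: list[tuple["Node", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaf_names())
        return out


@dataclass
class PhyloTree:
    root: Node
    leaves: list[str]
    supports: dict[frozenset, float] = field(default_factory=dict)
    clamped: list[tuple[str, float]] = field(default_factory=list)  # (context, deficit)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each canonicalized as the side not containing
        the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaves)
        ref = min(self.leaves)
        splits: set[frozenset] = set()

        def collect(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                below |= collect(child)
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if ref not in below else all_leaves - below
                splits.add(side)
            return below

        collect(self.root)
        return splits

    def support(self, side) -> float | None:
        """Bootstrap support of the split separating ``side`` from the rest
        (either side of the bipartition may be given)."""
        side = frozenset(side)
        ref = min(self.leaves)
        canonical = side if ref not in side else frozenset(self.leaves) - side
        return self.supports.get(canonical)

    def clades(self) -> set[frozenset]:
        """Both sides of every edge (all unrooted clades, incl. trivial)."""
        all_leaves = frozenset(self.leaves)
        out: set[frozenset] = set()

        def collect(node: Node) -> frozenset:
            if node.is_leaf:
                below = frozenset([node.name])
            else:
                below = frozenset()
                for child, _ in node.children:
                    below |= collect(child)
            if 0 < len(below) < len(all_leaves):
                out.add(below)
                out.add(all_leaves - below)
            return below

        collect(self.root)
        return out

    def total_length(self) -> float:
        def walk(node: Node) -> float:
            return sum(bl + walk(c) for c, bl in node.children)
        return walk(self.root)

    def to_newick(self, precision: int = 9) -> str:
        all_leaves = frozenset(self.leaves)
        ref = min(self.leaves)

        def fmt(node: Node) -> tuple[str, frozenset]:
            if node.is_leaf:
                return node.name, frozenset([node.name])
            parts = []
            below = frozenset()
            for child, bl in node.children:
                s, sub = fmt(child)
                parts.append(f"{s}:{bl:.{precision}f}")
                below |= sub
            label = ""
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if ref not in below else all_leaves - below
                if side in self.supports:
                    label = f"{self.supports[side]:g}"
            return "(" + ",".join(parts) + ")" + label, below

        s, _ = fmt(self.root)
        return s + ";"


def from_newick(newick: str) -> PhyloTree:
    """Parse a Newick string (dendropy-backed) into a PhyloTree.

    Internal node labels are read back as bootstrap supports.
    """
    import dendropy

    dtree = dendropy.Tree.get(data=newick, schema="newick",
                              suppress_internal_node_taxa=True)

    def convert(dnode) -> Node:
        if not dnode.child_nodes():
            return Node(name=dnode.taxon.label.replace(" ", "_"))
        node = Node()
        for child in dnode.child_nodes():
            node.children.append((convert(child), child.edge.length or 0.0))
        return node

    root = convert(dtree.seed_node)
    tree = PhyloTree(root=root, leaves=sorted(root.leaf_names()))
    # recover supports from internal labels
    all_leaves = frozenset(tree.leaves)
    ref = min(tree.leaves)
    for dnode in dtree.preorder_node_iter():
        if dnode.child_nodes() and dnode.label is not None:
            below = frozenset(t.label.replace(" ", "_")
                              for t in [lf.taxon for lf in dnode.leaf_iter()])
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if ref not in below else all_leaves - below
                tree.supports[side] = float(dnode.label)
    return tree


def p_distance_matrix(msa: Msa) -> tuple[list[str], np.ndarray]:
    """Proportion of mismatches over columns where both rows are non-gap."""
    n = len(msa.rows)
    if n < 2:
        raise ValueError("p_distance_matrix: need at least 2 rows")
    arr = np.array([list(r) for r in msa.rows])
    gap = arr == "-"
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gap[i] & ~gap[j]
            total = int(shared.sum())
            if total == 0:
                raise ValueError(
                    f"p_distance_matrix: rows {msa.ids[i]} and {msa.ids[j]} share no columns"
                )
            mism = int((arr[i][shared] != arr[j][shared]).sum())
            D[i, j] = D[j, i] = mism / total
    return list(msa.ids), D


def poisson_correct(D: np.ndarray) -> np.ndarray:
    """Optional -ln(1-p) correction of a p-distance matrix."""
    if (D >= 1.0).any():
        raise ValueError("poisson_correct: p-distance of 1 is not correctable")
    return -np.log(1.0 - D)


def neighbor_joining(ids: list[str], D: np.ndarray) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic lowest-index tie-break."""
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor_joining: need at least 3 taxa")
    if np.isnan(D).any():
        raise ValueError("neighbor_joining: NaN in distance matrix")
    D = D.astype(float).copy()
    nodes: list[Node] = [Node(name=t) for t in ids]
    clamped: list[tuple[str, float]] = []

    def clamp(length: float, context: str) -> float:
        if length < 0:
            clamped.append((context, -length))
            return 0.0
        return length

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        Q = (m - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i, j) pair among (near-)minima, i < j in current active order
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        cand = cand[cand[:, 0] < cand[:, 1]]
        a, b = min(map(tuple, cand))
        i, j = active[a], active[b]
        d_ij = D[i, j]
        li = 0.5 * d_ij + (row_sums[a] - row_sums[b]) / (2 * (m - 2))
        lj = d_ij - li
        new = Node(children=[(nodes[i], clamp(li, nodes[i].name or "internal")),
                             (nodes[j], clamp(lj, nodes[j].name or "internal"))])
        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0])
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - d_ij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # final trifurcation: closed-form limb lengths
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = Node(children=[(nodes[i], clamp(li, nodes[i].name or "internal")),
                          (nodes[j], clamp(lj, nodes[j].name or "internal")),
                          (nodes[k], clamp(lk, nodes[k].name or "internal"))])
    return PhyloTree(root=root, leaves=list(ids), clamped=clamped)


def bootstrap_support(msa: Msa, n_replicates: int = 1000, seed: int = 0,
                      distance: str = "p") -> PhyloTree:
    """NJ tree of the MSA with bootstrap supports on internal edges.

    Columns are resampled with replacement; each replicate's NJ tree is
    scored for the original tree's bipartitions. Fewer than 4 rows leave
    the support set empty (no internal edges exist).
    """
    if n_replicates < 1:
        raise ValueError("bootstrap_support: n_replicates must be >= 1")
    ids, D = _distance(msa, distance)
    tree = neighbor_joining(ids, D)
    if len(msa.rows) < 4:
        return tree
    splits = tree.bipartitions()
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    ncol = msa.n_columns
    arr_rows = msa.rows
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = ["".join(r[c] for c in cols) for r in arr_rows]
        rep = Msa(ids=list(msa.ids), rows=rep_rows)
        try:
            rep_ids, rep_D = _distance(rep, distance)
            rep_tree = neighbor_joining(rep_ids, rep_D)
        except ValueError:
            continue  # replicate degenerate (e.g. all-gap pair); skip
        rep_splits = rep_tree.bipartitions()
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    tree.supports = {s: 100.0 * c / n_replicates for s, c in counts.items()}
    return tree


def _distance(msa: Msa, distance: str) -> tuple[list[str], np.ndarray]:
    ids, D = p_distance_matrix(msa)
    if distance == "poisson":
        D = poisson_correct(D)
    elif distance != "p":
        raise ValueError(f"unknown distance model {distance!r}")
    return ids, D


def assign_subfamily(tree: PhyloTree, anchor_labels: dict[str, str]) -> dict[str, str]:
    """Label queries from anchored clades.

    Each query leaf gets the label of the smallest clade containing it
    whose anchors carry a single label; if every anchored clade containing
    the query is mixed, or equally small single-label clades disagree (the
    star-topology case), the query is 'unassigned'.
    """
    anchors = set(anchor_labels)
    present = anchors & set(tree.leaves)
    if not present:
        raise ValueError("assign_subfamily: no anchors present in tree")
    labels_present = {anchor_labels[a] for a in present}
    queries = [lf for lf in tree.leaves if lf not in anchors]
    clades = sorted(tree.clades(), key=len)
    out: dict[str, str] = {}
    for q in queries:
        label = "unassigned"
        k = 0
        while k < len(clades):
            size = len(clades[k])
            tier_labels = set()
            while k < len(clades) and len(clades[k]) == size:
                clade = clades[k]
                k += 1
                if q not in clade:
                    continue
                clade_anchors = clade & present
                if not clade_anchors:
                    continue
                labels = {anchor_labels[a] for a in clade_anchors}
                if len(labels) == 1:
                    tier_labels |= labels
            if len(tier_labels) == 1:
                label = tier_labels.pop()
                break
            if len(tier_labels) > 1:
                break  # equally small clades disagree: ambiguous
        out[q] = label
    return out
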