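"""Distance-based phylogenetics: p-distances, neighbor-joining, bootstrap.

Trees are built with the Saitou–Nei neighbor-joining algorithm from
p-distances (fraction of differing residues among pairwise-comparable,
non-gap alignment columns). Node confidence comes from bootstrap resampling
of alignment columns: each replicate alignment is rebuilt into a tree, and
an internal edge's support is the percentage of replicates containing the
same leaf bipartition. A majority-rule consensus (bipartitions appearing in
more than half of the replicates) is produced alongside.

Trees are :class:`dendropy.Tree` objects (unrooted; supports stored as
internal node labels), newick-serializable. Everything is deterministic:
NJ breaks Q-matrix ties by the smallest (i, j) index pair, and the bootstrap
resampler is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .core_model import Msa, SeldscopeError, ValidationError, GAP

__all__ = [
    "DistanceMatrix",
    "p_distance",
    "neighbor_joining",
    "BootstrapResult",
    "bootstrap_support",
    "is_monophyletic",
    "bipartitions",
    "write_newick",
    "read_newick",
    "read_phylip_matrix",
    "write_phylip_matrix",
]


class UndefinedDistanceError(SeldscopeError):
    """A sequence pair shares no gap-free alignment column."""


@dataclass
class DistanceMatrix:
    """A symmetric non-negative distance matrix with a zero diagonal."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValidationError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric within 1e-12")
        if np.any(np.diag(self.d) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValidationError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.ids)


def _char_rows(msa: Msa) -> tuple[list[str], np.ndarray]:
    ids = list(msa.rows)
    arr = np.frombuffer(
        "".join(msa.rows[i] for i in ids).encode("ascii"), dtype="S1"
    ).reshape(len(ids), msa.ncol)
    return ids, arr


def _pdist(ids: Sequence[str], arr: np.ndarray) -> DistanceMatrix:
    gap = GAP.encode()
    n = len(ids)
    d = np.zeros((n, n))
    valid = arr != gap
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise UndefinedDistanceError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            d[i, j] = d[j, i] = np.count_nonzero(arr[i, both] != arr[j, both]) / m
    return DistanceMatrix(list(ids), d)


def p_distance(msa: Msa) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gapped columns."""
    if len(msa) < 2:
        raise ValidationError("p-distance needs at least 2 rows")
    return _pdist(*_char_rows(msa))


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    Q-matrix pair selection with ties broken by the smallest (i, j) index
    pair (indices in join order: original taxa first, then internal nodes in
    creation order). Negative branch-length estimates are clamped to zero.
    Returns an unrooted tree whose seed node is the final trifurcation.
    """
    n = len(dm)
    if n < 3:
        raise ValidationError(f"neighbor joining needs >= 3 taxa, got {n}")
    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for label in dm.ids:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes.append(node)

    d = dm.d.copy()
    active = list(range(n))

    def join(i_pos: int, j_pos: int) -> None:
        """Join active[i_pos], active[j_pos]; append the parent to active."""
        nonlocal d
        r = len(active)
        i, j = active[i_pos], active[j_pos]
        row_sums = d[np.ix_(active, active)].sum(axis=1)
        dij = d[i, j]
        li = 0.5 * dij + (row_sums[i_pos] - row_sums[j_pos]) / (2 * (r - 2))
        lj = dij - li
        parent = dendropy.Node()
        for child, length in ((nodes[i], li), (nodes[j], lj)):
            parent.add_child(child)
            child.edge.length = max(float(length), 0.0)
        # distances from the new node to every remaining active node
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k not in (i, j):
                new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        for pos in sorted((i_pos, j_pos), reverse=True):
            active.pop(pos)
        active.append(d.shape[0] - 1)

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        best = None
        for a in range(r):
            for b in range(a + 1, r):
                key = (q[a, b], a, b)
                if best is None or key < best:
                    best = key
        join(best[1], best[2])

    # resolve the final three nodes around a central trifurcation
    i, j, k = active
    center = dendropy.Node()
    lengths = {
        i: 0.5 * (d[i, j] + d[i, k] - d[j, k]),
        j: 0.5 * (d[i, j] + d[j, k] - d[i, k]),
        k: 0.5 * (d[i, k] + d[j, k] - d[i, j]),
    }
    for idx in (i, j, k):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(float(lengths[idx]), 0.0)
    tree.seed_node = center
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree


# ---------------------------------------------------------------------------
# Bipartitions, support, consensus


def _leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def _canonical(side: frozenset[str], all_leaves: frozenset[str]) -> frozenset[str]:
    """Canonical form of a bipartition: the side not containing the
    lexicographically smallest leaf."""
    ref = min(all_leaves)
    return frozenset(all_leaves - side) if ref in side else side


def bipartitions(tree: dendropy.Tree,
                 include_trivial: bool = False) -> dict[frozenset[str], dendropy.Node]:
    """Canonical leaf bipartitions of every edge, mapped to the child node.

    Non-trivial bipartitions (both sides >= 2 leaves) by default.
    """
    all_leaves = _leaf_labels(tree)
    result: dict[frozenset[str], dendropy.Node] = {}
    below: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset({node.taxon.label})
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is None:
            continue
        side = below[node]
        if not include_trivial and min(len(side), len(all_leaves) - len(side)) < 2:
            continue
        result[_canonical(side, all_leaves)] = node
    return result


def is_monophyletic(tree: dendropy.Tree, leaf_set: Iterable[str]) -> bool:
    """Whether some edge of the unrooted tree separates exactly ``leaf_set``."""
    leaf_set = frozenset(leaf_set)
    all_leaves = _leaf_labels(tree)
    unknown = leaf_set - all_leaves
    if unknown:
        raise KeyError(f"leaves not in tree: {sorted(unknown)}")
    if len(leaf_set) in (0, 1, len(all_leaves), len(all_leaves) - 1):
        return True  # trivial bipartitions always exist (pendant edges)
    return _canonical(leaf_set, all_leaves) in bipartitions(tree)


@dataclass
class BootstrapResult:
    """NJ tree with bootstrap supports, plus the majority-rule consensus."""

    tree: dendropy.Tree
    consensus: dendropy.Tree
    n_replicates: int
    supports: dict[frozenset[str], float]


def bootstrap_support(msa: Msa, n_replicates: int = 100, seed: int = 0) -> BootstrapResult:
    """Column-resampling bootstrap of the NJ tree.

    Each replicate resamples alignment columns with replacement, recomputes
    p-distances and the NJ tree; an internal edge's support is the
    percentage of replicates whose tree contains the same bipartition.
    Supports annotate the original tree's internal node labels. The
    majority-rule consensus keeps exactly the bipartitions occurring in more
    than half of the replicates. Fixed seed => identical output.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    ids, arr = _char_rows(msa)
    original = neighbor_joining(_pdist(ids, arr))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    done = 0
    attempts = 0
    while done < n_replicates:
        attempts += 1
        if attempts > 100 * n_replicates:
            raise SeldscopeError("bootstrap: too many degenerate replicates")
        cols = rng.integers(0, msa.ncol, size=msa.ncol)
        try:
            rep_tree = neighbor_joining(_pdist(ids, arr[:, cols]))
        except UndefinedDistanceError:
            continue  # resampled columns left some pair with no overlap
        for bp in bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1
        done += 1

    supports = {bp: 100.0 * c / n_replicates for bp, c in counts.items()}
    for bp, node in bipartitions(original).items():
        node.label = str(int(round(supports.get(bp, 0.0))))
    consensus = _majority_rule_consensus(ids, supports)
    return BootstrapResult(original, consensus, n_replicates, supports)


def _majority_rule_consensus(labels: Sequence[str],
                             supports: dict[frozenset[str], float]) -> dendropy.Tree:
    """Tree containing exactly the bipartitions with support > 50.

    Majority bipartitions are pairwise compatible, so they nest: clades
    (canonical sides, which exclude the reference leaf) are inserted from
    the most to the least supported.
    """
    taxa = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    leafset: dict[dendropy.Node, frozenset[str]] = {}
    for label in labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        root.add_child(node)
        leafset[node] = frozenset({label})
    leafset[root] = frozenset(labels)

    majority = sorted(
        (bp for bp, s in supports.items() if s > 50.0),
        key=lambda bp: (-supports[bp], sorted(bp)),
    )
    for clade in majority:
        host = root
        while True:  # descend to the smallest node containing the clade
            nxt = next(
                (c for c in host.child_nodes()
                 if not c.is_leaf() and clade <= leafset[c]), None
            )
            if nxt is None:
                break
            host = nxt
        group = [c for c in host.child_nodes() if leafset[c] <= clade]
        if frozenset().union(*(leafset[c] for c in group)) != clade:
            continue  # incompatible with an earlier, better-supported clade
        new = dendropy.Node()
        new.label = str(int(round(supports[clade])))
        for child in group:
            host.remove_child(child)
            new.add_child(child)
        host.add_child(new)
        leafset[new] = clade
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree


# ---------------------------------------------------------------------------
# Serialization


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Newick with branch lengths and supports as internal node labels."""
    with open(path, "w") as fh:
        fh.write(as_newick(tree))


def as_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    )


def read_newick(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             suppress_internal_node_taxa=True)
    tree.is_rooted = False
    return tree


def read_phylip_matrix(path: str | Path) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix (taxon count line, then rows)."""
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise ValidationError(f"{path}: empty distance matrix file")
    n = int(tokens[0])
    ids, rows, pos = [], [], 1
    for _ in range(n):
        ids.append(tokens[pos])
        rows.append([float(x) for x in tokens[pos + 1:pos + 1 + n]])
        pos += 1 + n
    return DistanceMatrix(ids, np.array(rows))


def write_phylip_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(dm)}\n")
        for i, label in enumerate(dm.ids):
            row = " ".join(f"{x:.6f}" for x in dm.d[i])
            fh.write(f"{label} {row}\n")
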