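"""Tree building on distance matrices, behind a dendropy.Tree surface.

Three builders: Saitou-Nei neighbor joining (the AB and AF trees),
single-linkage agglomeration of Minkowski distances between the rows of
a distance table (the compromise tree, as a dendrogram with node
heights), and column-bootstrap support values for the latter (plain
bootstrap proportions; approximately-unbiased p-values are deliberately
NOT implemented). Plus Newick I/O, outgroup rooting, and conversion to
an ultrametric tree on a fixed height interval.

Dendrogram node heights are stored on ``node.height``; edge lengths are
kept consistent (parent height minus child height), so cophenetic
distances between leaves equal the merge heights of their MRCA.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .core import DistanceMatrix

ULTRAMETRIC_TOL = 1e-6


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(d: DistanceMatrix) -> dendropy.Tree:
    """Standard Saitou-Nei agglomeration; unrooted output.

    Ties in the Q criterion are broken by the smallest (i, j) pair in
    row-major order; negative branch lengths are clamped to zero with a
    warning.
    """
    n = len(d)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    taxa = dendropy.TaxonNamespace(d.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in d.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    D = d.values.copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            if x < -1e-9:
                warnings.warn(f"negative NJ branch length {x:g} clamped to 0")
            return 0.0
        return x

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(Q), Q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = sub[i_loc, j_loc]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = clamp(li)
        parent.add_child(nodes[j])
        nodes[j].edge.length = clamp(lj)
        # new distances to the remaining nodes
        new_row = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row) - 1] = new_row[:-1]
        D[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]

    i, j = active
    dij = D[i, j]
    if n == 2:
        root = dendropy.Node()
        root.add_child(nodes[i])
        nodes[i].edge.length = dij / 2.0
        root.add_child(nodes[j])
        nodes[j].edge.length = dij / 2.0
        tree.seed_node = root
    else:
        # attach one remaining node to the other: unrooted, 3-furcating seed
        nodes[j].add_child(nodes[i])
        nodes[i].edge.length = clamp(dij)
        tree.seed_node = nodes[j]
    tree.is_rooted = False
    return tree


def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distances of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    values = np.zeros((n, n))
    taxa = {t.label: t for t in tree.taxon_namespace}
    for a in range(n):
        for b in range(a + 1, n):
            values[a, b] = values[b, a] = pdm.patristic_distance(
                taxa[labels[a]], taxa[labels[b]]
            )
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# Single-linkage dendrograms
# ---------------------------------------------------------------------------


def _dendrogram_from_linkage(Z: np.ndarray, labels: list[str]) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = {}
    for idx, label in enumerate(labels):
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        node.height = 0.0
        nodes[idx] = node
    n = len(labels)
    for k, (a, b, h, _) in enumerate(Z):
        parent = dendropy.Node()
        parent.height = float(h)
        for child_idx in (int(a), int(b)):
            child = nodes[child_idx]
            parent.add_child(child)
            child.edge.length = max(parent.height - child.height, 0.0)
        nodes[n + k] = parent
    tree.seed_node = nodes[n + len(Z) - 1]
    tree.is_rooted = True
    return tree


def single_linkage_tree(
    d: DistanceMatrix, minkowski_p: float = 2.0
) -> dendropy.Tree:
    """Single-linkage dendrogram of the rows of a distance table.

    The rows of ``d`` are treated as feature vectors (each taxon's
    distance profile); pairwise Minkowski-p distances between rows feed
    the agglomeration, and merge heights become node heights.
    """
    if len(d) < 2:
        raise ValueError("need at least 2 taxa")
    if minkowski_p < 1:
        raise ValueError(f"Minkowski exponent must be >= 1, got {minkowski_p}")
    y = pdist(d.values, metric="minkowski", p=minkowski_p)
    Z = linkage(y, method="single")
    return _dendrogram_from_linkage(Z, list(d.labels))


def dendrogram_clades(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Map each internal node (except the root) to its leaf-label set."""
    out = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        out[leaves] = node
    return out


def bootstrap_support(
    features: np.ndarray,
    labels: list[str],
    n_boot: int = 1000,
    seed: int = 0,
    minkowski_p: float = 2.0,
) -> dendropy.Tree:
    """Column bootstrap of a single-linkage dendrogram.

    Features (columns) are resampled with replacement ``n_boot`` times;
    the support of an internal node is the percentage of replicate
    dendrograms containing the same leaf set (bootstrap proportion,
    0-100, stored on ``node.support`` and as the node label). The root
    carries no support value.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    features = np.asarray(features, dtype=float)
    rng = np.random.default_rng(seed)
    base = _dendrogram_from_linkage(
        linkage(pdist(features, metric="minkowski", p=minkowski_p), method="single"),
        list(labels),
    )
    clades = dendrogram_clades(base)
    counts = {c: 0 for c in clades}
    n_cols = features.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = features[:, cols]
        Zr = linkage(pdist(rep, metric="minkowski", p=minkowski_p), method="single")
        rep_tree = _dendrogram_from_linkage(Zr, list(labels))
        rep_clades = set(dendrogram_clades(rep_tree))
        for c in counts:
            if c in rep_clades:
                counts[c] += 1
    for clade, node in clades.items():
        node.support = 100.0 * counts[clade] / n_boot
        node.label = f"{node.support:g}"
    return base


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def to_newick(tree: dendropy.Tree) -> str:
    s = tree.as_string(
        schema="newick",
        suppress_rooting=False,
        real_value_format_specifier=".6f",
    )
    return s.strip()


def from_newick(s: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=s, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                pass
    return tree


# ---------------------------------------------------------------------------
# Rooting and ultrametric conversion
# ---------------------------------------------------------------------------


def root_on_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Root (a clone of) the tree on the edge above the given leaf."""
    tree = tree.clone(depth=1)
    leaf = None
    for l in tree.leaf_node_iter():
        if l.taxon is not None and l.taxon.label == outgroup_label:
            leaf = l
            break
    if leaf is None:
        raise ValueError(f"outgroup {outgroup_label!r} not found in tree")
    length = leaf.edge.length or 0.0
    tree.reroot_at_edge(
        leaf.edge, length1=length / 2.0, length2=length / 2.0,
        update_bipartitions=False,
    )
    tree.is_rooted = True
    return tree


def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def node_heights(
    tree: dendropy.Tree, tol: float = ULTRAMETRIC_TOL
) -> dict[dendropy.Node, float]:
    """Node ages of an ultrametric tree (leaves at 0); error if not
    ultrametric within ``tol`` relative to tree height."""
    depths = node_depths(tree)
    leaf_depths = [depths[l] for l in tree.leaf_node_iter()]
    H = max(leaf_depths)
    scale = max(H, 1.0)
    if max(leaf_depths) - min(leaf_depths) > tol * scale:
        raise ValueError(
            "tree is not ultrametric: leaf depth spread "
            f"{max(leaf_depths) - min(leaf_depths):g} exceeds tolerance"
        )
    return {node: H - depth for node, depth in depths.items()}


def cophenetic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """MRCA heights between all leaf pairs of an ultrametric tree."""
    heights = node_heights(tree)
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    labels = [l.taxon.label for l in leaves]
    n = len(labels)
    values = np.zeros((n, n))
    # collect leaf sets bottom-up
    leafsets = {}
    index = {l: k for k, l in enumerate(leaves)}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = [index[node]]
        else:
            kids = [leafsets[c] for c in node.child_nodes()]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for x in kids[a]:
                        for y in kids[b]:
                            values[x, y] = values[y, x] = heights[node]
            leafsets[node] = [x for kid in kids for x in kid]
    return DistanceMatrix(labels, values)


def make_ultrametric(
    tree: dendropy.Tree,
    interval: tuple[float, float] = (0.0, 10.0),
    outgroup: str | None = None,
) -> dendropy.Tree:
    """Return an ultrametric copy with leaves at lo and the root at hi.

    A tree that is already ultrametric (a dendrogram) is linearly
    rescaled. Otherwise the tree must be rooted (or an outgroup given to
    root it); each internal node's height is the mean path length to its
    descendant leaves, clamped to be at least the height of its children,
    then rescaled to the interval.
    """
    lo, hi = interval
    if hi <= lo:
        raise ValueError("interval must satisfy hi > lo")
    if outgroup is not None:
        tree = root_on_outgroup(tree, outgroup)
    elif not tree.is_rooted:
        raise ValueError("tree is unrooted and no outgroup was declared")
    else:
        tree = tree.clone(depth=1)

    try:
        heights = node_heights(tree)
    except ValueError:
        heights = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                heights[node] = 0.0
            else:
                dists = []
                for leaf in node.leaf_iter():
                    d, cur = 0.0, leaf
                    while cur is not node:
                        d += cur.edge.length or 0.0
                        cur = cur.parent_node
                    dists.append(d)
                h = float(np.mean(dists))
                heights[node] = max([h] + [heights[c] for c in node.child_nodes()])

    root_h = heights[tree.seed_node]
    if root_h <= 0:
        raise ValueError("tree has zero height; cannot rescale")
    factor = (hi - lo) / root_h
    for node in tree.preorder_node_iter():
        node.height = lo + heights[node] * factor if not node.is_leaf() else lo
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            child.edge.length = max(node.height - child.height, 0.0)
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def prune_taxa(tree: dendropy.Tree, labels: list[str]) -> dendropy.Tree:
    """Remove the given leaves (e.g. the outgroup) from a clone.

    The clone is migrated to a fresh taxon namespace so the caller's
    tree (which shares its namespace with level-1 clones) is untouched.
    """
    tree = tree.clone(depth=1)
    drop = {
        l.taxon for l in tree.leaf_node_iter()
        if l.taxon is not None and l.taxon.label in set(labels)
    }
    if drop:
        tree.prune_taxa(list(drop), suppress_unifurcations=True)
    remaining = [l.taxon.label for l in tree.leaf_node_iter()]
    tree.migrate_taxon_namespace(dendropy.TaxonNamespace(remaining))
    return tree
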