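"""Neighbor-Joining tree construction, bootstrap support, and rooting.

The agglomeration is the classic Saitou–Nei algorithm with the Q-criterion.
Two conventions are fixed to make trees bit-reproducible:

* ties in Q are broken by the lowest (i, j) pair in node-creation order;
* a negative branch length is clamped to zero and the deficit is absorbed by
  its sister edge (preserving the length of the path through the new node).

Trees are :class:`dendropy.Tree` objects; bootstrap supports (percent of
column-resampled replicates containing the same bipartition) are stored as
internal-node labels, the convention Newick viewers expect.
"""

from __future__ import annotations

import numpy as np
import dendropy

from .distances import DeletionRule, DistanceMatrix, DistanceModel, pairwise_distance
from .io import AlignedSequenceSet

__all__ = [
    "NewickParseError",
    "nj_tree",
    "bootstrap_support",
    "midpoint_root",
    "outgroup_root",
    "write_newick",
    "read_newick",
    "bipartitions",
    "tree_length",
]


class NewickParseError(ValueError):
    """Malformed Newick input."""


class _Subtree:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=()):
        self.label = label
        self.children = list(children)   # (subtree, branch_length)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # absorb a negative branch into its sister so the i--j path is preserved
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Build the unrooted Neighbor-Joining tree for a distance matrix.

    Requires at least 3 labels.  The result has a trifurcating seed node
    (unrooted convention) and non-negative branch lengths.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("Neighbor-Joining needs at least 3 labels")
    D = dm.d.astype(float).copy()
    nodes: list[_Subtree] = [_Subtree(label=lab) for lab in dm.labels]

    while len(nodes) > 3:
        r = D.shape[0]
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        # triu_indices enumerates i<j in row-major (creation) order and
        # argmin returns the first minimum, which is the tie-break rule
        iu, ju = np.triu_indices(r, k=1)
        best = int(np.argmin(Q[iu, ju]))
        i, j = int(iu[best]), int(ju[best])

        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        new = _Subtree(children=[(nodes[i], li), (nodes[j], lj)])

        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(r) if x not in (i, j)]
        D2 = np.empty((r - 1, r - 1))
        D2[: r - 2, : r - 2] = D[np.ix_(keep, keep)]
        D2[: r - 2, r - 2] = D2[r - 2, : r - 2] = dnew[keep]
        D2[r - 2, r - 2] = 0.0
        D = D2
        nodes = [nodes[x] for x in keep] + [new]

    # resolve the final three nodes around a central (unrooted) vertex
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = max(0.5 * (dab + dac - dbc), 0.0)
    lb = max(0.5 * (dab + dbc - dac), 0.0)
    lc = max(0.5 * (dac + dbc - dab), 0.0)
    center = _Subtree(children=[(nodes[0], la), (nodes[1], lb), (nodes[2], lc)])

    return _to_dendropy(center, dm.labels)


def _to_dendropy(root: _Subtree, labels: tuple[str, ...]) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=tns)

    def build(sub: _Subtree) -> dendropy.Node:
        node = dendropy.Node()
        if sub.label is not None:
            node.taxon = tns.get_taxon(sub.label)
        for child, length in sub.children:
            cn = build(child)
            node.add_child(cn)
            cn.edge.length = float(length)
        return node

    tree.seed_node = build(root)
    tree.is_rooted = False
    return tree


def _leaf_labels(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def bipartitions(tree: dendropy.Tree, nontrivial_only: bool = True
                 ) -> set[frozenset[str]]:
    """Canonical bipartition set of a tree (labels on the side not containing
    the alphabetically first leaf).  Used for topology comparison and
    bootstrap counting; rooting-invariant."""
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(all_labels)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = _leaf_labels(node)
        if ref in side:
            side = all_labels - side
        if nontrivial_only and not (1 < len(side) < len(all_labels) - 1):
            continue
        splits.add(side)
    return splits


def tree_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter())


def bootstrap_support(
    seqs: AlignedSequenceSet,
    model: DistanceModel = "MCL",
    deletion: DeletionRule = "complete",
    n_reps: int = 100,
    seed: int = 0,
) -> dendropy.Tree:
    """Point-estimate NJ tree with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement ``n_reps`` times; the
    support of each internal edge of the point tree is the percentage of
    replicate trees containing the same bipartition.  Supports are written as
    internal-node labels on the returned point tree.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    L = seqs.alignment_length
    if L == 0:
        raise ValueError("alignment length is zero")
    point = nj_tree(pairwise_distance(seqs, model=model, deletion=deletion))

    all_labels = frozenset(seqs.ids)
    ref = min(all_labels)
    counts: dict[frozenset[str], int] = {}
    targets: dict[int, frozenset[str]] = {}
    for node in point.preorder_node_iter():
        if node is point.seed_node or node.is_leaf():
            continue
        side = _leaf_labels(node)
        if ref in side:
            side = all_labels - side
        targets[id(node)] = side
        counts.setdefault(side, 0)

    rng = np.random.default_rng(seed)
    ordered_ids = sorted(seqs.ids)   # leaf-order invariance of resampling
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        resampled = AlignedSequenceSet(
            {sid: "".join(seqs.records[sid][c] for c in cols)
             for sid in ordered_ids}
        )
        rep = nj_tree(pairwise_distance(resampled, model=model, deletion=deletion))
        for side in bipartitions(rep, nontrivial_only=False):
            if side in counts:
                counts[side] += 1

    for node in point.preorder_node_iter():
        if id(node) in targets:
            pct = 100.0 * counts[targets[id(node)]] / n_reps
            node.label = str(int(round(pct)))
    return point


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a copy of the tree at the midpoint of its longest leaf-leaf path."""
    if sum(1 for _ in tree.leaf_node_iter()) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    rooted = tree.clone(depth=1)
    rooted.reroot_at_midpoint(update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def outgroup_root(tree: dendropy.Tree, outgroup_ids) -> dendropy.Tree:
    """Root a copy of the tree on the edge separating the outgroup.

    The outgroup ids must form one side of an (unrooted) bipartition of the
    tree; otherwise the outgroup is not monophyletic and an error lists it.
    """
    og = frozenset(outgroup_ids)
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    missing = og - all_labels
    if missing:
        raise ValueError(f"outgroup ids absent from tree: {sorted(missing)}")
    if not og or og == all_labels:
        raise ValueError("outgroup must be a proper non-empty subset of leaves")
    rooted = tree.clone(depth=1)
    target = None
    for node in rooted.preorder_node_iter():
        if node is rooted.seed_node:
            continue
        side = _leaf_labels(node)
        if side == og or side == all_labels - og:
            target = node
            break
    if target is None:
        raise ValueError(
            "outgroup is not monophyletic in the unrooted tree: "
            + ", ".join(sorted(og))
        )
    half = (target.edge.length or 0.0) / 2.0
    rooted.reroot_at_edge(target.edge, length1=half, length2=half,
                          update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise to Newick, supports as internal-node labels."""
    return tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=False,
        real_value_format_specifier=".12g",
    )


def read_newick(text: str) -> dendropy.Tree:
    """Parse Newick text; raises :class:`NewickParseError` on malformed input."""
    if not text or not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:   # dendropy raises schema-specific errors
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    if tree is None:
        raise NewickParseError("no tree found in Newick input")
    return tree
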