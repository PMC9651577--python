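import numpy as np
import pytest

from fawclans.io import AlignedSequenceSet


@pytest.fixture
def write_fasta(tmp_path):
    """Write records to a temp FASTA file and return its path."""

    def _write(records, name="seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for sid, seq in records:
                fh.write(f">{sid}\n{seq}\n")
        return path

    return _write


def random_binary_tree(n_leaves, rng):
    """Random rooted binary tree with exponential branch lengths.

    Returns (children, lengths, labels): children maps internal node id to its
    two children; lengths maps node id to the length of the edge above it.
    Leaves are 0..n-1 labelled t0..t(n-1).
    """
    nodes = list(range(n_leaves))
    lengths = {i: float(rng.exponential(1.0)) + 0.05 for i in nodes}
    children = {}
    nxt = n_leaves
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        children[nxt] = (a, b)
        lengths[nxt] = float(rng.exponential(1.0)) + 0.05
        nodes = [x for x in nodes if x not in (a, b)] + [nxt]
        nxt += 1
    root = nodes[0]
    lengths[root] = 0.0
    return children, lengths, root


def path_length_matrix(children, lengths, root, n_leaves):
    """Leaf-to-leaf path lengths of the tree built by random_binary_tree."""
    # depth of every node from root, then distance = d_i + d_j - 2*d_mrca
    parent = {}
    for p, (a, b) in children.items():
        parent[a] = p
        parent[b] = p

    def ancestors(v):
        out = [v]
        while v in parent:
            v = parent[v]
            out.append(v)
        return out

    depth = {}

    def fill(v, d):
        depth[v] = d
        if v in children:
            for c in children[v]:
                fill(c, d + lengths[c])

    fill(root, 0.0)
    m = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        anc_i = ancestors(i)
        set_i = set(anc_i)
        for j in range(i + 1, n_leaves):
            v = j
            while v not in set_i:
                v = parent[v]
            m[i, j] = m[j, i] = depth[i] + depth[j] - 2 * depth[v]
    return m


def make_aligned(records: dict) -> AlignedSequenceSet:
    return AlignedSequenceSet(dict(records))
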