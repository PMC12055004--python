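"""Phylogenetic tree handling: Newick I/O, patristic distances, neighbor joining.

Trees are represented as :class:`skbio.TreeNode`.  Patristic distance between
two leaves is the sum of branch lengths along the unique path connecting
them; it is invariant to the position of the root.  Neighbor joining is the
classic Saitou-Nei agglomeration and reconstructs any additive (tree-like)
distance matrix exactly.
"""

from __future__ import annotations

import io
from collections import Counter

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .errors import InvalidParameterError, InvalidTreeError, MissingBranchLengthError, NewickParseError


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string into a tree.

    Internal labels (including numeric support values) are kept as node
    names but play no role in patristic computation.  Missing branch
    lengths are preserved as ``None``.

    Raises
    ------
    NewickParseError
        On malformed input or duplicate leaf labels.
    """
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick",
                             convert_underscores=False)
    except Exception as exc:  # skbio raises NewickFormatError subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    labels = [tip.name for tip in tree.tips()]
    if any(lbl is None for lbl in labels):
        raise NewickParseError("unlabeled leaf in Newick input")
    dupes = sorted(lbl for lbl, k in Counter(labels).items() if k > 1)
    if dupes:
        raise NewickParseError(f"duplicate leaf labels: {dupes}")
    return tree


def read_newick(path) -> TreeNode:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: TreeNode, path=None) -> str:
    """Serialize a tree to Newick; writes to ``path`` if given."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _check_branch_lengths(tree: TreeNode) -> None:
    for node in tree.traverse(include_self=False):
        if node.length is None:
            name = node.name or f"internal node with tips {sorted(t.name for t in node.tips())}"
            raise MissingBranchLengthError(str(name))
        if not np.isfinite(node.length):
            raise InvalidTreeError(f"non-finite branch length on {node.name!r}")
        if node.length < 0:
            raise InvalidTreeError(f"negative branch length on {node.name!r}")


def patristic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Pairwise path-length (patristic) distances between all leaves.

    Entry (i, j) is the sum of branch lengths on the unique path between
    leaves i and j.  The root's own length, if any, cancels out of every
    path, so the result is independent of rooting.
    """
    _check_branch_lengths(tree)
    return tree.tip_tip_distances()


def minmax_scale(dm: DistanceMatrix) -> DistanceMatrix:
    """Optional min-max rescaling of off-diagonal distances to [0, 1].

    Provided for comparing matrices produced by different tree methods on a
    common scale; Pearson correlation is unaffected by this map.
    """
    vals = dm.condensed_form()
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise InvalidParameterError("cannot min-max scale a constant matrix")
    return DistanceMatrix((dm.data - lo) / (hi - lo) * (dm.data > 0), ids=dm.ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining on a distance matrix.

    Uses the standard Q-criterion; ties broken by the first (row-major)
    minimum, so the output is deterministic.  Negative inferred branch
    lengths are clamped to zero; the number of clamped branches is recorded
    on the returned tree as ``tree.n_clamped_negative``.  On an additive
    matrix the returned tree's patristic matrix reproduces the input
    exactly (to floating-point round-off).

    The result is an unrooted tree presented with a trifurcating root.
    """
    if len(dm.ids) < 3:
        raise InvalidParameterError("neighbor joining needs >= 3 taxa")
    if not np.all(np.isfinite(dm.data)):
        raise InvalidParameterError("distance matrix contains non-finite entries")

    d = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    clamped = 0

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = _clamp(li)
        child_j.length = _clamp(lj)
        new = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([np.hstack([d[np.ix_(keep, keep)], dnew[keep, None]]),
                       np.hstack([dnew[keep], [0.0]])])
        nodes = [nodes[k] for k in keep] + [new]

    # terminal 3-taxon star: branch lengths from the three pairwise distances
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    lengths = (0.5 * (d01 + d02 - d12),
               0.5 * (d01 + d12 - d02),
               0.5 * (d02 + d12 - d01))
    for node, ln in zip(nodes, lengths):
        node.length = _clamp(ln)
    root = TreeNode(children=list(nodes))
    root.n_clamped_negative = clamped
    return root
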