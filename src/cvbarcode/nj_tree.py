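"""Neighbor-joining tree construction and Newick serialization.

Canonical Saitou-Nei NJ: at each step join the pair (i, j) minimizing

    Q(i, j) = (n - 2) d(i, j) - r_i - r_j,      r_i = sum_k d(i, k),

attach limbs l_i = d(i,j)/2 + (r_i - r_j) / (2(n-2)), l_j = d(i,j) - l_i,
and reduce the matrix with d(u, k) = (d(i,k) + d(j,k) - d(i,j)) / 2. The
result is an unrooted tree, represented with a trifurcating root node. Ties
in Q are broken deterministically by the smallest (row, column) index pair,
so runs are reproducible. NJ is consistent: on an additive matrix it
recovers the generating topology and branch lengths exactly.

Branch lengths may come out negative on non-additive input; they are kept
as produced by default (as stock PHYLIP neighbor also reports them), with an
optional clamp that zeroes a negative limb and moves the deficit to its
sister.

Trees are ``skbio.tree.TreeNode`` objects throughout.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
from skbio.tree import TreeNode

__all__ = ["neighbor_joining", "write_newick", "newick_string", "read_newick"]


def neighbor_joining(
    ids: list[str] | tuple[str, ...],
    values: np.ndarray,
    clamp_negative: bool = False,
) -> TreeNode:
    """Build an unrooted NJ tree from a labeled symmetric distance matrix.

    Parameters
    ----------
    ids : sequence of str
        Unique leaf labels, one per matrix row.
    values : (n, n) array
        Symmetric distances with zero diagonal; n >= 3.
    clamp_negative : bool
        Zero out negative limb lengths, adding the deficit to the sister
        limb (PHYLIP-compatible alternative); default keeps them.
    """
    d = np.array(values, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {n}")
    if d.shape != (n, n) or len(ids) != n:
        raise ValueError("ids and matrix shape disagree")
    if len(set(ids)) != n:
        raise ValueError("leaf labels must be unique")
    if np.abs(d - d.T).max() > 1e-9:
        raise ValueError("matrix asymmetry exceeds 1e-9")

    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in ids]

    while len(nodes) > 3:
        m = d.shape[0]
        r = d.sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        # upper triangle only: row-major argmin == smallest (row, col) tie-break
        Q[np.tril_indices(m)] = np.inf
        i, j = divmod(int(np.argmin(Q)), m)
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if clamp_negative:
            li, lj = _clamp_pair(li, lj)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])

        d_new = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = d_new
        d[:, i] = d_new
        d[i, i] = 0.0
        keep = [k for k in range(m) if k != j]
        d = d[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]

    # final trifurcation: closed-form limbs for three remaining nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    if clamp_negative:
        la, lb = _clamp_pair(la, lb)
        lb, lc = _clamp_pair(lb, lc)
        la, lc = _clamp_pair(la, lc)
    root = TreeNode()
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = length
        root.append(node)
    return root


def _clamp_pair(a: float, b: float) -> tuple[float, float]:
    if a < 0:
        return 0.0, b + a
    if b < 0:
        return a + b, 0.0
    return a, b


_NEWICK_META = set("()[]{}/\\,;:=*'\"`+<> ")


def _quote_label(label: str) -> str:
    if label and not (_NEWICK_META & set(label)):
        return label
    return "'" + label.replace("'", "''") + "'"


def _node_to_newick(node: TreeNode) -> str:
    if node.is_tip():
        body = _quote_label(node.name or "")
    else:
        body = "(" + ",".join(_node_to_newick(c) for c in node.children) + ")"
        if node.name:
            body += _quote_label(node.name)
    if node.length is not None:
        body += f":{node.length:.10g}"
    return body


def newick_string(tree: TreeNode) -> str:
    """Serialize a tree as Newick with 10-significant-digit branch lengths."""
    return _node_to_newick(tree) + ";\n"


def write_newick(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree))


def read_newick(source: str | Path) -> TreeNode:
    """Read a Newick tree from a path or a literal Newick string.

    Unquoted underscores are kept literal (sequence ids use them), not
    converted to spaces as the strict Newick convention would.
    """
    text = str(source)
    if text.lstrip().startswith("(") or text.rstrip().endswith(";"):
        handle = io.StringIO(text)
    else:
        handle = str(source)
    return TreeNode.read(handle, convert_underscores=False)
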