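"""Independent brute-force oracles used only by the tests.

Everything here deliberately takes the slow, dense, enumerate-everything
route so it shares no code path with the package implementation.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from skbio.tree import TreeNode

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int, ambig_rate: float = 0.0) -> str:
    chars = rng.choice(list(BASES), size=length)
    if ambig_rate > 0:
        hits = rng.random(length) < ambig_rate
        chars[hits] = "N"
    return "".join(chars)


# --- dense composition-vector oracle --------------------------------------

def dense_counts(seq: str, K: int) -> np.ndarray:
    """Counts over all 4^K coordinates by literal window enumeration."""
    out = np.zeros(4 ** K)
    for i in range(len(seq) - K + 1):
        window = seq[i : i + K]
        if any(c not in BASES for c in window):
            continue
        idx = 0
        for c in window:
            idx = idx * 4 + BASES.index(c)
        out[idx] += 1
    return out


def dense_frequencies(seq: str, K: int) -> np.ndarray:
    return dense_counts(seq, K) / (len(seq) - K + 1)


def dense_cosine(seq_a: str, seq_b: str, K: int) -> float:
    pa = dense_frequencies(seq_a, K)
    pb = dense_frequencies(seq_b, K)
    return float(pa @ pb / (np.linalg.norm(pa) * np.linalg.norm(pb)))


def dense_cv_distance(seq_a: str, seq_b: str, K: int) -> float:
    return (1.0 - dense_cosine(seq_a, seq_b, K)) / 2.0


def dense_background(seq: str, K: int) -> np.ndarray:
    """(p - p0)/p0 over all 4^K strings; 0 where p0 = 0."""
    p = dense_frequencies(seq, K)
    p1 = dense_frequencies(seq, K - 1)
    p2 = dense_frequencies(seq, K - 2)
    out = np.zeros(4 ** K)
    for idx in range(4 ** K):
        digits = [(idx >> (2 * (K - 1 - i))) & 3 for i in range(K)]
        left = int("".join(map(str, digits[:-1])), 4) if K > 1 else 0
        right = int("".join(map(str, digits[1:])), 4)
        mid = int("".join(map(str, digits[1:-1])), 4) if K > 2 else 0
        if p2[mid] == 0:
            continue
        p0 = p1[left] * p1[right] / p2[mid]
        if p0 == 0:
            continue
        out[idx] = (p[idx] - p0) / p0
    return out


def dense_signed_distance(seq_a: str, seq_b: str, K: int) -> float:
    va = dense_background(seq_a, K)
    vb = dense_background(seq_b, K)
    C = float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
    return (1.0 - C) / 2.0


# --- tree oracles -----------------------------------------------------------

def random_binary_tree(
    rng: np.random.Generator, n_leaves: int, blen=(0.05, 1.0), names=None
) -> TreeNode:
    """Random rooted binary tree by sequential random joins; U(lo,hi) lengths."""
    if names is None:
        names = [f"t{i}" for i in range(n_leaves)]
    nodes = [TreeNode(name=nm) for nm in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(*blen))
        b.length = float(rng.uniform(*blen))
        parent = TreeNode()
        parent.extend([a, b])
        nodes[i] = parent
        del nodes[j]
    root = nodes[0]
    root.length = None
    return root


def path_length_matrix(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    dm = tree.tip_tip_distances()
    return list(dm.ids), np.asarray(dm.data, dtype=float)


def nontrivial_splits(tree: TreeNode) -> set[frozenset[frozenset[str]]]:
    """Unrooted nontrivial bipartitions, each as a frozen pair of leaf sets."""
    all_leaves = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.traverse(include_self=False):
        clade = frozenset(t.name for t in node.tips()) if not node.is_tip() \
            else frozenset([node.name])
        if 1 < len(clade) < len(all_leaves) - 1:
            splits.add(frozenset([clade, all_leaves - clade]))
    return splits


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    s1, s2 = nontrivial_splits(t1), nontrivial_splits(t2)
    return len(s1 ^ s2)


def tree_to_graph(tree: TreeNode) -> tuple[nx.Graph, dict]:
    g = nx.Graph()
    ids = {}
    for i, node in enumerate(tree.traverse(include_self=True)):
        ids[id(node)] = i
        g.add_node(i, name=node.name if node.is_tip() else None)
    for node in tree.traverse(include_self=False):
        g.add_edge(ids[id(node.parent)], ids[id(node)])
    return g, ids


def brute_bipartition_halves(tree: TreeNode) -> set[frozenset[str]]:
    """Every leaf set obtainable by deleting one edge (both halves)."""
    g, _ = tree_to_graph(tree)
    leaves = {n: d["name"] for n, d in g.nodes(data=True) if d["name"]}
    halves: set[frozenset[str]] = set()
    for u, v in list(g.edges):
        g.remove_edge(u, v)
        for comp in nx.connected_components(g):
            halves.add(frozenset(leaves[n] for n in comp if n in leaves))
        g.add_edge(u, v)
    halves.discard(frozenset())
    halves.add(frozenset(leaves.values()))
    return halves


def brute_is_cluster(tree: TreeNode, leafset: set[str]) -> bool:
    return frozenset(leafset) in brute_bipartition_halves(tree)


def random_taxonomy_labels(rng: np.random.Generator, leaves):
    """Random genus/species assignment over a few names (data holder only)."""
    from cvbarcode.sequence_io import TaxonLabel

    return {
        leaf: TaxonLabel(
            genus=f"G{rng.integers(0, 4)}",
            species=f"s{rng.integers(0, 3)}",
            individual="",
            sequence_id=leaf,
        )
        for leaf in leaves
    }


def brute_grouping(tree: TreeNode, taxonomy, semantics: str = "and"):
    """Recompute both grouping metrics straight from the bipartition halves."""
    halves = brute_bipartition_halves(tree)
    leaves = {t.name for t in tree.tips()}

    species_members: dict[tuple[str, str], set[str]] = {}
    genus_members: dict[str, set[str]] = {}
    genus_spset: dict[str, set[str]] = {}
    for leaf in leaves:
        lab = taxonomy[leaf]
        species_members.setdefault((lab.genus, lab.species), set()).add(leaf)
        genus_members.setdefault(lab.genus, set()).add(leaf)
        genus_spset.setdefault(lab.genus, set()).add(lab.species)

    def grouped(members: set[str]) -> bool:
        return frozenset(members) in halves

    n1 = successes = 0
    for leaf in leaves:
        lab = taxonomy[leaf]
        conds = []
        if len(genus_spset[lab.genus]) >= 2:
            conds.append(grouped(genus_members[lab.genus]))
        if len(species_members[(lab.genus, lab.species)]) >= 2:
            conds.append(grouped(species_members[(lab.genus, lab.species)]))
        if not conds:
            continue
        n1 += 1
        if (all(conds) if semantics == "and" else any(conds)):
            successes += 1

    multi = [m for m in species_members.values() if len(m) >= 2]
    n2 = len(multi)
    sp_ok = sum(1 for m in multi if grouped(m))
    pct_seq = 100.0 * successes / n1 if n1 else None
    pct_sp = 100.0 * sp_ok / n2 if n2 else None
    return n1, n2, pct_seq, pct_sp


# --- weighted-combination oracle -------------------------------------------

def brute_combined_entry(dataset, matrices: dict, i: int, j: int) -> float:
    """Per-pair weighted sum recomputed from raw lengths, loop style."""
    ti, tj = dataset.taxa[i], dataset.taxa[j]
    sums = {}
    for locus in dataset.loci:
        ri = dataset.record(ti, locus)
        rj = dataset.record(tj, locus)
        sums[locus] = (ri.length_L if ri else 0) + (rj.length_L if rj else 0)
    total = sum(sums.values())
    return sum(
        (sums[locus] / total) * matrices[locus].values[i, j]
        for locus in dataset.loci
    )
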