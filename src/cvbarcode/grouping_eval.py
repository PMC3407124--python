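"""Monophyly-based grouping-effectiveness metrics on an unrooted tree.

A set of leaves is "grouped" when some edge of the unrooted tree separates
exactly that set from all other leaves (an exact bipartition — a clade under
some rooting). Two percentages summarize how well a tree matches its
taxonomy:

* sequence-level success: among the N1 sequences from genera with multiple
  species or species with multiple individuals, the fraction whose genus
  (when it has >= 2 species) and species (when it has >= 2 sequences) both
  form exclusive groups;
* species-level success: among the N2 species with >= 2 sequences, the
  fraction forming an exclusive group.

Both metrics depend only on the bipartition set, so they are invariant to
rerooting. Singleton sequences are excluded from the denominators but stay
in the tree, where they can still break other groups' monophyly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from skbio.tree import TreeNode

from .sequence_io import TaxonLabel

__all__ = [
    "GroupDetail",
    "GroupingReport",
    "TreeClusters",
    "is_cluster",
    "sequence_grouping_success",
    "species_grouping_success",
    "evaluate_grouping",
]


@dataclass(frozen=True)
class GroupDetail:
    group: str          # "Genus" or "Genus species"
    kind: str           # "genus" | "species"
    size: int
    monophyletic: bool


@dataclass(frozen=True)
class GroupingReport:
    """Denominators and success percentages of the two grouping metrics."""

    N1: int
    N2: int
    pct_sequences: float | None   # None when N1 == 0 (undefined)
    pct_species: float | None     # None when N2 == 0
    details: tuple[GroupDetail, ...] = field(default=(), repr=False)

    def to_json_dict(self) -> dict:
        return {
            "N1": self.N1,
            "N2": self.N2,
            "pct_sequences": self.pct_sequences,
            "pct_species": self.pct_species,
        }

    def details_tsv(self) -> str:
        lines = ["group\ttype\tsize\tmonophyletic"]
        for det in self.details:
            lines.append(
                f"{det.group}\t{det.kind}\t{det.size}\t"
                f"{'yes' if det.monophyletic else 'no'}"
            )
        return "\n".join(lines) + "\n"


class TreeClusters:
    """Precomputed bipartition test for one tree.

    Each node's descendant-leaf set under an arbitrary rooting is encoded as
    a bitmask; a leaf set is an exact bipartition iff its mask (or its
    complement) equals some node's mask.
    """

    def __init__(self, tree: TreeNode) -> None:
        self._index: dict[str, int] = {}
        for tip in tree.tips():
            if tip.name in self._index:
                raise ValueError(f"duplicate leaf label {tip.name!r}")
            self._index[tip.name] = len(self._index)
        self.n_leaves = len(self._index)
        self._full = (1 << self.n_leaves) - 1
        self._clades: set[int] = set()
        self._collect(tree)

    def _collect(self, node: TreeNode) -> int:
        if node.is_tip():
            mask = 1 << self._index[node.name]
        else:
            mask = 0
            for child in node.children:
                mask |= self._collect(child)
        self._clades.add(mask)
        return mask

    def leaf_labels(self) -> set[str]:
        return set(self._index)

    def is_cluster(self, leafset: set[str]) -> bool:
        if not leafset:
            raise ValueError("empty leaf set")
        mask = 0
        for label in leafset:
            try:
                mask |= 1 << self._index[label]
            except KeyError:
                raise ValueError(f"unknown leaf label {label!r}") from None
        return mask in self._clades or (self._full ^ mask) in self._clades


def is_cluster(tree: TreeNode, leafset: set[str]) -> bool:
    """True iff some edge bipartitions the leaves into (leafset, rest).

    Singletons and the full leaf set are always clusters. Prefer
    :class:`TreeClusters` when testing many sets against one tree.
    """
    return TreeClusters(tree).is_cluster(leafset)


def _groups(taxonomy: dict[str, TaxonLabel]):
    by_species: dict[tuple[str, str], set[str]] = {}
    by_genus: dict[str, set[str]] = {}
    genus_species: dict[str, set[str]] = {}
    for leaf, label in taxonomy.items():
        by_species.setdefault((label.genus, label.species), set()).add(leaf)
        by_genus.setdefault(label.genus, set()).add(leaf)
        genus_species.setdefault(label.genus, set()).add(label.species)
    return by_species, by_genus, genus_species


def evaluate_grouping(
    tree: TreeNode,
    taxonomy: dict[str, TaxonLabel],
    semantics: str = "and",
) -> GroupingReport:
    """Compute both grouping-effectiveness percentages for one tree.

    ``semantics`` controls the sequence-level verdict when both the genus
    and the species condition apply to a leaf: "and" (default) requires
    both groups to be exclusive clusters, "or" accepts either.
    """
    if semantics not in ("and", "or"):
        raise ValueError(f"semantics must be 'and' or 'or', got {semantics!r}")
    clusters = TreeClusters(tree)
    leaves = clusters.leaf_labels()
    missing = leaves - set(taxonomy)
    if missing:
        raise ValueError(f"leaves without taxonomy: {sorted(missing)[:5]}")
    taxonomy = {leaf: taxonomy[leaf] for leaf in leaves}

    by_species, by_genus, genus_species = _groups(taxonomy)
    genus_mono = {g: clusters.is_cluster(s) for g, s in by_genus.items()}
    species_mono = {sp: clusters.is_cluster(s) for sp, s in by_species.items()}

    details: list[GroupDetail] = []
    for genus in sorted(by_genus):
        if len(genus_species[genus]) >= 2:
            details.append(
                GroupDetail(genus, "genus", len(by_genus[genus]), genus_mono[genus])
            )
    for (genus, species) in sorted(by_species):
        if len(by_species[(genus, species)]) >= 2:
            details.append(
                GroupDetail(
                    f"{genus} {species}",
                    "species",
                    len(by_species[(genus, species)]),
                    species_mono[(genus, species)],
                )
            )

    n1 = 0
    seq_success = 0
    for leaf, label in taxonomy.items():
        genus_applies = len(genus_species[label.genus]) >= 2
        species_applies = len(by_species[(label.genus, label.species)]) >= 2
        if not (genus_applies or species_applies):
            continue
        n1 += 1
        verdicts = []
        if genus_applies:
            verdicts.append(genus_mono[label.genus])
        if species_applies:
            verdicts.append(species_mono[(label.genus, label.species)])
        ok = all(verdicts) if semantics == "and" else any(verdicts)
        if ok:
            seq_success += 1

    multi_species = [sp for sp, s in by_species.items() if len(s) >= 2]
    n2 = len(multi_species)
    sp_success = sum(1 for sp in multi_species if species_mono[sp])

    return GroupingReport(
        N1=n1,
        N2=n2,
        pct_sequences=(100.0 * seq_success / n1) if n1 else None,
        pct_species=(100.0 * sp_success / n2) if n2 else None,
        details=tuple(details),
    )


def sequence_grouping_success(
    tree: TreeNode,
    taxonomy: dict[str, TaxonLabel],
    semantics: str = "and",
) -> GroupingReport:
    """Sequence-level grouping success (genus/species level); see module docs."""
    return evaluate_grouping(tree, taxonomy, semantics=semantics)


def species_grouping_success(
    tree: TreeNode,
    taxonomy: dict[str, TaxonLabel],
) -> GroupingReport:
    """Species-level grouping success for species with multiple sequences."""
    return evaluate_grouping(tree, taxonomy)
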