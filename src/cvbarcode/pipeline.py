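"""End-to-end wiring: FASTA/dataset -> distance matrices -> NJ -> report."""

from __future__ import annotations

from dataclasses import dataclass

from skbio.tree import TreeNode

from .grouping_eval import GroupingReport, evaluate_grouping
from .kscan import PRESET_K
from .multilocus_distance import (
    DistanceMatrix,
    combine_matrices,
    locus_distance_matrix,
)
from .nj_tree import neighbor_joining
from .sequence_io import MultiLocusDataset

__all__ = ["PipelineResult", "resolve_k_map", "build_matrices", "run_pipeline"]


@dataclass(frozen=True)
class PipelineResult:
    per_locus: dict[str, DistanceMatrix]
    combined: DistanceMatrix
    tree: TreeNode
    report: GroupingReport
    k_map: dict[str, int]


def resolve_k_map(
    loci: list[str], k_map: dict[str, int] | None = None
) -> dict[str, int]:
    """Fill per-locus K from user overrides, then the advisory presets."""
    resolved: dict[str, int] = {}
    for locus in loci:
        if k_map and locus in k_map:
            resolved[locus] = k_map[locus]
        elif locus in PRESET_K:
            resolved[locus] = PRESET_K[locus]
        else:
            raise ValueError(
                f"no K given for locus {locus!r} and no preset exists; pass a K "
                f"or run a best-K scan"
            )
    return resolved


def build_matrices(
    dataset: MultiLocusDataset,
    k_map: dict[str, int] | None = None,
    mode: str = "raw",
) -> tuple[dict[str, DistanceMatrix], DistanceMatrix, dict[str, int]]:
    ks = resolve_k_map(dataset.loci, k_map)
    per_locus = {
        locus: locus_distance_matrix(dataset, locus, ks[locus], mode=mode)
        for locus in dataset.loci
    }
    return per_locus, combine_matrices(per_locus, dataset), ks


def run_pipeline(
    dataset: MultiLocusDataset,
    k_map: dict[str, int] | None = None,
    mode: str = "raw",
    semantics: str = "and",
    clamp_negative: bool = False,
) -> PipelineResult:
    """Distance -> weighted combination -> NJ -> grouping evaluation."""
    per_locus, combined, ks = build_matrices(dataset, k_map, mode)
    tree = neighbor_joining(
        combined.ids, combined.values, clamp_negative=clamp_negative
    )
    report = evaluate_grouping(tree, dataset.taxonomy(), semantics=semantics)
    return PipelineResult(
        per_locus=per_locus, combined=combined, tree=tree, report=report, k_map=ks
    )
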