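"""Best-K selection: scan word sizes and score single-locus trees.

For each K in the scan range the single-locus pipeline runs end to end
(CV distance matrix -> NJ tree -> grouping evaluation) and the K with the
highest sequence-level grouping success is selected; ties go to the
smallest K (cheapest vectors). The default range is K = 6..20.

Scanning is the paper-of-record protocol for a new gene region but is
slow; for the three canonical plant barcoding loci the presets
matK=14, rbcL=14, trnH-psbA=8 are offered as advisory defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .grouping_eval import evaluate_grouping
from .multilocus_distance import locus_distance_matrix
from .nj_tree import neighbor_joining
from .sequence_io import MultiLocusDataset

logger = logging.getLogger(__name__)

__all__ = ["PRESET_K", "KScanRow", "KScanResult", "best_k_scan"]

# advisory presets for the canonical plant barcoding loci
PRESET_K: dict[str, int] = {"matK": 14, "rbcL": 14, "trnH-psbA": 8}

DEFAULT_K_RANGE = (6, 20)


@dataclass(frozen=True)
class KScanRow:
    K: int
    N1: int
    pct: float | None


@dataclass(frozen=True)
class KScanResult:
    locus: str
    metric: str
    best_K: int
    table: tuple[KScanRow, ...]
    skipped: tuple[int, ...] = ()

    def to_tsv(self) -> str:
        lines = ["locus\tK\tN1\tpct"]
        for row in self.table:
            pct = "NA" if row.pct is None else f"{row.pct:.4f}"
            lines.append(f"{self.locus}\t{row.K}\t{row.N1}\t{pct}")
        return "\n".join(lines) + "\n"


def score_single_k(
    dataset: MultiLocusDataset,
    locus: str,
    K: int,
    metric: str = "sequence",
    mode: str = "raw",
) -> KScanRow:
    """Score one (locus, K): distance matrix -> NJ -> grouping success."""
    dm = locus_distance_matrix(dataset, locus, K, mode=mode)
    tree = neighbor_joining(dm.ids, dm.values)
    report = evaluate_grouping(tree, dataset.taxonomy())
    pct = report.pct_sequences if metric == "sequence" else report.pct_species
    return KScanRow(K=K, N1=report.N1 if metric == "sequence" else report.N2, pct=pct)


def best_k_scan(
    dataset: MultiLocusDataset,
    locus: str,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    metric: str = "sequence",
    mode: str = "raw",
) -> KScanResult:
    """Scan K over ``k_range`` (inclusive) and pick the argmax score.

    K values exceeding any sequence's length at the locus are skipped with
    a warning and recorded as absent from the table. Ties break toward the
    smallest K.
    """
    if metric not in ("sequence", "species"):
        raise ValueError(f"metric must be 'sequence' or 'species', got {metric!r}")
    k_min, k_max = k_range
    if k_min < 1 or k_max < k_min:
        raise ValueError(f"invalid K range {k_range}")
    max_valid = dataset.min_length(locus) - 1
    rows: list[KScanRow] = []
    skipped: list[int] = []
    for K in range(k_min, k_max + 1):
        if K > max_valid:
            logger.warning(
                "locus %s: skipping K=%d (shortest sequence has length %d)",
                locus, K, max_valid + 1,
            )
            skipped.append(K)
            continue
        rows.append(score_single_k(dataset, locus, K, metric=metric, mode=mode))
    scored = [r for r in rows if r.pct is not None]
    if not scored:
        raise ValueError(
            f"locus {locus!r}: no K in [{k_min}, {k_max}] produced a defined score"
        )
    best = max(scored, key=lambda r: (r.pct, -r.K))  # tie -> smallest K
    return KScanResult(
        locus=locus,
        metric=metric,
        best_K=best.K,
        table=tuple(rows),
        skipped=tuple(skipped),
    )
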