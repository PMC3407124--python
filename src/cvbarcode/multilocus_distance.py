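"""Per-locus CV distance matrices and the length-weighted combination.

For each locus g a symmetric matrix of CV distances D_g(i, j) is computed at
that locus's word size K_g (per-locus K may differ). The combined distance is
a per-pair convex combination

    D(i, j) = sum_g w_g(i, j) * D_g(i, j),
    w_g(i, j) = (L_g^i + L_g^j) / sum_h (L_h^i + L_h^j),

where L_g^i is the length of taxon i's sequence at locus g: each locus is
weighted by its share of the pair's summed sequence length. The weights
depend only on lengths, never on K, and sum to 1 for every pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .composition_vector import count_kstrings, cv_correlation, normalize_background
from .sequence_io import MultiLocusDataset, TaxonLabel

__all__ = [
    "DistanceMatrix",
    "PairWeights",
    "locus_distance_matrix",
    "pair_weights",
    "weight_matrices",
    "combine_matrices",
]

COMBINED = "combined"


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric distance matrix for one locus or the combination."""

    ids: tuple[str, ...]
    values: np.ndarray
    locus: str
    K_used: int | dict[str, int] | None = None

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("nonzero diagonal")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("entries outside [0, 1]")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.values[i, j])

    def permuted(self, order: list[int]) -> "DistanceMatrix":
        idx = np.asarray(order)
        return DistanceMatrix(
            ids=tuple(self.ids[i] for i in order),
            values=self.values[np.ix_(idx, idx)],
            locus=self.locus,
            K_used=self.K_used,
        )


@dataclass(frozen=True)
class PairWeights:
    """Per-locus weights for one pair of taxa; sums to 1."""

    loci: tuple[str, ...]
    weights: tuple[float, ...]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.loci, self.weights))


def _sequence_vectors(dataset: MultiLocusDataset, locus: str, K: int, mode: str):
    vectors = []
    for taxon in dataset.taxa:
        rec = dataset.record(taxon, locus)
        if rec is None:
            if dataset.strict:
                raise ValueError(
                    f"taxon {taxon.sequence_id!r} has no sequence for locus {locus!r}"
                )
            vectors.append(None)
            continue
        if rec.length_L < K:
            raise ValueError(
                f"sequence {taxon.sequence_id!r} at locus {locus!r} has length "
                f"{rec.length_L} < K={K}"
            )
        cv = count_kstrings(rec.residues, K)
        if mode == "background":
            cv = normalize_background(
                cv,
                count_kstrings(rec.residues, K - 1),
                count_kstrings(rec.residues, K - 2),
            )
        vectors.append(cv)
    return vectors


def locus_distance_matrix(
    dataset: MultiLocusDataset,
    locus: str,
    K: int,
    mode: str = "raw",
) -> DistanceMatrix:
    """CV distance matrix for one locus: D(i,j) = (1 - C(i,j)) / 2.

    The pairwise cosines are evaluated in one sparse matrix product: each
    row of a CSR matrix holds one taxon's normalized frequency vector over
    the union of observed K-strings, so C = A A^T without ever allocating a
    dense 4^K axis.
    """
    if mode not in ("raw", "background"):
        raise ValueError(f"unknown mode {mode!r}")
    vectors = _sequence_vectors(dataset, locus, K, mode)
    present = [i for i, v in enumerate(vectors) if v is not None]
    if not present:
        raise ValueError(f"no sequences for locus {locus!r}")
    for i in present:
        if vectors[i].norm == 0.0:
            raise ValueError(
                f"zero-norm composition vector for taxon "
                f"{dataset.taxa[i].sequence_id!r} at locus {locus!r}"
            )

    all_keys = np.unique(np.concatenate([vectors[i].keys for i in present]))
    indptr = [0]
    indices_parts = []
    data_parts = []
    for i in present:
        v = vectors[i]
        indices_parts.append(np.searchsorted(all_keys, v.keys))
        data_parts.append(v.values / v.norm)
        indptr.append(indptr[-1] + v.keys.size)
    A = sp.csr_matrix(
        (
            np.concatenate(data_parts),
            np.concatenate(indices_parts),
            np.asarray(indptr),
        ),
        shape=(len(present), all_keys.size),
    )
    C = np.asarray((A @ A.T).todense())
    np.clip(C, -1.0, 1.0, out=C)
    D_sub = (1.0 - C) / 2.0

    n = len(dataset.taxa)
    D = np.zeros((n, n))
    ix = np.asarray(present)
    D[np.ix_(ix, ix)] = D_sub
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    np.clip(D, 0.0, 1.0, out=D)
    return DistanceMatrix(
        ids=tuple(dataset.sequence_ids), values=D, locus=locus, K_used=K
    )


def pair_weights(
    dataset: MultiLocusDataset,
    pair: tuple[TaxonLabel | str, TaxonLabel | str],
) -> PairWeights:
    """Length-share weights of each locus for one pair of taxa.

    w_g = (L_g^i + L_g^j) / sum_h (L_h^i + L_h^j); a locus absent from
    either taxon (non-strict datasets) gets weight 0 and the rest
    renormalize. The weights are independent of K by construction.
    """
    sums = []
    for locus in dataset.loci:
        ri = dataset.record(pair[0], locus)
        rj = dataset.record(pair[1], locus)
        if ri is None or rj is None:
            if dataset.strict:
                sid = pair[0] if ri is None else pair[1]
                raise ValueError(f"taxon {sid!r} lacks locus {locus!r}")
            sums.append(0.0)
        else:
            sums.append(float(ri.length_L + rj.length_L))
    total = sum(sums)
    if total == 0:
        raise ValueError(f"pair {pair!r}: no shared locus with nonzero length")
    return PairWeights(
        loci=tuple(dataset.loci), weights=tuple(s / total for s in sums)
    )


def weight_matrices(dataset: MultiLocusDataset) -> dict[str, np.ndarray]:
    """All-pairs weight matrices W_g with W_g[i,j] = w_g(i, j).

    Vectorized form of :func:`pair_weights`; the two agree exactly.
    """
    n = len(dataset.taxa)
    numerators = {}
    denom = np.zeros((n, n))
    for locus in dataset.loci:
        lens = dataset.lengths(locus).astype(float)
        pair_len = lens[:, None] + lens[None, :]
        present = (lens > 0).astype(float)
        both = present[:, None] * present[None, :]
        numerators[locus] = pair_len * both
        denom += numerators[locus]
    off = ~np.eye(n, dtype=bool)
    if np.any(denom[off] == 0):
        bad = np.argwhere((denom == 0) & off)[0]
        raise ValueError(
            f"taxa {dataset.taxa[bad[0]].sequence_id!r} and "
            f"{dataset.taxa[bad[1]].sequence_id!r} share no locus"
        )
    np.fill_diagonal(denom, 1.0)  # diagonal weights are unused
    return {locus: num / denom for locus, num in numerators.items()}


def combine_matrices(
    per_locus: dict[str, DistanceMatrix],
    dataset: MultiLocusDataset,
) -> DistanceMatrix:
    """Length-weighted combination of per-locus distance matrices.

    combined(i,j) = sum_g w_g(i,j) * D_g(i,j); because weights are convex,
    each combined entry lies between the per-locus min and max for that pair.
    Per-locus matrices may have been computed at different K.
    """
    ids = tuple(dataset.sequence_ids)
    if set(per_locus) != set(dataset.loci):
        raise ValueError(
            f"per-locus matrices {sorted(per_locus)} do not match dataset "
            f"loci {sorted(dataset.loci)}"
        )
    for locus, dm in per_locus.items():
        if dm.ids != ids:
            raise ValueError(f"taxon order mismatch in matrix for locus {locus!r}")
    W = weight_matrices(dataset)
    n = len(ids)
    combined = np.zeros((n, n))
    for locus in dataset.loci:
        combined += W[locus] * per_locus[locus].values
    combined = (combined + combined.T) / 2.0
    np.fill_diagonal(combined, 0.0)
    assert combined.min() >= 0.0 and combined.max() <= 1.0 + 1e-12
    np.clip(combined, 0.0, 1.0, out=combined)
    return DistanceMatrix(
        ids=ids,
        values=combined,
        locus=COMBINED,
        K_used={locus: per_locus[locus].K_used for locus in dataset.loci},
    )
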