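"""Sparse K-string composition vectors and the CV correlation distance.

The composition vector (CV) of a DNA sequence of length L at word size K is
the 4^K-dimensional vector of observed K-string frequencies
``p(s) = n(s) / (L - K + 1)``, where n(s) counts occurrences of the K-string
s among the L - K + 1 sliding windows (shift one nucleotide at a time).
Vectors are stored sparsely, keyed by 2-bit-packed integers (A=0, C=1, G=2,
T=3): dimension 4^14 ~ 2.7e8 makes dense storage infeasible, while a single
sequence contributes at most L - K + 1 nonzero keys.

The correlation between two sequences is the projection (cosine) of one
frequency vector on the other, and the CV distance is D = (1 - C) / 2.
With raw frequencies all entries are nonnegative, so C is in [0, 1] and D in
[0, 0.5]. The optional Markov background normalization replaces p(s) by
(p(s) - p0(s)) / p0(s) with the (K-2)-order Markov expectation p0; those
vectors are signed, so C may be negative and D ranges over [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CompositionVector",
    "SignedCompositionVector",
    "CVDistanceEntry",
    "count_kstrings",
    "frequencies",
    "cv_correlation",
    "normalize_background",
    "kstring_to_index",
    "index_to_kstring",
]

_BASES = "ACGT"

# residue byte -> 2-bit code; 255 marks anything outside {A,C,G,T}
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i


def kstring_to_index(kstring: str) -> int:
    """2-bit pack a K-string (A=0, C=1, G=2, T=3, big-endian)."""
    idx = 0
    for ch in kstring.upper():
        code = _CODE_LUT[ord(ch)]
        if code > 3:
            raise ValueError(f"non-ACGT character {ch!r} in K-string {kstring!r}")
        idx = (idx << 2) | int(code)
    return idx


def index_to_kstring(index: int, K: int) -> str:
    """Inverse of :func:`kstring_to_index`."""
    return "".join(_BASES[(index >> (2 * (K - 1 - i))) & 3] for i in range(K))


@dataclass(frozen=True)
class CompositionVector:
    """Sparse K-string count vector for one sequence at one K.

    ``keys`` are sorted 2-bit-packed K-strings; ``counts`` the matching
    occurrence counts. ``total_windows`` is always L - K + 1 — the frequency
    denominator stays L - K + 1 even when windows containing ambiguous
    residues were skipped, so sum(counts) <= total_windows.
    """

    K: int
    keys: np.ndarray          # int64, sorted ascending, unique
    counts: np.ndarray        # int64, aligned with keys
    total_windows: int
    norm: float = field(init=False)

    def __post_init__(self) -> None:
        freqs = self.counts / self.total_windows
        object.__setattr__(self, "norm", float(np.sqrt(np.dot(freqs, freqs))))

    @property
    def values(self) -> np.ndarray:
        """Frequency entries aligned with ``keys``."""
        return self.counts / self.total_windows

    def as_dict(self) -> dict[str, int]:
        """Counts keyed by the literal K-string (for debugging/dumps)."""
        return {
            index_to_kstring(int(k), self.K): int(c)
            for k, c in zip(self.keys, self.counts)
        }

    def to_tsv(self) -> str:
        """Debug dump: kstring, count, frequency — lexicographic order."""
        lines = ["kstring\tcount\tfrequency"]
        for k, c in zip(self.keys, self.counts):  # packed order == lexicographic
            lines.append(
                f"{index_to_kstring(int(k), self.K)}\t{int(c)}"
                f"\t{int(c) / self.total_windows:.10g}"
            )
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class SignedCompositionVector:
    """Background-normalized CV: signed entries (p - p0)/p0, sparse."""

    K: int
    keys: np.ndarray          # int64, sorted ascending, unique
    entries: np.ndarray       # float64, aligned with keys
    norm: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "norm", float(np.sqrt(np.dot(self.entries, self.entries)))
        )

    @property
    def values(self) -> np.ndarray:
        return self.entries


@dataclass(frozen=True)
class CVDistanceEntry:
    """Projection correlation C and the CV distance D = (1 - C)/2."""

    correlation_C: float
    distance_D: float


def _encode(residues: str) -> np.ndarray:
    return _CODE_LUT[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def _packed_windows(residues: str, K: int) -> tuple[np.ndarray, np.ndarray]:
    """All L-K+1 packed windows plus a validity mask (no ambiguous base)."""
    codes = _encode(residues)
    L = codes.size
    n_win = L - K + 1
    invalid = (codes > 3).astype(np.int64)
    # window i is valid iff no invalid residue in [i, i+K)
    csum = np.concatenate(([0], np.cumsum(invalid)))
    valid = (csum[K:] - csum[:-K]) == 0
    safe = np.where(codes > 3, 0, codes).astype(np.int64)
    packed = np.zeros(n_win, dtype=np.int64)
    for off in range(K):
        packed |= safe[off : off + n_win] << (2 * (K - 1 - off))
    return packed, valid


def count_kstrings(residues: str, K: int) -> CompositionVector:
    """Count K-strings by sliding a window one position at a time.

    Windows containing any non-ACGT symbol are skipped; the frequency
    denominator remains L - K + 1 regardless.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    L = len(residues)
    if L < K:
        raise ValueError(
            f"sequence of length {L} is shorter than K={K}; cannot count K-strings"
        )
    packed, valid = _packed_windows(residues, K)
    keys, counts = np.unique(packed[valid], return_counts=True)
    return CompositionVector(
        K=K,
        keys=keys.astype(np.int64),
        counts=counts.astype(np.int64),
        total_windows=L - K + 1,
    )


def frequencies(cv: CompositionVector) -> dict[str, float]:
    """Observed frequencies n(s)/(L-K+1), keyed by the literal K-string."""
    if cv.total_windows <= 0:
        raise ValueError("composition vector has no windows")
    return {
        index_to_kstring(int(k), cv.K): int(c) / cv.total_windows
        for k, c in zip(cv.keys, cv.counts)
    }


def cv_correlation(
    a: CompositionVector | SignedCompositionVector,
    b: CompositionVector | SignedCompositionVector,
) -> CVDistanceEntry:
    """Projection correlation of two composition vectors and D = (1-C)/2.

    The dot product accumulates over the sorted intersection of the two key
    sets, so C(a, b) == C(b, a) bit-for-bit.
    """
    if a.K != b.K:
        raise ValueError(f"K mismatch: {a.K} vs {b.K}")
    if a.norm == 0.0 or b.norm == 0.0:
        raise ValueError(
            "zero-norm composition vector: correlation undefined "
            "(homopolymer under background normalization?)"
        )
    # identical vectors correlate exactly: avoids sqrt round-off on D(a,a)
    if a.keys.size == b.keys.size and np.array_equal(a.keys, b.keys) and \
            np.array_equal(a.values, b.values):
        return CVDistanceEntry(correlation_C=1.0, distance_D=0.0)
    _, ia, ib = np.intersect1d(
        a.keys, b.keys, assume_unique=True, return_indices=True
    )
    dot = float(np.dot(a.values[ia], b.values[ib]))
    C = dot / (a.norm * b.norm)
    C = min(1.0, max(-1.0, C))
    return CVDistanceEntry(correlation_C=C, distance_D=(1.0 - C) / 2.0)


def normalize_background(
    cv: CompositionVector,
    cv_km1: CompositionVector,
    cv_km2: CompositionVector,
) -> SignedCompositionVector:
    """Markov background normalization: entries (p(s) - p0(s)) / p0(s).

    p0(a1..aK) = p(a1..aK-1) * p(a2..aK) / p(a2..aK-1) is the (K-2)-order
    Markov expectation built from the same sequence's (K-1)- and (K-2)-string
    frequencies. Strings with p0 = 0 contribute entry 0 (dropped from the
    sparse support); observed strings with p0 > 0 but count 0 get entry -1.
    """
    K = cv.K
    if K < 3:
        raise ValueError("background normalization requires K >= 3")
    if cv_km1.K != K - 1 or cv_km2.K != K - 2:
        raise ValueError("neighbor vectors must be at K-1 and K-2")

    p_k = {int(k): int(c) / cv.total_windows for k, c in zip(cv.keys, cv.counts)}
    p_k1 = {
        int(k): int(c) / cv_km1.total_windows
        for k, c in zip(cv_km1.keys, cv_km1.counts)
    }
    p_k2 = {
        int(k): int(c) / cv_km2.total_windows
        for k, c in zip(cv_km2.keys, cv_km2.counts)
    }

    mask_km2 = (1 << (2 * (K - 2))) - 1
    # group (K-1)-strings by their (K-2)-suffix / (K-2)-prefix
    by_suffix: dict[int, list[int]] = {}
    by_prefix: dict[int, list[int]] = {}
    for key in p_k1:
        by_suffix.setdefault(key & mask_km2, []).append(key)
        by_prefix.setdefault(key >> 2, []).append(key)

    keys_out: list[int] = []
    entries_out: list[float] = []
    for mid, p_mid in p_k2.items():
        lefts = by_suffix.get(mid)   # a1..aK-1 with suffix mid
        rights = by_prefix.get(mid)  # a2..aK with prefix mid
        if not lefts or not rights:
            continue
        for left in lefts:
            base = left << 2
            p_left = p_k1[left]
            for right in rights:
                s = base | (right & 3)
                p0 = p_left * p_k1[right] / p_mid
                if p0 == 0.0:
                    continue
                keys_out.append(s)
                entries_out.append((p_k.get(s, 0.0) - p0) / p0)

    keys_arr = np.asarray(keys_out, dtype=np.int64)
    order = np.argsort(keys_arr)
    return SignedCompositionVector(
        K=K,
        keys=keys_arr[order],
        entries=np.asarray(entries_out, dtype=np.float64)[order],
    )
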