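"""Canonical k-mer feature space and standardized design matrices.

Sequences are featurized by counts of short k-mers (by default all 4-mers
and 5-mers). A k-mer and its reverse complement are collapsed onto a single
feature so the representation is strand-symmetric; the canonical form of a
k-mer is the lexicographically smaller of the pair. Counts are z-scored
column-wise over the training set, and the standardization parameters are
retained so that held-out or user-supplied sequences can be projected into
the same space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_TO_INT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_TO_INT[ord(_b)] = _i
    _BASE_TO_INT[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_ints(seq: str) -> np.ndarray:
    """Map a DNA string to an int8 array (A=0, C=1, G=2, T=3, other=-1)."""
    return _BASE_TO_INT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(b: np.ndarray, k: int) -> np.ndarray:
    """Base-4 codes of all k-mers of an int sequence; -1 where any base is N."""
    L = b.size
    if L < k:
        return np.empty(0, dtype=np.int64)
    n = L - k + 1
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        window = b[j : j + n]
        codes = codes * 4 + np.maximum(window, 0)
        valid &= window >= 0
    codes[~valid] = -1
    return codes


def _revcomp_codes(k: int) -> np.ndarray:
    """Lookup table: code of a k-mer -> code of its reverse complement."""
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - tmp % 4)
        tmp //= 4
    return rc


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


@dataclass
class KmerSpace:
    """Index over canonical (reverse-complement-collapsed) k-mers.

    For the default k in {4, 5} there are 136 canonical 4-mers and 512
    canonical 5-mers, 648 features in total.
    """

    k_values: tuple[int, ...] = (4, 5)
    # per-k lookup: raw base-4 code -> global column id
    _code_to_col: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    kmers: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.k_values = tuple(sorted(self.k_values))
        col = 0
        for k in self.k_values:
            rc = _revcomp_codes(k)
            canon = np.minimum(np.arange(4**k, dtype=np.int64), rc)
            reps = np.unique(canon)
            mapping = np.empty(4**k, dtype=np.int64)
            rep_to_col = {int(r): col + i for i, r in enumerate(reps)}
            for code in range(4**k):
                mapping[code] = rep_to_col[int(canon[code])]
            self._code_to_col[k] = mapping
            self.kmers.extend(code_to_kmer(int(r), k) for r in reps)
            col += reps.size
        self.K_dim = col

    def canonical(self, kmer: str) -> int | None:
        """Column id of a k-mer, or ``None`` if it contains a non-ACGT base."""
        k = len(kmer)
        if k not in self._code_to_col:
            raise ValueError(f"k={k} not in this space (k_values={self.k_values})")
        b = seq_to_ints(kmer)
        if (b < 0).any():
            return None
        code = 0
        for v in b:
            code = code * 4 + int(v)
        return int(self._code_to_col[k][code])

    def count(self, seq: str) -> np.ndarray:
        """Raw canonical k-mer counts of one sequence (N-containing k-mers skipped)."""
        b = seq_to_ints(seq)
        out = np.zeros(self.K_dim, dtype=np.float64)
        for k in self.k_values:
            codes = _kmer_codes(b, k)
            codes = codes[codes >= 0]
            if codes.size:
                cols = self._code_to_col[k][codes]
                out += np.bincount(cols, minlength=self.K_dim)
        return out

    def count_matrix(self, seqs: list[str]) -> np.ndarray:
        """Raw count matrix, one row per sequence."""
        X = np.zeros((len(seqs), self.K_dim), dtype=np.float64)
        for i, s in enumerate(seqs):
            X[i] = self.count(s)
        return X

    def position_columns(self, seq: str, k: int) -> np.ndarray:
        """Per-start column ids for k-mers of ``seq`` (-1 where invalid)."""
        codes = _kmer_codes(seq_to_ints(seq), k)
        cols = np.full(codes.shape, -1, dtype=np.int64)
        ok = codes >= 0
        cols[ok] = self._code_to_col[k][codes[ok]]
        return cols


@dataclass
class FeatureMatrix:
    """Standardized design matrix plus the frozen standardization parameters."""

    X: np.ndarray
    col_means: np.ndarray
    col_sds: np.ndarray
    space: KmerSpace

    def transform(self, seqs: list[str]) -> np.ndarray:
        """Project new sequences using the training-set standardization."""
        C = self.space.count_matrix(seqs)
        return (C - self.col_means) / self.col_sds


def count_and_standardize(seqs: list[str], space: KmerSpace | None = None) -> FeatureMatrix:
    """Count canonical k-mers and z-score each column over the training set.

    Constant columns are set to all-zero and their sd recorded as 1 so the
    transform stays well-defined for new sequences.
    """
    if space is None:
        space = KmerSpace()
    if not seqs:
        raise ValueError("empty sequence list")
    C = space.count_matrix(seqs)
    means = C.mean(axis=0)
    sds = C.std(axis=0)
    sds = np.where(sds == 0.0, 1.0, sds)
    X = (C - means) / sds
    return FeatureMatrix(X=X, col_means=means, col_sds=sds, space=space)
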