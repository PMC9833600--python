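"""Sparse binary design matrices and interaction columns.

The design matrix X is an n-samples x p-features matrix that is both sparse
and (usually) strictly binary: each row marks which genes an siRNA silences,
or which variants a bacterial isolate carries.  Candidate effect columns of
the expanded matrix X* are element-wise products of one, two, or three
columns of X; on binary data this is a sorted-set intersection of the
columns' supports.

The matrix is stored dual-indexed (column-major and row-major) so the
active-set algorithms can walk rows as well as columns.  Realized interaction
columns are cached in a delta + Simple-8b compressed form, and duplicate
columns are detected via a 128-bit fingerprint of the support.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

#: An interaction identifier: a strictly increasing tuple of 1-3 feature
#: indices, naming a candidate column of X*.
InteractionId = Tuple[int, ...]


def iid(*indices: int) -> InteractionId:
    """Build a validated :data:`InteractionId` from 1-3 feature indices."""
    t = tuple(sorted(int(i) for i in indices))
    if not 1 <= len(t) <= 3:
        raise ValueError(f"interaction id must have 1-3 indices, got {len(t)}")
    if len(set(t)) != len(t):
        raise ValueError(f"interaction id indices must be distinct: {t}")
    if t[0] < 0:
        raise ValueError(f"negative feature index in interaction id: {t}")
    return t


class SparseBinaryMatrix:
    """Dual-indexed sparse design matrix, optionally with real entry values.

    Parameters
    ----------
    n_rows, n_cols:
        Matrix shape (samples x features).
    col_supports:
        Per column, the sorted array of row indices with a nonzero entry.
    col_values:
        Optional per-column real values aligned with ``col_supports``.
        Absent means all stored entries equal 1 (strictly binary mode).
    names:
        Optional feature names (length ``n_cols``), preserved for output.

    Row-major supports (and values) are derived on construction so that the
    two index structures always describe the same matrix.
    """

    def __init__(
        self,
        n_rows: int,
        n_cols: int,
        col_supports: Sequence[np.ndarray],
        col_values: Optional[Sequence[np.ndarray]] = None,
        names: Optional[Sequence[str]] = None,
    ):
        if len(col_supports) != n_cols:
            raise ValueError("col_supports length must equal n_cols")
        self.n_rows = int(n_rows)
        self.n_cols = int(n_cols)
        self.col_supports = [np.asarray(s, dtype=np.int64) for s in col_supports]
        for j, s in enumerate(self.col_supports):
            if s.size and (s[0] < 0 or s[-1] >= n_rows):
                raise ValueError(f"row index out of range in column {j}")
            if s.size > 1 and not np.all(np.diff(s) > 0):
                raise ValueError(f"column {j} support is not strictly increasing")
        if col_values is not None:
            self.col_values = [np.asarray(v, dtype=np.float64) for v in col_values]
            for j, (s, v) in enumerate(zip(self.col_supports, self.col_values)):
                if v.shape != s.shape:
                    raise ValueError(f"column {j} values misaligned with support")
                if np.any(v == 0.0):
                    raise ValueError(f"column {j} stores an explicit zero value")
        else:
            self.col_values = None
        if names is not None and len(names) != n_cols:
            raise ValueError("names length must equal n_cols")
        self.names = list(names) if names is not None else None
        self._build_row_major()

    def _build_row_major(self) -> None:
        rows = [[] for _ in range(self.n_rows)]
        vals = [[] for _ in range(self.n_rows)] if self.col_values is not None else None
        for j, s in enumerate(self.col_supports):
            if self.col_values is not None:
                for i, v in zip(s, self.col_values[j]):
                    rows[i].append(j)
                    vals[i].append(v)
            else:
                for i in s:
                    rows[i].append(j)
        self.row_supports = [np.asarray(r, dtype=np.int64) for r in rows]
        self.row_values = (
            [np.asarray(v, dtype=np.float64) for v in vals] if vals is not None else None
        )

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_dense(cls, arr: np.ndarray, real_values: bool = False,
                   names: Optional[Sequence[str]] = None) -> "SparseBinaryMatrix":
        arr = np.asarray(arr)
        if arr.ndim != 2:
            raise ValueError("dense input must be 2-dimensional")
        n, p = arr.shape
        supports = [np.flatnonzero(arr[:, j]).astype(np.int64) for j in range(p)]
        values = None
        if real_values:
            values = [arr[s, j].astype(np.float64) for j, s in enumerate(supports)]
        return cls(n, p, supports, col_values=values, names=names)

    @classmethod
    def from_scipy(cls, mat, real_values: bool = False,
                   names: Optional[Sequence[str]] = None) -> "SparseBinaryMatrix":
        """Build from any scipy.sparse matrix (CSC conversion internally)."""
        csc = mat.tocsc()
        csc.sum_duplicates()
        n, p = csc.shape
        supports, values = [], []
        for j in range(p):
            lo, hi = csc.indptr[j], csc.indptr[j + 1]
            idx = csc.indices[lo:hi].astype(np.int64)
            order = np.argsort(idx, kind="stable")
            supports.append(idx[order])
            if real_values:
                values.append(csc.data[lo:hi].astype(np.float64)[order])
        return cls(n, p, supports, col_values=values if real_values else None,
                   names=names)

    # -- basic queries ----------------------------------------------------

    def to_dense(self) -> np.ndarray:
        out = np.zeros((self.n_rows, self.n_cols))
        for j, s in enumerate(self.col_supports):
            out[s, j] = self.col_values[j] if self.col_values is not None else 1.0
        return out

    def column_values(self, j: int) -> np.ndarray:
        """Entry values of column ``j`` aligned with its support."""
        if self.col_values is not None:
            return self.col_values[j]
        return np.ones(self.col_supports[j].size)

    def check_transpose_consistency(self) -> bool:
        """Verify the row-major index describes the same matrix (invariant)."""
        cols = [[] for _ in range(self.n_cols)]
        for i, r in enumerate(self.row_supports):
            for j in r:
                cols[j].append(i)
        return all(
            np.array_equal(np.asarray(c, dtype=np.int64), s)
            for c, s in zip(cols, self.col_supports)
        )


def interaction_column(
    X: SparseBinaryMatrix, id: InteractionId
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Realize the X* column for ``id`` as (support, values).

    The support is the sorted intersection of the member columns' supports;
    on real-valued matrices the value at each surviving row is the product
    of the member columns' values there.  ``values`` is None in binary mode.
    """
    for i in id:
        if not 0 <= i < X.n_cols:
            raise IndexError(f"feature index {i} out of range for p={X.n_cols}")
    sup = X.col_supports[id[0]]
    vals = X.col_values[id[0]] if X.col_values is not None else None
    for i in id[1:]:
        other = X.col_supports[i]
        if vals is not None:
            sup, ia, ib = np.intersect1d(sup, other, assume_unique=True,
                                         return_indices=True)
            vals = vals[ia] * X.col_values[i][ib]
        else:
            sup = np.intersect1d(sup, other, assume_unique=True)
    return sup, vals


# -- delta + Simple-8b column compression ---------------------------------

#: Simple-8b selector table: (values per word, bits per value).  Selector k
#: is the k-th entry.  240- and 120-value modes store runs of zeros; the
#: 8x7-bit and 7x8-bit modes waste 4 of the 60 data bits.
SIMPLE8B_MODES: Tuple[Tuple[int, int], ...] = (
    (240, 0), (120, 0), (60, 1), (30, 2), (20, 3), (15, 4), (12, 5), (10, 6),
    (8, 7), (7, 8), (6, 10), (5, 12), (4, 15), (3, 20), (2, 30), (1, 60),
)

_DATA_BITS = 60
_MAX_DELTA = 1 << _DATA_BITS


class CorruptPayloadError(ValueError):
    """Raised when a compressed column payload cannot be decoded."""


@dataclass(frozen=True)
class CompressedColumn:
    """A column support stored as a Simple-8b packed delta sequence.

    ``payload`` holds 64-bit words: a 4-bit selector in the top bits chooses
    the packing mode, the low 60 bits hold the values (LSB-first).  The
    first row index is stored absolute, every later entry as the difference
    from its predecessor.  Decoding is exactly lossless.
    """

    payload: Tuple[int, ...]
    n_entries: int

    def nbytes(self) -> int:
        return 8 * len(self.payload)


def encode_column(indices: Sequence[int]) -> CompressedColumn:
    """Delta-encode and Simple-8b pack a sorted strictly-increasing index list."""
    idx = np.asarray(indices, dtype=np.int64)
    if idx.size == 0:
        return CompressedColumn((), 0)
    if idx[0] < 0:
        raise ValueError("indices must be nonnegative")
    if idx.size > 1 and not np.all(np.diff(idx) > 0):
        raise ValueError("indices must be sorted strictly increasing")
    deltas = np.empty(idx.size, dtype=np.int64)
    deltas[0] = idx[0]
    deltas[1:] = np.diff(idx)
    if int(deltas.max()) >= _MAX_DELTA:
        raise ValueError("delta does not fit in 60 bits (unrepresentable)")
    payload = []
    pos, m = 0, deltas.size
    while pos < m:
        # greedy: first (longest-run) mode whose next values all fit
        for sel, (count, bits) in enumerate(SIMPLE8B_MODES):
            k = min(count, m - pos)
            chunk = deltas[pos:pos + k]
            if bits == 0:
                ok = not chunk.any()
            else:
                ok = int(chunk.max()) < (1 << bits)
            if ok:
                word = sel << _DATA_BITS
                if bits:
                    for t in range(k):
                        word |= int(chunk[t]) << (t * bits)
                payload.append(word)
                pos += k
                break
        else:  # pragma: no cover - excluded by the range check above
            raise ValueError("no Simple-8b mode fits")
    return CompressedColumn(tuple(payload), m)


def decode_column(c: CompressedColumn) -> np.ndarray:
    """Exact inverse of :func:`encode_column` (prefix-sum of decoded deltas)."""
    need = c.n_entries
    if need == 0:
        if c.payload:
            raise CorruptPayloadError("payload words but zero entries")
        return np.empty(0, dtype=np.int64)
    deltas = np.empty(need, dtype=np.int64)
    got = 0
    used = 0
    for word in c.payload:
        if got >= need:
            raise CorruptPayloadError("trailing payload words")
        used += 1
        sel = (word >> _DATA_BITS) & 0xF
        count, bits = SIMPLE8B_MODES[sel]
        if bits == 0:
            k = min(count, need - got)
            deltas[got:got + k] = 0
            got += k
        else:
            mask = (1 << bits) - 1
            k = min(count, need - got)
            for t in range(k):
                deltas[got + t] = (word >> (t * bits)) & mask
            got += k
    if got < need:
        raise CorruptPayloadError(
            f"payload exhausted after {got} of {need} entries"
        )
    if used < len(c.payload):
        raise CorruptPayloadError("trailing payload words")
    return np.cumsum(deltas)


def column_fingerprint(indices: Sequence[int]) -> bytes:
    """128-bit digest of a column's support, for duplicate suppression.

    Equal supports always produce equal digests; digest equality is treated
    as column identity (columns with identical supports but different real
    values are deliberately considered identical).
    """
    arr = np.ascontiguousarray(np.asarray(indices, dtype=np.int64))
    return hashlib.blake2b(arr.tobytes(), digest_size=16).digest()


class DuplicateRegistry:
    """Sticky registry mapping column fingerprints to their canonical id.

    The first id admitted with a given support (in sorted-id order within a
    rebuild) becomes canonical; any later id with the same support is placed
    on the known-duplicates list and never enters the active set.
    """

    def __init__(self) -> None:
        self._canonical: dict[bytes, InteractionId] = {}
        self.known_duplicates: set[InteractionId] = set()

    def admit(self, id: InteractionId, support: Sequence[int]) -> bool:
        """Return True if ``id`` is (or becomes) canonical for its support."""
        if id in self.known_duplicates:
            return False
        digest = column_fingerprint(support)
        owner = self._canonical.get(digest)
        if owner is None:
            self._canonical[digest] = id
            return True
        if owner == id:
            return True
        self.known_duplicates.add(id)
        return False
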