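"""Brute-force reference implementations.

These define correctness for the fast search on small instances: a direct
bit-level pairwise-AND enumerator (no nibble table), a maximality verifier,
and a full closed-pattern enumerator that characterizes which maximal
all-ones submatrices pairwise-AND search can miss. Size caps keep them
honest about their exponential/naive nature; they are never a production
path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import BinaryMatrix, ValidationError
from .search import Bicluster, BiclusterSet

__all__ = [
    "OracleResult",
    "reference_pairwise_and",
    "verify_maximal",
    "enumerate_closed",
    "CapExceededError",
]


class CapExceededError(ValueError):
    """Instance exceeds the configured oracle size cap."""


@dataclass(frozen=True)
class OracleResult:
    biclusters: BiclusterSet
    method: str
    shape: tuple[int, int]


def _row_ints(matrix: BinaryMatrix) -> list[int]:
    # column c maps to bit c (LSB); internal only, containment is order-free
    return [
        int(sum(1 << c for c in np.flatnonzero(row)))
        for row in matrix.values
    ]


def _bits_to_cols(x: int) -> tuple[int, ...]:
    cols = []
    c = 0
    while x:
        if x & 1:
            cols.append(c)
        x >>= 1
        c += 1
    return tuple(cols)


def reference_pairwise_and(
    matrix: BinaryMatrix,
    r_min: int = 2,
    c_min: int = 2,
    max_rows: int = 64,
    max_cols: int = 64,
) -> BiclusterSet:
    """Whole-row bitwise-AND enumeration with explicit containment tests.

    Same contract as the fast search: for each seed pair the template is the
    AND of the two unencoded bit rows; all rows containing the template form
    the bicluster. Deduplication on the template bit-set.
    """
    n, m = matrix.shape
    if n > max_rows or m > max_cols:
        raise CapExceededError(
            f"oracle cap is {max_rows}×{max_cols}, instance is {n}×{m}"
        )
    rows = _row_ints(matrix)
    seen: set[int] = set()
    out = BiclusterSet()
    for i in range(n - 1):
        for j in range(i + 1, n):
            t = rows[i] & rows[j]
            if t in seen:
                continue
            seen.add(t)
            if bin(t).count("1") < c_min:
                continue
            members = tuple(l for l in range(n) if rows[l] & t == t)
            if len(members) < r_min:
                continue
            out.add(Bicluster(rows=members, cols=_bits_to_cols(t)))
    return out


def verify_maximal(b: Bicluster, matrix: BinaryMatrix) -> bool:
    """True iff (I, J) is all-ones and cannot be extended by any row or column."""
    vals = matrix.values
    rows = list(b.rows)
    cols = list(b.cols)
    sub = vals[np.ix_(rows, cols)]
    if not sub.all():
        raise ValidationError("bicluster is not an all-ones submatrix")
    outside_rows = [r for r in range(matrix.n_rows) if r not in set(rows)]
    if outside_rows and vals[np.ix_(outside_rows, cols)].all(axis=1).any():
        return False
    outside_cols = [c for c in range(matrix.n_cols) if c not in set(cols)]
    if outside_cols and vals[np.ix_(rows, outside_cols)].all(axis=0).any():
        return False
    return True


def enumerate_closed(
    matrix: BinaryMatrix,
    min_rows: int = 2,
    min_cols: int = 2,
    max_cols: int = 20,
) -> BiclusterSet:
    """All maximal all-ones submatrices, by closure over column sets.

    Closed column sets are exactly the intersections of row supports; the
    fixpoint of pairwise intersection over the row supports enumerates them
    all, and each closed J pairs with I = every row containing J. Exponential
    in the worst case, hence the column cap.
    """
    n, m = matrix.shape
    if m > max_cols:
        raise CapExceededError(f"closed enumeration cap is {max_cols} columns")
    supports = set(_row_ints(matrix))
    closed = set(supports)
    frontier = set(supports)
    while frontier:
        new = set()
        for a in frontier:
            for b in supports:
                x = a & b
                if x and x not in closed:
                    new.add(x)
        closed |= new
        frontier = new
    rows_int = _row_ints(matrix)
    out = BiclusterSet()
    for j_bits in sorted(closed):
        if bin(j_bits).count("1") < min_cols:
            continue
        members = tuple(l for l in range(n) if rows_int[l] & j_bits == j_bits)
        if len(members) < min_rows:
            continue
        # keep only genuinely closed column sets: J must equal the
        # intersection of the supports of its row set
        inter = rows_int[members[0]]
        for l in members[1:]:
            inter &= rows_int[l]
        if inter != j_bits:
            continue
        out.add(Bicluster(rows=members, cols=_bits_to_cols(j_bits)))
    return out
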