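"""Nibble encoding of binary rows and the submask lookup table.

Each row of a binary matrix is re-expressed as a sequence of nibbles: every
4 consecutive columns become one decimal value in D = {0..15}, most
significant bit first (column c within a nibble occupies bit position
3 - c mod 4). Rows whose length is not a multiple of 4 are zero-padded on
the right, so padded bits never contribute to templates or widths.

The submask table V = {V_i} answers row-inclusion queries by lookup instead
of repeated bitwise AND: V_0 = {0} and, for i >= 1, V_i collects the nonzero
values x with (i AND x) = x. The total membership count over all 16 sets is
66, which drives the average-case retention rate 66/256 of the search (about
one row in four survives each nibble comparison).

Two conventions coexist deliberately. ``members`` and ``probabilities``
follow the strict definition above (a zero template nibble belongs only to
V_0), which is what the 66-count and the probability classes are stated for.
The search predicate ``contains`` extends it so that a template nibble of 0
is contained in every row nibble — 0 is a submask of everything — otherwise
a template with any empty nibble would wrongly reject all rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .matrix import BinaryMatrix, ValidationError

__all__ = [
    "NIBBLE_WIDTH",
    "EncodedMatrix",
    "SubmaskTable",
    "encode_matrix",
    "decode_matrix",
    "build_submask_table",
]

NIBBLE_WIDTH = 4

# bit weights within a nibble, leftmost column first
_WEIGHTS = np.array([8, 4, 2, 1], dtype=np.uint8)

#: popcount for every nibble value (indexable by uint8 nibble arrays)
POPCOUNT = np.array([bin(v).count("1") for v in range(16)], dtype=np.uint8)


@dataclass(frozen=True)
class EncodedMatrix:
    """Per-row nibble sequences r̂_i = (d_i1, ..., d_iP)."""

    rows: np.ndarray  # N × P uint8, each value in 0..15
    n_cols: int       # original column count M
    pad_bits: int     # zero bits appended on the right, 0..3

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", np.ascontiguousarray(self.rows, dtype=np.uint8))

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    @property
    def n_nibbles(self) -> int:
        """P = ceil(M / 4)."""
        return self.rows.shape[1]


def encode_matrix(matrix: BinaryMatrix) -> EncodedMatrix:
    """Convert each binary row to its nibble (4-bit decimal) sequence.

    Nibble k of row i is the decimal value of columns 4k..4k+3, MSB first;
    e.g. the row 0101 1100 encodes to (5, 12).
    """
    bits = matrix.values
    n, m = bits.shape
    p = -(-m // NIBBLE_WIDTH)
    pad_bits = p * NIBBLE_WIDTH - m
    if pad_bits:
        bits = np.pad(bits, ((0, 0), (0, pad_bits)))
    nibbles = bits.reshape(n, p, NIBBLE_WIDTH).astype(np.uint8) @ _WEIGHTS
    return EncodedMatrix(rows=nibbles.astype(np.uint8), n_cols=m, pad_bits=pad_bits)


def decode_matrix(enc: EncodedMatrix,
                  row_labels=None, col_labels=None) -> BinaryMatrix:
    """Expand nibbles back to bits and strip padding; exact inverse of encode."""
    n, p = enc.rows.shape
    bits = (enc.rows[:, :, None] >> np.array([3, 2, 1, 0])) & 1
    bits = bits.reshape(n, p * NIBBLE_WIDTH)[:, : enc.n_cols]
    return BinaryMatrix(bits, row_labels=row_labels, col_labels=col_labels)


@dataclass(frozen=True)
class SubmaskTable:
    """The sets V = {V_i}, i in 0..15, with search probabilities and a
    16×16 membership grid for O(1) lookups.

    ``grid[t, r]`` answers "is template nibble t contained in row nibble r",
    using the zero-extension (t = 0 always contained). ``members`` and
    ``probabilities`` follow the strict printed convention.
    """

    members: tuple[frozenset, ...]
    probabilities: tuple[float, ...]
    grid: np.ndarray  # 16×16 bool

    def __post_init__(self) -> None:
        g = np.ascontiguousarray(self.grid, dtype=bool)
        g.setflags(write=False)
        object.__setattr__(self, "grid", g)

    def contains(self, template_nibble: int, row_nibble: int) -> bool:
        """True iff the template nibble is a submask of the row nibble."""
        return bool(self.grid[template_nibble, row_nibble])

    @property
    def total_membership(self) -> int:
        """Σ_i |V_i| under the strict convention (equals 66)."""
        return sum(len(v) for v in self.members)


@lru_cache(maxsize=1)
def build_submask_table() -> SubmaskTable:
    """Construct V by brute force over all 16×16 nibble pairs.

    V_0 = {0}; for i >= 1, V_i = {x in 1..15 : (i AND x) = x}. P_i is the
    fraction of j in D with i in V_j (so P_1 = 8/16, P_15 = 1/16, ...).
    """
    members = [frozenset({0})]
    for i in range(1, 16):
        members.append(frozenset(x for x in range(1, 16) if (i & x) == x))
    probabilities = tuple(
        sum(i in members[j] for j in range(16)) / 16.0 for i in range(16)
    )
    grid = np.zeros((16, 16), dtype=bool)
    for t in range(16):
        for r in range(16):
            grid[t, r] = (r & t) == t  # t == 0 row is all True
    return SubmaskTable(tuple(members), probabilities, grid)


def validate_encoded_row(row: np.ndarray, n_nibbles: int) -> np.ndarray:
    """Coerce/validate a nibble sequence against an expected length."""
    arr = np.asarray(row, dtype=np.uint8)
    if arr.ndim != 1 or arr.shape[0] != n_nibbles:
        raise ValidationError(
            f"encoded row has {arr.shape} nibbles, expected ({n_nibbles},)"
        )
    if (arr > 15).any():
        raise ValidationError("nibble values must lie in 0..15")
    return arr
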