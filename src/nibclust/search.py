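"""Maximal-bicluster enumeration from pairwise-AND templates.

For every ordered pair of seed rows (i < j) the template ρ_ij is the
nibble-wise AND of the two encoded rows; its 1-columns are the candidate
column set J. If the template is new and its width reaches c_min, every
other row is tested for inclusion — row l survives iff each template nibble
is a submask of the corresponding row nibble — and the bicluster
(matching rows, J) is emitted when it reaches r_min rows.

Two execution paths produce identical sets:

* the default vectorized path tests all rows against a template with one
  numpy expression (no per-comparison accounting);
* the instrumented path walks nibbles left to right with the submask table
  and stops a row at its first failing position, counting every membership
  check — this is the path whose comparison counts follow the best-case
  N + (M-1) / worst-case N×M analysis.

Base mode fixes r_min = c_min = 2, which yields the complete set of maximal
biclusters reachable by pairwise AND. Flex mode raises the minima and can
drop transpose-duplicate ("symmetric") clusters on square symmetric inputs
such as interaction adjacencies, and optionally truncate to the top-K by
area — fewer, larger clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .encoding import (
    POPCOUNT,
    EncodedMatrix,
    SubmaskTable,
    build_submask_table,
    encode_matrix,
    validate_encoded_row,
)
from .matrix import BinaryMatrix, ValidationError

__all__ = [
    "Template",
    "Bicluster",
    "BiclusterSet",
    "SearchParams",
    "ComparisonStats",
    "make_template",
    "row_matches_template",
    "enumerate_biclusters",
    "remove_symmetric",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Template:
    """Nibble vector ρ_ij with its derived column set and width ‖ρ‖."""

    nibbles: tuple[int, ...]
    seed_pair: tuple[int, int]

    @property
    def width(self) -> int:
        return int(POPCOUNT[np.asarray(self.nibbles, dtype=np.uint8)].sum())

    @property
    def columns(self) -> tuple[int, ...]:
        cols = []
        for k, d in enumerate(self.nibbles):
            for b in range(4):
                if d & (8 >> b):
                    cols.append(4 * k + b)
        return tuple(cols)


@dataclass(frozen=True, order=True)
class Bicluster:
    """A pair (I, J) of row and column index sets whose submatrix is all ones."""

    rows: tuple[int, ...]
    cols: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(sorted(self.rows)))
        object.__setattr__(self, "cols", tuple(sorted(self.cols)))
        if not self.rows or not self.cols:
            raise ValidationError("bicluster must have at least one row and column")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.cols)

    @property
    def area(self) -> int:
        return self.n_rows * self.n_cols

    def key(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        return (self.rows, self.cols)


class BiclusterSet:
    """Ordered, duplicate-free collection of biclusters.

    Iteration order is discovery order, which is deterministic given the
    input row order; set semantics are available through ``as_set``.
    """

    def __init__(self, items: Iterable[Bicluster] = ()) -> None:
        self._items: list[Bicluster] = []
        self._keys: set = set()
        self.seen_templates: set = set()
        for b in items:
            self.add(b)

    def add(self, b: Bicluster) -> bool:
        k = b.key()
        if k in self._keys:
            return False
        self._keys.add(k)
        self._items.append(b)
        return True

    def __iter__(self) -> Iterator[Bicluster]:
        return iter(self._items)

    def __len__(self) -> int:
        return len(self._items)

    def __contains__(self, b: Bicluster) -> bool:
        return b.key() in self._keys

    def __getitem__(self, i: int) -> Bicluster:
        return self._items[i]

    def as_set(self) -> frozenset:
        return frozenset(self._keys)

    def canonical(self) -> list[Bicluster]:
        """Sorted by (rows, cols); decouples comparisons from discovery order."""
        return sorted(self._items)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BiclusterSet):
            return NotImplemented
        return self.as_set() == other.as_set()

    def __repr__(self) -> str:
        return f"BiclusterSet(n={len(self)})"


@dataclass
class SearchParams:
    """Search configuration.

    base mode forces r_min = c_min = 2 (the full maximal-bicluster set);
    flex mode honours user minima plus optional symmetric removal and
    top-K truncation by area (off by default).
    """

    r_min: int = 2
    c_min: int = 2
    mode: str = "base"
    remove_symmetric: bool = False
    top_k: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("base", "flex"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "base" and (self.r_min, self.c_min) != (2, 2):
            logger.warning(
                "base mode forces r_min=c_min=2 (requested %d/%d)",
                self.r_min, self.c_min,
            )
            self.r_min = 2
            self.c_min = 2
        if self.r_min < 2:
            raise ValidationError("r_min must be >= 2 (seeds are row pairs)")
        if self.c_min < 1:
            raise ValidationError("c_min must be >= 1")
        if self.top_k is not None and self.top_k < 1:
            raise ValidationError("top_k must be positive")


@dataclass
class ComparisonStats:
    """Exact nibble-membership check accounting for an instrumented run.

    One ``contains`` call counts as one comparison. For each scanned
    template: the total checks spent on non-seed rows, and the K-sequence —
    how many rows were excluded at each nibble position (position of their
    first failing nibble).
    """

    n_rows: int
    n_nibbles: int
    per_template_checks: list[int] = field(default_factory=list)
    rows_excluded_per_column: list[list[int]] = field(default_factory=list)

    @property
    def total_checks(self) -> int:
        return sum(self.per_template_checks)

    @property
    def n_templates(self) -> int:
        return len(self.per_template_checks)

    def survivors_per_position(self) -> np.ndarray:
        """Mean number of rows still in play entering each nibble position."""
        if not self.rows_excluded_per_column:
            return np.zeros(self.n_nibbles)
        k = np.asarray(self.rows_excluded_per_column, dtype=float)
        n_scan = self.n_rows - 2
        entering = n_scan - np.concatenate(
            [np.zeros((k.shape[0], 1)), np.cumsum(k, axis=1)[:, :-1]], axis=1
        )
        return entering.mean(axis=0)

    def retention_per_position(self) -> np.ndarray:
        """Fraction of rows entering position k+1 among those entering k."""
        s = self.survivors_per_position()
        k = np.asarray(self.rows_excluded_per_column, dtype=float)
        leaving = s - k.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(s > 0, leaving / s, np.nan)


def make_template(enc: EncodedMatrix, i: int, j: int) -> Template:
    """ρ_ij: nibble-wise AND of encoded rows i and j (i < j)."""
    n = enc.n_rows
    if not (0 <= i < j < n):
        raise IndexError(f"seed pair ({i}, {j}) invalid for {n} rows")
    nib = enc.rows[i] & enc.rows[j]
    return Template(nibbles=tuple(int(x) for x in nib), seed_pair=(i, j))


def row_matches_template(
    enc_row: np.ndarray,
    template: Template,
    table: SubmaskTable | None = None,
) -> tuple[bool, int]:
    """Submask-table inclusion test with early exit.

    Returns (matched, checks_used): positions are examined left to right and
    the scan stops at the first nibble where the template is not a submask
    of the row — a row failing any column is excluded outright.
    """
    if table is None:
        table = build_submask_table()
    row = validate_encoded_row(enc_row, len(template.nibbles))
    checks = 0
    for k, t_nib in enumerate(template.nibbles):
        checks += 1
        if not table.contains(t_nib, int(row[k])):
            return False, checks
    return True, checks


def _columns_from_mask(nib: np.ndarray, n_cols: int) -> tuple[int, ...]:
    bits = (nib[:, None] >> np.array([3, 2, 1, 0])) & 1
    cols = np.flatnonzero(bits.reshape(-1))
    return tuple(int(c) for c in cols if c < n_cols)


def enumerate_biclusters(
    matrix: BinaryMatrix,
    params: SearchParams | None = None,
    collect_stats: bool = False,
    _skip_sparse_seeds: bool = True,
) -> tuple[BiclusterSet, ComparisonStats | None]:
    """Enumerate biclusters from all seed-row pairs.

    Seed pairs iterate lexicographically over the original row order; a
    template is scanned at most once (its full nibble vector is the
    uniqueness key, recorded even below c_min so identical templates are
    never rescanned). Seed rows always belong to the emitted row set. Rows
    with fewer than c_min ones are skipped as seeds — their templates can
    never reach the width threshold — but are still scanned for inclusion.

    Returns the bicluster set and, when ``collect_stats`` is true, exact
    comparison statistics from the submask-table path.
    """
    if params is None:
        params = SearchParams()
    enc = encode_matrix(matrix)
    rows = enc.rows
    n, p = rows.shape
    result = BiclusterSet()
    stats = ComparisonStats(n_rows=n, n_nibbles=p) if collect_stats else None
    if n < 2 or params.r_min > n or params.c_min > matrix.n_cols:
        return _postprocess(result, matrix, params)

    popc = POPCOUNT[rows].sum(axis=1).astype(np.int64)
    table = build_submask_table() if collect_stats else None
    seen = result.seen_templates

    for i in range(n - 1):
        if _skip_sparse_seeds and popc[i] < params.c_min:
            continue
        row_i = rows[i]
        for j in range(i + 1, n):
            if _skip_sparse_seeds and popc[j] < params.c_min:
                continue
            t_nib = row_i & rows[j]
            key = t_nib.tobytes()
            if key in seen:
                continue
            seen.add(key)
            width = int(POPCOUNT[t_nib].sum())
            if width < params.c_min:
                continue
            if collect_stats:
                template = Template(
                    nibbles=tuple(int(x) for x in t_nib), seed_pair=(i, j)
                )
                members = [i, j]
                checks_t = 0
                k_seq = [0] * p
                for l in range(n):
                    if l == i or l == j:
                        continue
                    ok, used = row_matches_template(rows[l], template, table)
                    checks_t += used
                    if ok:
                        members.append(l)
                    else:
                        k_seq[used - 1] += 1
                stats.per_template_checks.append(checks_t)
                stats.rows_excluded_per_column.append(k_seq)
                member_idx = sorted(members)
            else:
                mask = ((rows & t_nib) == t_nib).all(axis=1)
                member_idx = np.flatnonzero(mask)
            if len(member_idx) < params.r_min:
                continue
            cols = _columns_from_mask(t_nib, matrix.n_cols)
            result.add(Bicluster(rows=tuple(int(r) for r in member_idx), cols=cols))

    return _postprocess(result, matrix, params, stats)


def _postprocess(
    bs: BiclusterSet,
    matrix: BinaryMatrix,
    params: SearchParams,
    stats: ComparisonStats | None = None,
) -> tuple[BiclusterSet, ComparisonStats | None]:
    if params.mode == "flex":
        if params.remove_symmetric:
            bs = remove_symmetric(bs, matrix)
        if params.top_k is not None and len(bs) > params.top_k:
            kept = sorted(bs, key=lambda b: (-b.area, b.key()))[: params.top_k]
            trimmed = BiclusterSet(kept)
            trimmed.seen_templates = bs.seen_templates
            bs = trimmed
    return bs, stats


def remove_symmetric(bs: BiclusterSet, matrix: BinaryMatrix) -> BiclusterSet:
    """Drop one member of each transpose-duplicate pair.

    Meaningful on square matrices whose row and column label spaces coincide
    (e.g. an interaction adjacency): bicluster (I, J) and its transpose
    (J, I) describe the same module. The lexicographically smaller
    (rows, cols) key survives. On other matrices this is an identity pass
    with a warning.
    """
    if matrix.n_rows != matrix.n_cols or matrix.row_labels != matrix.col_labels:
        logger.warning(
            "symmetric removal requested on a non-square or label-mismatched "
            "matrix; returning the set unchanged"
        )
        return bs
    out = BiclusterSet()
    out.seen_templates = bs.seen_templates
    keys = bs.as_set()
    for b in bs:
        transpose_key = (b.cols, b.rows)
        if transpose_key in keys and transpose_key < b.key():
            continue  # the transpose partner is canonical
        out.add(b)
    return out
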