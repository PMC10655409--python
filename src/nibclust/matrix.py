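"""Labeled matrix containers.

`BinaryMatrix` is the substrate of the biclustering algorithm: a dense 0/1
matrix with unique row and column labels. `ExpressionMatrix` holds real-valued
genes × conditions data destined for discretization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["BinaryMatrix", "ExpressionMatrix", "ValidationError"]


class ValidationError(ValueError):
    """Raised when an input violates a container or operation contract."""


def _default_labels(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(n)]


def _check_labels(labels: Sequence[str], n: int, axis: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValidationError(
            f"{axis} labels: expected {n} entries, got {len(labels)}"
        )
    if len(set(labels)) != n:
        raise ValidationError(f"{axis} labels are not unique")
    return labels


@dataclass(frozen=True)
class BinaryMatrix:
    """Dense labeled 0/1 matrix A = (R, C).

    Every cell is exactly 0 or 1; labels are unique within each axis.
    """

    values: np.ndarray
    row_labels: list[str] = field(default=None)  # type: ignore[assignment]
    col_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValidationError(f"expected a 2-D matrix, got shape {arr.shape}")
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary value {arr[r, c]!r} at cell ({r}, {c})"
            )
        arr = arr.astype(np.uint8)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        n, m = arr.shape
        rl = self.row_labels if self.row_labels is not None else _default_labels("r", n)
        cl = self.col_labels if self.col_labels is not None else _default_labels("c", m)
        object.__setattr__(self, "row_labels", _check_labels(rl, n, "row"))
        object.__setattr__(self, "col_labels", _check_labels(cl, m, "column"))

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def density(self) -> float:
        return float(self.values.mean())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMatrix):
            return NotImplemented
        return (
            self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
            and np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # labels + bytes; frozen container
        return hash((tuple(self.row_labels), tuple(self.col_labels),
                     self.values.tobytes()))


@dataclass(frozen=True)
class ExpressionMatrix:
    """Real-valued genes × conditions matrix with finite entries."""

    values: np.ndarray
    row_labels: list[str] = field(default=None)  # type: ignore[assignment]
    col_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValidationError(f"expected a 2-D matrix, got shape {arr.shape}")
        if not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite entries")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        n, m = arr.shape
        rl = self.row_labels if self.row_labels is not None else _default_labels("g", n)
        cl = self.col_labels if self.col_labels is not None else _default_labels("s", m)
        object.__setattr__(self, "row_labels", _check_labels(rl, n, "row"))
        object.__setattr__(self, "col_labels", _check_labels(cl, m, "column"))

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape
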