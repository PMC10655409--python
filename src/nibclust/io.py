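"""Readers and writers: matrices, edge lists, bicluster sets.

CSV/TSV matrices may carry a header row and a label column; both are
autodetected (first line non-numeric → header, first column non-numeric →
row labels) and overridable. Matrix Market (MTX) coordinate files are
densified with absent entries as 0; for binary targets any stored value
other than 1 is rejected rather than coerced. Edge lists are two-column
label pairs converted to a square symmetric 0/1 adjacency with self-loops
dropped.

Bicluster sets serialize to TSV (one record per line, semicolon-joined
sorted labels) or JSON (records plus a provenance block), deterministically
ordered, and round-trip through the matching readers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from . import __version__
from .matrix import BinaryMatrix, ExpressionMatrix, ValidationError
from .search import Bicluster, BiclusterSet

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_edge_list",
    "edges_to_adjacency",
    "write_biclusters",
    "read_biclusters",
]

logger = logging.getLogger(__name__)

_FORMATS = ("csv", "tsv", "mtx", "edgelist")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "tsv", "mtx"):
        return suffix
    if suffix in ("txt", "edges", "edgelist"):
        return "edgelist"
    raise ValidationError(f"cannot infer format from {path.name!r}; pass format=")


def _is_numeric(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_matrix(
    path,
    format: str | None = None,
    kind: str = "binary",
    header: bool | None = None,
    row_labels: bool | None = None,
):
    """Read a matrix file into a BinaryMatrix or ExpressionMatrix.

    ``kind`` is "binary" or "expression"; ``header``/``row_labels`` override
    autodetection for CSV/TSV.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "edgelist":
        return edges_to_adjacency(read_edge_list(path))
    if fmt == "mtx":
        return _read_mtx(path, kind)
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    first = path.read_text().splitlines()[0].split(sep)
    if header is None:
        header = not all(_is_numeric(t) for t in first if t.strip() != "")
    df = pd.read_csv(path, sep=sep, header=0 if header else None)
    if row_labels is None:
        first_col = df.iloc[:, 0]
        row_labels = first_col.dtype == object and not first_col.map(
            lambda v: _is_numeric(str(v))
        ).all()
    if row_labels:
        df = df.set_index(df.columns[0])
    rl = [str(x) for x in df.index] if row_labels else None
    cl = [str(x) for x in df.columns] if header else None
    values = df.to_numpy()
    if kind == "binary":
        return _to_binary(values, rl, cl)
    return ExpressionMatrix(values, row_labels=rl, col_labels=cl)


def _to_binary(values: np.ndarray, rl, cl) -> BinaryMatrix:
    arr = np.asarray(values)
    if arr.dtype.kind == "f":
        if not np.isin(arr, (0.0, 1.0)).all():
            bad = np.argwhere(~np.isin(arr, (0.0, 1.0)))[0]
            raise ValidationError(
                f"non-binary value {arr[tuple(bad)]!r} at cell {tuple(bad)}"
            )
        arr = arr.astype(np.uint8)
    return BinaryMatrix(arr, row_labels=rl, col_labels=cl)


def _read_mtx(path: Path, kind: str):
    sparse = scipy.io.mmread(path)
    dense = np.asarray(sparse.todense() if scipy.sparse.issparse(sparse) else sparse)
    if kind == "binary":
        nz = dense[dense != 0]
        if not np.isin(nz, (1,)).all():
            raise ValidationError(
                "MTX entries other than 1 are not accepted for binary matrices"
            )
        return BinaryMatrix(dense.astype(np.uint8))
    return ExpressionMatrix(dense)


def write_matrix(matrix: BinaryMatrix | ExpressionMatrix, path, format: str = "csv") -> None:
    """Write a labeled matrix as CSV/TSV (header row + label column)."""
    sep = {"csv": ",", "tsv": "\t"}[format]
    df = pd.DataFrame(matrix.values, index=matrix.row_labels, columns=matrix.col_labels)
    df.to_csv(path, sep=sep)


def read_edge_list(path) -> list[tuple[str, str]]:
    """Two-column TSV/whitespace file of node-label pairs."""
    edges = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) < 2:
            raise ValidationError(f"line {line_no}: expected two columns")
        edges.append((parts[0], parts[1]))
    if not edges:
        raise ValidationError("edge list is empty")
    return edges


def edges_to_adjacency(edges: Iterable[tuple[str, str]]) -> BinaryMatrix:
    """Square symmetric 0/1 adjacency over sorted unique labels.

    Self-loops are dropped (and counted in a log message); duplicate edges
    collapse; the diagonal is all zero.
    """
    edges = list(edges)
    if not edges:
        raise ValidationError("edge list is empty")
    self_loops = sum(1 for u, v in edges if u == v)
    pairs = {(u, v) for u, v in edges if u != v}
    labels = sorted({n for e in pairs for n in e})
    if self_loops:
        logger.info("removed %d self-interaction(s)", self_loops)
    if not labels:
        raise ValidationError("edge list contains only self-loops")
    index = {lab: k for k, lab in enumerate(labels)}
    vals = np.zeros((len(labels), len(labels)), dtype=np.uint8)
    for u, v in pairs:
        vals[index[u], index[v]] = 1
        vals[index[v], index[u]] = 1
    return BinaryMatrix(vals, row_labels=labels, col_labels=labels)


def _provenance(matrix: BinaryMatrix, params: dict | None, seed) -> dict:
    cfg = json.dumps(params or {}, sort_keys=True)
    return {
        "tool": "nibclust",
        "version": __version__,
        "config_hash": hashlib.sha256(cfg.encode()).hexdigest()[:16],
        "params": params or {},
        "seed": seed,
        "matrix_shape": list(matrix.shape),
    }


def write_biclusters(
    bs: BiclusterSet,
    matrix: BinaryMatrix,
    path,
    format: str = "tsv",
    params: dict | None = None,
    seed=None,
    mode: str | None = None,
) -> None:
    """Serialize a bicluster set with labels resolved against the matrix."""
    path = Path(path)
    if format == "tsv":
        lines = ["id\tn_rows\tn_cols\tarea\trows\tcols"]
        for k, b in enumerate(bs):
            rl = ";".join(sorted(matrix.row_labels[r] for r in b.rows))
            cl = ";".join(sorted(matrix.col_labels[c] for c in b.cols))
            lines.append(f"{k}\t{b.n_rows}\t{b.n_cols}\t{b.area}\t{rl}\t{cl}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        records = []
        for k, b in enumerate(bs):
            records.append(
                {
                    "id": k,
                    "rows": sorted(matrix.row_labels[r] for r in b.rows),
                    "cols": sorted(matrix.col_labels[c] for c in b.cols),
                    "row_indices": list(b.rows),
                    "col_indices": list(b.cols),
                    "n_rows": b.n_rows,
                    "n_cols": b.n_cols,
                    "area": b.area,
                    "mode": mode,
                }
            )
        payload = {
            "provenance": _provenance(matrix, params, seed),
            "biclusters": records,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValidationError(f"unknown bicluster format {format!r}")


def read_biclusters(path, matrix: BinaryMatrix) -> BiclusterSet:
    """Read a TSV/JSON bicluster file back, resolving labels to indices."""
    path = Path(path)
    row_index = {lab: k for k, lab in enumerate(matrix.row_labels)}
    col_index = {lab: k for k, lab in enumerate(matrix.col_labels)}
    out = BiclusterSet()
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        for rec in payload["biclusters"]:
            out.add(
                Bicluster(
                    rows=tuple(row_index[r] for r in rec["rows"]),
                    cols=tuple(col_index[c] for c in rec["cols"]),
                )
            )
        return out
    lines = path.read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        _, _, _, _, rows, cols = line.split("\t")
        out.add(
            Bicluster(
                rows=tuple(row_index[r] for r in rows.split(";")),
                cols=tuple(col_index[c] for c in cols.split(";")),
            )
        )
    return out
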