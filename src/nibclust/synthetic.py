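"""Synthetic benchmark generators with ground truth.

Three families, mirroring the standard binary-biclustering benchmarks:

* Bernoulli density matrices — i.i.d. 0/1 cells at a given 1-density
  (the density sweep uses 200×200 matrices at 5–50% in 5% steps);
* a scaling suite — square matrices from 50×50 to 500×500 in steps of 50,
  each size crossed with densities 10–100% in 10% steps;
* implanted matrices — all-ones ground-truth biclusters of side 10–20
  chained along the diagonal of a ~100×100 matrix, with consecutive
  implants sharing a controlled fraction of rows and columns
  (overlap degree 0–100%) over a Bernoulli background (default 0).

Every generator is reproducible: one RNG stream per matrix, derived from
(master seed, matrix index), so suites regenerate element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import BinaryMatrix, ValidationError
from .search import Bicluster, BiclusterSet

__all__ = [
    "ImplantSpec",
    "GroundTruth",
    "gen_density_matrix",
    "gen_scaling_suite",
    "gen_implanted",
    "gen_implant_suite",
    "SCALING_SIZES",
    "SCALING_DENSITIES",
    "DENSITY_SWEEP",
]

SCALING_SIZES = tuple(range(50, 501, 50))
SCALING_DENSITIES = tuple(d / 10 for d in range(1, 11))
DENSITY_SWEEP = tuple(d / 100 for d in range(5, 51, 5))


def _rng(seed, *stream) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, stream)])


def gen_density_matrix(
    n: int, m: int, density: float, seed: int | np.random.Generator = 0
) -> BinaryMatrix:
    """n×m matrix of i.i.d. Bernoulli(density) cells."""
    if not 0.0 <= density <= 1.0:
        raise ValidationError(f"density must lie in [0, 1], got {density}")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed)
    vals = (rng.random((n, m)) < density).astype(np.uint8)
    return BinaryMatrix(vals)


def gen_scaling_suite(
    seed: int = 0,
    sizes: tuple[int, ...] = SCALING_SIZES,
    densities: tuple[float, ...] = SCALING_DENSITIES,
) -> list[tuple[int, float, BinaryMatrix]]:
    """The full (size × density) grid: group g holds one matrix per density.

    Returns (size, density, matrix) triples; the default grid is 10 groups
    of 10 matrices, group g of dimension (50·g)×(50·g).
    """
    out = []
    idx = 0
    for size in sizes:
        for density in densities:
            out.append(
                (size, density, gen_density_matrix(size, size, density, _rng(seed, idx)))
            )
            idx += 1
    return out


@dataclass(frozen=True)
class ImplantSpec:
    """Geometry of an implanted-bicluster benchmark matrix."""

    n_rows: int = 100
    n_cols: int = 100
    n_biclusters: int = 5
    size_range: tuple[int, int] = (10, 20)
    overlap_degree: int = 0          # percent of the smaller side shared
    background_density: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_degree <= 100:
            raise ValidationError("overlap_degree must be in 0..100")
        if not 0.0 <= self.background_density <= 1.0:
            raise ValidationError("background_density must lie in [0, 1]")
        lo, hi = self.size_range
        if not 1 <= lo <= hi:
            raise ValidationError(f"bad size range {self.size_range}")
        if self.n_biclusters < 1:
            raise ValidationError("need at least one implant")


@dataclass(frozen=True)
class GroundTruth:
    """The implanted (I, J) sets, each all-ones in the emitted matrix."""

    biclusters: tuple[Bicluster, ...]
    spec: ImplantSpec
    degenerate_nesting: bool = False  # 100% overlap nests consecutive implants

    def as_set(self) -> BiclusterSet:
        return BiclusterSet(self.biclusters)


def gen_implanted(spec: ImplantSpec) -> tuple[BinaryMatrix, GroundTruth]:
    """Implant all-ones biclusters along the diagonal.

    Consecutive implants share floor(overlap_degree% × min side) rows and
    columns; background cells are Bernoulli(background_density). Raises if
    the chain does not fit in the matrix.
    """
    rng = _rng(spec.seed)
    lo, hi = spec.size_range
    row_sizes = rng.integers(lo, hi + 1, size=spec.n_biclusters)
    col_sizes = rng.integers(lo, hi + 1, size=spec.n_biclusters)

    implants = []
    r0 = c0 = 0
    for k in range(spec.n_biclusters):
        if k > 0:
            share_r = (spec.overlap_degree * min(row_sizes[k - 1], row_sizes[k])) // 100
            share_c = (spec.overlap_degree * min(col_sizes[k - 1], col_sizes[k])) // 100
            r0 += int(row_sizes[k - 1] - share_r)
            c0 += int(col_sizes[k - 1] - share_c)
        r1, c1 = r0 + int(row_sizes[k]), c0 + int(col_sizes[k])
        if r1 > spec.n_rows or c1 > spec.n_cols:
            raise ValidationError(
                f"implant {k} spans rows {r0}:{r1}, cols {c0}:{c1}; "
                f"exceeds the {spec.n_rows}×{spec.n_cols} matrix"
            )
        implants.append((r0, r1, c0, c1))

    vals = (rng.random((spec.n_rows, spec.n_cols)) < spec.background_density).astype(
        np.uint8
    )
    truth = []
    for r0, r1, c0, c1 in implants:
        vals[r0:r1, c0:c1] = 1
        truth.append(
            Bicluster(rows=tuple(range(r0, r1)), cols=tuple(range(c0, c1)))
        )
    return (
        BinaryMatrix(vals),
        GroundTruth(
            biclusters=tuple(truth),
            spec=spec,
            degenerate_nesting=spec.overlap_degree >= 100,
        ),
    )


def gen_implant_suite(
    seed: int = 0,
    overlaps: tuple[int, ...] = tuple(range(0, 101, 10)),
    n_biclusters: int = 5,
    background_density: float = 0.0,
) -> list[tuple[int, BinaryMatrix, GroundTruth]]:
    """Eleven implanted matrices, overlap degree 0–100% in 10% steps.

    Matrix g is (100+g)×(100+g) at overlap 10g%, implants of side 10–20.
    """
    out = []
    for g, ov in enumerate(overlaps):
        spec = ImplantSpec(
            n_rows=100 + g,
            n_cols=100 + g,
            n_biclusters=n_biclusters,
            overlap_degree=ov,
            background_density=background_density,
            seed=int(_rng(seed, g).integers(0, 2**31 - 1)),
        )
        mat, truth = gen_implanted(spec)
        out.append((ov, mat, truth))
    return out
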