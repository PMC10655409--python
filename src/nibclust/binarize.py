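"""Discretization of expression matrices to binary form.

Biclustering operates on 0/1 matrices, so real-valued expression data must
first be discretized. Three methods are provided:

``threshold``
    cell = 1 iff value > τ; one global cutoff.
``quantile``
    per-gene cutoff at quantile q; cell = 1 iff value > that gene's
    q-quantile. Robust default when no model is wanted.
``ltmg_simplified``
    a censored two-component Gaussian mixture per gene, approximating the
    left-truncated mixture models used to separate "expressed" from
    "unexpressed" states: values below a detection floor (default: the
    gene's minimum positive value) are censored at the floor, a
    two-component mixture is fitted by EM, and a cell is called 1 when the
    posterior of the higher-mean component exceeds 0.5. Genes the mixture
    cannot fit (constant, degenerate variance, too few values) fall back to
    the quantile rule, and every fallback is recorded in the provenance.

The mixture fit is deterministic: components are initialized from a median
split of the gene's values and the EM seed comes from the config.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .matrix import BinaryMatrix, ExpressionMatrix, ValidationError

__all__ = ["BinarizeConfig", "BinarizeResult", "binarize"]

logger = logging.getLogger(__name__)

_METHODS = ("threshold", "quantile", "ltmg_simplified")


@dataclass(frozen=True)
class BinarizeConfig:
    method: str = "ltmg_simplified"
    threshold: float = 0.0
    quantile: float = 0.5
    max_components: int = 2
    em_max_iter: int = 200
    em_tol: float = 1e-4
    detection_floor: float | None = None  # None: per-gene min positive value
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValidationError(f"method must be one of {_METHODS}")
        if not 0.0 < self.quantile < 1.0:
            raise ValidationError("quantile must lie in (0, 1)")
        if self.em_tol <= 0:
            raise ValidationError("EM tolerance must be positive")


@dataclass
class BinarizeResult:
    """Binary matrix plus a provenance record of how it was produced."""

    matrix: BinaryMatrix
    provenance: dict = field(default_factory=dict)


def binarize(expr: ExpressionMatrix, cfg: BinarizeConfig | None = None) -> BinarizeResult:
    """Discretize an expression matrix per the configured method.

    Output shape and labels match the input; provenance records the method,
    its parameters, and any per-gene fallbacks.
    """
    if cfg is None:
        cfg = BinarizeConfig()
    vals = expr.values
    fallbacks: list[str] = []
    if cfg.method == "threshold":
        out = (vals > cfg.threshold).astype(np.uint8)
    elif cfg.method == "quantile":
        out = _quantile_calls(vals, cfg.quantile)
    else:
        out = np.zeros_like(vals, dtype=np.uint8)
        for g in range(vals.shape[0]):
            calls, ok = _mixture_calls_gene(vals[g], cfg)
            if not ok:
                calls = _quantile_calls(vals[g][None, :], cfg.quantile)[0]
                fallbacks.append(expr.row_labels[g])
            out[g] = calls
        if fallbacks:
            logger.info(
                "mixture binarization fell back to quantile for %d/%d genes",
                len(fallbacks), vals.shape[0],
            )
    matrix = BinaryMatrix(out, row_labels=expr.row_labels, col_labels=expr.col_labels)
    return BinarizeResult(
        matrix=matrix,
        provenance={
            "method": cfg.method,
            "threshold": cfg.threshold,
            "quantile": cfg.quantile,
            "seed": cfg.seed,
            "fallback_genes": fallbacks,
        },
    )


def _quantile_calls(vals: np.ndarray, q: float) -> np.ndarray:
    cuts = np.quantile(vals, q, axis=1, keepdims=True)
    return (vals > cuts).astype(np.uint8)


def _mixture_calls_gene(gene: np.ndarray, cfg: BinarizeConfig) -> tuple[np.ndarray, bool]:
    """Two-component censored mixture call for one gene.

    Returns (calls, ok); ok=False signals the caller to fall back.
    """
    floor = cfg.detection_floor
    if floor is None:
        positive = gene[gene > 0]
        if positive.size == 0:
            return np.zeros_like(gene, dtype=np.uint8), False
        floor = float(positive.min())
    x = np.maximum(gene, floor)  # left truncation approximated by censoring
    if np.ptp(x) == 0 or np.unique(x).size < 3:
        return np.zeros_like(gene, dtype=np.uint8), False
    med = np.median(x)
    lower, upper = x[x <= med], x[x > med]
    if lower.size == 0 or upper.size == 0:
        return np.zeros_like(gene, dtype=np.uint8), False
    means_init = np.array([[lower.mean()], [upper.mean()]])
    gm = GaussianMixture(
        n_components=min(cfg.max_components, 2),
        max_iter=cfg.em_max_iter,
        tol=cfg.em_tol,
        means_init=means_init,
        random_state=cfg.seed,
        reg_covar=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            gm.fit(x.reshape(-1, 1))
        except Exception:  # singular fits on pathological genes
            return np.zeros_like(gene, dtype=np.uint8), False
    post = gm.predict_proba(x.reshape(-1, 1))
    upper_comp = int(np.argmax(gm.means_.ravel()))
    calls = (post[:, upper_comp] > 0.5).astype(np.uint8)
    return calls, True
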