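"""Bicluster-set quality metrics: match score, relevance, recovery.

The match score of a set A against a set B is the mean, over biclusters of
A, of the best Jaccard similarity achieved against any bicluster of B. Run
against a ground truth it yields two directed summaries: *relevance*
(found vs truth — how well mined biclusters represent true ones) and
*recovery* (truth vs found — how completely the true modules are found).
Both lie in [0, 1]; 1 means the sets coincide, 0 that they are disjoint.

The Jaccard primitive supports two scopes: ``rows`` (gene sets only, the
conventional variant) and ``rows_and_cols`` (Jaccard on (row, col) cell
sets). Reports always name the scope used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .matrix import ValidationError
from .search import Bicluster, BiclusterSet

__all__ = ["MetricReport", "jaccard", "match_score", "relevance_and_recovery"]

_SCOPES = ("rows", "rows_and_cols")


def jaccard(b1: Bicluster, b2: Bicluster, scope: str = "rows") -> float:
    """Jaccard similarity of two biclusters under the given scope."""
    if scope not in _SCOPES:
        raise ValidationError(f"scope must be one of {_SCOPES}, got {scope!r}")
    if scope == "rows":
        s1, s2 = set(b1.rows), set(b2.rows)
    else:
        s1 = {(r, c) for r in b1.rows for c in b1.cols}
        s2 = {(r, c) for r in b2.rows for c in b2.cols}
    if not s1 or not s2:
        raise ValidationError("jaccard of an empty bicluster is undefined")
    return len(s1 & s2) / len(s1 | s2)


def match_score(
    found: BiclusterSet, reference: BiclusterSet, scope: str = "rows"
) -> float:
    """Mean over `found` of the best Jaccard against any `reference` member.

    Empty `found` scores 0 by convention; not symmetric in its arguments.
    """
    if len(found) == 0:
        return 0.0
    if len(reference) == 0:
        return 0.0
    total = 0.0
    for b in found:
        total += max(jaccard(b, r, scope) for r in reference)
    return total / len(found)


@dataclass
class MetricReport:
    """Both directed match scores plus the per-bicluster best matches."""

    scope: str
    relevance: float            # match_score(found, truth)
    recovery: float             # match_score(truth, found)
    match_score_ab: float       # alias of relevance (found -> truth)
    match_score_ba: float       # alias of recovery (truth -> found)
    best_matches: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "relevance": self.relevance,
            "recovery": self.recovery,
            "match_score_ab": self.match_score_ab,
            "match_score_ba": self.match_score_ba,
            "best_matches": self.best_matches,
        }


def relevance_and_recovery(
    found: BiclusterSet, truth: BiclusterSet, scope: str = "rows"
) -> MetricReport:
    """Average bicluster relevance and average module recovery vs a truth set."""
    if len(truth) == 0:
        raise ValidationError("truth set must be non-empty")
    best = []
    for idx, b in enumerate(found):
        scores = [(jaccard(b, t, scope), t_idx) for t_idx, t in enumerate(truth)]
        s, partner = max(scores) if scores else (0.0, None)
        best.append({"found_index": idx, "best_truth_index": partner, "jaccard": s})
    rel = match_score(found, truth, scope)
    rec = match_score(truth, found, scope)
    return MetricReport(
        scope=scope,
        relevance=rel,
        recovery=rec,
        match_score_ab=rel,
        match_score_ba=rec,
        best_matches=best,
    )
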