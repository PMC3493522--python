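"""LCA classification of marker-gene reads from alignment hits.

The assignment of one query proceeds in three stages:

1. **Hit selection.**  If the best alignment's bit-score is below a minimum
   (default 155) the query is left unclassified.  Otherwise all hits scoring
   within x% of the best bit-score (default x = 2) enter the assignment.
2. **Lowest common ancestor.**  The query is placed on the LCA of the taxa of
   the selected reference sequences: unanimous hits give a genus-or-better
   placement, disagreeing hits an ancestor.
3. **Minimum similarity filter.**  The placement must be supported by the
   percent identity to the best reference: species requires >= 99%, genus 97,
   family 95, order 90, class 85, phylum 80.  A placement whose rank demands
   more identity than observed is demoted to the nearest permissible ancestor
   and flagged, marking the read an unknown member of that ancestor.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .alignment import AlignmentHit, QueryHits
from .taxonomy import Rank, TaxonNode, lca

__all__ = [
    "ClassifierParams",
    "ClassificationResult",
    "ClassifierError",
    "Status",
    "DEFAULT_RANK_THRESHOLDS",
    "select_hits",
    "lca_assign",
    "similarity_filter",
    "rank_threshold",
    "classify_query",
    "classify_all",
]


class ClassifierError(ValueError):
    pass


#: Minimum percent identity to the best reference required to *retain* an
#: assignment at each rank.  Ranks rootward of phylum are always allowed.
DEFAULT_RANK_THRESHOLDS: Mapping[Rank, float] = {
    Rank.SPECIES: 99.0,
    Rank.GENUS: 97.0,
    Rank.FAMILY: 95.0,
    Rank.ORDER: 90.0,
    Rank.CLASS: 85.0,
    Rank.PHYLUM: 80.0,
}


@dataclass
class ClassifierParams:
    """Tunable parameters of the assignment.

    lca_range_percent
        Width x of the bit-score window: hits scoring at least
        (1 - x/100) x best bit-score enter the LCA.  Default 2.0.
    min_bitscore
        Queries whose best hit scores below this are unclassified.  The
        boundary is inclusive: a best score equal to the minimum is eligible.
        Default 155.
    rank_thresholds
        Per-rank minimum identity (percent) for the similarity filter.
    max_hits
        Cap on hits considered per query.  Default 100.
    """

    lca_range_percent: float = 2.0
    min_bitscore: float = 155.0
    rank_thresholds: Mapping[Rank, float] = field(
        default_factory=lambda: dict(DEFAULT_RANK_THRESHOLDS)
    )
    max_hits: int = 100

    def __post_init__(self):
        if self.lca_range_percent < 0:
            raise ClassifierError("lca_range_percent must be >= 0")
        if self.max_hits < 1:
            raise ClassifierError("max_hits must be >= 1")
        ordered = sorted(self.rank_thresholds.items(), key=lambda kv: kv[0].value)
        for (r1, t1), (r2, t2) in zip(ordered, ordered[1:]):
            if not t1 < t2:
                raise ClassifierError(
                    f"rank thresholds must strictly increase with depth: "
                    f"{r1.label}={t1} vs {r2.label}={t2}"
                )


class Status(enum.Enum):
    ASSIGNED = "assigned"
    UNKNOWN_DEMOTED = "unknown_demoted"
    UNCLASSIFIED_NO_HITS = "unclassified_no_hits"
    UNCLASSIFIED_LOW_SCORE = "unclassified_low_score"


@dataclass
class ClassificationResult:
    """Outcome for one query, with provenance of any demotion."""

    query_id: str
    status: Status
    weight: float = 1.0
    assigned_node: Optional[TaxonNode] = None
    best_identity: Optional[float] = None
    best_bitscore: Optional[float] = None
    pre_filter_node: Optional[TaxonNode] = None

    def __post_init__(self):
        if self.weight <= 0:
            raise ClassifierError(f"non-positive weight for query {self.query_id!r}")
        if self.status in (Status.ASSIGNED, Status.UNKNOWN_DEMOTED):
            if self.assigned_node is None:
                raise ClassifierError(f"{self.status.value} result without a node")
        elif self.assigned_node is not None:
            raise ClassifierError("unclassified result carries an assigned node")


def select_hits(
    q: QueryHits, params: ClassifierParams
) -> Optional[List[AlignmentHit]]:
    """Hits within the bit-score window, or ``None`` when below the minimum score.

    The returned subset always contains the best hit.
    """
    if not q.hits:
        raise ClassifierError(f"query {q.query_id!r} has no hits to select from")
    hits = list(q.hits[: params.max_hits])
    best = hits[0]
    if best.bitscore < params.min_bitscore:
        return None
    cutoff = (1.0 - params.lca_range_percent / 100.0) * best.bitscore
    return [h for h in hits if h.bitscore >= cutoff]


def lca_assign(
    selected: Sequence[AlignmentHit], refdb_map: Mapping[str, TaxonNode]
) -> TaxonNode:
    """LCA of the taxa of the selected hits' reference sequences."""
    nodes = []
    seen = set()
    for hit in selected:
        try:
            node = refdb_map[hit.subject_accession]
        except KeyError:
            raise ClassifierError(
                f"accession {hit.subject_accession!r} not in the reference database"
            ) from None
        if node.name not in seen:
            seen.add(node.name)
            nodes.append(node)
    return lca(nodes)


def rank_threshold(node: TaxonNode, params: ClassifierParams) -> float:
    """Effective identity threshold of a node: that of its nearest ranked
    ancestor-or-self; ranks rootward of phylum are always allowed (0)."""
    return float(params.rank_thresholds.get(node.effective_rank(), 0.0))


def similarity_filter(
    node: TaxonNode, best_identity: float, params: ClassifierParams
) -> Tuple[TaxonNode, bool]:
    """Demote a placement until its rank's identity requirement is met.

    Returns the deepest ancestor-or-self whose effective threshold is at most
    ``best_identity`` (the comparison is inclusive), and whether any demotion
    happened.
    """
    current = node
    demoted = False
    while rank_threshold(current, params) > best_identity:
        if current.parent is None:  # root threshold is 0; unreachable in practice
            break
        current = current.parent
        demoted = True
    return current, demoted


def classify_query(
    q: Optional[QueryHits],
    refdb_map: Mapping[str, TaxonNode],
    params: Optional[ClassifierParams] = None,
    weight: float = 1.0,
) -> ClassificationResult:
    """Classify one query: hit selection, LCA, then the similarity filter.

    ``q`` may be ``None`` (or empty) for a query that produced no alignments.
    """
    params = params or ClassifierParams()
    if q is None or not q.hits:
        qid = q.query_id if q is not None else ""
        return ClassificationResult(qid, Status.UNCLASSIFIED_NO_HITS, weight=weight)
    best = q.best
    selected = select_hits(q, params)
    if selected is None:
        return ClassificationResult(
            q.query_id,
            Status.UNCLASSIFIED_LOW_SCORE,
            weight=weight,
            best_identity=best.percent_identity,
            best_bitscore=best.bitscore,
        )
    pre = lca_assign(selected, refdb_map)
    node, demoted = similarity_filter(pre, best.percent_identity, params)
    return ClassificationResult(
        q.query_id,
        Status.UNKNOWN_DEMOTED if demoted else Status.ASSIGNED,
        weight=weight,
        assigned_node=node,
        best_identity=best.percent_identity,
        best_bitscore=best.bitscore,
        pre_filter_node=pre,
    )


def classify_all(
    query_ids: Sequence[str],
    hits: Iterable[QueryHits],
    refdb_map: Mapping[str, TaxonNode],
    params: Optional[ClassifierParams] = None,
    weights: Optional[Mapping[str, float]] = None,
) -> List[ClassificationResult]:
    """Classify every query in ``query_ids`` (order preserved).

    Queries without an entry in ``hits`` are reported unclassified-no-hits;
    duplicate query ids are rejected.
    """
    params = params or ClassifierParams()
    seen = set()
    for qid in query_ids:
        if qid in seen:
            raise ClassifierError(f"duplicate query id: {qid!r}")
        seen.add(qid)
    by_id: Dict[str, QueryHits] = {}
    for qh in hits:
        if qh is None:  # convenience: aligners may yield None for no-hit queries
            continue
        if qh.query_id in by_id:
            raise ClassifierError(f"duplicate hit set for query {qh.query_id!r}")
        by_id[qh.query_id] = qh
    weights = weights or {}
    results = []
    for qid in query_ids:
        w = weights.get(qid, 1.0)
        if qid in by_id:
            results.append(classify_query(by_id[qid], refdb_map, params, w))
        else:
            results.append(
                ClassificationResult(qid, Status.UNCLASSIFIED_NO_HITS, weight=w)
            )
    return results
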