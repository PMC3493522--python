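"""Cross-validation of the classifier: ten-fold and leave-taxon-out schemes.

Held-out reference sequences (optionally cropped to amplicon-like fragment
lengths) are classified against the remaining references, and each test
sequence is scored at each rank as TP (correctly classified to a taxon),
TN (correctly unclassified), FP (incorrectly classified) or FN (incorrectly
unclassified).  Accuracy, precision and recall summarize the counts, and a
sweep over the LCA range traces precision-recall curves.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import (
    Callable,
    Dict,
    List,
    Mapping,
    Optional,
    Sequence,
    Set,
    Tuple,
)

from .alignment import QueryHits
from .builder import ReferenceDatabase
from .classify import (
    ClassificationResult,
    ClassifierParams,
    Status,
    classify_query,
    similarity_filter,
)
from .simulate import simulate_hits
from .taxonomy import CANONICAL_RANKS, Rank, TaxonNode, lca

__all__ = [
    "CvFold",
    "ConfusionCounts",
    "Metrics",
    "EvaluationError",
    "tenfold_split",
    "leave_taxon_out",
    "crop",
    "score_at_rank",
    "metrics",
    "pr_sweep",
    "tenfold_pr_sweep",
    "run_tenfold",
    "removed_taxon_accuracy",
]

#: An aligner is any callable mapping (query id, query sequence, retained
#: reference database, crop offset) to that query's hits.  The default is the
#: simulated-hit oracle, so the harness runs without an external binary.
Aligner = Callable[[str, str, ReferenceDatabase, int], Optional[QueryHits]]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class CvFold:
    index: int
    held_out: frozenset
    retained: frozenset

    def __post_init__(self):
        if self.held_out & self.retained:
            raise EvaluationError("held-out and retained sets overlap")


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN tally at one rank and parameter setting."""

    rank: Rank
    setting: Optional[float] = None
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def add(self, outcome: str) -> None:
        if outcome == "TP":
            self.tp += 1
        elif outcome == "TN":
            self.tn += 1
        elif outcome == "FP":
            self.fp += 1
        elif outcome == "FN":
            self.fn += 1
        else:
            raise EvaluationError(f"unknown outcome {outcome!r}")


@dataclass(frozen=True)
class Metrics:
    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]


def metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, precision and recall; zero-denominator ratios are ``None``."""
    if c.total == 0:
        raise EvaluationError("cannot compute metrics on all-zero counts")
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    return Metrics(accuracy, precision, recall)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def tenfold_split(
    refdb: ReferenceDatabase,
    seed: int,
    n_folds: int = 10,
    stratify_rank: Optional[Rank] = None,
) -> List[CvFold]:
    """Random partition of the reference sequences into equal-size folds.

    Fold sizes differ by at most one and the split is deterministic per seed.
    With ``stratify_rank`` set, each taxon's sequences at that rank are dealt
    to consecutive folds, so any taxon with at least two sequences has them
    spread across folds.
    """
    accessions = sorted(refdb.assignments)
    if len(accessions) < n_folds:
        raise EvaluationError(
            f"need at least {n_folds} sequences, have {len(accessions)}"
        )
    rng = random.Random(seed)
    folds: List[List[str]] = [[] for _ in range(n_folds)]
    if stratify_rank is None:
        rng.shuffle(accessions)
        for i, acc in enumerate(accessions):
            folds[i % n_folds].append(acc)
    else:
        groups: Dict[str, List[str]] = {}
        for acc in accessions:
            anc = refdb.assignments[acc].ancestor_at_rank(stratify_rank)
            groups.setdefault(anc.name if anc else "", []).append(acc)
        cursor = 0
        for key in sorted(groups):
            members = groups[key]
            rng.shuffle(members)
            for acc in members:
                folds[cursor % n_folds].append(acc)
                cursor += 1
    all_accs = set(accessions)
    return [
        CvFold(i, frozenset(f), frozenset(all_accs - set(f)))
        for i, f in enumerate(folds)
    ]


def leave_taxon_out(
    refdb: ReferenceDatabase,
    rank: Rank,
    n_taxa: Optional[int] = None,
    seed: int = 0,
) -> List[Tuple[str, List[str], ReferenceDatabase]]:
    """Leave-whole-taxon-out splits at a rank.

    Exhaustive over the taxa of the rank, or a seeded random sample of
    ``n_taxa`` of them.  Returns (taxon name, held-out accessions, retained
    database) triples; the removed taxon is absent from the retained taxonomy.
    """
    taxa = sorted(
        {
            anc.name
            for node in refdb.assignments.values()
            if (anc := node.ancestor_at_rank(rank)) is not None
        }
    )
    if not taxa:
        raise EvaluationError(f"no taxa with sequences at rank {rank.label}")
    if n_taxa is not None and n_taxa < len(taxa):
        taxa = sorted(random.Random(seed).sample(taxa, n_taxa))
    out = []
    for name in taxa:
        retained, held_out = refdb.remove_taxon(name)
        out.append((name, held_out, retained))
    return out


def crop(sequence: str, length: int, rng: random.Random) -> Tuple[str, int]:
    """Uniform-random contiguous subsequence of the given length.

    Returns the fragment and its start offset.  Too-short sequences raise;
    callers skip and count them.
    """
    if len(sequence) < length:
        raise EvaluationError(
            f"sequence of length {len(sequence)} cannot be cropped to {length}"
        )
    start = rng.randint(0, len(sequence) - length)
    return sequence[start : start + length], start


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def score_at_rank(
    truth: TaxonNode,
    result: ClassificationResult,
    rank: Rank,
    represented: Optional[Set[str]] = None,
) -> str:
    """Confusion outcome of one test sequence at one rank.

    ``truth`` is the sequence's node in the full taxonomy.  An assignment at
    the rank that matches the truth is a TP, a mismatch an FP.  No assignment
    at the rank is a TN when the truth itself has no taxon at that rank — or
    when that taxon is not in ``represented`` (the names present in the
    retained reference, for leave-taxon-out tests) — and an FN otherwise.
    """
    t = truth.ancestor_at_rank(rank)
    a = (
        result.assigned_node.ancestor_at_rank(rank)
        if result.assigned_node is not None
        else None
    )
    if a is not None:
        return "TP" if (t is not None and a.name == t.name) else "FP"
    if t is None or (represented is not None and t.name not in represented):
        return "TN"
    return "FN"


def removed_taxon_accuracy(
    truths: Sequence[TaxonNode],
    results: Sequence[ClassificationResult],
    removed_rank: Rank,
    represented: Set[str],
) -> float:
    """Fraction of held-out sequences handled correctly after taxon removal.

    A sequence counts as correct when it is unclassified at the removed rank
    (a TN there, its true taxon being gone) *and* its assignment, if any, lies
    on the true lineage — i.e. the novel taxon's reads fall through to an
    ancestor rather than being misplaced into a sibling.
    """
    if len(truths) != len(results):
        raise EvaluationError("truths and results length mismatch")
    if not truths:
        raise EvaluationError("no held-out sequences")
    good = 0
    for truth, result in zip(truths, results):
        outcome = score_at_rank(truth, result, removed_rank, represented)
        on_lineage = result.assigned_node is None or (
            result.assigned_node.name in {n.name for n in truth.path_to_root()}
        )
        if outcome == "TN" and on_lineage:
            good += 1
    return good / len(truths)


# ---------------------------------------------------------------------------
# ten-fold driver
# ---------------------------------------------------------------------------


def _default_aligner(
    query_id: str, query_seq: str, retained: ReferenceDatabase, offset: int
) -> Optional[QueryHits]:
    return simulate_hits(query_id, query_seq, retained, offset=offset)


def run_tenfold(
    refdb: ReferenceDatabase,
    params: Optional[ClassifierParams] = None,
    seed: int = 0,
    ranks: Sequence[Rank] = CANONICAL_RANKS,
    crop_length: Optional[int] = None,
    aligner: Optional[Aligner] = None,
    stratify_rank: Optional[Rank] = None,
) -> Dict[Rank, ConfusionCounts]:
    """Ten-fold cross-validation of the classifier on a reference database.

    Each fold's sequences are (optionally cropped and) classified against the
    other nine folds; confusion counts accumulate per rank.  Sequences whose
    truth lacks a taxon at a rank still count (as TN/FP) so the per-rank
    totals equal the number of test sequences.
    """
    params = params or ClassifierParams()
    aligner = aligner or _default_aligner
    folds = tenfold_split(refdb, seed, stratify_rank=stratify_rank)
    counts = {rank: ConfusionCounts(rank, params.lca_range_percent) for rank in ranks}
    crop_rng = random.Random(seed + 1)
    for fold in folds:
        retained = refdb.subset(fold.retained)
        represented = retained.taxonomy.names()
        for acc in sorted(fold.held_out):
            seq = refdb.sequences[acc]
            offset = 0
            if crop_length is not None:
                if len(seq) < crop_length:
                    continue  # skipped, as with too-short reads in practice
                seq, offset = crop(seq, crop_length, crop_rng)
            qh = aligner(acc, seq, retained, offset)
            result = classify_query(qh, retained.assignments, params)
            truth = refdb.assignments[acc]
            for rank in ranks:
                counts[rank].add(score_at_rank(truth, result, rank, represented))
    return counts


# ---------------------------------------------------------------------------
# LCA-range sweep (precision-recall curves)
# ---------------------------------------------------------------------------


def _lca_profile(
    qh: QueryHits,
    refdb_map: Mapping[str, TaxonNode],
    params: ClassifierParams,
) -> Optional[List[Tuple[float, TaxonNode]]]:
    """Per-query critical-range profile: breakpoints (x, LCA node).

    As the LCA range x grows, hits enter the subset in descending score order;
    the pre-filter node at range x is the profile entry with the largest
    breakpoint <= x.  ``None`` when the best score is below the minimum
    (unclassified at every x).
    """
    hits = list(qh.hits[: params.max_hits])
    best = hits[0]
    if best.bitscore < params.min_bitscore:
        return None
    profile: List[Tuple[float, TaxonNode]] = []
    nodes: List[TaxonNode] = []
    current: Optional[TaxonNode] = None
    for hit in hits:
        x_enter = 100.0 * (1.0 - hit.bitscore / best.bitscore)
        node = refdb_map[hit.subject_accession]
        nodes.append(node)
        new_lca = lca(nodes)
        if current is None or new_lca.name != current.name:
            profile.append((x_enter, new_lca))
            current = new_lca
    return profile


def _node_at_x(
    profile: List[Tuple[float, TaxonNode]], x: float
) -> TaxonNode:
    node = profile[0][1]
    for x_enter, n in profile:
        if x_enter <= x + 1e-12:
            node = n
        else:
            break
    return node


def tenfold_pr_sweep(
    refdb: ReferenceDatabase,
    x_grid: Sequence[float],
    rank: Rank,
    params: Optional[ClassifierParams] = None,
    seed: int = 0,
    aligner: Optional[Aligner] = None,
    stratify_rank: Optional[Rank] = None,
) -> List[Tuple[float, Optional[float], Optional[float]]]:
    """Ten-fold precision-recall curve over the LCA range, pooled across folds."""
    if not list(x_grid):
        raise EvaluationError("empty LCA-range grid")
    params = params or ClassifierParams()
    aligner = aligner or _default_aligner
    folds = tenfold_split(refdb, seed, stratify_rank=stratify_rank)
    counts = {x: ConfusionCounts(rank, x) for x in x_grid}
    for fold in folds:
        retained = refdb.subset(fold.retained)
        represented = retained.taxonomy.names()
        for acc in sorted(fold.held_out):
            qh = aligner(acc, refdb.sequences[acc], retained, 0)
            truth = refdb.assignments[acc]
            if qh is None or not qh.hits:
                no_hit = ClassificationResult(acc, Status.UNCLASSIFIED_NO_HITS)
                for x in x_grid:
                    counts[x].add(score_at_rank(truth, no_hit, rank, represented))
                continue
            profile = _lca_profile(qh, retained.assignments, params)
            best_identity = qh.best.percent_identity
            for x in x_grid:
                if profile is None:
                    result = ClassificationResult(acc, Status.UNCLASSIFIED_LOW_SCORE)
                else:
                    pre = _node_at_x(profile, x)
                    node, demoted = similarity_filter(pre, best_identity, params)
                    result = ClassificationResult(
                        acc,
                        Status.UNKNOWN_DEMOTED if demoted else Status.ASSIGNED,
                        assigned_node=node,
                        best_identity=best_identity,
                        pre_filter_node=pre,
                    )
                counts[x].add(score_at_rank(truth, result, rank, represented))
    out = []
    for x in x_grid:
        m = metrics(counts[x])
        out.append((x, m.precision, m.recall))
    return out


def pr_sweep(
    queries: Sequence[Tuple[TaxonNode, Optional[QueryHits]]],
    refdb_map: Mapping[str, TaxonNode],
    x_grid: Sequence[float],
    rank: Rank,
    params: Optional[ClassifierParams] = None,
    represented: Optional[Set[str]] = None,
) -> List[Tuple[float, Optional[float], Optional[float]]]:
    """Precision and recall at one rank for each LCA range on a grid.

    Each query's LCA is profiled once against its hit-entry breakpoints and
    thresholded per grid value — equivalent to reclassifying at every x, but
    one pass over the hits.  Returns (x, precision, recall) per grid value.
    """
    if not list(x_grid):
        raise EvaluationError("empty LCA-range grid")
    params = params or ClassifierParams()
    profiles = []
    for truth, qh in queries:
        if qh is None or not qh.hits:
            profiles.append((truth, None, None))
            continue
        profiles.append(
            (truth, _lca_profile(qh, refdb_map, params), qh.best.percent_identity)
        )
    out = []
    for x in x_grid:
        if x < 0:
            raise EvaluationError("LCA range must be >= 0")
        c = ConfusionCounts(rank, x)
        for truth, profile, best_identity in profiles:
            if profile is None:
                result = ClassificationResult("", Status.UNCLASSIFIED_NO_HITS)
            else:
                pre = _node_at_x(profile, x)
                node, demoted = similarity_filter(pre, best_identity, params)
                result = ClassificationResult(
                    "",
                    Status.UNKNOWN_DEMOTED if demoted else Status.ASSIGNED,
                    assigned_node=node,
                    best_identity=best_identity,
                    pre_filter_node=pre,
                )
            c.add(score_at_rank(truth, result, rank, represented))
        m = metrics(c)
        out.append((x, m.precision, m.recall))
    return out
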