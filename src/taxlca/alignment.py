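"""Parsers for BLAST-style alignment output (tabular and XML) into per-query hit sets."""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, IO, Iterable, List, Union

from Bio.Blast import NCBIXML

__all__ = [
    "AlignmentHit",
    "QueryHits",
    "BlastParseError",
    "parse_blast_tabular",
    "parse_blast_xml",
    "best_hit",
]

#: Default cap on retained hits per query, mirroring the common practice of
#: restricting aligner output to 100 alignments.
DEFAULT_MAX_HITS = 100


class BlastParseError(ValueError):
    """Raised for malformed alignment input."""


@dataclass(frozen=True)
class AlignmentHit:
    """One query-vs-reference alignment (best HSP for that subject)."""

    query_id: str
    subject_accession: str
    bitscore: float
    percent_identity: float
    alignment_length: int

    def __post_init__(self):
        if self.bitscore < 0:
            raise BlastParseError(f"negative bitscore for query {self.query_id!r}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise BlastParseError(
                f"percent identity {self.percent_identity} outside [0, 100] "
                f"for query {self.query_id!r}"
            )
        if self.alignment_length <= 0:
            raise BlastParseError(
                f"non-positive alignment length for query {self.query_id!r}"
            )


def _hit_sort_key(hit: AlignmentHit):
    # Descending bitscore, ties to higher identity, then lexicographic subject.
    return (-hit.bitscore, -hit.percent_identity, hit.subject_accession)


class QueryHits:
    """All hits of one query, ordered by descending bitscore.

    Ties are broken by higher percent identity, then lexicographically by
    subject accession, so hit order is a pure function of hit content.
    """

    __slots__ = ("query_id", "hits")

    def __init__(self, query_id: str, hits: Iterable[AlignmentHit]):
        hits = list(hits)
        for h in hits:
            if h.query_id != query_id:
                raise BlastParseError(
                    f"hit for query {h.query_id!r} placed under {query_id!r}"
                )
        self.query_id = query_id
        self.hits = tuple(sorted(hits, key=_hit_sort_key))

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, QueryHits)
            and self.query_id == other.query_id
            and self.hits == other.hits
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"QueryHits({self.query_id!r}, {len(self.hits)} hits)"

    @property
    def best(self) -> AlignmentHit:
        return best_hit(self)


def best_hit(q: QueryHits) -> AlignmentHit:
    """The highest-scoring hit (ties: higher identity, then accession order)."""
    if not q.hits:
        raise BlastParseError(f"query {q.query_id!r} has no hits")
    return q.hits[0]


# ---------------------------------------------------------------------------
# input plumbing
# ---------------------------------------------------------------------------


def _open_text(source: Union[str, os.PathLike, IO]) -> IO[str]:
    """Open a path (gzip detected by magic bytes) or pass through a handle."""
    if isinstance(source, (str, os.PathLike)):
        path = Path(source)
        with open(path, "rb") as probe:
            magic = probe.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, "rt")
        return open(path, "rt")
    return source


def _collapse_per_subject(
    rows: Iterable[AlignmentHit], max_hits: int
) -> List[AlignmentHit]:
    """Keep only the best HSP per subject so no reference is double-counted."""
    best: Dict[str, AlignmentHit] = {}
    for hit in rows:
        prev = best.get(hit.subject_accession)
        if prev is None or _hit_sort_key(hit) < _hit_sort_key(prev):
            best[hit.subject_accession] = hit
    kept = sorted(best.values(), key=_hit_sort_key)
    return kept[:max_hits]


# ---------------------------------------------------------------------------
# tabular ("outfmt 6") parser
# ---------------------------------------------------------------------------


def parse_blast_tabular(
    source: Union[str, os.PathLike, IO[str]], max_hits: int = DEFAULT_MAX_HITS
) -> List[QueryHits]:
    """Parse 12-column BLAST tabular output.

    Columns: query, subject, %identity, alignment length, mismatches, gap
    opens, qstart, qend, sstart, send, evalue, bitscore.  Returns one
    :class:`QueryHits` per query in order of first appearance; comment lines
    (``#``) and blank lines are skipped.
    """
    handle = _open_text(source)
    per_query: Dict[str, List[AlignmentHit]] = {}
    order: List[str] = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise BlastParseError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        qid, sid = fields[0], fields[1]
        try:
            identity = float(fields[2])
            length = int(fields[3])
            bitscore = float(fields[11])
        except ValueError:
            raise BlastParseError(
                f"line {lineno}: non-numeric identity/length/bitscore"
            ) from None
        hit = AlignmentHit(qid, sid, bitscore, identity, length)
        if qid not in per_query:
            per_query[qid] = []
            order.append(qid)
        per_query[qid].append(hit)
    return [
        QueryHits(qid, _collapse_per_subject(per_query[qid], max_hits))
        for qid in order
    ]


# ---------------------------------------------------------------------------
# NCBI BLAST XML parser
# ---------------------------------------------------------------------------


def parse_blast_xml(
    source: Union[str, os.PathLike, IO], max_hits: int = DEFAULT_MAX_HITS
) -> List[QueryHits]:
    """Parse NCBI BLAST XML (Iteration/Hit/Hsp).

    Per subject, HSPs collapse to the single highest-bitscore one.  Percent
    identity is computed as 100 x identities / alignment length.
    """
    handle = _open_text(source)
    results: List[QueryHits] = []
    try:
        for record in NCBIXML.parse(handle):
            qid = (record.query or "").split(None, 1)[0] if record.query else ""
            if not qid:
                raise BlastParseError("XML iteration without a query definition")
            hits: List[AlignmentHit] = []
            for aln in record.alignments:
                accession = aln.accession or aln.hit_def.split(None, 1)[0]
                for hsp in aln.hsps:
                    if hsp.bits is None or hsp.identities is None or not hsp.align_length:
                        raise BlastParseError(
                            f"incomplete Hsp fields for query {qid!r}"
                        )
                    identity = 100.0 * hsp.identities / hsp.align_length
                    hits.append(
                        AlignmentHit(qid, accession, float(hsp.bits), identity,
                                     int(hsp.align_length))
                    )
            if hits:  # queries with no alignments are absent, as in tabular output
                results.append(QueryHits(qid, _collapse_per_subject(hits, max_hits)))
    except BlastParseError:
        raise
    except Exception as exc:  # NCBIXML surfaces various errors on bad input
        raise BlastParseError(f"malformed BLAST XML: {exc}") from exc
    return results
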