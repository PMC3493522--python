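"""Synthetic taxonomies, reference sequences and simulated alignment output.

Everything the classifier consumes can be generated here at desk scale: a
fully ranked toy taxonomy, reference sequences evolved from a root ancestor by
per-level substitution divergence, amplicon-style query sets with read-weight
annotations, and simulated hit tables in BLAST tabular or XML form.

The hit simulator is deliberately simple — ungapped Hamming identity and a
linear match/mismatch score (2·matches − 3·mismatches, floored at zero).  It
is an oracle for classifier logic, not an aligner emulator: scores are exact
functions of the sequences, monotone in identity at fixed length, so hit
selection thresholds can be hand-computed in tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .alignment import AlignmentHit, QueryHits
from .builder import ReferenceDatabase
from .taxonomy import Rank, TaxonNode, Taxonomy

__all__ = [
    "FixtureSpec",
    "make_taxonomy",
    "make_sequences",
    "make_fixture",
    "simulate_hits",
    "make_amplicon_dataset",
    "blast_tabular_text",
    "blast_xml_text",
    "mutate",
]

BASES = "ACGT"

#: Tree levels generated, tipward order, with their name prefixes.
LEVELS: Sequence[Tuple[Rank, str]] = (
    (Rank.DOMAIN, "D"),
    (Rank.PHYLUM, "P"),
    (Rank.CLASS, "C"),
    (Rank.ORDER, "O"),
    (Rank.FAMILY, "F"),
    (Rank.GENUS, "G"),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and divergence of a synthetic reference database.

    ``fanouts`` gives the number of children per node at each level
    (domain, phylum, class, order, family, genus); ``divergences`` the percent
    substitution divergence applied along each level's edges.  Each genus gets
    ``seqs_per_genus`` reference sequences, each ``seq_divergence`` percent
    from the genus ancestor.  The default is small enough for seconds-scale
    tests yet deep enough to exercise every rank threshold.
    """

    fanouts: Tuple[int, ...] = (2, 2, 1, 1, 2, 2)
    divergences: Tuple[float, ...] = (15.0, 10.0, 5.0, 3.0, 2.0, 1.0)
    seqs_per_genus: int = 3
    seq_divergence: float = 1.0
    length: int = 500
    seed: int = 0

    def __post_init__(self):
        if len(self.fanouts) != len(LEVELS) or len(self.divergences) != len(LEVELS):
            raise ValueError(f"fanouts and divergences must have {len(LEVELS)} levels")
        if any(f < 1 for f in self.fanouts):
            raise ValueError("fan-outs must be >= 1")
        if any(not (0 <= d < 100) for d in self.divergences + (self.seq_divergence,)):
            raise ValueError("divergences must lie in [0, 100)")

    @property
    def n_genera(self) -> int:
        n = 1
        for f in self.fanouts:
            n *= f
        return n


def make_taxonomy(spec: FixtureSpec) -> Taxonomy:
    """Complete ranked tree with lineage-encoding names like ``D1.P2.C1.O1.F2.G1``."""
    taxonomy = Taxonomy.create("root")

    def grow(parent: TaxonNode, level: int) -> None:
        if level == len(LEVELS):
            return
        rank, prefix = LEVELS[level]
        for i in range(1, spec.fanouts[level] + 1):
            label = f"{prefix}{i}"
            name = label if parent.is_root else f"{parent.name}.{label}"
            child = taxonomy.add(name, parent, rank)
            grow(child, level + 1)

    grow(taxonomy.root, 0)
    for i, node in enumerate(taxonomy):
        node.id = str(i)
    taxonomy._by_id = {n.id: n for n in taxonomy}
    return taxonomy


def mutate(sequence: str, divergence_percent: float, rng: random.Random) -> str:
    """Substitute ``round(d% * length)`` distinct positions to different bases."""
    n_sub = int(round(divergence_percent / 100.0 * len(sequence)))
    positions = rng.sample(range(len(sequence)), n_sub)
    seq = list(sequence)
    for pos in positions:
        seq[pos] = rng.choice([b for b in BASES if b != seq[pos]])
    return "".join(seq)


def make_sequences(taxonomy: Taxonomy, spec: FixtureSpec) -> ReferenceDatabase:
    """Evolve sequences down the tree and return the reference database.

    The root ancestor is a random sequence; each edge applies its level's
    divergence as random substitutions.  Genus nodes then receive
    ``seqs_per_genus`` references, each mutated from the genus ancestor by
    ``seq_divergence`` percent, with accessions ``<genus>.s<j>``.
    """
    rng = random.Random(spec.seed)
    root_seq = "".join(rng.choice(BASES) for _ in range(spec.length))
    divergence_by_rank = {LEVELS[i][0]: spec.divergences[i] for i in range(len(LEVELS))}

    ancestral: Dict[str, str] = {taxonomy.root.name: root_seq}
    assignments: Dict[str, TaxonNode] = {}
    sequences: Dict[str, str] = {}
    for node in taxonomy:
        if node.is_root:
            continue
        parent_seq = ancestral[node.parent.name]
        ancestral[node.name] = mutate(
            parent_seq, divergence_by_rank[node.rank], rng
        )
        if node.rank is Rank.GENUS:
            for j in range(1, spec.seqs_per_genus + 1):
                acc = f"{node.name}.s{j}"
                sequences[acc] = mutate(
                    ancestral[node.name], spec.seq_divergence, rng
                )
                assignments[acc] = node
    return ReferenceDatabase(taxonomy, assignments, sequences)


def make_fixture(spec: Optional[FixtureSpec] = None) -> ReferenceDatabase:
    """Convenience: taxonomy plus sequences in one call."""
    spec = spec or FixtureSpec()
    return make_sequences(make_taxonomy(spec), spec)


# ---------------------------------------------------------------------------
# simulated alignment
# ---------------------------------------------------------------------------


def _score(matches: int, mismatches: int) -> float:
    return float(max(0, 2 * matches - 3 * mismatches))


def simulate_hits(
    query_id: str,
    query_seq: str,
    refdb: ReferenceDatabase,
    max_hits: int = 100,
    offset: int = 0,
) -> Optional[QueryHits]:
    """Ungapped comparison of a query against every reference.

    Identity is exact Hamming identity over the compared window; the score is
    2·matches − 3·mismatches floored at zero, and zero-score references are
    not reported.  Queries shorter than the references are compared at the
    given reference offset (as produced by :func:`taxlca.evaluate.crop`).
    Returns ``None`` when nothing scores above zero.
    """
    hits: List[AlignmentHit] = []
    n = len(query_seq)
    for acc in refdb.accessions:
        window = refdb.sequences[acc][offset : offset + n]
        if len(window) != n:
            continue
        matches = sum(a == b for a, b in zip(query_seq, window))
        score = _score(matches, n - matches)
        if score <= 0:
            continue
        hits.append(
            AlignmentHit(query_id, acc, score, 100.0 * matches / n, n)
        )
    if not hits:
        return None
    qh = QueryHits(query_id, hits)
    return QueryHits(query_id, qh.hits[:max_hits])


# ---------------------------------------------------------------------------
# amplicon dataset generation
# ---------------------------------------------------------------------------


def make_amplicon_dataset(
    refdb: ReferenceDatabase,
    n_queries: int,
    seed: int,
    noise_percent: float = 0.0,
    skew: float = 1.5,
) -> Tuple[List[Tuple[str, str]], Dict[str, str]]:
    """Draw amplicon-style queries from the reference genera.

    Genus abundances follow a power-law skew (rank-abundance exponent
    ``skew``); each query is a reference sequence mutated by
    ``noise_percent`` and named ``q<i>_<weight>`` with a weight drawn from a
    lognormal read-count distribution.  Returns the (name, sequence) list and
    a truth table mapping base query name to the true genus name.
    """
    rng = random.Random(seed)
    genera = sorted(
        {node.name for node in refdb.assignments.values()}
    )
    weights_raw = [1.0 / (i + 1) ** skew for i in range(len(genera))]
    total = sum(weights_raw)
    probs = [w / total for w in weights_raw]
    by_genus: Dict[str, List[str]] = {}
    for acc, node in refdb.assignments.items():
        by_genus.setdefault(node.name, []).append(acc)
    for accs in by_genus.values():
        accs.sort()

    queries: List[Tuple[str, str]] = []
    truth: Dict[str, str] = {}
    for i in range(n_queries):
        genus = rng.choices(genera, weights=probs, k=1)[0]
        acc = rng.choice(by_genus[genus])
        seq = refdb.sequences[acc]
        if noise_percent > 0:
            seq = mutate(seq, noise_percent, rng)
        weight = max(1, int(round(rng.lognormvariate(1.0, 1.0))))
        base = f"q{i:05d}"
        queries.append((f"{base}_{weight}", seq))
        truth[base] = genus
    return queries, truth


# ---------------------------------------------------------------------------
# alignment-format writers (round-trip fixtures for the parsers)
# ---------------------------------------------------------------------------


def blast_tabular_text(hit_sets: Iterable[QueryHits]) -> str:
    """Serialize hit sets as 12-column BLAST tabular text.

    Floats are written at full precision so parsing is lossless.
    """
    lines = []
    for qh in hit_sets:
        for h in qh:
            mismatches = h.alignment_length - round(
                h.percent_identity / 100.0 * h.alignment_length
            )
            lines.append(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_accession,
                        repr(h.percent_identity),
                        str(h.alignment_length),
                        str(mismatches),
                        "0",
                        "1",
                        str(h.alignment_length),
                        "1",
                        str(h.alignment_length),
                        "1e-50",
                        repr(h.bitscore),
                    ]
                )
            )
    return "\n".join(lines) + ("\n" if lines else "")


def blast_xml_text(hit_sets: Iterable[QueryHits]) -> str:
    """Serialize hit sets as minimal NCBI BLAST XML (Iteration/Hit/Hsp).

    ``Hsp_identity`` is reconstructed from the identity percentage so the XML
    parser recomputes the same value.
    """
    out = [
        '<?xml version="1.0"?>',
        '<!DOCTYPE BlastOutput PUBLIC "-//NCBI//NCBI BlastOutput/EN" '
        '"http://www.ncbi.nlm.nih.gov/dtd/NCBI_BlastOutput.dtd">',
        "<BlastOutput>",
        "  <BlastOutput_program>megablast</BlastOutput_program>",
        "  <BlastOutput_version>megablast 2.0.0+</BlastOutput_version>",
        "  <BlastOutput_db>fixture</BlastOutput_db>",
        "  <BlastOutput_query-ID>0</BlastOutput_query-ID>",
        "  <BlastOutput_query-def>fixture</BlastOutput_query-def>",
        "  <BlastOutput_query-len>0</BlastOutput_query-len>",
        "  <BlastOutput_param>",
        "    <Parameters>",
        "      <Parameters_expect>10</Parameters_expect>",
        "      <Parameters_sc-match>2</Parameters_sc-match>",
        "      <Parameters_sc-mismatch>-3</Parameters_sc-mismatch>",
        "      <Parameters_gap-open>5</Parameters_gap-open>",
        "      <Parameters_gap-extend>2</Parameters_gap-extend>",
        "      <Parameters_filter>F</Parameters_filter>",
        "    </Parameters>",
        "  </BlastOutput_param>",
        "  <BlastOutput_iterations>",
    ]
    for it_num, qh in enumerate(hit_sets, start=1):
        out += [
            "    <Iteration>",
            f"      <Iteration_iter-num>{it_num}</Iteration_iter-num>",
            f"      <Iteration_query-def>{qh.query_id}</Iteration_query-def>",
            "      <Iteration_hits>",
        ]
        for hit_num, h in enumerate(qh, start=1):
            identities = round(h.percent_identity / 100.0 * h.alignment_length)
            out += [
                "        <Hit>",
                f"          <Hit_num>{hit_num}</Hit_num>",
                f"          <Hit_id>gnl|fixture|{h.subject_accession}</Hit_id>",
                f"          <Hit_def>{h.subject_accession}</Hit_def>",
                f"          <Hit_accession>{h.subject_accession}</Hit_accession>",
                f"          <Hit_len>{h.alignment_length}</Hit_len>",
                "          <Hit_hsps>",
                "            <Hsp>",
                "              <Hsp_num>1</Hsp_num>",
                f"              <Hsp_bit-score>{h.bitscore!r}</Hsp_bit-score>",
                f"              <Hsp_score>{int(h.bitscore)}</Hsp_score>",
                "              <Hsp_evalue>1e-50</Hsp_evalue>",
                "              <Hsp_query-from>1</Hsp_query-from>",
                f"              <Hsp_query-to>{h.alignment_length}</Hsp_query-to>",
                "              <Hsp_hit-from>1</Hsp_hit-from>",
                f"              <Hsp_hit-to>{h.alignment_length}</Hsp_hit-to>",
                f"              <Hsp_identity>{identities}</Hsp_identity>",
                f"              <Hsp_positive>{identities}</Hsp_positive>",
                f"              <Hsp_align-len>{h.alignment_length}</Hsp_align-len>",
                "            </Hsp>",
                "          </Hit_hsps>",
                "        </Hit>",
            ]
        out += [
            "      </Iteration_hits>",
            "    </Iteration>",
        ]
    out += [
        "  </BlastOutput_iterations>",
        "</BlastOutput>",
        "",
    ]
    return "\n".join(out)
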