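"""Community composition tables: weighted abundance, richness and Chao1 per rank.

Each classified read contributes its weight (the number of raw reads the
dereplicated sequence represents) to its assigned taxon and every ancestor;
per-rank tables are projections of assignments onto a rank, with reads
assigned rootward of the rank collected in an explicit ``Unclassified`` row so
every table sums to the total input weight.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .classify import ClassificationResult
from .taxonomy import CANONICAL_RANKS, Rank, TaxonNode, Taxonomy

__all__ = [
    "TaxonStats",
    "CompositionTable",
    "ReportError",
    "parse_weight",
    "chao_estimate",
    "accumulate",
    "merge_datasets",
    "export_fasta_by_taxon",
]

UNCLASSIFIED_LABEL = "Unclassified"


class ReportError(ValueError):
    pass


# ---------------------------------------------------------------------------
# weight annotations
# ---------------------------------------------------------------------------

_WEIGHT_EQ = re.compile(r"\s*\bweight\s*=\s*(-?\d+)")
_WEIGHT_SUFFIX = re.compile(r"^(.+)_(\d+)$")


def parse_weight(sequence_name: str) -> Tuple[str, int]:
    """Extract a read weight from a sequence name.

    ``"weight = N"`` anywhere in the name takes precedence; otherwise a
    trailing all-digit ``_N`` suffix is used; otherwise the weight is 1.
    Returns the name with the annotation stripped, and the weight.
    """
    m = _WEIGHT_EQ.search(sequence_name)
    if m:
        weight = int(m.group(1))
        base = (sequence_name[: m.start()] + sequence_name[m.end():]).strip()
    else:
        m = _WEIGHT_SUFFIX.match(sequence_name)
        if m:
            base, weight = m.group(1), int(m.group(2))
        else:
            return sequence_name, 1
    if weight <= 0:
        raise ReportError(f"non-positive weight in sequence name {sequence_name!r}")
    return base, weight


# ---------------------------------------------------------------------------
# Chao1
# ---------------------------------------------------------------------------


def chao_estimate(richness: int, singletons: int, doubletons: int) -> float:
    """Chao1 minimum-richness estimate from singleton/doubleton counts.

    Classic form S + F1^2 / (2 F2); the bias-corrected form
    S + F1 (F1 - 1) / 2 is used when there are no doubletons.
    """
    if min(richness, singletons, doubletons) < 0:
        raise ReportError("Chao1 inputs must be non-negative")
    if singletons + doubletons > richness:
        raise ReportError("Chao1 requires S_obs >= F1 + F2")
    if doubletons > 0:
        return richness + singletons**2 / (2.0 * doubletons)
    return richness + singletons * (singletons - 1) / 2.0


# ---------------------------------------------------------------------------
# composition tables
# ---------------------------------------------------------------------------


@dataclass
class TaxonStats:
    """Aggregated statistics of one taxon in one dataset."""

    taxon: Optional[TaxonNode]
    weighted_abundance: float
    richness: int
    chao: Optional[float]


class _Cell:
    __slots__ = ("abundance", "richness", "f1", "f2")

    def __init__(self):
        self.abundance = 0.0
        self.richness = 0
        self.f1 = 0  # unique sequences of weight exactly 1
        self.f2 = 0  # ... of weight exactly 2

    def add(self, weight: float) -> None:
        self.abundance += weight
        self.richness += 1
        if weight == 1:
            self.f1 += 1
        elif weight == 2:
            self.f2 += 1

    def stats(self, taxon: Optional[TaxonNode]) -> TaxonStats:
        chao = chao_estimate(self.richness, self.f1, self.f2) if self.richness else 0.0
        return TaxonStats(taxon, self.abundance, self.richness, chao)


class CompositionTable:
    """Per-rank, per-taxon abundance/richness/Chao1 for one or more datasets."""

    def __init__(self, taxonomy: Taxonomy, labels: Sequence[str],
                 ranks: Sequence[Rank] = CANONICAL_RANKS):
        if len(set(labels)) != len(labels):
            raise ReportError("dataset labels must be unique")
        self.taxonomy = taxonomy
        self.labels = list(labels)
        self.ranks = tuple(ranks)
        # rank -> taxon name -> label -> cell
        self._cells: Dict[Rank, Dict[str, Dict[str, _Cell]]] = {
            r: {} for r in self.ranks
        }
        self._unassigned: Dict[Rank, Dict[str, float]] = {
            r: {lb: 0.0 for lb in self.labels} for r in self.ranks
        }
        self._totals: Dict[str, float] = {lb: 0.0 for lb in self.labels}

    # -- filling -------------------------------------------------------------

    def _cell(self, rank: Rank, taxon_name: str, label: str) -> _Cell:
        per_label = self._cells[rank].setdefault(taxon_name, {})
        if label not in per_label:
            per_label[label] = _Cell()
        return per_label[label]

    def add_result(self, result: ClassificationResult, label: str) -> None:
        self._totals[label] += result.weight
        for rank in self.ranks:
            node = (
                result.assigned_node.ancestor_at_rank(rank)
                if result.assigned_node is not None
                else None
            )
            if node is None:
                self._unassigned[rank][label] += result.weight
            else:
                self._cell(rank, node.name, label).add(result.weight)

    # -- reading -------------------------------------------------------------

    def taxa_at_rank(self, rank: Rank) -> List[str]:
        return sorted(self._cells[rank])

    def get(self, rank: Rank, taxon_name: str, label: str) -> TaxonStats:
        node = self.taxonomy.node(taxon_name)
        cell = self._cells[rank].get(taxon_name, {}).get(label)
        if cell is None:
            return TaxonStats(node, 0.0, 0, 0.0)
        return cell.stats(node)

    def unassigned(self, rank: Rank, label: str) -> float:
        return self._unassigned[rank][label]

    def total(self, label: str) -> float:
        return self._totals[label]

    # -- output --------------------------------------------------------------

    def _fmt_abundance(self, value: float) -> str:
        if all(float(t).is_integer() for t in self._totals.values()):
            return str(int(round(value)))
        return f"{value:.2f}"

    def to_tsv(self, rank: Rank) -> str:
        """One rank's table: taxon path, then (abundance, richness, chao) per dataset."""
        header = ["taxon_path"]
        for label in self.labels:
            header += [f"{label}_abundance", f"{label}_richness", f"{label}_chao"]
        lines = ["\t".join(header)]
        rows = sorted(
            self._cells[rank],
            key=lambda name: ";".join(self.taxonomy.node(name).lineage_names()),
        )
        for name in rows:
            path = ";".join(self.taxonomy.node(name).lineage_names())
            fields = [path]
            for label in self.labels:
                st = self.get(rank, name, label)
                fields += [
                    self._fmt_abundance(st.weighted_abundance),
                    str(st.richness),
                    f"{st.chao:.2f}",
                ]
            lines.append("\t".join(fields))
        unc = [UNCLASSIFIED_LABEL]
        for label in self.labels:
            unc += [self._fmt_abundance(self._unassigned[rank][label]), "", ""]
        lines.append("\t".join(unc))
        return "\n".join(lines) + "\n"

    def to_dataframe(self, rank: Rank) -> pd.DataFrame:
        """Long-format DataFrame of one rank's table."""
        records = []
        for name in self.taxa_at_rank(rank):
            for label in self.labels:
                st = self.get(rank, name, label)
                records.append(
                    {
                        "taxon": name,
                        "dataset": label,
                        "abundance": st.weighted_abundance,
                        "richness": st.richness,
                        "chao": st.chao,
                    }
                )
        return pd.DataFrame.from_records(
            records, columns=["taxon", "dataset", "abundance", "richness", "chao"]
        )


def accumulate(
    results: Iterable[ClassificationResult],
    taxonomy: Taxonomy,
    label: str = "sample",
    ranks: Sequence[Rank] = CANONICAL_RANKS,
) -> CompositionTable:
    """Build a single-dataset composition table from classification results."""
    table = CompositionTable(taxonomy, [label], ranks)
    for result in results:
        table.add_result(result, label)
    return table


def merge_datasets(tables: Sequence[CompositionTable]) -> CompositionTable:
    """Merge per-dataset tables over one taxonomy.

    Taxa present in any dataset appear for all, zero-filled where absent.
    """
    if not tables:
        raise ReportError("nothing to merge")
    first = tables[0]
    names = first.taxonomy.names()
    for t in tables[1:]:
        if t.taxonomy.names() != names or t.ranks != first.ranks:
            raise ReportError("cannot merge tables over different taxonomies")
    labels = [lb for t in tables for lb in t.labels]
    merged = CompositionTable(first.taxonomy, labels, first.ranks)
    for t in tables:
        for label in t.labels:
            merged._totals[label] = t._totals[label]
            for rank in t.ranks:
                merged._unassigned[rank][label] = t._unassigned[rank][label]
                for name, per_label in t._cells[rank].items():
                    merged._cells[rank].setdefault(name, {})
                    if label in per_label:
                        merged._cells[rank][name][label] = per_label[label]
        # zero-fill: ensure every taxon key exists in merged for all ranks
    return merged


# ---------------------------------------------------------------------------
# FASTA export
# ---------------------------------------------------------------------------


def export_fasta_by_taxon(
    results: Iterable[ClassificationResult],
    sequences: Mapping[str, str],
    taxon: TaxonNode,
    wrap: int = 60,
) -> str:
    """FASTA of all query sequences assigned within a taxon's subtree.

    Headers are augmented with the assigned taxon's full path.
    """
    out: List[str] = []
    for result in results:
        node = result.assigned_node
        if node is None or not taxon.is_ancestor_or_self_of(node):
            continue
        try:
            seq = sequences[result.query_id]
        except KeyError:
            raise ReportError(
                f"no sequence available for query {result.query_id!r}"
            ) from None
        path = ";".join(node.lineage_names())
        out.append(f">{result.query_id} {path}")
        for i in range(0, len(seq), wrap):
            out.append(seq[i : i + wrap])
    return "\n".join(out) + ("\n" if out else "")
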