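"""Reference-database construction from a lineage export and a manual-changes file.

The input is the tab-separated dump a curation tool produces: one row per
reference sequence with its accession and semicolon-delimited taxonomic path
(optionally a parallel list of rank labels).  A manual-changes file (MCF)
records curation operations — taxa added, renamed or deleted — which are
applied to the lineages and verified against the built taxonomy.

Ranks are inferred per taxon: primarily from the supplied rank label,
secondarily from standard nomenclature suffixes (``-ales`` = order,
``-aceae`` = family), and lastly as one step deeper than the parent's rank.

The output is the classifier's reference triple: a Newick tree-file, a
tab-separated mapping file, and a FASTA of reference sequences.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxonomy import (
    RANK_BY_LABEL,
    Rank,
    TaxonNode,
    Taxonomy,
    parse_mapping,
    parse_newick,
    write_mapping,
    write_newick,
)

__all__ = [
    "LineageRecord",
    "ManualChange",
    "ChangeReport",
    "ReferenceDatabase",
    "BuilderError",
    "parse_lineages",
    "parse_mcf",
    "apply_manual_changes",
    "infer_rank",
    "build",
]


class BuilderError(ValueError):
    pass


@dataclass(frozen=True)
class LineageRecord:
    """One reference sequence: accession plus root-to-tip taxon path."""

    accession: str
    lineage: Tuple[str, ...]
    ncbi_ranks: Optional[Tuple[Optional[str], ...]] = None

    def __post_init__(self):
        if not self.accession:
            raise BuilderError("empty accession")
        if not self.lineage or any(not n for n in self.lineage):
            raise BuilderError(f"empty lineage element for {self.accession!r}")
        if self.ncbi_ranks is not None and len(self.ncbi_ranks) != len(self.lineage):
            raise BuilderError(
                f"rank list length mismatch for {self.accession!r}"
            )


@dataclass(frozen=True)
class ManualChange:
    """One curation operation: add/rename/delete of a taxon path."""

    action: str  # add | rename | delete
    target: Tuple[str, ...]
    payload: Optional[str] = None

    def __post_init__(self):
        if self.action not in ("add", "rename", "delete"):
            raise BuilderError(f"unknown MCF action {self.action!r}")
        if not self.target:
            raise BuilderError("MCF change with empty target path")
        if self.action == "rename" and not self.payload:
            raise BuilderError("rename change requires a new name payload")


@dataclass
class ChangeReport:
    change: ManualChange
    applied: bool
    detail: str = ""


def parse_lineages(text: str) -> List[LineageRecord]:
    """Parse a tab-separated lineage export: accession, ';'-delimited path,
    optionally a third column of ';'-delimited rank labels."""
    records: List[LineageRecord] = []
    seen: Set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) not in (2, 3):
            raise BuilderError(
                f"lineage line {lineno}: expected 2 or 3 columns, got {len(fields)}"
            )
        accession = fields[0].strip()
        if not accession:
            raise BuilderError(f"lineage line {lineno}: empty accession")
        if accession in seen:
            raise BuilderError(f"lineage line {lineno}: duplicate accession {accession!r}")
        seen.add(accession)
        lineage = tuple(p.strip() for p in fields[1].split(";") if p.strip())
        if not lineage:
            raise BuilderError(f"lineage line {lineno}: empty lineage")
        ranks = None
        if len(fields) == 3 and fields[2].strip():
            ranks = tuple(
                (p.strip() or None) for p in fields[2].split(";")
            )
            if len(ranks) != len(lineage):
                raise BuilderError(
                    f"lineage line {lineno}: {len(ranks)} ranks for "
                    f"{len(lineage)} lineage levels"
                )
        records.append(LineageRecord(accession, lineage, ranks))
    return records


def parse_mcf(text: str) -> List[ManualChange]:
    """Parse a manual-changes file: ``action<TAB>/path/to/taxon<TAB>payload``."""
    changes: List[ManualChange] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) not in (2, 3):
            raise BuilderError(
                f"MCF line {lineno}: expected 2 or 3 tab-separated fields"
            )
        action = fields[0].strip().lower()
        target = tuple(p for p in fields[1].split("/") if p)
        payload = fields[2].strip() if len(fields) == 3 and fields[2].strip() else None
        try:
            changes.append(ManualChange(action, target, payload))
        except BuilderError as exc:
            raise BuilderError(f"MCF line {lineno}: {exc}") from exc
    return changes


def _matches_at(lineage: Tuple[str, ...], path: Tuple[str, ...]) -> bool:
    """Whether ``lineage`` passes through ``path`` (path is a prefix)."""
    return len(lineage) >= len(path) and lineage[: len(path)] == path


def apply_manual_changes(
    records: Sequence[LineageRecord], changes: Sequence[ManualChange]
) -> Tuple[List[LineageRecord], List[Tuple[str, ...]], List[ChangeReport]]:
    """Apply MCF operations to lineage records.

    Returns the rewritten records, extra taxon paths to create (from ``add``
    changes), and a per-change report.  Renames rewrite every occurrence of
    the target taxon; deletes drop the taxon together with the sequence
    records it annotated (a sequence without valid annotation is removed).
    A rename or delete whose target does not occur is recorded as failed,
    not fatal.
    """
    current = list(records)
    extra: List[Tuple[str, ...]] = []
    report: List[ChangeReport] = []
    for change in changes:
        path = change.target
        if change.action == "add":
            extra.append(path)
            report.append(ChangeReport(change, True, "taxon scheduled for creation"))
            continue
        hits = [r for r in current if _matches_at(r.lineage, path)]
        if change.action == "rename":
            if not hits:
                report.append(ChangeReport(change, False, "target taxon not found"))
                continue
            depth = len(path) - 1
            rewritten = []
            for r in current:
                if _matches_at(r.lineage, path):
                    new_lineage = (
                        r.lineage[:depth] + (change.payload,) + r.lineage[depth + 1 :]
                    )
                    rewritten.append(
                        LineageRecord(r.accession, new_lineage, r.ncbi_ranks)
                    )
                else:
                    rewritten.append(r)
            current = rewritten
            report.append(
                ChangeReport(change, True, f"renamed in {len(hits)} records")
            )
        elif change.action == "delete":
            if not hits:
                report.append(ChangeReport(change, False, "target taxon not found"))
                continue
            removed = {r.accession for r in hits}
            current = [r for r in current if r.accession not in removed]
            report.append(
                ChangeReport(change, True, f"removed {len(removed)} orphaned records")
            )
    return current, extra, report


_ORDER_SUFFIXES = ("ales",)
_FAMILY_SUFFIXES = ("aceae", "acaea")  # second spelling tolerated


def infer_rank(
    name: str, ncbi_rank: Optional[str], parent_rank: Rank
) -> Rank:
    """Infer a taxon's rank: explicit label, then name suffix, then parent+1.

    A candidate that is not strictly deeper than the parent's rank would break
    the taxonomy's monotonicity invariant and falls through to the next rule.
    """
    if parent_rank is Rank.NORANK:
        raise BuilderError("parent rank must be a ranked level")

    def admissible(rank: Optional[Rank]) -> bool:
        return rank is not None and rank.value > parent_rank.value

    if ncbi_rank:
        candidate = RANK_BY_LABEL.get(ncbi_rank.strip().lower())
        if candidate is Rank.NORANK:
            return Rank.NORANK
        if admissible(candidate):
            return candidate
    lowered = name.lower()
    if any(lowered.endswith(s) for s in _ORDER_SUFFIXES) and admissible(Rank.ORDER):
        return Rank.ORDER
    if any(lowered.endswith(s) for s in _FAMILY_SUFFIXES) and admissible(Rank.FAMILY):
        return Rank.FAMILY
    return parent_rank.deeper()


@dataclass
class ReferenceDatabase:
    """The classifier's reference triple held in memory."""

    taxonomy: Taxonomy
    assignments: Dict[str, TaxonNode]  # accession -> taxon node
    sequences: Dict[str, str]  # accession -> nucleotide sequence

    def __post_init__(self):
        if set(self.assignments) != set(self.sequences):
            raise BuilderError(
                "accession sets of assignments and sequences differ"
            )

    @property
    def accessions(self) -> List[str]:
        return sorted(self.assignments)

    def node_map(self) -> Mapping[str, TaxonNode]:
        return self.assignments

    # -- derived databases ---------------------------------------------------

    def subset(self, keep_accessions: Iterable[str]) -> "ReferenceDatabase":
        """Database restricted to some accessions; unsupported taxa are pruned."""
        keep = set(keep_accessions)
        missing = keep - set(self.assignments)
        if missing:
            raise BuilderError(f"unknown accessions: {sorted(missing)[:5]}")
        keep_names: Set[str] = {self.taxonomy.root.name}
        for acc in keep:
            keep_names.update(n.name for n in self.assignments[acc].path_to_root())
        taxonomy = self.taxonomy.copy_filtered(keep_names)
        assignments = {
            acc: taxonomy.node(self.assignments[acc].name) for acc in keep
        }
        sequences = {acc: self.sequences[acc] for acc in keep}
        return ReferenceDatabase(taxonomy, assignments, sequences)

    def remove_taxon(self, taxon_name: str) -> Tuple["ReferenceDatabase", List[str]]:
        """Database with one taxon's whole subtree removed.

        Returns the retained database and the held-out accessions.
        """
        node = self.taxonomy.node(taxon_name)
        held_out = [
            acc
            for acc, n in self.assignments.items()
            if node.is_ancestor_or_self_of(n)
        ]
        retained = self.subset(set(self.assignments) - set(held_out))
        return retained, sorted(held_out)

    # -- serialization ---------------------------------------------------------

    def write(self, outdir: os.PathLike, name: str = "refdb") -> Dict[str, Path]:
        """Write the triple ``<name>.tre``, ``<name>.map``, ``<name>.fasta``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "tre": outdir / f"{name}.tre",
            "map": outdir / f"{name}.map",
            "fasta": outdir / f"{name}.fasta",
        }
        paths["tre"].write_text(write_newick(self.taxonomy))
        paths["map"].write_text(write_mapping(self.taxonomy))
        records = [
            SeqRecord(
                Seq(self.sequences[acc]),
                id=acc,
                description=self.assignments[acc].name,
            )
            for acc in self.accessions
        ]
        with open(paths["fasta"], "w") as handle:
            SeqIO.write(records, handle, "fasta")
        return paths

    @classmethod
    def read(cls, directory: os.PathLike, name: Optional[str] = None) -> "ReferenceDatabase":
        """Load a triple from a directory (by stem name, or the unique one found)."""
        directory = Path(directory)
        if name is None:
            tres = sorted(directory.glob("*.tre"))
            if len(tres) != 1:
                raise BuilderError(
                    f"expected exactly one .tre file in {directory}, found {len(tres)}"
                )
            name = tres[0].stem
        tre = directory / f"{name}.tre"
        mapping = directory / f"{name}.map"
        fasta = directory / f"{name}.fasta"
        for p in (tre, mapping, fasta):
            if not p.exists():
                raise BuilderError(f"missing reference database file: {p}")
        taxonomy = parse_mapping(mapping.read_text(), parse_newick(tre.read_text()))
        sequences: Dict[str, str] = {}
        assignments: Dict[str, TaxonNode] = {}
        for rec in SeqIO.parse(str(fasta), "fasta"):
            taxon_name = rec.description.split(None, 1)[1] if " " in rec.description else None
            if taxon_name is None:
                raise BuilderError(f"FASTA record {rec.id!r} lacks a taxon annotation")
            sequences[rec.id] = str(rec.seq)
            assignments[rec.id] = taxonomy.node(taxon_name)
        return cls(taxonomy, assignments, sequences)


def _prune_unsupported(taxonomy: Taxonomy, supported: Set[str]) -> Taxonomy:
    """Drop nodes with no supported node in their subtree (root always kept)."""
    keep: Set[str] = {taxonomy.root.name}
    for name in supported:
        keep.update(n.name for n in taxonomy.node(name).path_to_root())
    return taxonomy.copy_filtered(keep)


def build(
    records: Sequence[LineageRecord],
    sequences: Mapping[str, str],
    extra_taxa: Sequence[Tuple[str, ...]] = (),
    root_name: str = "root",
) -> ReferenceDatabase:
    """Build a reference database from lineage records and their sequences.

    The taxonomy is the trie of lineages under a synthetic root, with ranks
    inferred per taxon and siblings ordered by name (so identical inputs give
    byte-identical serialized outputs).  Taxa without any sequence support —
    including freshly added MCF taxa — are pruned.
    """
    missing = [r.accession for r in records if r.accession not in sequences]
    if missing:
        raise BuilderError(f"accessions without sequences: {missing[:10]}")

    taxonomy = Taxonomy.create(root_name)
    assignments: Dict[str, TaxonNode] = {}

    def insert_path(
        lineage: Tuple[str, ...], ranks: Optional[Tuple[Optional[str], ...]]
    ) -> TaxonNode:
        parent = taxonomy.root
        for i, taxon_name in enumerate(lineage):
            if taxon_name in taxonomy:
                node = taxonomy.node(taxon_name)
                if node.parent is not parent:
                    raise BuilderError(
                        f"taxon name collision: {taxon_name!r} occurs under both "
                        f"{node.parent.name if node.parent else 'root'!r} and {parent.name!r}"
                    )
            else:
                rank = infer_rank(
                    taxon_name,
                    ranks[i] if ranks else None,
                    parent.effective_rank(),
                )
                node = taxonomy.add(taxon_name, parent, rank)
            parent = node
        return parent

    for record in records:
        assignments[record.accession] = insert_path(record.lineage, record.ncbi_ranks)
    for path in extra_taxa:
        insert_path(path, None)

    supported = {node.name for node in assignments.values()}
    taxonomy = _prune_unsupported(taxonomy, supported)
    taxonomy.sort()
    # Stable ids: preorder index after sorting.
    for i, node in enumerate(taxonomy):
        node.id = str(i)
    taxonomy._by_id = {n.id: n for n in taxonomy}
    assignments = {acc: taxonomy.node(n.name) for acc, n in assignments.items()}
    seqs = {acc: str(sequences[acc]).upper() for acc in assignments}
    return ReferenceDatabase(taxonomy, assignments, seqs)


def verify_changes(
    taxonomy: Taxonomy, changes: Sequence[ManualChange]
) -> List[ChangeReport]:
    """Re-check MCF operations against the built taxonomy (post-hoc audit)."""
    report: List[ChangeReport] = []
    for change in changes:
        tip = change.target[-1]
        if change.action == "rename":
            ok = tip not in taxonomy and (change.payload in taxonomy)
            detail = "old name absent, new name present" if ok else (
                "old name still present" if tip in taxonomy else
                f"new name {change.payload!r} absent (possibly pruned)"
            )
            # a renamed taxon may legitimately be pruned if it lost all support
            ok = ok or (tip not in taxonomy)
            report.append(ChangeReport(change, ok, detail))
        elif change.action == "delete":
            ok = tip not in taxonomy
            report.append(
                ChangeReport(change, ok, "taxon absent" if ok else "taxon still present")
            )
        else:  # add
            present = tip in taxonomy
            detail = "taxon present" if present else "taxon pruned (no sequence support)"
            report.append(ChangeReport(change, True, detail))
    return report
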