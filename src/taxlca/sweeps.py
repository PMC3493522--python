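"""Parameter-boundary diagnostics: recover effective classifier thresholds by sweeping.

These helpers probe a classifier configuration empirically: they build
minimal single- or two-hit queries against a fixture taxonomy and scan an
input quantity (best-hit identity, top bit-score, a second hit's bit-score)
to locate the boundary at which the classifier's behavior changes.  They are
useful both as a self-check that a parameter set behaves as documented and
for characterizing non-default configurations.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from .alignment import AlignmentHit, QueryHits
from .classify import ClassifierParams, classify_query
from .taxonomy import Rank, TaxonNode, Taxonomy

__all__ = [
    "rank_fixture",
    "identity_cutoff_for_rank",
    "min_bitscore_cutoff",
    "lca_range_cutoff",
]


def rank_fixture() -> Tuple[Taxonomy, Dict[str, TaxonNode]]:
    """A species-depth lineage plus a sibling genus in a second family.

    Returns the taxonomy and an accession map with one reference per rank
    (``REF_species`` ... ``REF_phylum``) and a second-family genus reference
    (``REF_other``) for two-hit LCA probes.
    """
    t = Taxonomy.create("root")
    domain = t.add("DomainA", t.root, Rank.DOMAIN)
    phylum = t.add("PhylumA", domain, Rank.PHYLUM)
    klass = t.add("ClassA", phylum, Rank.CLASS)
    order = t.add("OrderA", klass, Rank.ORDER)
    family = t.add("FamilyA", order, Rank.FAMILY)
    genus = t.add("GenusA", family, Rank.GENUS)
    species = t.add("SpeciesA", genus, Rank.SPECIES)
    family_b = t.add("FamilyB", order, Rank.FAMILY)
    genus_b = t.add("GenusB", family_b, Rank.GENUS)
    refs = {
        "REF_species": species,
        "REF_genus": genus,
        "REF_family": family,
        "REF_order": order,
        "REF_class": klass,
        "REF_phylum": phylum,
        "REF_other": genus_b,
    }
    return t, refs


def _single_hit_query(accession: str, bitscore: float, identity: float) -> QueryHits:
    return QueryHits(
        "probe", [AlignmentHit("probe", accession, bitscore, identity, 500)]
    )


def identity_cutoff_for_rank(
    rank: Rank,
    params: Optional[ClassifierParams] = None,
    identities: Optional[List[float]] = None,
) -> Optional[float]:
    """Smallest best-hit identity at which an assignment survives at ``rank``.

    Classifies a single high-scoring hit to a reference annotated exactly at
    ``rank`` for each identity in the sweep (default 75 to 100 in 0.5 steps)
    and reports the smallest identity whose post-filter assignment keeps that
    rank; ``None`` if the rank is never retained.
    """
    params = params or ClassifierParams()
    if identities is None:
        identities = [75.0 + 0.5 * i for i in range(51)]
    _, refs = rank_fixture()
    accession = f"REF_{rank.label}"
    refmap = {accession: refs[accession]}
    for identity in sorted(identities):
        q = _single_hit_query(accession, 1000.0, identity)
        r = classify_query(q, refmap, params)
        if r.assigned_node is not None and r.assigned_node.rank is rank:
            return identity
    return None


def min_bitscore_cutoff(
    params: Optional[ClassifierParams] = None,
    bitscores: Optional[List[float]] = None,
) -> Optional[float]:
    """Smallest top-hit bit-score at which the query is classified at all.

    Sweeps a single 100%-identity hit's bit-score (default 100 to 200 in
    integer steps); ``None`` if every probe stays unclassified.
    """
    params = params or ClassifierParams()
    if bitscores is None:
        bitscores = [float(b) for b in range(100, 201)]
    _, refs = rank_fixture()
    refmap = {"REF_genus": refs["REF_genus"]}
    for bitscore in sorted(bitscores):
        q = _single_hit_query("REF_genus", bitscore, 100.0)
        r = classify_query(q, refmap, params)
        if r.assigned_node is not None:
            return bitscore
    return None


def lca_range_cutoff(
    params: Optional[ClassifierParams] = None,
    top_bitscore: float = 1000.0,
    second_bitscores: Optional[List[float]] = None,
) -> Optional[float]:
    """Effective LCA range (percent of the top bit-score) recovered by probing.

    The top hit is a genus in one family, the second a genus in a sibling
    family; the second hit's bit-score is swept upward (default 950 to 1000 in
    integer steps) until the assignment rises above genus rank — i.e. the
    second hit entered the LCA.  Returns 100 x (1 - t / top) for the smallest
    such score t, or ``None`` if it never enters.
    """
    params = params or ClassifierParams()
    if second_bitscores is None:
        second_bitscores = [float(b) for b in range(950, 1001)]
    _, refs = rank_fixture()
    refmap = {"REF_genus": refs["REF_genus"], "REF_other": refs["REF_other"]}
    for second in sorted(second_bitscores):
        q = QueryHits(
            "probe",
            [
                AlignmentHit("probe", "REF_genus", top_bitscore, 100.0, 500),
                AlignmentHit("probe", "REF_other", second, 100.0, 500),
            ],
        )
        r = classify_query(q, refmap, params)
        if r.assigned_node is not None and r.assigned_node.rank is not Rank.GENUS:
            # rounded to avoid spurious float residue in 1 - t/top
            return round(100.0 * (1.0 - second / top_bitscore), 9)
    return None
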