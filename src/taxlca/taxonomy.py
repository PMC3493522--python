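"""Ranked taxonomy model with Newick/mapping-file serialization and LCA queries.

A taxonomy is a rooted tree of uniquely named taxa.  Each node carries a rank
from the canonical ladder root < domain < kingdom < phylum < class < order <
family < genus < species, or ``norank`` for intermediate levels (clades,
subgroups, incertae sedis holders) that are transparent to rank arithmetic.

On disk a taxonomy is a pair of files: a Newick tree-file giving the topology
(every node labelled, internal nodes included) and a tab-separated mapping
file giving each node's stable id, name, rank depth and parent id.
"""

from __future__ import annotations

import enum
import io
import re
import warnings
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set

from skbio import TreeNode as _SkbioTreeNode
from skbio.io import NewickFormatError as _NewickFormatError

__all__ = [
    "Rank",
    "CANONICAL_RANKS",
    "TaxonNode",
    "Taxonomy",
    "TaxonomyError",
    "lca",
    "parse_newick",
    "write_newick",
    "parse_mapping",
    "write_mapping",
]


class TaxonomyError(ValueError):
    """Raised for malformed taxonomies or serialized taxonomy files."""


class Rank(enum.Enum):
    """Taxonomic rank with an integer depth (root=0 ... species=8).

    ``NORANK`` marks unranked intermediate nodes; they inherit rank semantics
    from their nearest ranked ancestor.
    """

    NORANK = -1
    ROOT = 0
    DOMAIN = 1
    KINGDOM = 2
    PHYLUM = 3
    CLASS = 4
    ORDER = 5
    FAMILY = 6
    GENUS = 7
    SPECIES = 8

    @property
    def depth(self) -> int:
        return self.value

    @property
    def label(self) -> str:
        return self.name.lower()

    def deeper(self) -> "Rank":
        """The rank one step deeper, capped at species."""
        if self is Rank.NORANK:
            raise TaxonomyError("norank has no successor rank")
        return Rank(min(self.value + 1, Rank.SPECIES.value))


#: Ranks at which assignments are reported, tipward order.
CANONICAL_RANKS: Sequence[Rank] = (
    Rank.DOMAIN,
    Rank.KINGDOM,
    Rank.PHYLUM,
    Rank.CLASS,
    Rank.ORDER,
    Rank.FAMILY,
    Rank.GENUS,
    Rank.SPECIES,
)

#: Accepted spellings for rank labels (e.g. from NCBI rank annotations).
RANK_BY_LABEL: Dict[str, Rank] = {
    "root": Rank.ROOT,
    "domain": Rank.DOMAIN,
    "superkingdom": Rank.DOMAIN,
    "kingdom": Rank.KINGDOM,
    "subkingdom": Rank.KINGDOM,
    "phylum": Rank.PHYLUM,
    "class": Rank.CLASS,
    "order": Rank.ORDER,
    "family": Rank.FAMILY,
    "genus": Rank.GENUS,
    "species": Rank.SPECIES,
    "norank": Rank.NORANK,
    "no rank": Rank.NORANK,
}


class TaxonNode:
    """One taxon: a named, ranked node with a parent link and ordered children."""

    __slots__ = ("id", "name", "rank", "parent", "children")

    def __init__(
        self,
        name: str,
        rank: Rank = Rank.NORANK,
        parent: Optional["TaxonNode"] = None,
        id: Optional[str] = None,
    ):
        if not name:
            raise TaxonomyError("taxon name must be non-empty")
        self.name = name
        self.rank = rank
        self.parent = parent
        self.id = id if id is not None else name
        self.children: List["TaxonNode"] = []

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TaxonNode({self.name!r}, rank={self.rank.label})"

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def path_to_root(self) -> List["TaxonNode"]:
        """Nodes from self (first) to the root (last)."""
        path = [self]
        node = self
        while node.parent is not None:
            node = node.parent
            path.append(node)
        return path

    @property
    def depth(self) -> int:
        """Number of edges between this node and the root."""
        return len(self.path_to_root()) - 1

    def lineage_names(self) -> List[str]:
        """Names from the root (first) down to self (last)."""
        return [n.name for n in reversed(self.path_to_root())]

    def ancestor_at_rank(self, rank: Rank) -> Optional["TaxonNode"]:
        """The unique ancestor-or-self with the given rank, if the lineage has one."""
        for node in self.path_to_root():
            if node.rank is rank:
                return node
        return None

    def effective_rank(self) -> Rank:
        """Rank of the nearest ranked ancestor-or-self (root counts as ROOT)."""
        for node in self.path_to_root():
            if node.rank is not Rank.NORANK:
                return node.rank
        return Rank.ROOT

    def is_ancestor_or_self_of(self, other: "TaxonNode") -> bool:
        return any(n is self for n in other.path_to_root())

    def traverse(self) -> Iterator["TaxonNode"]:
        """Preorder traversal of the subtree rooted here."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


class Taxonomy:
    """A rooted taxonomy with name and id indexes kept in sync with the tree."""

    def __init__(self, root: TaxonNode):
        self.root = root
        self._by_name: Dict[str, TaxonNode] = {}
        self._by_id: Dict[str, TaxonNode] = {}
        for node in root.traverse():
            self._register(node)

    def _register(self, node: TaxonNode) -> None:
        if node.name in self._by_name:
            raise TaxonomyError(f"duplicate taxon name: {node.name!r}")
        if node.id in self._by_id:
            raise TaxonomyError(f"duplicate taxon id: {node.id!r}")
        self._by_name[node.name] = node
        self._by_id[node.id] = node

    # -- construction ------------------------------------------------------

    @classmethod
    def create(cls, root_name: str = "root") -> "Taxonomy":
        return cls(TaxonNode(root_name, rank=Rank.ROOT, id="0"))

    def add(
        self,
        name: str,
        parent: TaxonNode,
        rank: Rank = Rank.NORANK,
        id: Optional[str] = None,
    ) -> TaxonNode:
        """Attach a new taxon under ``parent``; names must stay unique."""
        if parent.name not in self._by_name or self._by_name[parent.name] is not parent:
            raise TaxonomyError(f"parent {parent.name!r} is not part of this taxonomy")
        if rank is not Rank.NORANK and rank.value < parent.effective_rank().value:
            raise TaxonomyError(
                f"rank {rank.label} of {name!r} is more rootward than its "
                f"parent {parent.name!r} ({parent.effective_rank().label})"
            )
        node = TaxonNode(name, rank=rank, parent=parent, id=id)
        self._register(node)
        parent.children.append(node)
        return node

    # -- lookup ------------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self) -> Iterator[TaxonNode]:
        return self.root.traverse()

    def __len__(self) -> int:
        return len(self._by_name)

    def node(self, name: str) -> TaxonNode:
        try:
            return self._by_name[name]
        except KeyError:
            raise TaxonomyError(f"unknown taxon name: {name!r}") from None

    def by_id(self, node_id: str) -> TaxonNode:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise TaxonomyError(f"unknown taxon id: {node_id!r}") from None

    def names(self) -> Set[str]:
        return set(self._by_name)

    def nodes_at_rank(self, rank: Rank) -> List[TaxonNode]:
        return [n for n in self if n.rank is rank]

    def lca(self, nodes: Iterable[TaxonNode]) -> TaxonNode:
        return lca(nodes)

    # -- structural operations ----------------------------------------------

    def sort(self) -> None:
        """Order siblings alphabetically by name (stable, deterministic output)."""
        for node in self:
            node.children.sort(key=lambda c: c.name)

    def copy_filtered(self, keep_names: Set[str]) -> "Taxonomy":
        """Deep copy retaining only the named nodes.

        ``keep_names`` must be ancestor-closed (contain the root and, for every
        kept node, all of its ancestors); nodes outside the set are dropped
        with their subtrees.
        """
        if self.root.name not in keep_names:
            raise TaxonomyError("filtered copy must retain the root")

        def clone(node: TaxonNode, parent: Optional[TaxonNode]) -> TaxonNode:
            new = TaxonNode(node.name, rank=node.rank, parent=parent, id=node.id)
            new.children = [
                clone(c, new) for c in node.children if c.name in keep_names
            ]
            return new

        return Taxonomy(clone(self.root, None))


def lca(nodes: Iterable[TaxonNode]) -> TaxonNode:
    """Lowest common ancestor: the deepest node ancestral-or-equal to all inputs."""
    paths = [list(reversed(n.path_to_root())) for n in nodes]
    if not paths:
        raise TaxonomyError("lca of an empty node set is undefined")
    if any(p[0] is not paths[0][0] for p in paths):
        raise TaxonomyError("lca inputs belong to different taxonomies")
    result = paths[0][0]
    for level in range(min(len(p) for p in paths)):
        candidate = paths[0][level]
        if all(p[level] is candidate for p in paths):
            result = candidate
        else:
            break
    return result


# ---------------------------------------------------------------------------
# Newick serialization
# ---------------------------------------------------------------------------

_NEEDS_QUOTE = re.compile(r"[\s()\[\]:;,']")


def parse_newick(text: str) -> Taxonomy:
    """Parse a Newick tree-file into a taxonomy with all ranks unset (norank).

    Every node, internal or leaf, must carry a non-empty label; labels must be
    unique.  Branch lengths are tolerated and discarded.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sniffer warns before the error surfaces
            tree = _SkbioTreeNode.read(
                io.StringIO(text), format="newick", convert_underscores=False
            )
    except (_NewickFormatError, ValueError) as exc:
        raise TaxonomyError(f"malformed Newick: {exc}") from exc

    def convert(sknode, parent: Optional[TaxonNode]) -> TaxonNode:
        name = sknode.name
        if not name:
            where = "root" if parent is None else f"child of {parent.name!r}"
            raise TaxonomyError(f"unlabelled Newick node ({where})")
        node = TaxonNode(name, rank=Rank.NORANK, parent=parent)
        node.children = [convert(c, node) for c in sknode.children]
        return node

    root = convert(tree, None)
    root.rank = Rank.ROOT
    return Taxonomy(root)  # Taxonomy() rejects duplicate labels


def _quote_label(name: str) -> str:
    if _NEEDS_QUOTE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(taxonomy: Taxonomy) -> str:
    """Serialize the topology: labels on every node, no branch lengths."""

    def fmt(node: TaxonNode) -> str:
        label = _quote_label(node.name)
        if node.children:
            return "(" + ",".join(fmt(c) for c in node.children) + ")" + label
        return label

    return fmt(taxonomy.root) + ";\n"


# ---------------------------------------------------------------------------
# Mapping-file serialization
# ---------------------------------------------------------------------------

_MAPPING_HEADER = "#id\tname\tdepth\tparent_id\n"


def parse_mapping(text: str, taxonomy: Taxonomy) -> Taxonomy:
    """Merge a tab-separated mapping file onto a parsed taxonomy.

    Columns: node id, name, rank depth integer (-1 for norank), parent id
    ("-" for the root).  Lines starting with ``#`` are headers and skipped.
    Every row must reference a node present in the tree; nodes without a row
    keep rank norank.  Returns the (mutated) taxonomy.
    """
    seen: Set[str] = set()
    pending: List[tuple] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise TaxonomyError(
                f"mapping line {lineno}: expected 4 tab-separated fields, got {len(fields)}"
            )
        node_id, name, depth_s, parent_id = fields
        if name not in taxonomy:
            raise TaxonomyError(f"mapping line {lineno}: unknown node {name!r}")
        if name in seen:
            raise TaxonomyError(f"mapping line {lineno}: duplicate row for {name!r}")
        seen.add(name)
        try:
            depth = int(depth_s)
            rank = Rank(depth)
        except ValueError:
            raise TaxonomyError(
                f"mapping line {lineno}: invalid rank depth {depth_s!r}"
            ) from None
        node = taxonomy.node(name)
        node.rank = rank
        node.id = node_id
        pending.append((lineno, node, parent_id))

    # Rebuild the id index and verify parent links once all ids are known.
    taxonomy._by_id = {}
    for node in taxonomy:
        if node.id in taxonomy._by_id:
            raise TaxonomyError(f"duplicate taxon id: {node.id!r}")
        taxonomy._by_id[node.id] = node
    for lineno, node, parent_id in pending:
        if node.parent is None:
            if parent_id != "-":
                raise TaxonomyError(
                    f"mapping line {lineno}: root row must have parent id '-'"
                )
        # parent ids are only checkable when the parent itself has a row
        elif node.parent.name in seen and node.parent.id != parent_id:
            raise TaxonomyError(
                f"mapping line {lineno}: parent id {parent_id!r} does not match "
                f"tree parent {node.parent.name!r} (id {node.parent.id!r})"
            )
    # Rank monotonicity: no node more rootward-ranked than its parent.
    for node in taxonomy:
        if node.parent is None or node.rank is Rank.NORANK:
            continue
        parent_rank = node.parent.effective_rank()
        if node.rank.value < parent_rank.value:
            raise TaxonomyError(
                f"rank {node.rank.label} of {node.name!r} is more rootward than "
                f"its parent's rank {parent_rank.label}"
            )
    return taxonomy


def write_mapping(taxonomy: Taxonomy) -> str:
    """Serialize ranks and ids: one row per node, preorder, header included."""
    out = [_MAPPING_HEADER]
    for node in taxonomy:
        parent_id = "-" if node.parent is None else node.parent.id
        out.append(f"{node.id}\t{node.name}\t{node.rank.value}\t{parent_id}\n")
    return "".join(out)
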