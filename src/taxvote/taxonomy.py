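"""NCBI-dump-style taxonomy tree: loading, lineages, rank projection, LCA.

The tree is the coordinate system for everything else in the package:
votes are projected to a target rank before tallying, ties collapse to the
lowest common ancestor, and scoring compares rank projections.

Only the dump columns actually needed are consumed: ``nodes.dmp`` columns
1-3 (taxid, parent taxid, rank) and the "scientific name" rows of
``names.dmp``. Fields are separated by ``\\t|\\t`` and rows terminated by
``\\t|``, per the NCBI taxdump convention.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import StructureError, UnknownTaxidError

#: Default ordered rank ladder, coarsest first. "no rank" (and any rank
#: name not on the ladder) is transparent to projection.
DEFAULT_RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
)

NO_RANK = "no rank"

#: Sentinel label for "the tool emitted no taxon for this read"
#: (Kraken2's taxid-0 convention). Never a valid tree node.
UNCLASSIFIED = 0


@dataclass(frozen=True)
class TaxonNode:
    parent: int
    rank: str
    name: str = ""


class TaxonomyTree:
    """Rooted tree of taxid nodes with parent, rank and scientific name.

    Parameters
    ----------
    nodes
        Mapping ``taxid -> TaxonNode`` or ``taxid -> (parent, rank[, name])``.
    root
        Root taxid; inferred as the unique self-parented node when omitted.
    rank_ladder
        Ordered rank names, coarsest first. Projection and ladder queries
        are restricted to these ranks.
    """

    def __init__(
        self,
        nodes: Mapping[int, TaxonNode | tuple],
        root: int | None = None,
        rank_ladder: Sequence[str] = DEFAULT_RANKS,
    ):
        self._nodes: dict[int, TaxonNode] = {}
        for taxid, node in nodes.items():
            taxid = int(taxid)
            if taxid == UNCLASSIFIED:
                raise StructureError(
                    f"taxid {UNCLASSIFIED} is reserved for the unclassified sentinel"
                )
            if not isinstance(node, TaxonNode):
                node = TaxonNode(*node)
            self._nodes[taxid] = node

        self.rank_ladder: tuple[str, ...] = tuple(rank_ladder)
        self._rank_index = {r: i for i, r in enumerate(self.rank_ladder)}

        roots = [t for t, n in self._nodes.items() if n.parent == t]
        if root is None:
            if len(roots) != 1:
                raise StructureError(
                    f"expected exactly one self-parented root node, found {len(roots)}"
                )
            root = roots[0]
        elif root not in self._nodes or self._nodes[root].parent != root:
            raise StructureError(f"declared root {root} is not a self-parented node")
        self.root: int = root
        self._validate()
        self._children: dict[int, list[int]] | None = None

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        ok: set[int] = {self.root}
        for start in self._nodes:
            path: list[int] = []
            on_path: set[int] = set()
            t = start
            while t not in ok:
                if t in on_path:
                    raise StructureError(f"cycle detected through taxid {t}")
                on_path.add(t)
                path.append(t)
                parent = self._nodes[t].parent
                if parent not in self._nodes:
                    raise StructureError(f"taxid {t} references absent parent {parent}")
                t = parent
            ok.update(path)

    # -- basic queries --------------------------------------------------------

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[int]:
        return iter(self._nodes)

    def _node(self, taxid: int) -> TaxonNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise UnknownTaxidError(f"taxid {taxid} not in taxonomy") from None

    def parent(self, taxid: int) -> int:
        return self._node(taxid).parent

    def rank(self, taxid: int) -> str:
        return self._node(taxid).rank

    def name(self, taxid: int) -> str:
        return self._node(taxid).name

    def children(self, taxid: int) -> list[int]:
        """Sorted child taxids (root excludes its self-loop)."""
        if self._children is None:
            index: dict[int, list[int]] = {t: [] for t in self._nodes}
            for t, node in self._nodes.items():
                if t != node.parent:
                    index[node.parent].append(t)
            for kids in index.values():
                kids.sort()
            self._children = index
        self._node(taxid)
        return self._children[taxid]

    def taxids_at_rank(self, rank: str) -> list[int]:
        return sorted(t for t, n in self._nodes.items() if n.rank == rank)

    # -- lineage / projection / LCA ------------------------------------------

    def lineage(self, taxid: int) -> list[tuple[int, str]]:
        """Chain of ``(taxid, rank)`` from the node up to (and including) root."""
        out = [(taxid, self._node(taxid).rank)]
        t = taxid
        while t != self.root:
            t = self._nodes[t].parent
            out.append((t, self._nodes[t].rank))
        return out

    def ancestor_chain(self, taxid: int) -> list[int]:
        return [t for t, _ in self.lineage(taxid)]

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """Ancestor-or-self of ``taxid`` carrying ladder rank ``rank``.

        Returns ``None`` when the node sits strictly above the requested
        rank or no ancestor on the walk to root carries it. Nodes whose
        rank is off-ladder (e.g. "no rank") are transparent: skipped, never
        returned.
        """
        if rank not in self._rank_index:
            raise ValueError(f"rank {rank!r} is not on the rank ladder")
        t = taxid
        node = self._node(t)
        while True:
            if node.rank == rank:
                return t
            if t == self.root:
                return None
            t = node.parent
            node = self._nodes[t]

    def lca(self, taxids: Iterable[int]) -> int:
        """Deepest node ancestral-or-equal to every input taxid."""
        taxids = list(taxids)
        if not taxids:
            raise ValueError("lca of an empty taxid set is undefined")
        chain = self.ancestor_chain(taxids[0])
        common = set(chain)
        for t in taxids[1:]:
            common &= set(self.ancestor_chain(t))
        for t in chain:  # chain runs deepest-first
            if t in common:
                return t
        raise StructureError("disconnected taxids share no ancestor")  # pragma: no cover


# -- dump I/O -----------------------------------------------------------------


def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            yield from fh
    elif hasattr(source, "read"):
        yield from source
    else:
        yield from source


def _split_dump_row(line: str) -> list[str]:
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[:-2]
    return line.split("\t|\t")


def load_taxonomy(
    nodes_source,
    names_source=None,
    rank_ladder: Sequence[str] = DEFAULT_RANKS,
) -> TaxonomyTree:
    """Build a :class:`TaxonomyTree` from nodes.dmp / names.dmp style text.

    ``names_source`` is optional; nodes without a scientific-name row get an
    empty name. Sources may be paths, open text streams, or line iterables.
    """
    from .errors import ParseError

    nodes: dict[int, TaxonNode] = {}
    raw: dict[int, tuple[int, str]] = {}
    for lineno, line in enumerate(_iter_lines(nodes_source), start=1):
        if not line.strip():
            continue
        fields = _split_dump_row(line)
        if len(fields) < 3:
            raise ParseError("nodes row has fewer than 3 fields", lineno)
        try:
            taxid = int(fields[0])
            parent = int(fields[1])
        except ValueError:
            raise ParseError("non-integer taxid or parent taxid", lineno) from None
        raw[taxid] = (parent, fields[2].strip())

    names: dict[int, str] = {}
    if names_source is not None:
        for lineno, line in enumerate(_iter_lines(names_source), start=1):
            if not line.strip():
                continue
            fields = _split_dump_row(line)
            if len(fields) < 4:
                raise ParseError("names row has fewer than 4 fields", lineno)
            if fields[3].strip() == "scientific name":
                try:
                    names[int(fields[0])] = fields[1].strip()
                except ValueError:
                    raise ParseError("non-integer taxid", lineno) from None

    for taxid, (parent, rank) in raw.items():
        nodes[taxid] = TaxonNode(parent, rank, names.get(taxid, ""))
    return TaxonomyTree(nodes, rank_ladder=rank_ladder)


def write_taxonomy(tree: TaxonomyTree, nodes_sink, names_sink=None) -> None:
    """Serialize a tree back to nodes.dmp / names.dmp dialect (sorted rows)."""
    for taxid in sorted(tree):
        nodes_sink.write(f"{taxid}\t|\t{tree.parent(taxid)}\t|\t{tree.rank(taxid)}\t|\n")
    if names_sink is not None:
        for taxid in sorted(tree):
            name = tree.name(taxid)
            if name:
                names_sink.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")


def toy_taxonomy() -> TaxonomyTree:
    """Small packaged taxonomy (2 genera, 3 species, strains) for demos/tests."""
    data = importlib.resources.files("taxvote.data")
    with (data / "toy_nodes.dmp").open(encoding="utf-8") as nodes_fh:
        with (data / "toy_names.dmp").open(encoding="utf-8") as names_fh:
            return load_taxonomy(nodes_fh, names_fh)
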