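"""Rank-annotated taxonomy trees.

Classification and threshold training both operate at five taxonomic ranks
(genus, family, order, class, phylum), most specific first.  A taxonomy is a
rooted tree of nodes carrying a rank label; lineages are resolved by walking
parent links and recording the nearest ancestor-or-self at each of the five
ranks.  Taxon identifiers are opaque strings so that synthetic taxonomies can
use readable ids.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

#: The five ranks at which classification is attempted, most specific first.
RANKS: tuple[str, ...] = ("genus", "family", "order", "class", "phylum")

#: Ranks recognised in input besides the five classification ranks.
STRUCTURAL_RANKS: tuple[str, ...] = ("root", "no_rank", "species", "strain")

_KNOWN_RANKS = frozenset(RANKS) | frozenset(STRUCTURAL_RANKS)

_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}


class TaxonomyError(ValueError):
    """Malformed taxonomy input (cycle, orphan, duplicate, missing root)."""


def rank_index(rank: str) -> int:
    """Position of ``rank`` in the genus→phylum order (genus = 0)."""
    return _RANK_INDEX[rank]


@dataclass(frozen=True)
class TaxonNode:
    taxid: str
    parent: str
    rank: str
    name: str


@dataclass(frozen=True)
class Lineage:
    """Per-rank map of a node's ancestors at the five classification ranks.

    Ranks missing from the ancestor chain are simply absent from ``ranks``.
    """

    taxid: str
    ranks: Mapping[str, str] = field(default_factory=dict)

    def get(self, rank: str) -> str | None:
        return self.ranks.get(rank)

    def __contains__(self, rank: str) -> bool:
        return rank in self.ranks


def same_clade(a: Lineage, b: Lineage, rank: str) -> bool:
    """True iff both lineages resolve ``rank`` and to the same taxon.

    An absent rank on either side yields False (never raises): training must
    tolerate incomplete lineages.
    """
    if rank not in _RANK_INDEX:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    ta = a.get(rank)
    return ta is not None and ta == b.get(rank)


class TaxonomyTree:
    """A validated, rooted, rank-labelled taxonomy."""

    def __init__(self, nodes: Iterable[TaxonNode]):
        self._nodes: dict[str, TaxonNode] = {}
        for node in nodes:
            if node.taxid in self._nodes:
                raise TaxonomyError(f"duplicate taxid {node.taxid!r}")
            self._nodes[node.taxid] = node
        roots = [n.taxid for n in self._nodes.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self.root: str = roots[0]
        self._validate()
        self._lineage_cache: dict[str, Lineage] = {}

    def _validate(self) -> None:
        ok: set[str] = {self.root}
        for taxid in self._nodes:
            chain = []
            cur = taxid
            seen = set()
            while cur not in ok:
                if cur in seen:
                    raise TaxonomyError(f"cycle detected at taxid {cur!r}")
                seen.add(cur)
                chain.append(cur)
                node = self._nodes.get(cur)
                if node is None:
                    raise TaxonomyError(f"orphan node: parent {cur!r} not in table")
                cur = node.parent
                if cur not in self._nodes:
                    raise TaxonomyError(
                        f"orphan node {node.taxid!r}: parent {cur!r} not in table"
                    )
            ok.update(chain)

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, taxid: str) -> bool:
        return taxid in self._nodes

    def node(self, taxid: str) -> TaxonNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise KeyError(f"unknown taxid {taxid!r}") from None

    def name(self, taxid: str) -> str:
        return self.node(taxid).name

    def taxids(self) -> list[str]:
        return sorted(self._nodes)

    def children(self, taxid: str) -> list[str]:
        self.node(taxid)
        return sorted(
            t for t, n in self._nodes.items() if n.parent == taxid and t != taxid
        )

    def ancestors(self, taxid: str) -> list[str]:
        """Chain from ``taxid`` (inclusive) up to the root (inclusive)."""
        chain = [taxid]
        cur = self.node(taxid)
        while cur.parent != cur.taxid:
            cur = self._nodes[cur.parent]
            chain.append(cur.taxid)
        return chain

    def lineage_of(self, taxid: str) -> Lineage:
        """Nearest ancestor-or-self at each of the five ranks."""
        cached = self._lineage_cache.get(taxid)
        if cached is not None:
            return cached
        ranks: dict[str, str] = {}
        for anc in self.ancestors(taxid):
            rank = self._nodes[anc].rank
            if rank in _RANK_INDEX and rank not in ranks:
                ranks[rank] = anc
        lineage = Lineage(taxid=taxid, ranks=ranks)
        self._lineage_cache[taxid] = lineage
        return lineage

    def is_ancestor(self, ancestor: str, taxid: str) -> bool:
        return ancestor in self.ancestors(taxid)


def _normalize_rank(rank: str) -> str:
    rank = rank.strip().replace(" ", "_")
    return rank if rank in _KNOWN_RANKS else "no_rank"


def load_taxonomy(path_or_handle) -> TaxonomyTree:
    """Read a TSV node table with header ``taxid  parent  rank  name``.

    Ranks outside the five classification ranks and the structural set are
    passed through as ``no_rank``.
    """
    if hasattr(path_or_handle, "read"):
        handle = path_or_handle
        close = False
    else:
        handle = open(path_or_handle, "rt")
        close = True
    try:
        nodes = []
        header = None
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                expected = ["taxid", "parent", "rank", "name"]
                if header[:4] != expected:
                    raise TaxonomyError(
                        f"line {lineno}: expected header {expected}, got {header}"
                    )
                continue
            if len(fields) < 4:
                raise TaxonomyError(f"line {lineno}: expected 4 columns, got {len(fields)}")
            taxid, parent, rank, name = (f.strip() for f in fields[:4])
            nodes.append(TaxonNode(taxid, parent, _normalize_rank(rank), name))
        if header is None:
            raise TaxonomyError("empty node table")
        return TaxonomyTree(nodes)
    finally:
        if close:
            handle.close()


def write_taxonomy(tree: TaxonomyTree, path_or_handle) -> None:
    """Write the TSV node table read back by :func:`load_taxonomy`."""
    if hasattr(path_or_handle, "write"):
        handle = path_or_handle
        close = False
    else:
        handle = open(path_or_handle, "wt")
        close = True
    try:
        handle.write("taxid\tparent\trank\tname\n")
        for taxid in tree.taxids():
            n = tree.node(taxid)
            handle.write(f"{n.taxid}\t{n.parent}\t{n.rank}\t{n.name}\n")
    finally:
        if close:
            handle.close()


def load_ncbi_dump(nodes_dmp, names_dmp=None) -> TaxonomyTree:
    """Read the NCBI ``nodes.dmp``/``names.dmp`` dialect.

    Fields are separated by ``\\t|\\t`` and rows end with ``\\t|``.  Only the
    taxid, parent and rank columns of nodes.dmp are used; scientific names are
    taken from names.dmp when provided, otherwise the taxid doubles as name.
    """

    def rows(handle_or_path):
        if hasattr(handle_or_path, "read"):
            text = handle_or_path.read()
        else:
            with open(handle_or_path, "rt") as fh:
                text = fh.read()
        for line in io.StringIO(text):
            line = line.rstrip("\n").rstrip("\t|")
            if line:
                yield [f.strip() for f in line.split("\t|\t")]

    names: dict[str, str] = {}
    if names_dmp is not None:
        for fields in rows(names_dmp):
            # names.dmp: taxid | name | unique name | name class
            if len(fields) >= 4 and fields[3] == "scientific name":
                names[fields[0]] = fields[1]
    nodes = []
    for fields in rows(nodes_dmp):
        if len(fields) < 3:
            raise TaxonomyError(f"nodes.dmp row with {len(fields)} fields")
        taxid, parent, rank = fields[0], fields[1], fields[2]
        nodes.append(
            TaxonNode(taxid, parent, _normalize_rank(rank), names.get(taxid, taxid))
        )
    return TaxonomyTree(nodes)
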