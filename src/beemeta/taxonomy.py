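"""Taxonomic hierarchy with lineage and lowest-common-ancestor queries.

The tree follows the NCBI taxonomy structure: nodes are keyed by numeric
taxid, carry a scientific name and a rank, and point at a parent node (the
root points at itself).  Intermediate ``no_rank`` nodes are allowed and are
transparent to rank-directed queries.  Subspecies collapse to their parent
species for all scoring, since assignments are reported at species
resolution at best.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

#: Canonical ranks from coarsest to most specific.  ``no_rank`` nodes may sit
#: anywhere and are skipped by rank-directed queries.
CANONICAL_RANKS = ("phylum", "class", "order", "family", "genus", "species")

VALID_RANKS = frozenset(CANONICAL_RANKS) | {"subspecies", "no_rank"}

_RANK_DEPTH = {rank: i for i, rank in enumerate(CANONICAL_RANKS)}
_RANK_DEPTH["subspecies"] = len(CANONICAL_RANKS)


class TaxonomyError(ValueError):
    """Raised for malformed trees or unresolvable taxid queries."""


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    name: str
    rank: str
    parent: int  # parent taxid; the root is self-parented


@dataclass(frozen=True)
class Lineage:
    """Ordered (rank, taxid, name) triples from phylum down to the node."""

    entries: tuple[tuple[str, int, str], ...]

    def at_rank(self, rank: str) -> tuple[str, int, str] | None:
        for entry in self.entries:
            if entry[0] == rank:
                return entry
        return None

    def __iter__(self):
        return iter(self.entries)


class TaxonomyTree:
    """Rank-labelled hierarchy supporting ancestor walks and LCA queries."""

    def __init__(self, nodes: dict[int, TaxonNode], root: int):
        self._nodes = nodes
        self.root = root

    # -- construction ------------------------------------------------------

    @classmethod
    def build(cls, rows: Iterable[tuple[int, str, str, int]]) -> "TaxonomyTree":
        """Build a tree from (taxid, name, rank, parent_taxid) rows.

        Parent references may appear in any order; the full set is validated
        after loading.  Rejects duplicate taxids, dangling parents, cycles,
        and anything other than exactly one self-parented root.
        """
        nodes: dict[int, TaxonNode] = {}
        for taxid, name, rank, parent in rows:
            if taxid <= 0:
                raise TaxonomyError(f"taxid must be positive, got {taxid}")
            if rank not in VALID_RANKS:
                raise TaxonomyError(f"unknown rank {rank!r} for taxid {taxid}")
            if taxid in nodes:
                raise TaxonomyError(f"duplicate taxid {taxid}")
            nodes[taxid] = TaxonNode(taxid, name, rank, parent)
        roots = [t for t, n in nodes.items() if n.parent == t]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one self-parented root, found {len(roots)}")
        root = roots[0]
        for node in nodes.values():
            if node.parent not in nodes:
                raise TaxonomyError(f"taxid {node.taxid} has dangling parent {node.parent}")
        tree = cls(nodes, root)
        for taxid in nodes:
            tree._walk_to_root(taxid)  # raises on cycles
        return tree

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTree":
        """Load from a four-column TSV: taxid, name, rank, parent_taxid."""
        rows = []
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            for rec in reader:
                if not rec or rec[0].startswith("#"):
                    continue
                taxid, name, rank, parent = rec[:4]
                rows.append((int(taxid), name, rank, int(parent)))
        return cls.build(rows)

    # -- queries -----------------------------------------------------------

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, taxid: int) -> TaxonNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise TaxonomyError(f"unknown taxid {taxid}") from None

    def _walk_to_root(self, taxid: int) -> list[int]:
        """Taxid path from the node up to (and including) the root."""
        path = []
        seen = set()
        current = taxid
        while True:
            if current in seen:
                raise TaxonomyError(f"cycle detected in parent chain of taxid {taxid}")
            seen.add(current)
            path.append(current)
            node = self.node(current)
            if node.parent == current:
                return path
            current = node.parent

    def ancestors(self, taxid: int) -> list[TaxonNode]:
        """Nodes from the query node up to the root, inclusive."""
        return [self._nodes[t] for t in self._walk_to_root(taxid)]

    def rank_of(self, taxid: int) -> str:
        return self.node(taxid).rank

    def ancestor_at_rank(self, taxid: int, rank: str) -> TaxonNode | None:
        """Unique ancestor-or-self with the requested canonical rank.

        ``no_rank`` intermediates are skipped; returns None when the lineage
        lacks the rank (including ranks more specific than the node's own).
        """
        if rank not in VALID_RANKS or rank == "no_rank":
            raise TaxonomyError(f"cannot query rank {rank!r}")
        for node in self.ancestors(taxid):
            if node.rank == rank:
                return node
        return None

    def lineage(self, taxid: int) -> Lineage:
        """Canonical-rank lineage from phylum down; subspecies collapse to species."""
        entries = []
        for node in self.ancestors(taxid):
            if node.rank in _RANK_DEPTH and node.rank != "subspecies":
                entries.append((node.rank, node.taxid, node.name))
        entries.sort(key=lambda e: _RANK_DEPTH[e[0]])
        return Lineage(tuple(entries))

    def effective_taxid(self, taxid: int) -> int:
        """Collapse subspecies to the parent species; other nodes map to themselves."""
        node = self.node(taxid)
        if node.rank == "subspecies":
            species = self.ancestor_at_rank(taxid, "species")
            if species is not None:
                return species.taxid
        return taxid

    def lca(self, taxids: Iterable[int]) -> TaxonNode:
        """Deepest node ancestral to (or equal to) every input taxid.

        Computed as the intersection of root-ward paths; the singleton LCA is
        the node itself.
        """
        taxids = list(taxids)
        if not taxids:
            raise TaxonomyError("lca of an empty set is undefined")
        common = self._walk_to_root(taxids[0])
        for taxid in taxids[1:]:
            other = set(self._walk_to_root(taxid))
            common = [t for t in common if t in other]
            if not common:  # cannot happen with a single root
                raise TaxonomyError("no common ancestor found")
        return self._nodes[common[0]]

    def rank_depth(self, taxid: int) -> int:
        """Specificity of the node's rank: -1 for no_rank/above-phylum, else
        position in the canonical order (species deepest)."""
        return _RANK_DEPTH.get(self.node(taxid).rank, -1)


def rank_more_specific(a: str, b: str) -> bool:
    """True when rank ``a`` is strictly more specific than ``b``."""
    return _RANK_DEPTH.get(a, -1) > _RANK_DEPTH.get(b, -1)
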