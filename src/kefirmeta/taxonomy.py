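"""Rooted, rank-labelled taxonomy with LCA and ancestry queries.

The tree is the substrate for every classification step downstream: naive
lowest-common-ancestor (LCA) read assignment, min-support push-up, genus
roll-up for consensus profiles, and target-genus membership tests during
metagenome-assembled-genome (MAG) curation.

Taxon identifiers are opaque strings, so both numeric NCBI-style ids and
name-keyed synthetic taxa work unchanged.  ``no_rank`` nodes are transparent
to rank queries: they sit on the root path but never match a requested rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "RANK_ORDER",
    "VALID_RANKS",
    "TaxonNode",
    "TaxonomyTree",
    "TaxonomyError",
    "load_taxonomy",
]

#: Ranks from shallowest to deepest.  ``species_group`` sits between genus and
#: species (it is a below-genus rank in the NCBI taxonomy).
RANK_ORDER = [
    "root",
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species_group",
    "species",
    "subspecies",
]

VALID_RANKS = frozenset(RANK_ORDER) | {"no_rank"}

#: Ranks strictly below genus; assignments at these ranks roll up to genus.
SUBGENUS_RANKS = frozenset({"species_group", "species", "subspecies"})


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy table (orphan, cycle, duplicate...)."""


@dataclass(frozen=True)
class TaxonNode:
    """One taxon: id, display name, rank label, and parent pointer.

    The root node is its own parent.
    """

    taxon_id: str
    name: str
    rank: str
    parent_id: str

    def __post_init__(self) -> None:
        if self.rank not in VALID_RANKS:
            raise TaxonomyError(
                f"taxon {self.taxon_id!r}: unknown rank {self.rank!r}"
            )


class TaxonomyTree:
    """Indexed rooted tree over :class:`TaxonNode` records.

    Construction validates the full structure: unique ids, exactly one root
    (``parent_id == taxon_id``), every parent resolvable, and no cycles.
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self._nodes: dict[str, TaxonNode] = {}
        for node in nodes:
            if node.taxon_id in self._nodes:
                raise TaxonomyError(f"duplicate taxon_id {node.taxon_id!r}")
            self._nodes[node.taxon_id] = node
        if not self._nodes:
            raise TaxonomyError("taxonomy table is empty")

        roots = [n.taxon_id for n in self._nodes.values() if n.parent_id == n.taxon_id]
        if len(roots) != 1:
            raise TaxonomyError(
                f"expected exactly one root (parent_id == taxon_id), found {len(roots)}"
            )
        self.root_id: str = roots[0]

        for node in self._nodes.values():
            if node.parent_id not in self._nodes:
                raise TaxonomyError(
                    f"taxon {node.taxon_id!r} has unknown parent {node.parent_id!r}"
                )

        # Depth computation doubles as the cycle check: any walk longer than
        # the node count means the path never reaches the root.
        self._depth: dict[str, int] = {self.root_id: 0}
        limit = len(self._nodes)
        for tid in self._nodes:
            chain: list[str] = []
            cur = tid
            while cur not in self._depth:
                chain.append(cur)
                cur = self._nodes[cur].parent_id
                if len(chain) > limit:
                    raise TaxonomyError(f"cycle detected at taxon {tid!r}")
            base = self._depth[cur]
            for i, cid in enumerate(reversed(chain), start=1):
                self._depth[cid] = base + i

    # -- basic accessors ---------------------------------------------------

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, taxon_id: str) -> TaxonNode:
        try:
            return self._nodes[taxon_id]
        except KeyError:
            raise TaxonomyError(f"unknown taxon_id {taxon_id!r}") from None

    def rank(self, taxon_id: str) -> str:
        return self.node(taxon_id).rank

    def name(self, taxon_id: str) -> str:
        return self.node(taxon_id).name

    def parent(self, taxon_id: str) -> str:
        return self.node(taxon_id).parent_id

    def depth(self, taxon_id: str) -> int:
        self.node(taxon_id)
        return self._depth[taxon_id]

    def taxon_ids(self) -> list[str]:
        return list(self._nodes)

    def root_path(self, taxon_id: str) -> list[str]:
        """Path from ``taxon_id`` up to (and including) the root."""
        path = [taxon_id]
        cur = self.node(taxon_id)
        while cur.taxon_id != self.root_id:
            cur = self.node(cur.parent_id)
            path.append(cur.taxon_id)
        return path

    # -- queries -----------------------------------------------------------

    def lca(self, taxa: Iterable[str]) -> str:
        """Lowest common ancestor: the deepest node ancestral-or-self to all.

        Commutative and associative under set union:
        ``lca(A | B) == lca({lca(A), lca(B)})``.
        """
        taxa = list(taxa)
        if not taxa:
            raise TaxonomyError("lca of an empty taxon set is undefined")
        # Root-first paths; the LCA is the last element of the common prefix.
        paths = [list(reversed(self.root_path(t))) for t in taxa]
        result = self.root_id
        for level in range(min(len(p) for p in paths)):
            candidate = paths[0][level]
            if all(p[level] == candidate for p in paths):
                result = candidate
            else:
                break
        return result

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> str | None:
        """Nearest ancestor-or-self holding exactly ``rank``; None if absent.

        ``no_rank`` nodes on the path are skipped over, never matched.
        """
        if rank not in VALID_RANKS or rank == "no_rank":
            raise TaxonomyError(f"unknown rank label {rank!r}")
        for tid in self.root_path(taxon_id):
            if self._nodes[tid].rank == rank:
                return tid
        return None

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff ``a`` lies on ``b``'s root path (ancestor-or-self)."""
        self.node(a)
        return a in self.root_path(b)

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "TaxonomyTree":
        required = {"taxon_id", "parent_id", "rank", "name"}
        missing = required - set(table.columns)
        if missing:
            raise TaxonomyError(f"taxonomy table lacks columns: {sorted(missing)}")
        nodes = [
            TaxonNode(
                taxon_id=str(row.taxon_id),
                name=str(row.name_),
                rank=str(row.rank),
                parent_id=str(row.parent_id),
            )
            for row in table.rename(columns={"name": "name_"}).itertuples(index=False)
        ]
        return cls(nodes)

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTree":
        table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        return cls.from_table(table)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "taxon_id": n.taxon_id,
                    "parent_id": n.parent_id,
                    "rank": n.rank,
                    "name": n.name,
                }
                for n in self._nodes.values()
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_taxonomy(source) -> TaxonomyTree:
    """Build a validated tree from a DataFrame, a path to a four-column TSV
    (taxon_id, parent_id, rank, name), or an iterable of mappings."""
    if isinstance(source, pd.DataFrame):
        return TaxonomyTree.from_table(source)
    if isinstance(source, (str,)) or hasattr(source, "__fspath__"):
        return TaxonomyTree.from_tsv(source)
    records = list(source)
    if records and isinstance(records[0], Mapping):
        return TaxonomyTree.from_table(pd.DataFrame(records))
    return TaxonomyTree(records)
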