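"""Consensus taxonomic profiling across multiple per-read classifiers.

Different profilers (Kaiju, Kraken, blastn vs nt, blastn vs RefSeq, blastx
vs nr, ...) each produce a read→taxon map, with characteristic blind spots —
a database lacking one genus makes every read from that genus invisible to
that tool.  The consensus merges them per read with a strict priority rule:
the first tool in the configured order that assigns the read wins.

Consensus taxa are then summarised as a genus-level profile: calls at
subspecies / species / species-group rank roll up to their genus, calls at
ranks above genus pool into "above genus", genera holding less than a
minority threshold of all reads collapse into "minorities", and the rest of
the read universe is "unassigned".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import UNASSIGNED
from .taxonomy import SUBGENUS_RANKS, TaxonomyTree

logger = logging.getLogger(__name__)

__all__ = [
    "ABOVE_GENUS",
    "MINORITIES",
    "UNASSIGNED_CATEGORY",
    "ToolAssignmentSet",
    "ConsensusParams",
    "GenusTable",
    "consensus_assign",
    "consensus_all",
    "build_genus_table",
    "compute_temporal_shift",
    "select_recruitment_genera",
]

ABOVE_GENUS = "above genus"
MINORITIES = "minorities"
UNASSIGNED_CATEGORY = "unassigned"
SPECIAL_CATEGORIES = (ABOVE_GENUS, MINORITIES, UNASSIGNED_CATEGORY)


@dataclass
class ToolAssignmentSet:
    """Per-tool read→taxon maps plus the priority order used to merge them."""

    priority: list[str]
    assignments: dict[str, dict[str, str]]

    def __post_init__(self):
        if not self.priority:
            raise ValueError("priority list is empty")
        if len(set(self.priority)) != len(self.priority):
            raise ValueError("priority list contains duplicate tool names")
        missing = [t for t in self.priority if t not in self.assignments]
        if missing:
            raise ValueError(f"no assignment table for tool(s): {missing}")

    @classmethod
    def from_tables(
        cls,
        priority: Sequence[str],
        tables: Mapping[str, Mapping[str, str]],
    ) -> "ToolAssignmentSet":
        """Normalise tool tables onto the union read universe.

        Classifier outputs often omit unclassified reads; a read missing from
        one tool's table is treated as UNASSIGNED for that tool (counted and
        logged).
        """
        universe: set[str] = set()
        for name in priority:
            universe.update(tables[name])
        normalised: dict[str, dict[str, str]] = {}
        for name in priority:
            table = tables[name]
            missing = len(universe) - len(table)
            if missing:
                logger.info(
                    "tool %s: %d reads absent from its table, treated as unassigned",
                    name,
                    missing,
                )
            normalised[name] = {r: table.get(r, UNASSIGNED) for r in universe}
        return cls(priority=list(priority), assignments=normalised)

    @property
    def reads(self) -> set[str]:
        return set(self.assignments[self.priority[0]])


@dataclass(frozen=True)
class ConsensusParams:
    """minority_threshold: genera under this % of all reads collapse into
    "minorities" (strictly less).  selection_threshold: genera above this %
    in any sample/method cell are selected for recruitment (strictly more)."""

    minority_threshold: float = 0.5
    selection_threshold: float = 0.1

    def __post_init__(self):
        for v in (self.minority_threshold, self.selection_threshold):
            if not (0.0 <= v <= 100.0):
                raise ValueError("thresholds must lie in [0, 100]")


@dataclass
class GenusTable:
    """Per-sample category→percentage profile over *all* reads.

    Categories are genus names plus "above genus", "minorities" and
    "unassigned"; percentages sum to 100 up to rounding.
    """

    sample: str
    counts: dict[str, int]
    total_reads: int
    percentages: dict[str, float] = field(init=False)

    def __post_init__(self):
        self.percentages = {
            c: 100.0 * n / self.total_reads for c, n in self.counts.items()
        }

    def percent(self, category: str) -> float:
        return self.percentages.get(category, 0.0)

    def to_frame(self) -> pd.DataFrame:
        """Long format: sample, category, percent (2 decimals)."""
        return pd.DataFrame(
            {
                "sample": self.sample,
                "category": list(self.percentages),
                "reads": list(self.counts.values()),
                "percent": [round(p, 2) for p in self.percentages.values()],
            }
        )


def consensus_assign(read_id: str, tools: ToolAssignmentSet) -> str:
    """First tool in priority order with a non-UNASSIGNED call wins."""
    for name in tools.priority:
        table = tools.assignments[name]
        if read_id not in table:
            raise KeyError(f"read {read_id!r} missing from tool {name!r}")
        taxon = table[read_id]
        if taxon != UNASSIGNED:
            return taxon
    return UNASSIGNED


def consensus_all(tools: ToolAssignmentSet) -> dict[str, str]:
    return {r: consensus_assign(r, tools) for r in tools.reads}


def _categorize(taxon: str, tree: TaxonomyTree) -> str:
    """Map one consensus taxon to its genus-table category (pre-minorities)."""
    if taxon == UNASSIGNED:
        return UNASSIGNED_CATEGORY
    if taxon == tree.root_id:
        # A root-level call carries no information.
        return UNASSIGNED_CATEGORY
    rank = tree.rank(taxon)
    genus = tree.ancestor_at_rank(taxon, "genus")
    if rank == "genus":
        return tree.name(taxon)
    if rank in SUBGENUS_RANKS or (rank == "no_rank" and genus is not None):
        if genus is None:
            logger.warning(
                "taxon %s has rank %s but no genus ancestor; counted as 'above genus'",
                taxon,
                rank,
            )
            return ABOVE_GENUS
        return tree.name(genus)
    return ABOVE_GENUS


def build_genus_table(
    assignments: Mapping[str, str],
    tree: TaxonomyTree,
    params: ConsensusParams,
    total_reads: int,
    sample: str = "sample",
) -> GenusTable:
    """Roll consensus assignments up to a genus-level category profile.

    Reads of the universe not present in ``assignments`` count as
    unassigned, so every read lands in exactly one category and percentages
    sum to 100.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if total_reads < len(assignments):
        raise ValueError("total_reads smaller than the number of assignments")
    counts: dict[str, int] = {}
    for taxon in assignments.values():
        cat = _categorize(taxon, tree)
        counts[cat] = counts.get(cat, 0) + 1
    counts[UNASSIGNED_CATEGORY] = counts.get(UNASSIGNED_CATEGORY, 0) + (
        total_reads - len(assignments)
    )

    # Collapse minority genera (never the special categories).
    merged: dict[str, int] = {}
    for cat, n in counts.items():
        pct = 100.0 * n / total_reads
        if cat not in SPECIAL_CATEGORIES and pct < params.minority_threshold:
            merged[MINORITIES] = merged.get(MINORITIES, 0) + n
        else:
            merged[cat] = merged.get(cat, 0) + n
    return GenusTable(sample=sample, counts=merged, total_reads=total_reads)


def compute_temporal_shift(
    table_t1: GenusTable, table_t2: GenusTable
) -> dict[str, float]:
    """Per-category percentage-point change, later minus earlier.

    Categories absent from one table count as 0 there; antisymmetric by
    construction.
    """
    categories = set(table_t1.percentages) | set(table_t2.percentages)
    return {c: table_t2.percent(c) - table_t1.percent(c) for c in sorted(categories)}


def select_recruitment_genera(
    tables: Iterable[GenusTable], params: ConsensusParams
) -> list[str]:
    """Genera strictly exceeding the selection threshold in any table.

    Tables span samples × profiling methods; one qualifying cell suffices.
    Special categories never qualify.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one genus table")
    selected: set[str] = set()
    for table in tables:
        for cat, pct in table.percentages.items():
            if cat in SPECIAL_CATEGORIES:
                continue
            if pct > params.selection_threshold:
                selected.add(cat)
    return sorted(selected)
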