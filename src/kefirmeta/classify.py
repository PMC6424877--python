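"""MEGAN-style per-read taxonomic classification.

Pipeline per read: threshold the alignment hits on bitscore and E-value,
keep the near-best hits (top-percent window), assign the read to the naive
lowest common ancestor of the survivors' taxa, then adjust whole-sample
assignments for minimum support.

Two presets mirror the parameter sets used for whole-read and marker-gene
classification respectively:

* ``megan-main``:   MinScore 100, MaxExpected 0.01, TopPercent 10, MinSupport 150
* ``megan-marker``: MinScore 80,  MaxExpected 0.01, TopPercent 100, MinSupport 10

The min-support step pushes reads from weakly supported taxa upward: counts
are accumulated leaf-to-root, and a taxon whose accumulated count is positive
but below the threshold hands its reads to its parent.  A read therefore ends
at the nearest ancestor where accumulated support reaches the threshold, or
becomes unassigned if even the root falls short.  The alternative
``mode="unassign"`` simply discards weakly supported calls.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

__all__ = [
    "UNASSIGNED",
    "AlignmentHit",
    "LcaParams",
    "ReadAssignment",
    "AssignmentSummary",
    "PRESETS",
    "filter_hits",
    "assign_read",
    "assign_reads",
    "apply_min_support",
    "summarize_assignments",
]

#: Sentinel taxon label for reads no classifier could place.
UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise alignment record (read × subject)."""

    read_id: str
    subject_id: str
    subject_taxon: str
    percent_identity: float
    align_length: int
    query_length: int
    bitscore: float
    evalue: float
    subject_start: int = 1
    subject_end: int = 1

    def __post_init__(self):
        if self.align_length < 1:
            raise ValueError(f"hit {self.read_id}/{self.subject_id}: align_length < 1")
        if self.evalue < 0:
            raise ValueError(f"hit {self.read_id}/{self.subject_id}: negative evalue")

    @property
    def query_coverage(self) -> float:
        """Percent of the read covered by the alignment, clamped to 100."""
        return min(100.0, 100.0 * self.align_length / self.query_length)


@dataclass(frozen=True)
class LcaParams:
    """Thresholds of the naive-LCA classifier.

    min_score
        Bitscore floor; weaker hits are discarded.
    max_expected
        E-value ceiling; less significant hits are discarded.
    top_percent
        Retain hits with bitscore within this percentage of the read's best
        surviving bitscore (boundary inclusive).
    min_support
        Minimum number of reads a taxon needs to keep its assignments.
    lca_percent
        Fraction of retained taxa the LCA must cover.  Only the plain naive
        LCA (100) is implemented; other values are rejected.
    """

    min_score: float
    max_expected: float
    top_percent: float
    min_support: int
    lca_percent: float = 100.0

    def __post_init__(self):
        if not (0.0 <= self.top_percent <= 100.0):
            raise ValueError("top_percent must lie in [0, 100]")
        if self.min_support < 0:
            raise ValueError("min_support must be >= 0")
        if self.lca_percent != 100.0:
            raise NotImplementedError(
                "only lca_percent=100 (plain naive LCA) is supported"
            )


PRESETS: dict[str, LcaParams] = {
    "megan-main": LcaParams(min_score=100.0, max_expected=0.01, top_percent=10.0, min_support=150),
    "megan-marker": LcaParams(min_score=80.0, max_expected=0.01, top_percent=100.0, min_support=10),
}


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    taxon: str  # taxon_id or UNASSIGNED
    source: str = "lca"


@dataclass
class AssignmentSummary:
    """Per-taxon read counts and percentages of *all* reads in the sample."""

    counts: dict[str, int]
    total_reads: int
    percentages: dict[str, float] = field(init=False)

    def __post_init__(self):
        self.percentages = {
            t: 100.0 * c / self.total_reads for t, c in self.counts.items()
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon_id": list(self.counts),
                "reads": list(self.counts.values()),
                "percent_of_all_reads": [
                    round(p, 2) for p in self.percentages.values()
                ],
            }
        )


def filter_hits(hits: Sequence[AlignmentHit], params: LcaParams) -> list[AlignmentHit]:
    """Apply the score/E-value floors, then the top-percent window.

    Floors first: hits with ``bitscore < min_score`` or ``evalue >
    max_expected`` are dropped; among the survivors, only hits with bitscore
    ≥ ``(1 - top_percent/100) * best`` are kept (ties at the boundary are
    retained).  Idempotent; empty in → empty out.
    """
    survivors = [
        h
        for h in hits
        if h.bitscore >= params.min_score and h.evalue <= params.max_expected
    ]
    if not survivors:
        return []
    best = max(h.bitscore for h in survivors)
    cutoff = (1.0 - params.top_percent / 100.0) * best
    return [h for h in survivors if h.bitscore >= cutoff]


def assign_read(
    hits: Sequence[AlignmentHit],
    tree: TaxonomyTree,
    params: LcaParams,
    source: str = "lca",
) -> ReadAssignment:
    """Naive LCA over the retained hits' taxa; UNASSIGNED if none survive."""
    read_ids = {h.read_id for h in hits}
    if len(read_ids) > 1:
        raise ValueError(f"hits span multiple reads: {sorted(read_ids)}")
    retained = filter_hits(hits, params)
    if not retained:
        read_id = next(iter(read_ids)) if read_ids else ""
        return ReadAssignment(read_id=read_id, taxon=UNASSIGNED, source=source)
    taxa = {h.subject_taxon for h in retained}
    return ReadAssignment(
        read_id=retained[0].read_id, taxon=tree.lca(taxa), source=source
    )


def assign_reads(
    hit_table: pd.DataFrame,
    tree: TaxonomyTree,
    params: LcaParams,
    subject_taxa: Mapping[str, str] | None = None,
    source: str = "lca",
) -> dict[str, str]:
    """Classify every read in a canonical hit table; returns read→taxon.

    ``subject_taxa`` maps subject ids to taxon ids; when omitted the table
    must already carry a ``subject_taxon`` column.
    """
    df = hit_table.copy()
    if "subject_taxon" not in df.columns:
        if subject_taxa is None:
            raise ValueError("need subject_taxa map or a subject_taxon column")
        df["subject_taxon"] = df["subject_id"].map(subject_taxa)
        if df["subject_taxon"].isna().any():
            bad = df.loc[df["subject_taxon"].isna(), "subject_id"].iloc[0]
            raise ValueError(f"subject {bad!r} has no taxon mapping")
    out: dict[str, str] = {}
    for read_id, grp in df.groupby("read_id", sort=False):
        hits = [
            AlignmentHit(
                read_id=str(read_id),
                subject_id=str(r.subject_id),
                subject_taxon=str(r.subject_taxon),
                percent_identity=float(r.percent_identity),
                align_length=int(r.align_length),
                query_length=int(r.query_length),
                bitscore=float(r.bitscore),
                evalue=float(r.evalue),
                subject_start=int(r.subject_start),
                subject_end=int(r.subject_end),
            )
            for r in grp.itertuples(index=False)
        ]
        out[str(read_id)] = assign_read(hits, tree, params, source=source).taxon
    return out


def apply_min_support(
    assignments: Mapping[str, str],
    tree: TaxonomyTree,
    min_support: int,
    mode: str = "push_up",
) -> dict[str, str]:
    """Relocate reads at weakly supported taxa; conserves every read.

    ``push_up`` (default): a taxon's support is its cumulative clade count —
    its own directly assigned reads plus those of all descendants.  Reads at
    a taxon whose clade count falls below ``min_support`` move to the nearest
    ancestor whose clade count reaches it (so a weak genus surfaces at, say,
    its family when sibling genera carry the clade); when even the root falls
    short the reads become UNASSIGNED.  Post-condition: every taxon retaining
    reads has clade count ≥ ``min_support``.

    ``unassign``: reads at taxa with direct count below the threshold are
    simply unassigned.
    """
    if mode not in ("push_up", "unassign"):
        raise ValueError(f"unknown min-support mode {mode!r}")
    if min_support <= 0:
        return dict(assignments)

    direct = Counter(t for t in assignments.values() if t != UNASSIGNED)
    for t in direct:
        tree.node(t)  # validate early

    if mode == "unassign":
        weak = {t for t, c in direct.items() if c < min_support}
        return {
            r: (UNASSIGNED if t in weak else t) for r, t in assignments.items()
        }

    # Cumulative clade counts: every taxon's direct reads contribute to all
    # of its ancestors.
    clade: dict[str, int] = {}
    for taxon, c in direct.items():
        for anc in tree.root_path(taxon):
            clade[anc] = clade.get(anc, 0) + c

    relocation: dict[str, str] = {}
    for taxon in direct:
        target = UNASSIGNED
        for anc in tree.root_path(taxon):
            if clade.get(anc, 0) >= min_support:
                target = anc
                break
        relocation[taxon] = target

    return {
        r: (t if t == UNASSIGNED else relocation[t]) for r, t in assignments.items()
    }


def summarize_assignments(
    assignments: Mapping[str, str] | Iterable[ReadAssignment],
    total_reads: int,
) -> AssignmentSummary:
    """Count reads per taxon; percentages use *all* reads as denominator.

    Reads absent from ``assignments`` (and explicit UNASSIGNED ones) are
    pooled under UNASSIGNED, so unclassified reads dilute percentages rather
    than disappearing.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not isinstance(assignments, Mapping):
        assignments = {a.read_id: a.taxon for a in assignments}
    if total_reads < len(assignments):
        raise ValueError("total_reads smaller than the number of assignments")
    counts: Counter[str] = Counter(assignments.values())
    counts[UNASSIGNED] = counts.get(UNASSIGNED, 0) + (total_reads - len(assignments))
    return AssignmentSummary(counts=dict(counts), total_reads=total_reads)
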