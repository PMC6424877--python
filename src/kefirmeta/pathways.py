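"""Four-level biosynthetic-potential scoring from per-gene evidence.

Each (organism, pathway) pair is summarised from the evidence status of its
constituent genes into one of four calls, rendered green/yellow/gray/black
in the classic biosynthetic-potential grid:

* ``VERY_LIKELY``   (green)  — every gene of the pathway found complete;
* ``LIKELY``        (yellow) — at least one gene found but not fully assembled;
* ``UNLIKELY``      (gray)   — at least one gene not found at all;
* ``VERY_UNLIKELY`` (black)  — conclusive loss-of-function evidence
  (e.g. a nonsense mutation) in at least one gene.

The four conditions can co-occur; precedence runs loss-of-function > absent
> partial > complete, reflecting evidential strength: one pseudogene settles
the question regardless of how the other genes look.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneStatus",
    "PathwayCall",
    "PathwayDefinition",
    "score_pathway",
    "score_matrix",
    "plot_matrix",
]


class GeneStatus(str, Enum):
    """Evidence status of one gene in one organism."""

    FOUND_COMPLETE = "FOUND_COMPLETE"
    FOUND_PARTIAL = "FOUND_PARTIAL"  # present but not fully assembled
    NOT_FOUND = "NOT_FOUND"  # no evidence of the gene
    LOSS_OF_FUNCTION = "LOSS_OF_FUNCTION"  # e.g. nonsense mutation


class PathwayCall(IntEnum):
    """Totally ordered verdict; higher value = biosynthesis more plausible."""

    VERY_UNLIKELY = 0  # black
    UNLIKELY = 1  # gray
    LIKELY = 2  # yellow
    VERY_LIKELY = 3  # green


#: Plot colours matching the published grid convention.
CALL_COLORS = {
    PathwayCall.VERY_LIKELY: "#2ca02c",
    PathwayCall.LIKELY: "#ffdf00",
    PathwayCall.UNLIKELY: "#9e9e9e",
    PathwayCall.VERY_UNLIKELY: "#000000",
}


@dataclass(frozen=True)
class PathwayDefinition:
    """A pathway as an ordered list of required gene identifiers."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} defines no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"pathway {self.name!r} lists a gene twice")

    @staticmethod
    def from_tsv(path) -> dict[str, "PathwayDefinition"]:
        """Read a (pathway, gene) TSV into definitions, preserving order."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        out: dict[str, PathwayDefinition] = {}
        for name, grp in df.groupby("pathway", sort=False):
            out[str(name)] = PathwayDefinition(
                name=str(name), genes=tuple(grp["gene"])
            )
        return out


def score_pathway(statuses: Iterable[GeneStatus | str]) -> PathwayCall:
    """Precedence rule: loss-of-function > not-found > partial > complete."""
    statuses = [GeneStatus(s) for s in statuses]
    if not statuses:
        raise ValueError("cannot score a pathway with no gene statuses")
    present = set(statuses)
    if GeneStatus.LOSS_OF_FUNCTION in present:
        return PathwayCall.VERY_UNLIKELY
    if GeneStatus.NOT_FOUND in present:
        return PathwayCall.UNLIKELY
    if GeneStatus.FOUND_PARTIAL in present:
        return PathwayCall.LIKELY
    return PathwayCall.VERY_LIKELY


def score_matrix(
    status_table: pd.DataFrame,
    definitions: Mapping[str, PathwayDefinition],
    taxa: Sequence[str],
) -> pd.DataFrame:
    """Taxon × pathway grid of calls from a long-format status table.

    ``status_table`` columns: taxon, pathway, gene, status.  A gene defined
    for a pathway but missing from the table defaults to NOT_FOUND (absence
    of evidence), with a logged warning.  A pathway appearing in the table
    without a definition is an error.
    """
    undefined = set(status_table["pathway"].unique()) - set(definitions)
    if undefined:
        raise KeyError(f"pathway {sorted(undefined)[0]!r} has no definition")
    lookup = {
        (str(r.taxon), str(r.pathway), str(r.gene)): GeneStatus(str(r.status))
        for r in status_table.itertuples(index=False)
    }
    calls = pd.DataFrame(
        index=list(taxa), columns=list(definitions), dtype=object
    )
    n_defaulted = 0
    for taxon in taxa:
        for pname, pdef in definitions.items():
            statuses = []
            for gene in pdef.genes:
                status = lookup.get((taxon, pname, gene))
                if status is None:
                    n_defaulted += 1
                    status = GeneStatus.NOT_FOUND
                statuses.append(status)
            calls.loc[taxon, pname] = score_pathway(statuses)
    if n_defaulted:
        logger.warning(
            "%d (taxon, pathway, gene) entries missing from status table; "
            "defaulted to NOT_FOUND",
            n_defaulted,
        )
    return calls


def plot_matrix(calls: pd.DataFrame, path):
    """Render the coloured taxon × pathway grid to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    fig, ax = plt.subplots(
        figsize=(max(4, 0.6 * len(calls.columns)), max(2, 0.5 * len(calls.index)))
    )
    for i, taxon in enumerate(calls.index):
        for j, pathway in enumerate(calls.columns):
            ax.add_patch(
                Rectangle(
                    (j, len(calls.index) - 1 - i),
                    1,
                    1,
                    facecolor=CALL_COLORS[PathwayCall(calls.loc[taxon, pathway])],
                    edgecolor="white",
                )
            )
    ax.set_xlim(0, len(calls.columns))
    ax.set_ylim(0, len(calls.index))
    ax.set_xticks([j + 0.5 for j in range(len(calls.columns))])
    ax.set_xticklabels(calls.columns, rotation=90, fontsize=7)
    ax.set_yticks([len(calls.index) - 1 - i + 0.5 for i in range(len(calls.index))])
    ax.set_yticklabels(calls.index, fontsize=7)
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
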