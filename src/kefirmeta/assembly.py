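"""Contig filtering, assembly contiguity statistics, and MAG bin curation.

Assembly and binning themselves happen upstream (MEGAHIT, CONCOCT, read
mapping, rRNA annotation are all external); this module implements the
decision layer applied to their outputs: the >1000 bp contig length filter,
total/longest/mean/median/N50/L50 statistics, removal of contaminant contigs
from a target-genus bin, and the rescue of rRNA-carrying contigs into the
final metagenome-assembled genome (MAG).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .taxonomy import TaxonomyTree

__all__ = [
    "Contig",
    "ContigSet",
    "AssemblyStats",
    "BinAssignment",
    "filter_contigs",
    "compute_stats",
    "mean_contig_size",
    "purify_bin",
    "add_rrna_contigs",
]


@dataclass(frozen=True)
class Contig:
    """One contig: length plus optional external attributions.

    ``mapped_species`` is the species a read-mapper attributed the contig to;
    ``target_similarity`` flags detectable similarity to the target genus in
    a nucleotide database; ``rrna_genus`` is the genus an rRNA gene on the
    contig was annotated to.  All three are external inputs, never computed
    here.
    """

    contig_id: str
    length: int
    mapped_species: Optional[str] = None
    target_similarity: bool = False
    rrna_genus: Optional[str] = None

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"contig {self.contig_id}: length must be >= 1")


class ContigSet:
    """Unique-id collection of contigs with tabular round-tripping."""

    def __init__(self, contigs: Iterable[Contig]):
        self._by_id: dict[str, Contig] = {}
        for c in contigs:
            if c.contig_id in self._by_id:
                raise ValueError(f"duplicate contig_id {c.contig_id!r}")
            self._by_id[c.contig_id] = c

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._by_id

    def get(self, contig_id: str) -> Contig:
        return self._by_id[contig_id]

    def lengths(self) -> np.ndarray:
        return np.array([c.length for c in self], dtype=np.int64)

    def ids(self) -> list[str]:
        return list(self._by_id)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ContigSet":
        def _opt(row, col):
            if col not in df.columns:
                return None
            v = row[col]
            return None if pd.isna(v) else str(v)

        contigs = []
        for _, row in df.iterrows():
            contigs.append(
                Contig(
                    contig_id=str(row["contig_id"]),
                    length=int(row["length"]),
                    mapped_species=_opt(row, "mapped_species"),
                    target_similarity=bool(int(row["target_similarity"]))
                    if "target_similarity" in df.columns and not pd.isna(row.get("target_similarity"))
                    else False,
                    rrna_genus=_opt(row, "rrna_genus"),
                )
            )
        return cls(contigs)

    @classmethod
    def from_tsv(cls, path) -> "ContigSet":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"))

    @classmethod
    def from_fasta(cls, path) -> "ContigSet":
        from Bio import SeqIO

        return cls(
            Contig(contig_id=rec.id, length=len(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig_id": [c.contig_id for c in self],
                "length": [c.length for c in self],
                "mapped_species": [c.mapped_species for c in self],
                "target_similarity": [int(c.target_similarity) for c in self],
                "rrna_genus": [c.rrna_genus for c in self],
            }
        )


@dataclass
class AssemblyStats:
    """Contiguity summary of one contig set.

    N50 is the length of the contig at which the descending cumulative
    length first reaches half the total assembly size; L50 is that contig's
    1-based index in the descending order.
    """

    total_size: int
    n_contigs: int
    longest: int
    mean: float
    median: float
    n50: int
    l50: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "total_size_bp": self.total_size,
            "n_contigs": self.n_contigs,
            "longest_bp": self.longest,
            "mean_bp": self.mean,
            "median_bp": self.median,
            "n50_bp": self.n50,
            "l50": self.l50,
        }
        d.update(self.extras)
        return d

    def to_table_row(self, sample: str = "") -> dict:
        """Publication-style row: Mbp/kbp formatting at 1 decimal, computed
        from the raw values (nothing is stored rounded)."""
        return {
            "sample": sample,
            "total_size_mbp": round(self.total_size / 1e6, 2),
            "n_contigs": self.n_contigs,
            "longest_kbp": round(self.longest / 1e3, 1),
            "mean_kbp": round(self.mean / 1e3, 1),
            "median_kbp": round(self.median / 1e3, 1),
            "n50_kbp": round(self.n50 / 1e3, 1),
            "l50": self.l50,
        }


def filter_contigs(contigs: ContigSet, min_len: int = 1000) -> ContigSet:
    """Retain contigs strictly longer than ``min_len`` (default 1000 bp)."""
    return ContigSet(c for c in contigs if c.length > min_len)


def compute_stats(contigs: ContigSet | Sequence[int], **extras) -> AssemblyStats:
    """Contiguity statistics from contig lengths.

    Accepts a :class:`ContigSet` or a bare length sequence.  The median of an
    even count is the mean of the two central values.  Raises on empty input.
    """
    if isinstance(contigs, ContigSet):
        lengths = contigs.lengths()
    else:
        lengths = np.asarray(list(contigs), dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("cannot compute assembly statistics of an empty contig set")
    desc = np.sort(lengths)[::-1]
    total = int(desc.sum())
    cumulative = np.cumsum(desc)
    half = total / 2.0
    idx = int(np.searchsorted(cumulative, half, side="left"))
    return AssemblyStats(
        total_size=total,
        n_contigs=int(lengths.size),
        longest=int(desc[0]),
        mean=total / lengths.size,
        median=float(np.median(lengths)),
        n50=int(desc[idx]),
        l50=idx + 1,
        extras=dict(extras),
    )


def mean_contig_size(total_size: float, n_contigs: int) -> float:
    """Mean contig length = total assembly size / contig count.

    Exposed separately so published (total, count) pairs can be routed
    through the same formula :func:`compute_stats` uses internally.
    """
    if n_contigs <= 0:
        raise ValueError("n_contigs must be positive")
    return total_size / n_contigs


@dataclass
class BinAssignment:
    """One composition/coverage bin targeted at a genus."""

    bin_id: str
    members: list[str]
    target_genus: str

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"bin {self.bin_id}: duplicate member contigs")


def _in_target_genus(species: str, target_genus: str, tree: TaxonomyTree | None) -> bool:
    if species == target_genus:
        return True
    if tree is not None and species in tree and target_genus in tree:
        return tree.is_ancestor(target_genus, species)
    return False


def purify_bin(
    bin_: BinAssignment,
    contigs: ContigSet,
    tree: TaxonomyTree | None = None,
) -> list[str]:
    """Discard contaminant contigs from a target-genus bin.

    A member contig mapped to a species outside the target genus is removed,
    *unless* it exhibits similarity to the target genus (``target_similarity``
    flag).  Contigs mapped within the target genus, and unmapped contigs, are
    kept.  Genus membership of a mapped species is resolved through ``tree``
    when given, otherwise by identity with the target genus id.  Never adds
    contigs; preserves member order.
    """
    missing = [m for m in bin_.members if m not in contigs]
    if missing:
        raise KeyError(f"bin member {missing[0]!r} absent from contig set")
    kept = []
    for cid in bin_.members:
        c = contigs.get(cid)
        if c.mapped_species is None:
            kept.append(cid)
        elif _in_target_genus(c.mapped_species, bin_.target_genus, tree):
            kept.append(cid)
        elif c.target_similarity:
            kept.append(cid)
    return kept


def add_rrna_contigs(
    curated: Sequence[str],
    contigs: ContigSet,
    target_genus: str,
) -> list[str]:
    """Append contigs carrying target-genus rRNA annotations to the MAG.

    Searches the whole contig set (rRNA contigs usually fail to bin with
    their genome), skips contigs already present, never removes anything,
    and is idempotent.
    """
    result = list(curated)
    present = set(result)
    for c in contigs:
        if c.rrna_genus == target_genus and c.contig_id not in present:
            result.append(c.contig_id)
            present.add(c.contig_id)
    return result
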