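"""Synthetic communities with planted ground truth.

Every downstream stage (LCA classification, consensus profiling, fragment
recruitment, bin curation, pathway scoring) is exercised against communities
generated here, so the generators plant the features the real study data
exhibit:

* short single-end reads, 20–260 bp with median near 205 bp;
* per-species read-identity models — near 100% for species whose reference
  genome is in the database, a 70–85% band for a planted "novel relative"
  of the references (the signature of an unsequenced species);
* classifier blind spots (a tool whose database lacks a genus assigns
  nothing to reads from that genus, as happens for under-sequenced yeasts);
* decoy alignment hits to same-genus genomes at reduced identity, so
  top-percent filtering and top-hit recruitment are exercised both ways;
* contaminated bins with a similarity-flag exception and off-bin rRNA
  contigs;
* random gene-status tables with their expected pathway calls.

All generators are pure functions of (parameters, seed): the same seed
reproduces byte-identical outputs.  Bitscores and E-values are monotone
surrogates (bitscore = alignment length × (2·identity/100 − 1); E-value
strictly decreasing in bitscore), calibrated for ordering and thresholding
only, not for BLAST-statistics realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assembly import BinAssignment, Contig, ContigSet
from .classify import UNASSIGNED
from .pathways import GeneStatus, score_pathway
from .recruitment import ReferenceDB, ReferenceGenome
from .taxonomy import TaxonNode, TaxonomyTree

__all__ = [
    "CommunityMember",
    "CommunityProfile",
    "SyntheticRead",
    "ToolProfile",
    "BinFixture",
    "generate_reads",
    "generate_alignment_hits",
    "generate_tool_assignments",
    "generate_contig_set",
    "generate_bin_fixture",
    "generate_gene_status_table",
    "default_community",
    "default_taxonomy",
]

# Read-length model: only the published medians (184–225 bp, pooled 205) and
# the 20–260 bp range are known, so lengths are drawn from a normal(205, 30)
# truncated to [20, 260].
READ_LENGTH_MEAN = 205.0
READ_LENGTH_SD = 30.0
READ_LENGTH_MIN, READ_LENGTH_MAX = 20, 260

#: Identity band (percentage points below the true hit) for decoy hits to
#: same-genus genomes; wide enough that a 10% top-percent window sometimes
#: keeps and sometimes drops them.
DECOY_DROP_RANGE = (5.0, 20.0)

#: Reads with planted identity below this are assigned at genus rather than
#: species rank by the simulated classifiers (divergent reads resolve less
#: deeply).
SPECIES_CALL_MIN_IDENTITY = 90.0


@dataclass(frozen=True)
class CommunityMember:
    genome_id: str
    species_taxon: str
    abundance: float
    identity_mean: float
    identity_sd: float
    genome_length: int

    def __post_init__(self):
        if not (50.0 < self.identity_mean <= 100.0):
            raise ValueError(f"{self.genome_id}: identity mean must lie in (50, 100]")
        if self.identity_sd < 0:
            raise ValueError(f"{self.genome_id}: negative identity sd")
        if self.genome_length < 10_000:
            raise ValueError(f"{self.genome_id}: genome_length must be >= 10 kbp")
        if not (0.0 <= self.abundance <= 1.0):
            raise ValueError(f"{self.genome_id}: abundance outside [0, 1]")


@dataclass(frozen=True)
class CommunityProfile:
    """Reference community: members with abundances and identity models."""

    members: tuple[CommunityMember, ...]
    seed: int = 0

    def __post_init__(self):
        if not self.members:
            raise ValueError("community has no members")
        total = sum(m.abundance for m in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, expected 1")
        ids = [m.genome_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome_id in community")

    def member(self, genome_id: str) -> CommunityMember:
        for m in self.members:
            if m.genome_id == genome_id:
                return m
        raise KeyError(genome_id)


@dataclass(frozen=True)
class SyntheticRead:
    read_id: str
    genome_id: str
    start: int  # 1-based
    length: int
    true_identity: float

    def __post_init__(self):
        if not (READ_LENGTH_MIN <= self.length <= READ_LENGTH_MAX):
            raise ValueError(f"{self.read_id}: length outside [20, 260]")


@dataclass(frozen=True)
class ToolProfile:
    """Behavioural sketch of one external classifier.

    ``blind_spot`` taxa (any rank) make reads from their clades unassignable
    by this tool, emulating database gaps.  ``misassignment_rate`` reads are
    sent to ``substitute_taxon`` instead of the truth.
    """

    name: str
    assignment_probability: float = 0.8
    blind_spot: frozenset[str] = frozenset()
    misassignment_rate: float = 0.0
    substitute_taxon: Optional[str] = None

    def __post_init__(self):
        for v in (self.assignment_probability, self.misassignment_rate):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"tool {self.name}: probability outside [0, 1]")
        if self.misassignment_rate > 0 and self.substitute_taxon is None:
            raise ValueError(f"tool {self.name}: misassignment without substitute")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_reads(
    profile: CommunityProfile, n: int, seed: int
) -> tuple[list[SyntheticRead], pd.DataFrame]:
    """Draw ``n`` reads; per-genome counts are multinomial in abundances.

    Returns the reads and a truth table (read_id, genome_id, species_taxon,
    true_identity, length, start).  Identities are drawn per member from a
    normal truncated to (50, 100]; an identity_sd of 0 plants the mean
    exactly (useful for boundary cases like a pure 100%-identity species).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    abundances = np.array([m.abundance for m in profile.members])
    counts = rng.multinomial(n, abundances)
    reads: list[SyntheticRead] = []
    rows = []
    idx = 0
    for member, count in zip(profile.members, counts):
        if count == 0:
            continue
        lengths = np.clip(
            np.rint(
                _truncated_normal(
                    rng,
                    READ_LENGTH_MEAN,
                    READ_LENGTH_SD,
                    READ_LENGTH_MIN,
                    READ_LENGTH_MAX,
                    count,
                )
            ).astype(int),
            READ_LENGTH_MIN,
            READ_LENGTH_MAX,
        )
        identities = _truncated_normal(
            rng, member.identity_mean, member.identity_sd, 50.0, 100.0, count
        )
        # (50, 100]: the open lower bound is enforced by nudging exact 50s.
        identities = np.maximum(identities, np.nextafter(50.0, 100.0))
        starts = rng.integers(1, member.genome_length - lengths + 2)
        for L, ident, start in zip(lengths, identities, starts):
            rid = f"r{idx:07d}"
            idx += 1
            reads.append(
                SyntheticRead(
                    read_id=rid,
                    genome_id=member.genome_id,
                    start=int(start),
                    length=int(L),
                    true_identity=float(ident),
                )
            )
            rows.append(
                {
                    "read_id": rid,
                    "genome_id": member.genome_id,
                    "species_taxon": member.species_taxon,
                    "true_identity": float(ident),
                    "length": int(L),
                    "start": int(start),
                }
            )
    truth = pd.DataFrame(rows)
    return reads, truth


def _bitscore(align_length: np.ndarray, identity: np.ndarray) -> np.ndarray:
    return align_length * (2.0 * identity / 100.0 - 1.0)


def _evalue(bitscore: np.ndarray) -> np.ndarray:
    # Strictly decreasing in bitscore; a surrogate, not a BLAST statistic.
    return np.power(10.0, -np.asarray(bitscore, dtype=float) / 10.0)


def generate_alignment_hits(
    reads: Sequence[SyntheticRead],
    db: ReferenceDB,
    seed: int,
    max_decoys: int = 3,
) -> pd.DataFrame:
    """Build a hit table: one true top hit per read plus same-genus decoys.

    The true hit aligns the read full-length at its planted identity on its
    source genome.  0–``max_decoys`` decoy hits go to other genomes of the
    same genus (decoy references are allowed in ``db`` without being
    community members) at identity reduced by Uniform(5, 20) points; decoys
    falling to ≤50% identity are dropped.  Bitscores are strictly ordered
    within a read whenever identities differ, so the true hit is always the
    best.
    """
    for r in reads:
        if r.genome_id not in db:
            raise KeyError(f"read source genome {r.genome_id!r} not in references")
    rng = np.random.default_rng(seed)
    rows = []
    genus_members = {
        genus: [g.genome_id for g in db.genomes_of_genus(genus)]
        for genus in db.genera()
    }
    for read in reads:
        L = read.length
        bs = float(_bitscore(np.array([L]), np.array([read.true_identity]))[0])
        rows.append(
            {
                "read_id": read.read_id,
                "subject_id": read.genome_id,
                "percent_identity": read.true_identity,
                "align_length": L,
                "query_length": L,
                "bitscore": bs,
                "evalue": float(_evalue(bs)),
                "subject_start": read.start,
                "subject_end": read.start + L - 1,
            }
        )
        genus = db.genus_of(read.genome_id)
        siblings = [g for g in genus_members[genus] if g != read.genome_id]
        if not siblings:
            continue
        n_decoys = int(rng.integers(0, max_decoys + 1))
        for _ in range(n_decoys):
            target = siblings[int(rng.integers(0, len(siblings)))]
            drop = float(rng.uniform(*DECOY_DROP_RANGE))
            ident = read.true_identity - drop
            if ident <= 50.0:
                continue
            tlen = db.genome(target).length
            start = int(rng.integers(1, max(2, tlen - L + 2)))
            dbs = float(_bitscore(np.array([L]), np.array([ident]))[0])
            rows.append(
                {
                    "read_id": read.read_id,
                    "subject_id": target,
                    "percent_identity": ident,
                    "align_length": L,
                    "query_length": L,
                    "bitscore": dbs,
                    "evalue": float(_evalue(dbs)),
                    "subject_start": start,
                    "subject_end": min(start + L - 1, tlen),
                }
            )
    return pd.DataFrame(rows)


def generate_tool_assignments(
    truth: pd.DataFrame,
    tool_profiles: Sequence[ToolProfile],
    tree: TaxonomyTree,
    seed: int,
) -> dict[str, dict[str, str]]:
    """Simulate per-tool read→taxon tables from the truth table.

    Per tool and read: reads whose true species falls under a blind-spot
    taxon are UNASSIGNED; otherwise the read is assigned with the tool's
    assignment probability — to its true species when the planted identity
    is high, to the species' genus when it is low (a divergent read resolves
    less deeply) — and misassigned to the substitute taxon at the tool's
    misassignment rate.
    """
    out: dict[str, dict[str, str]] = {}
    for t, tool in enumerate(tool_profiles):
        rng = np.random.default_rng(np.random.SeedSequence((seed, t)))
        table: dict[str, str] = {}
        for row in truth.itertuples(index=False):
            species = str(row.species_taxon)
            blocked = any(
                b in tree and tree.is_ancestor(b, species) for b in tool.blind_spot
            )
            u = float(rng.random())
            v = float(rng.random())
            if blocked or u >= tool.assignment_probability:
                table[str(row.read_id)] = UNASSIGNED
                continue
            if tool.misassignment_rate > 0 and v < tool.misassignment_rate:
                table[str(row.read_id)] = tool.substitute_taxon  # type: ignore[assignment]
                continue
            if row.true_identity < SPECIES_CALL_MIN_IDENTITY:
                genus = tree.ancestor_at_rank(species, "genus")
                table[str(row.read_id)] = genus if genus is not None else species
            else:
                table[str(row.read_id)] = species
        out[tool.name] = table
    return out


def generate_contig_set(
    seed: int,
    n: int,
    mean_log: float = 8.0,
    sigma_log: float = 1.0,
    min_len: int = 1,
) -> tuple[ContigSet, "pd.Series"]:
    """Lognormal contig lengths plus independently computed true statistics.

    The returned Series holds the true total size, N50 and L50 obtained by a
    plain descending cumulative scan, so downstream statistics code can be
    cross-checked against the generator's own bookkeeping.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = np.maximum(
        np.rint(rng.lognormal(mean_log, sigma_log, size=n)).astype(int), min_len
    )
    contigs = ContigSet(
        Contig(contig_id=f"c{i:05d}", length=int(L)) for i, L in enumerate(lengths)
    )
    # Independent sort-and-scan bookkeeping of the planted truth.
    desc = sorted(lengths.tolist(), reverse=True)
    total = sum(desc)
    acc = 0
    n50 = desc[0]
    l50 = 1
    for i, L in enumerate(desc, start=1):
        acc += L
        if acc >= total / 2.0:
            n50, l50 = L, i
            break
    truth = pd.Series(
        {"total_size": total, "n_contigs": n, "longest": desc[0], "n50": n50, "l50": l50}
    )
    return contigs, truth


@dataclass
class BinFixture:
    """A planted target-genus bin with contamination and off-bin rRNA contigs."""

    bin: BinAssignment
    contigs: ContigSet
    tree: TaxonomyTree
    expected_after_purify: list[str]
    expected_final: list[str]


def _fixture_taxonomy() -> TaxonomyTree:
    nodes = [
        TaxonNode("root", "root", "root", "root"),
        TaxonNode("bac", "Bacteria", "domain", "root"),
        TaxonNode("g_target", "Targetgenus", "genus", "bac"),
        TaxonNode("s_target1", "Targetgenus alpha", "species", "g_target"),
        TaxonNode("s_target2", "Targetgenus beta", "species", "g_target"),
        TaxonNode("g_other", "Othergenus", "genus", "bac"),
        TaxonNode("s_other1", "Othergenus one", "species", "g_other"),
        TaxonNode("s_other2", "Othergenus two", "species", "g_other"),
    ]
    return TaxonomyTree(nodes)


def generate_bin_fixture(
    seed: int,
    n_target: int | None = None,
    n_unmapped: int | None = None,
    n_contaminant: int | None = None,
    n_flagged: int | None = None,
    n_rrna_offbin: int = 2,
) -> BinFixture:
    """Plant a bin whose correct curation outcome is known.

    Members: target-genus contigs and unmapped contigs (kept), contaminants
    mapped to another genus (removed), contaminants with the target-genus
    similarity flag (kept despite the off-target mapping).  Off-bin contigs
    annotated with target-genus rRNA genes must be appended afterwards.
    """
    rng = np.random.default_rng(seed)
    tree = _fixture_taxonomy()
    if n_target is None:
        n_target = int(rng.integers(8, 16))
    if n_unmapped is None:
        n_unmapped = int(rng.integers(2, 6))
    if n_contaminant is None:
        n_contaminant = int(rng.integers(0, 6))
    if n_flagged is None:
        n_flagged = int(rng.integers(0, 4))

    contigs: list[Contig] = []
    members: list[str] = []
    keep: list[str] = []
    i = 0

    def _len() -> int:
        return int(rng.integers(1001, 200_000))

    target_species = ["s_target1", "s_target2"]
    other_species = ["s_other1", "s_other2"]
    for _ in range(n_target):
        cid = f"bin_c{i:03d}"
        i += 1
        contigs.append(
            Contig(cid, _len(), mapped_species=str(rng.choice(target_species)))
        )
        members.append(cid)
        keep.append(cid)
    for _ in range(n_unmapped):
        cid = f"bin_c{i:03d}"
        i += 1
        contigs.append(Contig(cid, _len()))
        members.append(cid)
        keep.append(cid)
    for _ in range(n_contaminant):
        cid = f"bin_c{i:03d}"
        i += 1
        contigs.append(
            Contig(cid, _len(), mapped_species=str(rng.choice(other_species)))
        )
        members.append(cid)  # removed by purification
    for _ in range(n_flagged):
        cid = f"bin_c{i:03d}"
        i += 1
        contigs.append(
            Contig(
                cid,
                _len(),
                mapped_species=str(rng.choice(other_species)),
                target_similarity=True,
            )
        )
        members.append(cid)
        keep.append(cid)

    rrna_ids = []
    for _ in range(n_rrna_offbin):
        cid = f"off_c{i:03d}"
        i += 1
        contigs.append(Contig(cid, _len(), rrna_genus="g_target"))
        rrna_ids.append(cid)

    # Interleave member order so curation order-independence is exercised.
    order = rng.permutation(len(members))
    members = [members[k] for k in order]
    keep_set = set(keep)
    expected_after_purify = [m for m in members if m in keep_set]
    return BinFixture(
        bin=BinAssignment(bin_id="bin0", members=members, target_genus="g_target"),
        contigs=ContigSet(contigs),
        tree=tree,
        expected_after_purify=expected_after_purify,
        expected_final=expected_after_purify + rrna_ids,
    )


_STATUSES = list(GeneStatus)


def generate_gene_status_table(
    seed: int,
    pathways: Mapping[str, Sequence[str]],
    taxa: Sequence[str],
    status_probs: Sequence[float] = (0.6, 0.15, 0.15, 0.1),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random gene-status table plus the expected taxon × pathway calls.

    Statuses are drawn independently per (taxon, pathway, gene) with the
    given probabilities over (complete, partial, not-found, loss).  Expected
    calls come from the same precedence rule the scorer implements.
    """
    if not pathways:
        raise ValueError("no pathway definitions given")
    rng = np.random.default_rng(seed)
    rows = []
    expected = pd.DataFrame(index=list(taxa), columns=list(pathways), dtype=object)
    for taxon in taxa:
        for pname, genes in pathways.items():
            statuses = [
                _STATUSES[int(k)]
                for k in rng.choice(len(_STATUSES), size=len(genes), p=status_probs)
            ]
            for gene, status in zip(genes, statuses):
                rows.append(
                    {
                        "taxon": taxon,
                        "pathway": pname,
                        "gene": gene,
                        "status": status.value,
                    }
                )
            expected.loc[taxon, pname] = score_pathway(statuses)
    return pd.DataFrame(rows), expected


# ---------------------------------------------------------------------------
# Default study-like community


def default_taxonomy() -> TaxonomyTree:
    """Small taxonomy covering the default community's genera and species."""
    n = [
        TaxonNode("root", "root", "root", "root"),
        TaxonNode("bacteria", "Bacteria", "domain", "root"),
        TaxonNode("fungi", "Fungi", "domain", "root"),
        TaxonNode("firmicutes", "Firmicutes", "phylum", "bacteria"),
        TaxonNode("actinobacteria", "Actinobacteria", "phylum", "bacteria"),
        TaxonNode("lactobacillaceae", "Lactobacillaceae", "family", "firmicutes"),
        TaxonNode("leuconostocaceae", "Leuconostocaceae", "family", "firmicutes"),
        TaxonNode("bifidobacteriaceae", "Bifidobacteriaceae", "family", "actinobacteria"),
        TaxonNode("saccharomycetaceae", "Saccharomycetaceae", "family", "fungi"),
        TaxonNode("g_lactobacillus", "Lactobacillus", "genus", "lactobacillaceae"),
        TaxonNode("g_oenococcus", "Oenococcus", "genus", "leuconostocaceae"),
        TaxonNode("g_bifidobacterium", "Bifidobacterium", "genus", "bifidobacteriaceae"),
        TaxonNode("g_saccharomyces", "Saccharomyces", "genus", "saccharomycetaceae"),
        TaxonNode("g_dekkera", "Dekkera", "genus", "saccharomycetaceae"),
        TaxonNode("s_l_hilgardii", "Lactobacillus hilgardii", "species", "g_lactobacillus"),
        TaxonNode("s_l_nagelii", "Lactobacillus nagelii", "species", "g_lactobacillus"),
        TaxonNode("s_o_oeni", "Oenococcus oeni", "species", "g_oenococcus"),
        TaxonNode("s_o_kitaharae", "Oenococcus kitaharae", "species", "g_oenococcus"),
        TaxonNode("s_b_aquikefiri", "Bifidobacterium aquikefiri", "species", "g_bifidobacterium"),
        TaxonNode("s_s_cerevisiae", "Saccharomyces cerevisiae", "species", "g_saccharomyces"),
        TaxonNode("s_d_bruxellensis", "Dekkera bruxellensis", "species", "g_dekkera"),
    ]
    return TaxonomyTree(n)


def default_community() -> tuple[CommunityProfile, ReferenceDB]:
    """Five-member community mirroring the study's headline structure.

    Four species with sequenced references recruit near 100% identity;
    the fifth member is a novel relative of a sequenced genus, planted at
    identity Normal(77, 3) to mirror the 70–85% recruitment band an
    unsequenced species produces against its known congeners.  Genome
    lengths are scaled down (0.2–0.5 Mbp) so desk-scale runs stay fast;
    abundances echo the observed community balance.
    """
    members = (
        CommunityMember("lhil", "s_l_hilgardii", 0.30, 99.0, 0.5, 400_000),
        CommunityMember("baqu", "s_b_aquikefiri", 0.25, 99.0, 0.5, 350_000),
        # Novel Oenococcus relative: reads recruit to O. oeni at ~77%.
        CommunityMember("ooen", "s_o_oeni", 0.15, 77.0, 3.0, 300_000),
        CommunityMember("scer", "s_s_cerevisiae", 0.20, 99.0, 0.5, 500_000),
        CommunityMember("dbru", "s_d_bruxellensis", 0.10, 98.0, 1.0, 250_000),
    )
    db = ReferenceDB(
        [
            ReferenceGenome("lhil", "s_l_hilgardii", "g_lactobacillus", 400_000),
            ReferenceGenome("lnag", "s_l_nagelii", "g_lactobacillus", 380_000),
            ReferenceGenome("baqu", "s_b_aquikefiri", "g_bifidobacterium", 350_000),
            ReferenceGenome("ooen", "s_o_oeni", "g_oenococcus", 300_000),
            ReferenceGenome("okit", "s_o_kitaharae", "g_oenococcus", 280_000),
            ReferenceGenome("scer", "s_s_cerevisiae", "g_saccharomyces", 500_000),
            ReferenceGenome("dbru", "s_d_bruxellensis", "g_dekkera", 250_000),
        ]
    )
    return CommunityProfile(members=members), db
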