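"""End-to-end orchestration: simulate → classify → consensus → recruit →
assemble/curate → score pathways → report.

The pipeline composes the stage modules over a synthetic community (or over
user-supplied stage inputs via the stage functions directly) and writes one
stage-scoped output directory per stage plus a run manifest listing every
output file with a content hash.  Re-running with the same configuration is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
import yaml

from . import io as kio
from .assembly import compute_stats, filter_contigs, purify_bin, add_rrna_contigs
from .classify import PRESETS, LcaParams, apply_min_support, assign_reads, summarize_assignments
from .consensus import (
    ConsensusParams,
    ToolAssignmentSet,
    build_genus_table,
    consensus_all,
    select_recruitment_genera,
)
from .pathways import PathwayDefinition, plot_matrix, score_matrix
from .recruitment import (
    RecruitmentParams,
    build_matrix,
    call_presence,
    plot_recruitment,
    recruit_top_hits,
    recruitment_percentages,
)
from .simulate import (
    ToolProfile,
    default_community,
    default_taxonomy,
    generate_alignment_hits,
    generate_bin_fixture,
    generate_contig_set,
    generate_gene_status_table,
    generate_reads,
    generate_tool_assignments,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "kefirmeta/1"

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    Defaults are the published analysis parameters: the whole-read LCA
    preset (MinScore 100, MaxExpected 0.01, TopPercent 10, MinSupport 150),
    recruitment thresholds 60% identity / 60% query coverage, the 0.5%
    minorities threshold, the 0.1% recruitment-selection threshold, and the
    1000 bp contig filter.
    """

    outdir: Path
    seed: int = 0
    sample: str = "synthetic"
    n_reads: int = 20_000
    lca_preset: str = "megan-main"
    lca_overrides: dict = field(default_factory=dict)
    priority: list[str] = field(
        default_factory=lambda: ["kaiju", "kraken", "blastn_nt"]
    )
    minority_threshold: float = 0.5
    selection_threshold: float = 0.1
    min_contig_len: int = 1000
    n_contigs: int = 300
    recruitment: RecruitmentParams = field(default_factory=RecruitmentParams)
    target_genus: str = "g_target"
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "recruitment" in raw:
            raw["recruitment"] = RecruitmentParams(**raw["recruitment"])
        raw["outdir"] = Path(raw["outdir"])
        return cls(**raw)

    def lca_params(self) -> LcaParams:
        base = PRESETS[self.lca_preset]
        if not self.lca_overrides:
            return base
        values = {
            "min_score": base.min_score,
            "max_expected": base.max_expected,
            "top_percent": base.top_percent,
            "min_support": base.min_support,
            "lca_percent": base.lca_percent,
        }
        values.update(self.lca_overrides)
        return LcaParams(**values)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a seeded synthetic community; return the manifest.

    Stage outputs land in per-stage subdirectories of ``config.outdir``; no
    stage touches another stage's directory.  The manifest records inputs,
    parameters, seed and a sha256 per output file.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_tsv(df: pd.DataFrame, rel: str) -> Path:
        p = out / rel
        kio.write_tsv(df, p)
        written.append(p)
        return p

    # -- stage 0: synthetic inputs ----------------------------------------
    profile, db = default_community()
    tree = default_taxonomy()
    reads, truth = generate_reads(profile, config.n_reads, seed=config.seed)
    hits = generate_alignment_hits(reads, db, seed=config.seed + 1)
    save_tsv(truth, "simulate/truth.tsv")
    hits_path = out / "simulate" / "hits.outfmt6.tsv"
    hits_path.parent.mkdir(parents=True, exist_ok=True)
    kio.write_outfmt6(hits, hits_path)
    written.append(hits_path)
    logger.info("stage simulate: %d reads, %d alignment hits", len(reads), len(hits))

    # -- stage 1: per-read LCA classification ------------------------------
    params = config.lca_params()
    subject_taxa = {g.genome_id: g.species_taxon for g in db.genomes}
    lca_raw = assign_reads(hits, tree, params, subject_taxa=subject_taxa)
    lca_adj = apply_min_support(lca_raw, tree, params.min_support)
    summary = summarize_assignments(lca_adj, total_reads=len(reads))
    kio.write_assignments(lca_adj, out / "classify/lca_assignments.tsv")
    written.append(out / "classify/lca_assignments.tsv")
    save_tsv(summary.to_frame(), "classify/lca_summary.tsv")
    logger.info(
        "stage classify: %d reads classified, %d taxa retained",
        len(lca_adj),
        len(summary.counts),
    )

    # -- stage 2: consensus across simulated classifiers -------------------
    tool_profiles = [
        ToolProfile("kaiju", assignment_probability=0.60),
        ToolProfile(
            "kraken",
            assignment_probability=0.45,
            blind_spot=frozenset({"g_dekkera"}),
        ),
        ToolProfile("blastn_nt", assignment_probability=0.50),
    ]
    tool_tables = generate_tool_assignments(
        truth, tool_profiles, tree, seed=config.seed + 2
    )
    tools = ToolAssignmentSet.from_tables(config.priority, tool_tables)
    cons = consensus_all(tools)
    cparams = ConsensusParams(
        minority_threshold=config.minority_threshold,
        selection_threshold=config.selection_threshold,
    )
    genus_table = build_genus_table(
        cons, tree, cparams, total_reads=len(reads), sample=config.sample
    )
    save_tsv(genus_table.to_frame(), "consensus/genus_table.tsv")
    selected = select_recruitment_genera([genus_table], cparams)
    logger.info(
        "stage consensus: %d categories, selected genera for recruitment: %s",
        len(genus_table.counts),
        ", ".join(selected) or "(none)",
    )

    # -- stage 3: fragment recruitment -------------------------------------
    rec = recruit_top_hits(hits, db, config.recruitment)
    pct = recruitment_percentages(rec, total_reads=len(reads), db=db)
    save_tsv(pct, "recruit/genus_percentages.tsv")
    calls = [
        call_presence(rec, db, g.genome_id, config.recruitment) for g in db.genomes
    ]
    calls_path = out / "recruit/presence_calls.json"
    calls_path.parent.mkdir(parents=True, exist_ok=True)
    with open(calls_path, "w") as fh:
        json.dump(
            {
                "schema": SCHEMA_VERSION,
                "seed": config.seed,
                "params": {
                    "min_identity": config.recruitment.min_identity,
                    "min_query_coverage": config.recruitment.min_query_coverage,
                    "high_identity_floor": config.recruitment.high_identity_floor,
                    "novel_band": list(config.recruitment.novel_band),
                    "breadth_min": config.recruitment.breadth_min,
                    "pos_bin_size": config.recruitment.pos_bin_size,
                },
                "calls": [c.to_dict() for c in calls],
            },
            fh,
            indent=2,
        )
    written.append(calls_path)
    for genus in db.genera():
        gids = [g.genome_id for g in db.genomes_of_genus(genus)]
        matrix = build_matrix(rec, db, gids, config.recruitment)
        save_tsv(matrix.to_frame(), f"recruit/matrix_{genus}.tsv")
        if config.make_plots:
            plot_path = out / f"recruit/plot_{genus}.png"
            plot_recruitment(matrix, plot_path)
            written.append(plot_path)
    logger.info("stage recruit: %d/%d reads recruited", len(rec), len(reads))

    # -- stage 4: assembly statistics and bin curation ----------------------
    contigs, _ = generate_contig_set(seed=config.seed + 3, n=config.n_contigs)
    kept = filter_contigs(contigs, min_len=config.min_contig_len)
    stats = compute_stats(kept) if len(kept) else None
    if stats is None:
        raise RuntimeError("stage assembly: no contig passed the length filter")
    stats_path = out / "assembly/stats.json"
    stats_path.parent.mkdir(parents=True, exist_ok=True)
    with open(stats_path, "w") as fh:
        json.dump({"schema": SCHEMA_VERSION, "stats": stats.to_dict()}, fh, indent=2)
    written.append(stats_path)
    fixture = generate_bin_fixture(seed=config.seed + 4)
    curated = purify_bin(fixture.bin, fixture.contigs, fixture.tree)
    final = add_rrna_contigs(curated, fixture.contigs, fixture.bin.target_genus)
    save_tsv(pd.DataFrame({"contig_id": final}), "assembly/curated_mag_contigs.tsv")
    logger.info(
        "stage assembly: %d/%d contigs kept, MAG of %d contigs after curation",
        len(kept),
        len(contigs),
        len(final),
    )

    # -- stage 5: pathway scoring -------------------------------------------
    pathway_genes = {
        "L-lysine": ["lysC", "asd", "dapA", "dapB"],
        "L-tryptophan": ["trpA", "trpB", "trpC"],
        "riboflavin": ["ribA", "ribB", "ribE"],
    }
    taxa = sorted({m.species_taxon for m in profile.members})
    status_table, _expected = generate_gene_status_table(
        seed=config.seed + 5, pathways=pathway_genes, taxa=taxa
    )
    definitions = {
        name: PathwayDefinition(name=name, genes=tuple(genes))
        for name, genes in pathway_genes.items()
    }
    call_grid = score_matrix(status_table, definitions, taxa)
    grid_out = call_grid.map(lambda c: c.name)
    grid_out.insert(0, "taxon", grid_out.index)
    save_tsv(grid_out.reset_index(drop=True), "pathways/pathway_calls.tsv")
    if config.make_plots:
        pplot = out / "pathways/pathway_matrix.png"
        plot_matrix(call_grid, pplot)
        written.append(pplot)
    logger.info("stage pathways: scored %d taxa x %d pathways", len(taxa), len(definitions))

    # -- manifest ------------------------------------------------------------
    manifest = {
        "schema": SCHEMA_VERSION,
        "sample": config.sample,
        "seed": config.seed,
        "n_reads": config.n_reads,
        "lca_preset": config.lca_preset,
        "priority": config.priority,
        "parameters": {
            "min_score": params.min_score,
            "max_expected": params.max_expected,
            "top_percent": params.top_percent,
            "min_support": params.min_support,
            "minority_threshold": config.minority_threshold,
            "selection_threshold": config.selection_threshold,
            "min_contig_len": config.min_contig_len,
            "min_identity": config.recruitment.min_identity,
            "min_query_coverage": config.recruitment.min_query_coverage,
        },
        "selected_genera": selected,
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(written)
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
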