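# Methods

`kefirmeta` implements the decision layer of a shotgun-metagenomics community
analysis: every alignment, assembly, binning and annotation step is taken as
input (BLAST tabular hits, per-tool read→taxon tables, contig lengths and
attributions, gene-status tables), and the package implements the rules that
turn those inputs into taxonomic profiles, presence calls, curated
metagenome-assembled genomes (MAGs) and biosynthetic-potential grids.  A
synthetic-community generator provides planted ground truth so every rule is
testable without reference downloads or external aligners.

## Taxonomy model

The taxonomy is a rooted tree of nodes with ranks drawn from
root > domain > phylum > class > order > family > genus > species group >
species > subspecies, plus `no_rank`.  Taxon identifiers are opaque strings,
so numeric NCBI ids and name-keyed synthetic taxa both work.  Design
choices:

* `no_rank` nodes are transparent to rank queries — they sit on the root
  path but never match a requested rank.  NCBI-style taxonomies interleave
  unranked clades; skipping them makes "the genus ancestor of X" well
  defined regardless.
* `species_group` is placed between genus and species, so assignments at
  that rank roll up to genus like species-level assignments do.
* Construction validates the whole structure (single root, resolvable
  parents, acyclicity, unique ids); all queries afterwards can assume a
  well-formed tree.

The lowest common ancestor of a taxon set is the deepest node on the common
prefix of all root-first paths.  It is commutative and associative under
set union, which the property tests exercise directly.

## Naive-LCA read classification

Per read, alignment hits pass three filters in a frozen order: a bitscore
floor (`min_score`), an E-value ceiling (`max_expected`), then a top-percent
window retaining hits with bitscore ≥ (1 − top_percent/100) × best surviving
bitscore, with boundary ties retained.  The read is assigned to the naive
LCA of the survivors' taxa, or left unassigned when nothing survives.  Two
presets bundle the parameter sets used for whole-read and marker-gene
profiling: (100, 0.01, 10%, 150) and (80, 0.01, 100%, 10) for
(min_score, max_expected, top_percent, min_support).  Only the plain naive
LCA (`lca_percent` = 100) is implemented; other values raise, because
weighted-LCA semantics would be a guess.

Applying the score floor before the window matters: the window anchors on
the best *surviving* bitscore.  A useful consequence, verified analytically
and by property test, is monotonicity — tightening either floor never grows
the retained set, because a newly admitted hit would have to beat the very
best hit the tighter floor removed.

**Minimum support.**  A taxon's support is its cumulative clade count: reads
assigned directly to it plus all reads assigned within its clade.  Reads at
a taxon whose clade support falls below `min_support` move to the nearest
ancestor whose clade support reaches it; when even the root falls short they
become unassigned.  This keeps the higher-rank signal visible (a weak genus
surfaces at its family when sibling genera carry the clade) and guarantees
that every taxon retaining reads is clade-supported at the threshold.  A
configurable alternative (`mode="unassign"`) simply discards weakly
supported calls instead.  Read conservation holds through every stage: each
input read appears exactly once in the output.

Percentage summaries always use the *total* read count of the sample as the
denominator, so unclassified reads dilute percentages rather than
disappearing.

## Consensus profiling

Multiple classifiers are merged per read by strict priority: the first tool
in the configured order with a non-unassigned call wins, regardless of the
rank it called at.  Reads missing from one tool's table (classifiers often
omit unclassified reads) count as unassigned for that tool, with a logged
count.  Root-level calls are treated as unassigned — they carry no
information.

The genus table rolls consensus taxa into categories: subspecies-, species-
and species-group-rank calls map to their genus; genus-rank calls stay;
anything above genus pools into "above genus"; genera below the minority
threshold (default 0.5% of all reads, strictly less) collapse into
"minorities"; the rest of the read universe is "unassigned".  Minority
collapsing applies only to named genera, never to the special categories.
Temporal shifts are plain per-category differences in percentage points
between two samples' tables.  Genus selection for recruitment keeps genera
strictly exceeding the selection threshold (default 0.1%) in at least one
(sample, method) cell.

## Fragment recruitment

Per read, in a frozen order: (1) discard hits below the identity floor
(default 60%); (2) choose the single highest-bitscore survivor, breaking
ties by lower E-value and then lexicographic subject id; (3) discard the
read if that one hit's query coverage (100 × aligned length / read length,
clamped to 100) is below the coverage floor (default 60%).  The order is
frozen deliberately: a better-covered weaker hit never rescues a read whose
top hit fails coverage, and reordering these steps changes results.  The
recruited position is the subject-alignment midpoint — symmetric under
strand, with reverse-strand coordinates normalised by swapping.

Recruitment percentages are reported per genus as a percent of all reads at
two decimals, with a TOTAL row equal to the sum of the reported per-genus
values (so a printed column sums exactly to its printed total).

The plot matrix histograms (position, identity) on a grid of 5 kbp × 1%
bins by default (both configurable; the published plots do not state their
bin sizes) over concatenated genome coordinates in database order, and
normalises by the largest bin; an empty recruitment yields an all-zero
matrix rather than NaNs.

**Presence calling** replaces the visual read of a recruitment plot with
three numbers: `breadth_high`, the fraction of genome windows (one per
position bin) holding at least one read at ≥ 95% identity; `breadth_novel`,
the same for the 70–90% band; and the median recruited identity.  A genome
is `present` when `breadth_high` ≥ 0.6; otherwise `novel_relative` when
`breadth_novel` ≥ 0.6 *and* the median identity falls inside the novel
band; otherwise `absent`.  The 95% floor, 0.6 breadth and [70, 90] band are
package definitions standing in for visual judgement — they are reported
alongside every call and are configurable.  They cleanly separate the three
canonical situations: a present species recruits near-identical reads
genome-wide; an unsequenced relative produces a uniform lower-identity band
(≈70–85%) genome-wide; conserved-region artifacts recruit high-identity
reads over only a small fraction of windows.

## Assembly statistics and MAG curation

Contigs strictly longer than 1000 bp are retained ("longer than" read
literally).  N50 is the length of the contig at which the descending
cumulative length first reaches ≥ half the total; L50 is that contig's
1-based index; the median of an even count is the mean of the central pair.
Raw values are stored unrounded; kbp/Mbp table formatting is a view.
`mean_contig_size(total, n)` exposes the mean formula separately so printed
(total, count) pairs can be routed through the same arithmetic.

Bin curation implements two rules.  *Purification*: a member contig mapped
to a species outside the bin's target genus is discarded unless it carries
the target-genus similarity flag (an external BLAST-vs-nt judgement taken
as input); unmapped contigs and in-genus contigs are kept.  *rRNA rescue*:
contigs anywhere in the assembly whose rRNA annotation matches the target
genus are appended to the curated list (rRNA contigs usually fail to bin
with their genome), without duplicates; the operation is idempotent and
never removes anything.

## Pathway scoring

Each (organism, pathway) cell is scored from per-gene evidence statuses
with the precedence loss-of-function > not-found > partial > complete,
yielding VERY_UNLIKELY / UNLIKELY / LIKELY / VERY_LIKELY
(black/gray/yellow/green).  The four caption-level conditions can co-occur;
the precedence reflects evidential strength — one pseudogene settles the
question regardless of the other genes.  The rule is monotone (worsening
any single gene status never raises the call) and permutation-invariant.
A gene defined for a pathway but absent from the status table defaults to
NOT_FOUND with a logged warning: absence of evidence, scored as such.
Pathway gene lists are user input; the shipped example definitions are
illustrative only.

## Synthetic communities

The generator plants the features the real data exhibit, with all
randomness a pure function of (parameters, seed):

* **Reads** — lengths from normal(205, 30) truncated to [20, 260] bp (the
  published per-sample medians span 184–225 with a pooled median of 205 and
  that exact range; only those summaries are printed, so a truncated normal
  is the least-committal model).  Per-genome counts are multinomial in the
  abundances; per-member identities come from a truncated normal on
  (50, 100], with sd = 0 planting the mean exactly.
* **Hits** — each read gets a full-length top hit on its source genome at
  its planted identity, plus 0–3 decoy hits to same-genus genomes at
  identity reduced by Uniform(5, 20) points (dropped if ≤ 50%), a range
  chosen so the 10% top-percent window keeps some decoys and drops others.
  Bitscore = aligned length × (2·identity/100 − 1) and E-value
  10^(−bitscore/10) are monotone surrogates: downstream code may rely on
  ordering and thresholds only, never on absolute calibration.
* **Tool tables** — per tool, reads under a blind-spot taxon are
  unassignable (a database gap); otherwise the read is assigned with the
  tool's probability, to its species when the planted identity is ≥ 90%
  and to its genus below that (divergent reads resolve less deeply), with
  an optional misassignment rate to a substitute taxon.
* **Default community** — five members: four species recruiting at
  ~99% identity against their own references and one novel relative planted
  at Normal(77, 3) against its congener's genome, mirroring the 70–85%
  band that signals an unsequenced species.  Reference genomes are scaled
  to 0.25–0.5 Mbp so a 50,000-read experiment runs in seconds; abundances
  (0.30/0.25/0.20/0.15/0.10) echo a lactobacilli-dominated fermentation
  community.  Two same-genus decoy references are present in the database
  but absent from the community.
* **Bin fixtures and gene-status tables** carry their expected outcome
  computed at generation time by the same explicit rules the modules
  implement, written independently (sort-and-scan for N50, counting for
  pathway precedence), so generator truth and implementation can disagree
  when one is wrong.

What the generator does **not** model: positional sequencing error or
quality scores (identity is a single scalar per read), chimeric reads,
GC- or coverage-dependent bias, genuinely shared sequence between genomes
(decoys are explicit, not emergent homology), or assembly fragmentation
mechanics.  Passing tests therefore demonstrate that the decision rules are
implemented correctly and recover planted structure, not that the upstream
aligners and assemblers behave — those remain out of scope by design.

## Numerical conventions and problem sizes

Percentages are computed at full precision and rounded to two decimals only
at output.  Ties at the top-percent boundary are retained (≥).  Empty
inputs are handled explicitly (empty filter output, zero matrices, errors
on empty contig sets and status lists).  The test and acceptance runs use
desk-scale sizes chosen to make the statistical checks sharp but fast:
50,000 reads for recruitment recovery (binomial ±1-point bands), 10,000
reads for consensus conservation, 1,000 random trees (≤ 200 nodes) for the
LCA oracle suite, 500 random contig sets for the assembly oracle, and 50
seeded bin fixtures.  The full suite runs in well under a minute.

## Known limitations

* Weighted LCA (`lca_percent` < 100) and MEGAN RMA parsing are not
  implemented; hit tables must be BLAST tabular.
* The recruitment engine assigns each read to exactly one genome; it does
  not model multi-mapping ambiguity beyond the deterministic tie-break.
* Presence calls depend on the window size through breadth; very small
  genomes with few windows make breadth coarse.
* The pipeline's end-to-end runner drives the synthetic generator; real
  data flow through the per-stage functions and CLI subcommands, which
  accept external files.
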