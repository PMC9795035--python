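# Methods

This note records the models, conventions and design choices behind
`comorbidnet`, and what the synthetic study conditions do and do not show
about real data.

## Coordinate and format conventions

All internal coordinates are 0-based half-open. 1-based file formats
(GTF gene/exon records, contact-file positions, eQTL and catalog SNP
positions) are converted at parse time and back at write time. Restriction
digestion matches the recognition site case-insensitively (soft-masked
FASTA lowercase is ordinary sequence); sites containing `N` never match,
`N` runs are tiled like ordinary sequence, and chromosome-end fragments
are ordinary fragments. Cuts that would fall at position 0 or at the
chromosome end are ignored so no empty fragment exists; fragment IDs
restart at 0 on each chromosome, matching per-chromosome fragment
numbering in Hi-C contact files.

## Hi-C contact library

Input is 11-column whitespace-separated contact text (read name, strand /
chromosome / position / fragment / mapq per end). A read pair enters the
library only if both ends have mapq ≥ 30 (`mapq_min`, configurable).
Contacts are undirected; pair keys are order-normalised. Positional
duplicates are records sharing both (strand, chromosome, position)
endpoints after order normalisation — position-level, not fragment-level,
dedup semantics, because fragment-level keys would over-collapse distinct
ligation events. QC passes when the unique-contact fraction exceeds 0.5
and the duplication rate is below 0.4. Sequencing-level alignability
statistics cannot be recomputed from a contact list; the QC report covers
only what the list supports. Multiple contact files given to one run are
pooled into a single library before mapping, treating replicate libraries
of one tissue as one evidence source.

## Spatial eQTL–gene calling

For each SNP the pipeline locates its restriction fragment, collects all
fragments sharing ≥ 1 retained contact with it, and emits one candidate
pair per gene whose span overlaps any such fragment (any overlap of the
half-open intervals; no TSS refinement). A gene on the SNP's own fragment
is a candidate only when a self-contact is recorded — spatial support is
never assumed. Contact counts are summed over all interacting fragments a
gene overlaps, and duplicate (SNP, gene) pairs collapse to one test so the
FDR family is not inflated by multi-fragment genes.

Candidates are joined to the eQTL table on (rsid, gene); pairs without an
association record are dropped. BH adjustment then runs within the chosen
family:

* **seed-SNP runs** — one global family across all candidate pairs (the
  eQTL is the tested regulatory unit);
* **whole-GRN builds** — one family per SNP chromosome (the grouping key
  for trans pairs is the SNP's chromosome), after excluding variants with
  MAF < 0.05.

Interactions with adjusted p < 0.05 are significant; the seed-run report
additionally counts the stricter 0.01 tier. Both thresholds are config
keys. Classification uses chromosome identity and the distance from the
SNP to the nearest edge of the gene span (0 inside the span): same
chromosome and ≤ 1 Mb → cis; same chromosome, > 1 Mb → trans-intra;
different chromosomes → trans-inter. The span-edge convention is the
conservative reading of a "≤ 1 Mb" rule stated without a TSS convention.

The genic-context annotation (exonic / intronic / intergenic) is a
deliberately simple interval classifier over the supplied exon records;
it does not attempt transcript-aware consequence calling.

## Tissue PPIN

Protein links are thresholded at combined score ≥ 0.7. Scores are
accepted on the 0–1000 integer dialect or the 0–1 fraction dialect,
auto-detected per file from the value range. Protein pairs collapse to
gene pairs via the supplied mapping, keeping the maximum score among
protein-pair variants (preserves the strongest evidence and is consistent
under thresholding); gene-level self-loops are discarded and unmapped
proteins are counted, not fatal. The tissue filter keeps only genes that
are eQTL targets in the GRN; it is idempotent, and node/edge retention
fractions are reported. Seed subnetworks are the connected components
(≥ 2 nodes) of the graph induced on the seed genes, sorted by size then
lexicographically; isolated seeds are reported separately rather than
counted as subnetworks. Expression-based node sizing is visualization
metadata and never a topology filter.

## Level expansion and trait enrichment

Levels are disjoint breadth-first shells: level 0 is the seed condition's
GRN target genes (requested genes absent from the graph are logged, not
fatal), level k the neighbours of level k−1 not seen earlier; an empty
shell stops expansion. Shells rather than cumulative sets keep per-level
trait calls distinct. Level-0 eQTLs are not excluded from higher-level
tests.

Each level's gene set maps back to its GRN eQTLs, and every catalog trait
is scored with the exact hypergeometric upper tail P(X ≥ k) (a numerically
stable survival function; the test suite checks it against exact rational
enumeration). The population N is the set of unique catalog rsIDs —
the sampled units are SNPs, so the population must be SNPs, not traits.
Membership is by rsID string match; positional matching is out of scope.

**BH family.** Adjustment runs per level across the *full* catalog trait
universe: traits with zero overlap carry p = 1 and are only reported
implicitly, but they count in the family size m. Restricting the family
to traits selected by k ≥ 1 looked harmless but measurably inflates the
false-flag rate several-fold, because discrete hypergeometric p-values
conditioned on overlap are stochastically small; with the full family the
null-catalog flag rate sits at its nominal level (~0.05 across 200
simulated runs). Traits with FDR ≤ 0.05 are flagged.

## Bootstrap specificity

Each of the 1,000 iterations (configurable) samples the same number of
SNPs as the seed condition uniformly without replacement from the unique
catalog rsIDs, runs the global-family spatial mapping, and records which
observed genes reappear among significant targets. The empirical p is
exactly occurrences/iterations — no pseudo-count — so 0 means "below
1/iterations", and the output says so. Sampling is unmatched for MAF, LD
and chromosome (a known limitation; the draw emulates the catalog, not
the genome), and the condition's own SNPs stay in the pool unless the
off-by-default exclusion flag is set. Per-iteration generators are
spawned from `SeedSequence([parent_seed, iteration])`, so runs are
reproducible and individual iterations re-derivable.

## Synthetic study conditions

The generator's defaults define the reference conditions: 2 chromosomes ×
2 Mb (so cis and trans-intra are both exercisable), ~0.05 recognition
sites/kb (≈ 200 fragments), 60 genes with 1–3 exons, 500 eQTL-table
variants drawn from a 2,000-SNP catalog, MAF ~ Uniform(0.05, 0.5),
20 planted seed interactions (over ~12 target genes and ~15 SNPs, so the
genes-per-eQTL histogram is non-trivial) with nominal p ≤ 1e-6 and 3 Hi-C
contacts each, 200 null spatial pairs with p ~ Uniform(0, 1), 500
background contacts plus planted positional duplicates and sub-mapq
records, PPI shells of sizes [5, 8, 10, 10, 10] wired so level-k genes sit
at graph distance exactly k (decoy edges only among leftover genes), 50
scattered catalog traits of 5–40 SNPs each, and one planted trait whose
SNP set covers 80% of the level-2 genes' eQTLs (padding SNPs are drawn
from catalog SNPs outside the eQTL table so the planted trait cannot leak
into other levels). Chance occurrences of the recognition site are
scrubbed from the random sequence before injection so the configured site
density is exact. Every planted entity is recorded in a truth ledger
sufficient to score recovery from the generated files alone.

Multi-seed statistical checks (trait localization, null calibration) run
the same conditions on 500 kb chromosomes with 200 background contacts;
this scales the genome, not the planted structure or any threshold, and
was fixed once as the package's reference problem size for repeated runs.

What the generator does *not* emulate: Hi-C distance decay, LD structure,
haplotypes, realistic gene density or trait ontology overlap. Passing
tests therefore demonstrate correctness of the algorithms and calibration
of the statistics under the stated model, not performance on real
tissue data.

## Numerical choices and degenerate inputs

BH adjustment is delegated to statsmodels (`fdr_bh`); the test suite
holds it against a hand-coded textbook implementation. Hypergeometric
tails use scipy's survival function; exact rational arithmetic appears
only in test oracles. Ties in p-values are handled by stable sorts, and
all output tables are deterministically ordered, so identical inputs and
config reproduce byte-identical tables. Degenerate inputs fail loudly:
empty sequences, empty contact libraries, malformed contact lines (with
line numbers), unknown traits (listing what is available), out-of-range
thresholds, seed SNPs with no GRN targets. Empty candidate sets, unknown
fragments and zero-overlap traits return empty results rather than
errors.

## Known limitations

* The eQTL association p-values are consumed, never recomputed; the
  pipeline's guarantees start downstream of the association scan.
* The enrichment catalog's trait labels are treated as flat strings; no
  ontology harmonisation.
* Bootstrap draws ignore LD and MAF matching (above).
* The QC stage cannot check sequencing-level alignability from contact
  lists.
* One tissue per run; cross-tissue comparisons are orchestration, not
  library code.
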