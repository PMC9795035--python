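# comorbidnet

Spatially constrained eQTL–gene networks and de novo comorbidity discovery.

Many complex diseases co-occur more often than chance allows, and part of
that co-occurrence is genetic: regulatory variants (eQTLs) for one
condition sit in chromatin contact with genes whose protein products
interact with the gene products of other conditions. `comorbidnet`
implements the full analysis chain that turns this idea into testable
calls:

1. **In-silico restriction digest** of a genome (HindIII, `A^AGCTT`, by
   default) and constant-time position→fragment lookup.
2. **Hi-C contact library** parsing (11-column deduplicated contact text),
   mapq ≥ 30 filtering, and library QC (unique-contact fraction,
   duplication rate).
3. **Spatial eQTL–gene calling**: a SNP–gene pair is kept only if the
   SNP's restriction fragment shares a Hi-C contact with a fragment
   overlapping the gene *and* the pair's expression association survives
   Benjamini–Hochberg FDR. Pairs are classified *cis* (≤ 1 Mb, same
   chromosome), *trans-intrachromosomal* (> 1 Mb) or
   *trans-interchromosomal*. The whole-tissue gene regulatory network
   (GRN) is built from all common variants (MAF ≥ 0.05) with
   per-chromosome FDR families; condition (seed-SNP) runs use one global
   family.
4. **Tissue PPIN**: high-confidence protein links (combined score ≥ 0.7)
   collapsed to gene level and restricted to GRN target genes.
5. **Level-wise comorbidity scan**: breadth-first shells of the PPIN
   around the seed condition's genes; at each level k the eQTLs of the
   level's genes are tested for enrichment in every GWAS-catalog trait
   with the hypergeometric tail

   ```
   p = P(X ≥ k),  X ~ Hypergeometric(N, K, n)
   ```

   (N = unique catalog SNPs, K = SNPs with the trait, n = level eQTLs in
   the catalog, k = their overlap), BH-adjusted across the catalog's
   traits per level; traits with FDR ≤ 0.05 are flagged as candidate
   co-occurring conditions.
6. **Bootstrap specificity**: 1,000 random same-size SNP draws from the
   catalog re-run through the spatial mapping; a gene's empirical p is
   `occurrences / iterations`.

Because the real inputs of such analyses (tissue Hi-C libraries,
controlled-access eQTL databases, protein-link databases, GWAS-catalog
snapshots) are huge and partly access-restricted, the package ships a
first-class **synthetic data generator** that emulates every input with
planted, ledgered ground truth — planted spatial interactions, planted
PPI shells at exact graph distances, and a planted trait enriched at one
level — so the entire pipeline is testable at desk scale.

## Worked example

Simulate a dataset (two 500 kb chromosomes, planted structure at the
default study conditions) and run every stage:

```bash
comorbidnet simulate --seed 7 --config sim.yaml --out data   # sim.yaml: chrom_length_bp: 500000, background_contacts: 200
comorbidnet -q run-all --data-dir data --out run --bootstrap-iterations 200
```

prints

```
comorbidnet pipeline report
============================

Hi-C QC: 760/780 records retained, 740 unique contacts (dup rate 0.026, pass=True)

GRN: 85 interactions, 80 eQTLs, 55 genes; classes {'cis': 37, 'trans_intra': 0, 'trans_inter': 48}

Seed run (seed_condition): 20 significant interactions (20 at the headline tier), 15 eQTLs, 12 genes

LSPPIN: 55/59 nodes, 69/72 edges retained

Per-level flagged traits:
  level 0: 12 genes, 16 eQTLs, flagged: seed_condition
  level 1: 5 genes, 7 eQTLs, flagged: -
  level 2: 8 genes, 12 eQTLs, flagged: planted_trait
  level 3: 10 genes, 14 eQTLs, flagged: -
  level 4: 10 genes, 15 eQTLs, flagged: -
```

Reading this: the contact library passes QC (2.6% positional duplicates);
the whole-tissue GRN recovers 85 significant spatial interactions (the 84
planted ones plus one borderline null pair); the seed condition's 15
genome-wide-significant SNPs map to all 20 planted eQTL–gene interactions
over 12 target genes; the tissue filter keeps the 55 GRN genes in the
PPIN; and the scan flags the seed condition itself at level 0 and the
planted comorbid trait exactly at its planted level 2 — at no other
level. `run/` additionally holds the GRN and seed-interaction TSVs, the
per-level enrichment table, the bootstrap table (empirical p per observed
gene), the fragment BED, QC JSON and a machine-readable `report.json`.

Individual stages are available as `digest`, `hic-qc`, `build-grn`,
`map-seed`, `ppin`, `multimorbid` and `bootstrap` subcommands, and as
plain library functions (`comorbidnet.build_grn`,
`comorbidnet.run_multimorbid`, ...).

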