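"""Bootstrap gene-specificity testing.

How specific are the genes found for a condition to that condition's SNPs?
Each bootstrap iteration draws the same number of SNPs uniformly at random
(without replacement) from the GWAS catalog, runs the spatial eQTL-gene
mapping on the random set, and records which observed genes reappear among
the significant targets.  The empirical p-value of a gene is exactly

    occurrences / iterations

with no pseudo-count, so 0 means "less than 1/iterations".  Sampling is
unmatched for MAF, LD or chromosome.  Per-iteration RNG streams are
spawned deterministically from the parent seed and the iteration index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation
from .genome_digest import FragmentIndex
from .hic import ContactLibrary
from .spatial_eqtl import Variant, call_interactions, candidate_pairs

__all__ = ["BootstrapResult", "sample_random_snps", "bootstrap_gene_specificity"]


@dataclass(frozen=True)
class BootstrapResult:
    gene_id: str
    occurrences: int
    iterations: int
    rng_seed: int

    @property
    def empirical_p(self) -> float:
        return self.occurrences / self.iterations


def sample_random_snps(
    catalog: pd.DataFrame, size: int, rng: np.random.Generator
) -> set[str]:
    """Uniform sample of ``size`` unique catalog rsIDs, without replacement."""
    unique = sorted(catalog["rsid"].unique())
    if size > len(unique):
        raise ValueError(f"requested {size} SNPs but catalog has {len(unique)} unique rsIDs")
    if size == 0:
        return set()
    picked = rng.choice(len(unique), size=size, replace=False)
    return {unique[i] for i in picked}


def _catalog_variants(catalog: pd.DataFrame) -> dict[str, Variant]:
    if not {"chrom", "pos"} <= set(catalog.columns):
        raise ValueError("catalog lacks chrom/pos columns needed to run the pipeline")
    sub = catalog.drop_duplicates("rsid")
    return {
        row.rsid: Variant(row.rsid, str(row.chrom), int(row.pos))
        for row in sub.itertuples(index=False)
    }


def bootstrap_gene_specificity(
    observed_genes: Iterable[str],
    seed_size: int,
    catalog: pd.DataFrame,
    index: FragmentIndex,
    library: ContactLibrary,
    genes: GeneAnnotation,
    eqtls: pd.DataFrame,
    iterations: int = 1000,
    rng_seed: int = 0,
    fdr_threshold: float = 0.05,
    exclude_rsids: Iterable[str] | None = None,
) -> list[BootstrapResult]:
    """Empirical recovery frequency of each observed gene under random seeds.

    ``exclude_rsids`` optionally removes the condition's own SNPs from the
    sampling pool (off by default).  Results are sorted by empirical p
    then gene_id.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    observed = sorted(set(observed_genes))
    variants = _catalog_variants(catalog)
    pool = catalog
    if exclude_rsids is not None:
        pool = catalog[~catalog["rsid"].isin(set(exclude_rsids))]

    counts = {gene: 0 for gene in observed}
    for i in range(iterations):
        rng = np.random.default_rng(np.random.SeedSequence([rng_seed, i]))
        sampled = sample_random_snps(pool, seed_size, rng)
        snps = {rsid: variants[rsid] for rsid in sampled}
        pairs = candidate_pairs(snps.values(), index, library, genes)
        hits = call_interactions(
            pairs, eqtls, snps=snps, genes=genes,
            fdr_threshold=fdr_threshold, fdr_grouping="global",
        )
        recovered = {it.gene_id for it in hits}
        for gene in observed:
            if gene in recovered:
                counts[gene] += 1

    results = [
        BootstrapResult(gene, counts[gene], iterations, rng_seed) for gene in observed
    ]
    return sorted(results, key=lambda r: (r.empirical_p, r.gene_id))


def results_dataframe(results: list[BootstrapResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                gene_id=r.gene_id,
                occurrences=r.occurrences,
                iterations=r.iterations,
                empirical_p=r.empirical_p,
                seed=r.rng_seed,
            )
            for r in results
        ],
        columns=["gene_id", "occurrences", "iterations", "empirical_p", "seed"],
    )
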