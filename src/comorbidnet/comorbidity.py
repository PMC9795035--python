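"""Level-wise PPI expansion and GWAS-trait enrichment (comorbidity calling).

Starting from the genes targeted by a condition's eQTLs (level 0), the PPI
graph is expanded in breadth-first shells: level k holds the genes at graph
distance exactly k from level 0.  For each level, the eQTLs regulating its
genes are collected from the GRN and every GWAS-catalog trait overlapping
them is tested for enrichment with the hypergeometric tail

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

where N is the number of unique catalog SNPs, K the catalog SNPs annotated
to the trait, n the level eQTLs present in the catalog, and k their
overlap.  BH adjustment runs across the traits actually tested at each
level; traits with FDR <= 0.05 are flagged as candidate co-occurring
conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .spatial_eqtl import GRN, bh_adjust

__all__ = [
    "LevelEnrichment",
    "level_expansion",
    "eqtls_for_genes",
    "hypergeom_tail",
    "trait_enrichment",
    "run_multimorbid",
    "enrichment_dataframe",
]

ENRICHMENT_COLUMNS = ["trait", "k", "n", "K", "N", "p", "fdr", "flagged"]


@dataclass
class LevelEnrichment:
    level: int
    genes: set[str]
    eqtls: set[str]
    table: pd.DataFrame  # columns ENRICHMENT_COLUMNS

    @property
    def flagged_traits(self) -> list[str]:
        return self.table.loc[self.table["flagged"], "trait"].tolist()


def level_expansion(
    graph: nx.Graph, level0_genes: Iterable[str], max_level: int = 4
) -> list[set[str]]:
    """Disjoint breadth-first shells around the level-0 genes.

    Level 0 is the intersection of the input genes with the graph's nodes
    (absent genes are dropped with a warning, not an error); level k holds
    the neighbours of level k-1 not seen at any earlier level.  Expansion
    stops early on an empty shell.
    """
    if max_level < 0:
        raise ValueError("max_level must be >= 0")
    requested = set(level0_genes)
    level0 = requested & set(graph.nodes)
    absent = requested - level0
    if absent:
        warnings.warn(
            f"{len(absent)} level-0 gene(s) absent from the PPI graph", stacklevel=2
        )
    levels = [level0]
    seen = set(level0)
    for _ in range(max_level):
        frontier: set[str] = set()
        for gene in levels[-1]:
            frontier.update(graph.neighbors(gene))
        frontier -= seen
        if not frontier:
            break
        levels.append(frontier)
        seen |= frontier
    return levels


def eqtls_for_genes(grn: GRN, genes: Iterable[str]) -> set[str]:
    """Union of GRN eQTLs regulating any of the given genes."""
    out: set[str] = set()
    for gene in genes:
        out |= grn.eqtls_for(gene)
    return out


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N):
        raise ValueError(f"population successes K={K} outside [0, N={N}]")
    if not (0 <= n <= N):
        raise ValueError(f"sample size n={n} outside [0, N={N}]")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    return float(hypergeom.sf(k - 1, N, K, n))


def trait_enrichment(
    level_eqtls: Iterable[str], catalog: pd.DataFrame, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Per-trait hypergeometric enrichment of a level's eQTL set.

    Rows are emitted only for traits with at least one overlapping SNP,
    but the BH family spans every distinct catalog trait: a trait with no
    overlap carries p = 1 and can never be significant, yet it belongs to
    the tested universe, and restricting the family to traits selected by
    k >= 1 would inflate the false-positive rate of the discrete tests.
    An eQTL set disjoint from the catalog yields an empty table with a
    warning.
    """
    if catalog.empty:
        raise ValueError("catalog is empty")
    catalog_rsids = set(catalog["rsid"])
    N = len(catalog_rsids)
    sample = set(level_eqtls) & catalog_rsids
    n = len(sample)
    if n == 0:
        warnings.warn("no level eQTLs present in the catalog; no test performed",
                      stacklevel=2)
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)

    trait_snps = catalog.groupby("trait")["rsid"].agg(set)
    rows = []
    for trait, snps in trait_snps.items():
        k = len(sample & snps)
        if k < 1:
            continue
        K = len(snps)
        rows.append((trait, k, n, K, N, hypergeom_tail(k, N, K, n)))
    table = pd.DataFrame(rows, columns=["trait", "k", "n", "K", "N", "p"])
    # BH over the full trait universe: pad the zero-overlap traits' p = 1
    n_untested = len(trait_snps) - len(table)
    padded = np.concatenate([table["p"].to_numpy(), np.ones(n_untested)])
    table["fdr"] = bh_adjust(padded)[: len(table)]
    table["flagged"] = table["fdr"] <= fdr_threshold
    return table.sort_values(["fdr", "trait"], kind="mergesort", ignore_index=True)


def run_multimorbid(
    seed_snps: Iterable[str],
    grn: GRN,
    graph: nx.Graph,
    catalog: pd.DataFrame,
    max_level: int = 4,
    fdr_threshold: float = 0.05,
) -> list[LevelEnrichment]:
    """Full level-wise comorbidity scan from a seed SNP set.

    Level-0 genes are the GRN targets of the seed SNPs (an empty target
    set is an error: there is nothing to expand).  Every level yields its
    gene set, its GRN eQTLs, and the trait-enrichment table with flagged
    (FDR <= threshold) candidate co-occurring traits.
    """
    level0 = grn.target_genes(seed_snps)
    if not level0:
        raise ValueError("seed SNPs have no target genes in the GRN")
    levels = level_expansion(graph, level0, max_level=max_level)
    results = []
    for level, genes in enumerate(levels):
        eqtls = eqtls_for_genes(grn, genes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = (
                trait_enrichment(eqtls, catalog, fdr_threshold)
                if eqtls
                else pd.DataFrame(columns=ENRICHMENT_COLUMNS)
            )
        results.append(LevelEnrichment(level=level, genes=genes, eqtls=eqtls, table=table))
    return results


def enrichment_dataframe(results: Sequence[LevelEnrichment]) -> pd.DataFrame:
    """Concatenate per-level tables into one long table with a level column."""
    frames = []
    for res in results:
        if res.table.empty:
            continue
        frame = res.table.copy()
        frame.insert(0, "level", res.level)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["level", *ENRICHMENT_COLUMNS])
    return pd.concat(frames, ignore_index=True)
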