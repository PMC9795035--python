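"""Spatially constrained eQTL-gene interaction calling and the tissue GRN.

An eQTL-gene pair is *spatially constrained* when (i) the SNP's restriction
fragment shares at least one Hi-C contact with a fragment overlapping the
gene, and (ii) the pair has a significant expression association after
Benjamini-Hochberg FDR adjustment.  The gene regulatory network (GRN) of a
tissue is the indexed collection of all such pairs.

Interaction classes follow the standard distance trichotomy: *cis* (same
chromosome, SNP within 1 Mb of the gene span), *trans-intrachromosomal*
(same chromosome, > 1 Mb) and *trans-interchromosomal* (different
chromosomes).

Two FDR families are supported: a single global family (used when mapping a
seed SNP set for one condition) and per-chromosome families keyed by the
SNP's chromosome (used when building the whole-tissue GRN from all common
variants).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .annotation import Gene, GeneAnnotation
from .genome_digest import FragmentIndex
from .hic import ContactLibrary, interacting_fragments

__all__ = [
    "Variant",
    "SpatialInteraction",
    "GRN",
    "bh_adjust",
    "read_trait_associations",
    "read_eqtl_table",
    "eqtl_table_variants",
    "filter_gwas_snps",
    "candidate_pairs",
    "classify_interaction",
    "call_interactions",
    "build_grn",
    "annotate_variant_context",
    "summarize_grn",
]

InteractionClass = Literal["cis", "trans_intra", "trans_inter"]
CIS_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class Variant:
    rsid: str
    chrom: str
    pos: int  # 0-based
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.rsid}: MAF {self.maf} outside [0, 0.5]")


@dataclass(frozen=True)
class SpatialInteraction:
    rsid: str
    gene_id: str
    nominal_p: float
    adjusted_p: float
    interaction_class: str
    supporting_contacts: int
    effect_size: float

    def __post_init__(self) -> None:
        if self.supporting_contacts < 1:
            raise ValueError("spatial interaction requires >=1 supporting contact")


class GRN:
    """Set of significant spatial interactions, indexed both directions."""

    def __init__(self, interactions: Iterable[SpatialInteraction]):
        self.interactions: list[SpatialInteraction] = sorted(
            interactions, key=lambda i: (i.rsid, i.gene_id)
        )
        self._by_eqtl: dict[str, set[str]] = {}
        self._by_gene: dict[str, set[str]] = {}
        for it in self.interactions:
            self._by_eqtl.setdefault(it.rsid, set()).add(it.gene_id)
            self._by_gene.setdefault(it.gene_id, set()).add(it.rsid)

    def __len__(self) -> int:
        return len(self.interactions)

    @property
    def eqtls(self) -> set[str]:
        return set(self._by_eqtl)

    @property
    def genes(self) -> set[str]:
        return set(self._by_gene)

    def genes_for(self, rsid: str) -> set[str]:
        return set(self._by_eqtl.get(rsid, set()))

    def eqtls_for(self, gene_id: str) -> set[str]:
        return set(self._by_gene.get(gene_id, set()))

    def target_genes(self, rsids: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for rsid in rsids:
            out |= self.genes_for(rsid)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    rsid=i.rsid,
                    gene_id=i.gene_id,
                    interaction_class=i.interaction_class,
                    supporting_contacts=i.supporting_contacts,
                    nominal_p=i.nominal_p,
                    adjusted_p=i.adjusted_p,
                    effect_size=i.effect_size,
                )
                for i in self.interactions
            ],
            columns=[
                "rsid", "gene_id", "interaction_class", "supporting_contacts",
                "nominal_p", "adjusted_p", "effect_size",
            ],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GRN":
        df = pd.read_csv(path, sep="\t")
        return cls(
            SpatialInteraction(
                rsid=row.rsid,
                gene_id=row.gene_id,
                nominal_p=float(row.nominal_p),
                adjusted_p=float(row.adjusted_p),
                interaction_class=row.interaction_class,
                supporting_contacts=int(row.supporting_contacts),
                effect_size=float(row.effect_size),
            )
            for row in df.itertuples(index=False)
        )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (one testing family)."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# table readers (1-based file positions -> 0-based internal)
# ---------------------------------------------------------------------------

def read_trait_associations(path: str | Path) -> pd.DataFrame:
    """Read a GWAS-catalog-like TSV (rsid, chrom, pos, trait, p); pos -> 0-based."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"rsid", "trait", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trait association table missing columns: {sorted(missing)}")
    if "pos" in df.columns:
        df = df.assign(pos=df["pos"].astype(int) - 1)
    return df


def read_eqtl_table(path: str | Path) -> pd.DataFrame:
    """Read an eQTL TSV (rsid, gene_id, tissue, maf, nominal_p, effect_size
    plus optional variant chrom/pos); pos -> 0-based."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"rsid", "gene_id", "nominal_p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"eQTL table missing columns: {sorted(missing)}")
    if "pos" in df.columns:
        df = df.assign(pos=df["pos"].astype(int) - 1)
    return df


def eqtl_table_variants(eqtls: pd.DataFrame) -> list[Variant]:
    """Unique variants of an eQTL table (requires chrom/pos/maf columns)."""
    cols = {"rsid", "chrom", "pos", "maf"}
    if not cols <= set(eqtls.columns):
        raise ValueError("eQTL table lacks variant coordinate columns (chrom, pos, maf)")
    sub = eqtls.drop_duplicates("rsid")
    return [
        Variant(row.rsid, str(row.chrom), int(row.pos), float(row.maf))
        for row in sub.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def filter_gwas_snps(
    associations: pd.DataFrame, trait: str, p_threshold: float = 5e-8
) -> set[Variant]:
    """Genome-wide-significant (p < threshold, strict) unique SNPs for a trait."""
    traits = associations["trait"].unique()
    if trait not in traits:
        raise ValueError(
            f"trait {trait!r} not in table; available: {sorted(map(str, traits))}"
        )
    hits = associations[
        (associations["trait"] == trait) & (associations["p"] < p_threshold)
    ].drop_duplicates("rsid")
    return {
        Variant(row.rsid, str(row.chrom), int(row.pos)) for row in hits.itertuples(index=False)
    }


def candidate_pairs(
    snps: Iterable[Variant],
    index: FragmentIndex,
    library: ContactLibrary,
    genes: GeneAnnotation,
) -> set[tuple[str, str, int]]:
    """Spatial candidates: (rsid, gene_id, supporting_contacts) triples.

    For each SNP, collect the fragments its own fragment contacts (the
    SNP's fragment itself only via a recorded self-contact), then every
    gene whose span overlaps any of those fragments.  Contact counts are
    summed over all interacting fragments a gene overlaps, and duplicate
    (rsid, gene) pairs are collapsed.
    """
    support: dict[tuple[str, str], int] = {}
    for snp in snps:
        frag_id = index.locate(snp.chrom, snp.pos)
        for chrom, other_id, count in interacting_fragments(library, snp.chrom, frag_id):
            frag = index.fragment(chrom, other_id)
            for gene_id in genes.overlapping(chrom, frag.start, frag.end):
                key = (snp.rsid, gene_id)
                support[key] = support.get(key, 0) + count
    return {(rsid, gene_id, n) for (rsid, gene_id), n in support.items()}


def classify_interaction(
    snp: Variant, gene: Gene, cis_window: int = CIS_WINDOW_BP
) -> str:
    """cis / trans_intra / trans_inter by chromosome and span-edge distance."""
    if snp.chrom != gene.chrom:
        return "trans_inter"
    if gene.start <= snp.pos < gene.end:
        distance = 0
    elif snp.pos < gene.start:
        distance = gene.start - snp.pos
    else:
        distance = snp.pos - (gene.end - 1)
    return "cis" if distance <= cis_window else "trans_intra"


def call_interactions(
    pairs: Iterable[tuple[str, str, int]],
    eqtls: pd.DataFrame,
    snps: Mapping[str, Variant],
    genes: GeneAnnotation,
    fdr_threshold: float = 0.05,
    fdr_grouping: Literal["global", "per_chromosome"] = "global",
    cis_window: int = CIS_WINDOW_BP,
) -> list[SpatialInteraction]:
    """Join spatial candidates to the eQTL table and BH-test them.

    Pairs without an eQTL record are dropped before testing.  BH runs
    within the chosen family: one global family, or one family per SNP
    chromosome.  Interactions with adjusted p < fdr_threshold are returned
    with their distance-class labels.
    """
    if not (0 < fdr_threshold <= 1):
        raise ValueError(f"fdr_threshold {fdr_threshold} outside (0, 1]")
    pair_list = sorted(pairs)
    if not pair_list:
        return []
    contacts = {(rsid, gene_id): n for rsid, gene_id, n in pair_list}
    pair_df = pd.DataFrame(
        [(r, g) for r, g, _ in pair_list], columns=["rsid", "gene_id"]
    )
    eq = eqtls.drop_duplicates(subset=["rsid", "gene_id"])
    joined = pair_df.merge(
        eq[["rsid", "gene_id", "nominal_p"]
           + (["effect_size"] if "effect_size" in eq.columns else [])],
        on=["rsid", "gene_id"],
        how="inner",
    ).sort_values(["rsid", "gene_id"], kind="mergesort", ignore_index=True)
    if joined.empty:
        return []
    if "effect_size" not in joined.columns:
        joined["effect_size"] = np.nan

    if fdr_grouping == "global":
        joined["adjusted_p"] = bh_adjust(joined["nominal_p"].to_numpy())
    elif fdr_grouping == "per_chromosome":
        joined["_chrom"] = [snps[r].chrom for r in joined["rsid"]]
        joined["adjusted_p"] = np.nan
        for _, idx in joined.groupby("_chrom").groups.items():
            joined.loc[idx, "adjusted_p"] = bh_adjust(
                joined.loc[idx, "nominal_p"].to_numpy()
            )
        joined = joined.drop(columns="_chrom")
    else:
        raise ValueError(f"unknown fdr_grouping: {fdr_grouping!r}")

    out: list[SpatialInteraction] = []
    for row in joined.itertuples(index=False):
        if row.adjusted_p >= fdr_threshold:
            continue
        out.append(
            SpatialInteraction(
                rsid=row.rsid,
                gene_id=row.gene_id,
                nominal_p=float(row.nominal_p),
                adjusted_p=float(row.adjusted_p),
                interaction_class=classify_interaction(
                    snps[row.rsid], genes[row.gene_id], cis_window
                ),
                supporting_contacts=contacts[(row.rsid, row.gene_id)],
                effect_size=float(row.effect_size),
            )
        )
    return out


def build_grn(
    all_snps: Iterable[Variant],
    index: FragmentIndex,
    library: ContactLibrary,
    genes: GeneAnnotation,
    eqtls: pd.DataFrame,
    maf_min: float = 0.05,
    fdr_threshold: float = 0.05,
    cis_window: int = CIS_WINDOW_BP,
) -> GRN:
    """Whole-tissue GRN: common variants, per-chromosome BH families."""
    common = [
        s for s in all_snps if s.maf is not None and s.maf >= maf_min
    ]
    if not common:
        return GRN([])
    pairs = candidate_pairs(common, index, library, genes)
    interactions = call_interactions(
        pairs,
        eqtls,
        snps={s.rsid: s for s in common},
        genes=genes,
        fdr_threshold=fdr_threshold,
        fdr_grouping="per_chromosome",
        cis_window=cis_window,
    )
    return GRN(interactions)


def annotate_variant_context(snp: Variant, genes: GeneAnnotation) -> str:
    """Genic context of a variant: exonic, intronic or intergenic."""
    if genes.exonic_at(snp.chrom, snp.pos):
        return "exonic"
    if genes.genes_at(snp.chrom, snp.pos):
        return "intronic"
    return "intergenic"


def summarize_grn(grn: GRN, genes: GeneAnnotation | None = None) -> dict:
    """Descriptive statistics of a GRN.

    Reports interaction counts per class, the genes-per-eQTL histogram,
    unique eQTL/gene totals, and (when an annotation is supplied) gene
    counts per biotype.
    """
    class_counts: dict[str, int] = {"cis": 0, "trans_intra": 0, "trans_inter": 0}
    for it in grn.interactions:
        class_counts[it.interaction_class] = class_counts.get(it.interaction_class, 0) + 1
    genes_per_eqtl: dict[int, int] = {}
    for rsid in grn.eqtls:
        k = len(grn.genes_for(rsid))
        genes_per_eqtl[k] = genes_per_eqtl.get(k, 0) + 1
    summary = {
        "n_interactions": len(grn),
        "n_eqtls": len(grn.eqtls),
        "n_genes": len(grn.genes),
        "class_counts": class_counts,
        "genes_per_eqtl": dict(sorted(genes_per_eqtl.items())),
    }
    if genes is not None:
        biotype_counts: dict[str, int] = {}
        for gene_id in grn.genes:
            biotype = genes[gene_id].biotype if gene_id in genes else "unknown"
            biotype_counts[biotype] = biotype_counts.get(biotype, 0) + 1
        summary["biotype_counts"] = dict(sorted(biotype_counts.items()))
    return summary
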