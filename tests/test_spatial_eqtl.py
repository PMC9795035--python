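"""Spatial eQTL-gene calling: GWAS filter, candidate pairs, BH, classes, GRN."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import bh_oracle
from comorbidnet import (
    GRN,
    Gene,
    GeneAnnotation,
    SimulationConfig,
    Variant,
    annotate_variant_context,
    bh_adjust,
    build_grn,
    call_interactions,
    candidate_pairs,
    classify_interaction,
    filter_gwas_snps,
    generate_all,
    parse_contacts,
    summarize_grn,
)
from comorbidnet.genome_digest import FragmentIndex
from comorbidnet.spatial_eqtl import eqtl_table_variants


# --- a tiny hand-built spatial fixture: chr1 tiled into 100 bp fragments ----

@pytest.fixture()
def tiny():
    index = FragmentIndex({"chr1": [(i * 100, (i + 1) * 100) for i in range(8)]})
    genes = GeneAnnotation(
        [
            Gene("G1", "G1", "chr1", 700, 780, "+", exons=((700, 740),)),
            Gene("G2", "G2", "chr1", 350, 560, "+", exons=((350, 400),)),  # spans frags 3-5
        ]
    )
    def contact(read, f1, f2, p1, p2, q=60):
        return f"{read} 0 chr1 {p1} {f1} {q} 16 chr1 {p2} {f2} {q}"
    lines = [
        contact("r1", 1, 7, 150, 750),            # F1-F7 (G1)
        contact("r2", 1, 3, 160, 360),            # F1-F3 (G2), count 1
        contact("r3", 1, 3, 170, 370),            # F1-F3 again -> count 2
        contact("r4", 1, 5, 180, 520),            # F1-F5 (G2) x3
        contact("r5", 1, 5, 181, 521),
        contact("r6", 1, 5, 182, 522),
    ]
    return index, genes, parse_contacts(lines)


def test_filter_gwas_snps_boundary_and_dedup():
    table = pd.DataFrame(
        {
            "rsid": ["rs1", "rs2", "rs3", "rs3"],
            "chrom": ["chr1"] * 4,
            "pos": [10, 20, 30, 30],
            "trait": ["COPD"] * 4,
            "p": [5e-8, 4.9e-8, 1e-9, 1e-10],
        }
    )
    snps = filter_gwas_snps(table, "COPD")
    assert {s.rsid for s in snps} == {"rs2", "rs3"}  # strict <, deduplicated
    with pytest.raises(ValueError, match="COPD"):
        filter_gwas_snps(table, "asthma")


def test_candidate_pairs_sums_contacts_across_fragments(tiny):
    index, genes, library = tiny
    snp = Variant("rsA", "chr1", 105)  # fragment 1
    pairs = candidate_pairs([snp], index, library, genes)
    assert ("rsA", "G1", 1) in pairs
    # G2 spans fragments 3,4,5; counts 2 (F3) + 3 (F5) = 5
    assert ("rsA", "G2", 5) in pairs
    assert len(pairs) == 2


def test_candidate_pairs_empty_without_contacts(tiny):
    index, genes, library = tiny
    assert candidate_pairs([Variant("rsB", "chr1", 650)], index, library, genes) == set()


def test_candidate_pairs_unlocatable_snp_raises(tiny):
    index, genes, library = tiny
    with pytest.raises(IndexError):
        candidate_pairs([Variant("rsC", "chr1", 10_000)], index, library, genes)


@pytest.mark.parametrize(
    "snp,gene_span,gene_chrom,expected",
    [
        ((("chr1"), 500_000), (600_000, 700_000), "chr1", "cis"),
        ((("chr1"), 0), (2_000_000, 2_100_000), "chr1", "trans_intra"),
        ((("chr14"), 100), (200, 300), "chr15", "trans_inter"),
        ((("chr1"), 0), (1_000_000, 1_000_050), "chr1", "cis"),  # distance exactly 1 Mb
        ((("chr1"), 650_000), (600_000, 700_000), "chr1", "cis"),  # inside span
    ],
)
def test_classify_interaction(snp, gene_span, gene_chrom, expected):
    chrom, pos = snp
    gene = Gene("G", "G", gene_chrom, *gene_span, "+")
    assert classify_interaction(Variant("rs", chrom, pos), gene) == expected


def _eqtls(rows):
    return pd.DataFrame(rows, columns=["rsid", "gene_id", "nominal_p", "effect_size"])


def test_call_interactions_bh_worked_example(tiny):
    index, genes, _ = tiny
    snps = {f"rs{i}": Variant(f"rs{i}", "chr1", 10 * i) for i in range(1, 5)}
    pairs = {(f"rs{i}", "G1", 1) for i in range(1, 5)}
    eqtls = _eqtls([(f"rs{i}", "G1", 0.01 * i, 0.5) for i in range(1, 5)])
    hits = call_interactions(pairs, eqtls, snps, genes, fdr_threshold=0.05)
    assert len(hits) == 4
    assert all(it.adjusted_p == pytest.approx(0.04) for it in hits)


def test_call_interactions_drops_and_errors(tiny):
    index, genes, _ = tiny
    snps = {"rs1": Variant("rs1", "chr1", 10)}
    pairs = {("rs1", "G1", 1)}
    assert call_interactions(pairs, _eqtls([("rs1", "G1", 0.2, 0.1)]), snps, genes) == []
    # pair with no eQTL record is dropped before testing
    assert call_interactions(pairs, _eqtls([("rsX", "G1", 1e-9, 0.1)]), snps, genes) == []
    with pytest.raises(ValueError):
        call_interactions(pairs, _eqtls([("rs1", "G1", 0.001, 0.1)]), snps, genes,
                          fdr_threshold=1.5)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    pvec=st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=120)
)
def test_bh_matches_oracle_and_never_gains_discoveries(pvec):
    adjusted = bh_adjust(pvec)
    assert np.allclose(adjusted, bh_oracle(pvec), rtol=1e-12, atol=0)
    for threshold in (0.01, 0.05, 0.1):
        assert (adjusted < threshold).sum() <= (np.asarray(pvec) < threshold).sum()


def test_build_grn_recovers_planted_pairs(default_dataset):
    """All planted pairs (p <= 1e-6) survive per-chromosome BH at FDR 0.05."""
    ds = default_dataset
    grn = build_grn(
        eqtl_table_variants(ds.eqtls), ds.index, ds.library, ds.annotation, ds.eqtls
    )
    recovered = {(i.rsid, i.gene_id) for i in grn.interactions}
    assert ds.ledger.true_pairs <= recovered
    # low-MAF variants are excluded before candidate generation
    assert not {i.rsid for i in grn.interactions} & set(ds.ledger.low_maf_rsids)


def test_build_grn_empty_snp_set(default_dataset):
    ds = default_dataset
    grn = build_grn([], ds.index, ds.library, ds.annotation, ds.eqtls)
    assert len(grn) == 0 and grn.genes == set()


def test_grn_indices_are_mutually_consistent(small_result):
    grn = small_result.grn
    for rsid in grn.eqtls:
        for gene in grn.genes_for(rsid):
            assert rsid in grn.eqtls_for(gene)
    assert len(grn) >= len(grn.eqtls)  # every eQTL has >= 1 interaction


def test_interaction_class_trichotomy(small_result):
    classes = {i.interaction_class for i in small_result.grn.interactions}
    assert classes <= {"cis", "trans_intra", "trans_inter"}
    assert all(i.supporting_contacts >= 1 for i in small_result.grn.interactions)


def test_annotate_variant_context():
    genes = GeneAnnotation(
        [Gene("G1", "G1", "chr1", 1000, 2000, "+", exons=((1000, 1200), (1800, 2000)))]
    )
    assert annotate_variant_context(Variant("a", "chr1", 1100), genes) == "exonic"
    assert annotate_variant_context(Variant("b", "chr1", 1500), genes) == "intronic"
    assert annotate_variant_context(Variant("c", "chr1", 50_000), genes) == "intergenic"


def test_summarize_grn_hand_counts():
    def si(rsid, gene, cls):
        from comorbidnet import SpatialInteraction

        return SpatialInteraction(rsid, gene, 1e-9, 1e-8, cls, 1, 0.5)

    grn = GRN([si("s1", "g1", "cis"), si("s1", "g2", "cis"), si("s2", "g3", "trans_inter")])
    summary = summarize_grn(grn)
    assert summary["genes_per_eqtl"] == {1: 1, 2: 1}
    assert summary["class_counts"] == {"cis": 2, "trans_intra": 0, "trans_inter": 1}
    empty = summarize_grn(GRN([]))
    assert empty["n_interactions"] == 0 and empty["genes_per_eqtl"] == {}


def test_summary_biotype_counts_conserve_gene_total(small_result, small_dataset):
    summary = summarize_grn(small_result.grn, small_dataset.annotation)
    assert sum(summary["biotype_counts"].values()) == summary["n_genes"]


def test_grn_tsv_round_trip(tmp_path, small_result):
    path = tmp_path / "grn.tsv"
    small_result.grn.write_tsv(path)
    loaded = GRN.read_tsv(path)
    assert [(i.rsid, i.gene_id, i.interaction_class) for i in loaded.interactions] == [
        (i.rsid, i.gene_id, i.interaction_class) for i in small_result.grn.interactions
    ]
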