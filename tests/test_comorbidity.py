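"""Level expansion, hypergeometric enrichment and the comorbidity scan."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from _oracles import bfs_distances, hypergeom_tail_exact
from comorbidnet import (
    GRN,
    RunConfig,
    SimulationConfig,
    eqtls_for_genes,
    generate_all,
    hypergeom_tail,
    level_expansion,
    run_multimorbid,
    run_pipeline_dataset,
    trait_enrichment,
)
from comorbidnet.spatial_eqtl import SpatialInteraction


def _grn(pairs):
    return GRN(
        SpatialInteraction(r, g, 1e-9, 1e-8, "cis", 1, 0.5) for r, g in pairs
    )


# --- level expansion --------------------------------------------------------

def test_level_expansion_path_and_triangle():
    path = nx.Graph([("a", "b"), ("b", "c")])
    assert level_expansion(path, {"a"}) == [{"a"}, {"b"}, {"c"}]
    triangle = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
    assert level_expansion(triangle, {"a"}) == [{"a"}, {"b", "c"}]


def test_level_expansion_absent_gene_warns():
    graph = nx.Graph([("a", "b")])
    with pytest.warns(UserWarning, match="absent"):
        levels = level_expansion(graph, {"a", "ghost"})
    assert levels[0] == {"a"}


def test_level_expansion_max_level_zero():
    graph = nx.Graph([("a", "b")])
    assert level_expansion(graph, {"a"}, max_level=0) == [{"a"}]


def test_level_shells_match_bfs_distance_oracle():
    rng = np.random.default_rng(11)
    for _ in range(30):
        n = int(rng.integers(10, 200))
        graph = nx.gnp_random_graph(n, 3 / n, seed=int(rng.integers(0, 2**31)))
        sources = set(rng.choice(n, size=max(1, n // 20), replace=False).tolist())
        levels = level_expansion(graph, sources, max_level=6)
        dist = bfs_distances({u: set(graph.neighbors(u)) for u in graph.nodes}, sources)
        for k, shell in enumerate(levels):
            assert shell == {u for u, d in dist.items() if d == k}


# --- eQTL collection --------------------------------------------------------

def test_eqtls_for_genes_union_dedup():
    grn = _grn([("s1", "g1"), ("s2", "g1"), ("s2", "g2")])
    assert eqtls_for_genes(grn, {"g1"}) == {"s1", "s2"}
    assert eqtls_for_genes(grn, {"g3"}) == set()
    assert eqtls_for_genes(grn, {"g1", "g2"}) == {"s1", "s2"}


# --- hypergeometric tail ----------------------------------------------------

def test_hypergeom_tail_examples():
    assert hypergeom_tail(0, 50, 10, 5) == 1.0
    assert hypergeom_tail(5, 20, 5, 5) == pytest.approx(1 / 15504, rel=1e-9)
    assert hypergeom_tail(1, 10, 5, 2) == pytest.approx(35 / 45, rel=1e-9)


def test_hypergeom_tail_domain_errors():
    for k, N, K, n in [(3, 10, 2, 5), (1, 10, 11, 2), (1, 10, 5, 11), (-1, 10, 5, 5)]:
        with pytest.raises(ValueError):
            hypergeom_tail(k, N, K, n)


def test_hypergeom_tail_exhaustive_small_populations():
    for N in range(1, 13):
        for K in range(N + 1):
            for n in range(N + 1):
                previous = None
                for k in range(min(n, K) + 1):
                    p = hypergeom_tail(k, N, K, n)
                    exact = float(hypergeom_tail_exact(k, N, K, n))
                    assert p == pytest.approx(exact, rel=1e-10, abs=1e-15)
                    if previous is not None:
                        assert p <= previous + 1e-15  # non-increasing in k
                    previous = p


# --- trait enrichment -------------------------------------------------------

def _catalog(trait_snps: dict[str, list[str]], extra_rsids=()):
    rows = [(rsid, trait) for trait, snps in trait_snps.items() for rsid in snps]
    rows += [(rsid, "background_trait") for rsid in extra_rsids]
    return pd.DataFrame(rows, columns=["rsid", "trait"])


def test_trait_enrichment_worked_example():
    """Catalog of 100 rsIDs, trait T on 10; sample 5 in catalog, 3 with T."""
    all_rsids = [f"rs{i}" for i in range(100)]
    catalog = _catalog({"T": all_rsids[:10]}, extra_rsids=all_rsids[10:])
    level_eqtls = all_rsids[:3] + all_rsids[50:52]  # 3 with T, 2 without
    table = trait_enrichment(level_eqtls, catalog)
    row = table[table["trait"] == "T"].iloc[0]
    assert row["k"] == 3 and row["n"] == 5 and row["K"] == 10 and row["N"] == 100
    expected = float(hypergeom_tail_exact(3, 100, 10, 5))
    assert row["p"] == pytest.approx(expected, rel=1e-9)
    # exact: (C(10,3)C(90,2) + C(10,4)C(90,1) + C(10,5)) / C(100,5) = 499752/75287520
    assert expected == pytest.approx(499752 / 75287520, rel=1e-12)


def test_trait_enrichment_zero_overlap_not_tested():
    catalog = _catalog({"T": ["rs1", "rs2"], "U": ["rs3"]})
    table = trait_enrichment(["rs1"], catalog)
    assert set(table["trait"]) == {"T"}  # U has no overlap


def test_trait_enrichment_single_trait_catalog_fdr_equals_p():
    catalog = _catalog({"T": [f"rs{i}" for i in range(10)]})
    table = trait_enrichment(["rs0", "rs1"], catalog)
    assert table["fdr"].iloc[0] == pytest.approx(table["p"].iloc[0])


def test_trait_enrichment_family_spans_all_catalog_traits():
    """Zero-overlap traits still widen the BH family (p padded with ones)."""
    snps = {f"T{i}": [f"rs{100 + i}"] for i in range(9)}
    snps["T_hit"] = ["rs0", "rs1", "rs2"]
    catalog = _catalog(snps)
    table = trait_enrichment(["rs0", "rs1", "rs2"], catalog)
    row = table[table["trait"] == "T_hit"].iloc[0]
    assert row["fdr"] == pytest.approx(min(1.0, row["p"] * 10))  # m = 10 traits


def test_trait_enrichment_disjoint_sample_warns():
    catalog = _catalog({"T": ["rs1"]})
    with pytest.warns(UserWarning):
        table = trait_enrichment(["rsX"], catalog)
    assert table.empty


def test_flagged_sets_nest_across_thresholds():
    rng = np.random.default_rng(2)
    all_rsids = [f"rs{i}" for i in range(300)]
    trait_snps = {
        f"T{i}": list(rng.choice(all_rsids, size=20, replace=False)) for i in range(15)
    }
    catalog = _catalog(trait_snps)
    sample = list(rng.choice(all_rsids, size=40, replace=False))
    loose = trait_enrichment(sample, catalog, fdr_threshold=0.5)
    tight = trait_enrichment(sample, catalog, fdr_threshold=0.05)
    assert set(tight.loc[tight["flagged"], "trait"]) <= set(
        loose.loc[loose["flagged"], "trait"]
    )


def test_trait_enrichment_empty_catalog_is_error():
    with pytest.raises(ValueError):
        trait_enrichment(["rs1"], pd.DataFrame(columns=["rsid", "trait"]))


# --- full comorbidity scan --------------------------------------------------

def test_planted_trait_flagged_only_at_its_level(small_dataset, small_result):
    ledger = small_dataset.ledger
    for res in small_result.enrichment:
        flagged = set(res.flagged_traits)
        if res.level == ledger.planted_trait_level:
            assert ledger.planted_trait in flagged
        else:
            assert ledger.planted_trait not in flagged


def test_run_multimorbid_max_level_zero(small_dataset, small_result):
    results = run_multimorbid(
        small_dataset.ledger.seed_snps,
        small_result.grn,
        nx.Graph([("a", "b")]),
        small_dataset.catalog,
        max_level=0,
    )
    assert len(results) == 1 and results[0].level == 0


def test_run_multimorbid_no_targets_is_error(small_dataset, small_result):
    with pytest.raises(ValueError, match="no target genes"):
        run_multimorbid(
            ["rs_not_in_grn"], small_result.grn, nx.Graph(), small_dataset.catalog
        )
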