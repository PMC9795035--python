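"""Tissue-filtered protein-protein interaction networks.

High-confidence protein links (combined score >= 0.7 by default) are
collapsed to an undirected gene-level graph via a protein -> gene mapping.
The tissue-specific PPIN keeps only genes that are eQTL targets in the
tissue GRN; condition-specific subnetworks are the connected components of
the graph induced on a seed gene set.

Scores are accepted on either the 0-1000 integer dialect or the 0-1
fraction dialect, auto-detected per table and normalised to fractions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .spatial_eqtl import GRN

__all__ = ["load_ppi", "tissue_filter", "seed_subnetworks", "write_edges_tsv", "read_edges_tsv"]


def _normalise_scores(scores: pd.Series) -> pd.Series:
    values = pd.to_numeric(scores, errors="raise").astype(float)
    if (values < 0).any():
        raise ValueError("negative combined score")
    if values.max() > 1.0:  # 0-1000 STRING file dialect
        if values.max() > 1000:
            raise ValueError("combined score above 1000")
        values = values / 1000.0
    return values


def load_ppi(
    edges: pd.DataFrame | str | Path,
    mapping: pd.DataFrame | str | Path,
    score_min: float = 0.7,
) -> nx.Graph:
    """Build the gene-level PPI graph from a protein link table.

    Links below ``score_min`` are dropped; protein pairs are collapsed to
    gene pairs keeping the maximum score; reciprocal and duplicate records
    collapse to one undirected edge; gene-level self-loops (two proteins of
    one gene) are discarded.  The count of link endpoints whose protein has
    no gene mapping is stored in ``graph.graph["unmapped_proteins"]``.
    """
    if isinstance(edges, (str, Path)):
        edges = pd.read_csv(edges, sep="\t")
    if isinstance(mapping, (str, Path)):
        mapping = pd.read_csv(mapping, sep="\t")
    protein_to_gene = dict(zip(mapping["protein_id"], mapping["gene_id"]))

    scores = _normalise_scores(edges["combined_score"])
    kept = edges.loc[scores >= score_min].assign(score=scores[scores >= score_min])

    graph = nx.Graph(provenance="full", score_min=score_min)
    unmapped: set[str] = set()
    for row in kept.itertuples(index=False):
        gene_a = protein_to_gene.get(row.protein1)
        gene_b = protein_to_gene.get(row.protein2)
        if gene_a is None:
            unmapped.add(row.protein1)
        if gene_b is None:
            unmapped.add(row.protein2)
        if gene_a is None or gene_b is None or gene_a == gene_b:
            continue
        prev = graph.edges.get((gene_a, gene_b), {}).get("score", 0.0)
        graph.add_edge(gene_a, gene_b, score=max(prev, float(row.score)))
    graph.graph["unmapped_proteins"] = len(unmapped)
    return graph


def tissue_filter(graph: nx.Graph, grn: GRN) -> nx.Graph:
    """Restrict the PPI graph to genes present as eQTL targets in the GRN.

    Coverage fractions (nodes/edges retained over totals) are stored in
    the returned graph's ``graph`` attributes.
    """
    keep = set(graph.nodes) & grn.genes
    filtered = nx.Graph(graph.subgraph(keep))
    filtered.graph.update(graph.graph)
    filtered.graph["provenance"] = "tissue_filtered"
    filtered.graph["node_retention"] = (
        filtered.number_of_nodes() / graph.number_of_nodes() if graph.number_of_nodes() else 0.0
    )
    filtered.graph["edge_retention"] = (
        filtered.number_of_edges() / graph.number_of_edges() if graph.number_of_edges() else 0.0
    )
    return filtered


def seed_subnetworks(
    graph: nx.Graph, seed_genes: Iterable[str]
) -> tuple[list[set[str]], set[str]]:
    """Connected components of the subgraph induced on seed genes.

    Returns (subnetworks, singletons): components with >= 2 nodes sorted
    by size descending then lexicographically by smallest member, and the
    seed genes left isolated (including seeds absent from the graph).
    """
    seeds = set(seed_genes)
    induced = graph.subgraph(seeds & set(graph.nodes))
    components = [set(c) for c in nx.connected_components(induced)]
    subnetworks = sorted(
        (c for c in components if len(c) >= 2),
        key=lambda c: (-len(c), min(c)),
    )
    connected = set().union(*subnetworks) if subnetworks else set()
    singletons = seeds - connected
    return subnetworks, singletons


def write_edges_tsv(graph: nx.Graph, path: str | Path) -> None:
    rows = sorted((min(a, b), max(a, b), d["score"]) for a, b, d in graph.edges(data=True))
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for a, b, score in rows:
            fh.write(f"{a}\t{b}\t{score:.3f}\n")


def read_edges_tsv(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    graph = nx.Graph(provenance="full")
    for row in df.itertuples(index=False):
        graph.add_edge(row.gene_a, row.gene_b, score=float(row.score))
    return graph
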