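"""Gene annotation: GTF-style gene/exon records with interval queries.

Internally everything is 0-based half-open; GTF input (1-based inclusive)
is converted on read and back on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from intervaltree import IntervalTree

__all__ = ["Gene", "GeneAnnotation", "read_gtf", "write_gtf"]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    symbol: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    biotype: str = "protein_coding"
    exons: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")


class GeneAnnotation:
    """Indexed gene set supporting overlap and point queries."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {}
        self._gene_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        for gene in genes:
            if gene.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id: {gene.gene_id}")
            self.genes[gene.gene_id] = gene
            self._gene_trees.setdefault(gene.chrom, IntervalTree()).addi(
                gene.start, gene.end, gene.gene_id
            )
            for ex_start, ex_end in gene.exons:
                self._exon_trees.setdefault(gene.chrom, IntervalTree()).addi(
                    ex_start, ex_end, gene.gene_id
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    def overlapping(self, chrom: str, start: int, end: int) -> set[str]:
        """gene_ids whose span intersects [start, end) on chrom."""
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    def genes_at(self, chrom: str, pos: int) -> set[str]:
        return self.overlapping(chrom, pos, pos + 1)

    def exonic_at(self, chrom: str, pos: int) -> bool:
        tree = self._exon_trees.get(chrom)
        return bool(tree is not None and tree.overlap(pos, pos + 1))


def _parse_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gtf(path: str | Path) -> GeneAnnotation:
    """Read gene and exon records from a GTF file into a GeneAnnotation."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=[
            "chrom", "source", "feature", "start", "end",
            "score", "strand", "frame", "attributes",
        ],
        dtype={"chrom": str},
    )
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        attrs = _parse_attributes(row.attributes)
        gene_id = attrs.get("gene_id", "")
        start0, end0 = int(row.start) - 1, int(row.end)  # GTF is 1-based inclusive
        if row.feature == "gene":
            genes[gene_id] = dict(
                gene_id=gene_id,
                symbol=attrs.get("gene_name", gene_id),
                chrom=row.chrom,
                start=start0,
                end=end0,
                strand=row.strand,
                biotype=attrs.get("gene_biotype", attrs.get("gene_type", "protein_coding")),
            )
        elif row.feature == "exon":
            exons.setdefault(gene_id, []).append((start0, end0))
    return GeneAnnotation(
        Gene(**info, exons=tuple(sorted(exons.get(gid, ()))))
        for gid, info in genes.items()
    )


def write_gtf(annotation: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in annotation.genes.values():
            attrs = (
                f'gene_id "{gene.gene_id}"; gene_name "{gene.symbol}"; '
                f'gene_biotype "{gene.biotype}";'
            )
            fh.write(
                f"{gene.chrom}\tsynthetic\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )
            for ex_start, ex_end in gene.exons:
                fh.write(
                    f"{gene.chrom}\tsynthetic\texon\t{ex_start + 1}\t{ex_end}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )
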