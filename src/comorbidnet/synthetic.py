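"""Synthetic pipeline inputs with planted, ledgered ground truth.

Every input the pipeline consumes — genome FASTA, gene annotation, Hi-C
contact text, eQTL table, protein links and mapping, GWAS catalog — is
generated at desk scale with known structure planted into it:

* *planted interactions*: seed-condition SNP-gene pairs given both Hi-C
  contacts and a strongly significant eQTL record (p <= 1e-6 by default);
* *PPI shells*: genes wired so that level-k shell genes sit at graph
  distance exactly k from the level-0 (seed target) genes, each with its
  own planted GRN eQTLs;
* *planted trait*: a GWAS-catalog trait whose SNP set over-samples the
  eQTLs of one shell level;

plus null structure: spatial SNP-gene pairs with Uniform(0,1) eQTL
p-values, background contacts, eQTL rows without spatial support, and
uniformly scattered catalog traits.  The :class:`TruthLedger` records all
planted entities so recovery can be scored without consulting generator
internals.

The default configuration is the package's reference study condition:
2 chromosomes x 2 Mb, ~100 restriction sites per chromosome, 60 genes,
20 planted interactions over ~12 target genes, 200 null pairs, shells
[5, 8, 10, 10, 10], a 2,000-SNP / 50-trait catalog, and the planted trait
at level 2 with 0.8 overlap.

Everything is deterministic under ``rng_seed``; each generation stage
draws from its own child stream so stages are individually reproducible.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import Gene, GeneAnnotation, write_gtf
from .genome_digest import HINDIII, EnzymeSpec, FragmentIndex, build_fragment_index
from .hic import ContactLibrary, parse_contacts
from .spatial_eqtl import Variant, classify_interaction

__all__ = [
    "SimulationConfig",
    "TruthLedger",
    "SyntheticDataset",
    "generate_genome",
    "generate_spatial_truth",
    "generate_network_truth",
    "generate_all",
    "write_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    rng_seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 2_000_000
    site_density_per_kb: float = 0.05  # expected recognition sites per kb
    n_genes: int = 60
    n_snps: int = 500  # variants appearing in the eQTL table
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_planted_interactions: int = 20
    planted_p_ceiling: float = 1e-6
    n_null_interactions: int = 200
    contacts_per_planted_pair: int = 3
    background_contacts: int = 500
    n_duplicate_records: int = 20
    n_low_mapq_records: int = 20
    ppi_shell_sizes: tuple[int, ...] = (5, 8, 10, 10, 10)
    n_catalog_snps: int = 2000
    n_traits: int = 50
    trait_size_range: tuple[int, int] = (5, 40)
    planted_trait_level: int | None = 2
    planted_trait_overlap_fraction: float = 0.8
    seed_trait: str = "seed_condition"
    planted_trait: str = "planted_trait"
    tissue: str = "lung"
    enzyme: EnzymeSpec = field(default_factory=lambda: HINDIII)

    def validate(self) -> None:
        if min(self.n_chromosomes, self.chrom_length_bp, self.n_genes) <= 0:
            raise ValueError("genome dimensions must be positive")
        if self.planted_p_ceiling >= 0.05:
            raise ValueError("planted_p_ceiling must sit below any significance threshold")
        if self.planted_trait_level is not None and self.planted_trait_level > len(
            self.ppi_shell_sizes
        ):
            raise ValueError(
                f"planted_trait_level {self.planted_trait_level} beyond the "
                f"{len(self.ppi_shell_sizes)} configured shells"
            )
        if not (0 <= self.planted_trait_overlap_fraction <= 1):
            raise ValueError("planted_trait_overlap_fraction outside [0, 1]")
        if self.n_snps > self.n_catalog_snps:
            raise ValueError("eQTL variants must be drawn from the catalog SNP pool")


@dataclass
class TruthLedger:
    seed_trait: str
    seed_snps: list[str]
    planted_pairs: list[tuple[str, str, str]]  # (rsid, gene_id, class)
    shell_pairs: list[tuple[str, str, str, int]]  # (rsid, gene_id, class, level)
    null_pairs: list[tuple[str, str]]
    low_maf_rsids: list[str]
    shells: list[list[str]]  # index 0 = level-0 genes
    decoy_genes: list[str]
    planted_trait: str | None
    planted_trait_level: int | None
    planted_trait_snps: list[str]

    @property
    def planted_gene_ids(self) -> set[str]:
        return {g for _, g, _ in self.planted_pairs}

    @property
    def true_pairs(self) -> set[tuple[str, str]]:
        """All (rsid, gene) pairs planted as genuinely significant."""
        return {(r, g) for r, g, _ in self.planted_pairs} | {
            (r, g) for r, g, _, _ in self.shell_pairs
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        raw = json.loads(Path(path).read_text())
        raw["planted_pairs"] = [tuple(x) for x in raw["planted_pairs"]]
        raw["shell_pairs"] = [tuple(x) for x in raw["shell_pairs"]]
        raw["null_pairs"] = [tuple(x) for x in raw["null_pairs"]]
        return cls(**raw)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: dict[str, str]
    annotation: GeneAnnotation
    index: FragmentIndex
    contact_lines: list[str]
    library: ContactLibrary
    eqtls: pd.DataFrame  # rsid, gene_id, tissue, chrom, pos(0-based), maf, nominal_p, effect_size
    catalog: pd.DataFrame  # rsid, chrom, pos(0-based), trait, p
    ppi_links: pd.DataFrame  # protein1, protein2, combined_score (0-1000)
    protein_map: pd.DataFrame  # protein_id, gene_id
    ledger: TruthLedger


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def _random_sequence_without_site(
    length: int, site: str, rng: np.random.Generator
) -> str:
    seq = bytearray(_BASES[rng.integers(0, 4, size=length)].tobytes())
    # scrub chance occurrences so site density is controlled by injection only
    pattern = re.compile(site.encode())
    while True:
        hits = [m.start() for m in pattern.finditer(bytes(seq))]
        if not hits:
            return seq.decode()
        for start in hits:
            mid = start + len(site) // 2
            seq[mid] = ord("C") if seq[mid] != ord("C") else ord("G")


def generate_genome(config: SimulationConfig) -> tuple[dict[str, str], GeneAnnotation]:
    """Random genome with injected restriction sites and non-overlapping genes."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    site = config.enzyme.recognition_site
    genome: dict[str, str] = {}
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        seq = _random_sequence_without_site(config.chrom_length_bp, site, rng)
        n_sites = int(round(config.site_density_per_kb * config.chrom_length_bp / 1000))
        if n_sites:
            raw = np.sort(
                rng.choice(config.chrom_length_bp - len(site), size=n_sites, replace=False)
            )
            positions = [p for i, p in enumerate(raw) if i == 0 or p - raw[i - 1] > 2 * len(site)]
            arr = bytearray(seq.encode())
            for p in positions:
                arr[p : p + len(site)] = site.encode()
            seq = arr.decode()
        genome[chrom] = seq

    genes: list[Gene] = []
    per_chrom = -(-config.n_genes // config.n_chromosomes)  # ceil
    gene_no = 0
    biotypes = np.array(["protein_coding", "ncRNA", "pseudogene"])
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        slot = config.chrom_length_bp // (per_chrom + 1)
        if slot < 2000:
            raise ValueError("chromosome too short to place the requested genes")
        for g in range(per_chrom):
            if gene_no >= config.n_genes:
                break
            max_len = min(12_000, slot - 200)
            length = int(rng.integers(4_000, max_len)) if max_len > 4_000 else max_len
            offset = int(rng.integers(0, slot - length))
            start = g * slot + offset
            end = start + length
            n_exons = int(rng.integers(1, 4))
            exon_span = length // (2 * n_exons)
            exons = tuple(
                (start + 2 * i * exon_span, start + (2 * i + 1) * exon_span)
                for i in range(n_exons)
            )
            gene_no += 1
            genes.append(
                Gene(
                    gene_id=f"GENE{gene_no:04d}",
                    symbol=f"SYM{gene_no}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    biotype=str(rng.choice(biotypes, p=[0.8, 0.15, 0.05])),
                    exons=exons,
                )
            )
    return genome, GeneAnnotation(genes)


# ---------------------------------------------------------------------------
# spatial truth: contacts + eQTL table
# ---------------------------------------------------------------------------

class _ContactWriter:
    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.lines: list[str] = []
        self._read_no = 0

    def record(
        self,
        index: FragmentIndex,
        end1: tuple[str, int],
        end2: tuple[str, int],
        mapq: int = 60,
        pos_override: tuple[int, int] | None = None,
    ) -> tuple[int, int]:
        """Append one merged_nodups-style line between two fragments (chrom, frag_id)."""
        self._read_no += 1
        frag_a = index.fragment(*end1)
        frag_b = index.fragment(*end2)
        if pos_override is not None:
            pos1, pos2 = pos_override
        else:
            pos1 = int(self.rng.integers(frag_a.start, frag_a.end)) + 1  # 1-based file coords
            pos2 = int(self.rng.integers(frag_b.start, frag_b.end)) + 1
        str1 = int(self.rng.choice([0, 16]))
        str2 = int(self.rng.choice([0, 16]))
        self.lines.append(
            f"read{self._read_no} {str1} {frag_a.chrom} {pos1} {frag_a.frag_id} {mapq} "
            f"{str2} {frag_b.chrom} {pos2} {frag_b.frag_id} {mapq}"
        )
        return pos1, pos2


def _gene_fragments(index: FragmentIndex, gene: Gene) -> list[int]:
    first = index.locate(gene.chrom, gene.start)
    last = index.locate(gene.chrom, gene.end - 1)
    return list(range(first, last + 1))


def generate_spatial_truth(
    config: SimulationConfig,
    genome: dict[str, str],
    annotation: GeneAnnotation,
    index: FragmentIndex,
) -> tuple[list[str], pd.DataFrame, pd.DataFrame, TruthLedger]:
    """Plant contacts and eQTL rows; build the SNP catalog positions.

    Returns (contact lines, eQTL table, catalog SNP frame (rsid/chrom/pos),
    truth ledger).  The catalog frame has no trait labels yet; those are
    assigned by :func:`generate_network_truth`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 2]))
    chroms = list(genome)
    chrom_len = {c: len(s) for c, s in genome.items()}

    # SNP pool: catalog SNPs with positions; the first n_snps (after shuffle)
    # are available to the eQTL table.
    pool = []
    for i in range(config.n_catalog_snps):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(0, chrom_len[chrom]))
        pool.append((f"rs{100000 + i}", chrom, pos))
    rng.shuffle(pool)
    catalog_snps = pd.DataFrame(pool, columns=["rsid", "chrom", "pos"])
    eqtl_pool = pool[: config.n_snps]
    maf_lo, maf_hi = config.maf_range
    maf = {rsid: float(rng.uniform(maf_lo, maf_hi)) for rsid, _, _ in pool}

    gene_ids = list(annotation.genes)
    n_pairs = config.n_planted_interactions
    n_seed_snps = max(1, int(round(n_pairs * 0.75)))
    n_level0 = max(1, int(round(n_pairs * 0.6)))
    shell_total = sum(config.ppi_shell_sizes)
    n_null = config.n_null_interactions
    needed_genes = n_level0 + shell_total
    if needed_genes > len(gene_ids):
        raise ValueError(
            f"config needs {needed_genes} distinct genes for level 0 + shells "
            f"but only {len(gene_ids)} exist"
        )

    cursor = 0

    def take_snps(n: int) -> list[tuple[str, str, int]]:
        nonlocal cursor
        if cursor + n > len(eqtl_pool):
            raise ValueError("eQTL SNP pool exhausted; raise n_snps")
        out = eqtl_pool[cursor : cursor + n]
        cursor += n
        return out

    writer = _ContactWriter(rng)
    eqtl_rows: list[dict] = []

    def plant_pair(snp: tuple[str, str, int], gene: Gene, n_contacts: int, p: float) -> str:
        rsid, chrom, pos = snp
        snp_frag = index.locate(chrom, pos)
        gene_frag = int(rng.choice(_gene_fragments(index, gene)))
        for _ in range(n_contacts):
            writer.record(index, (chrom, snp_frag), (gene.chrom, gene_frag))
        eqtl_rows.append(
            dict(
                rsid=rsid, gene_id=gene.gene_id, tissue=config.tissue,
                chrom=chrom, pos=pos, maf=maf[rsid],
                nominal_p=p,
                effect_size=float(rng.uniform(0.1, 1.5)) * (1 if rng.random() < 0.5 else -1),
            )
        )
        return classify_interaction(Variant(rsid, chrom, pos), gene)

    def planted_p() -> float:
        return float(10 ** rng.uniform(np.log10(config.planted_p_ceiling) - 6,
                                       np.log10(config.planted_p_ceiling)))

    # --- seed-condition planted pairs (level-0 targets)
    seed_snps = take_snps(n_seed_snps)
    level0_genes = gene_ids[:n_level0]
    planted_pairs: list[tuple[str, str, str]] = []
    seen_pairs: set[tuple[str, str]] = set()
    i = 0
    while len(planted_pairs) < n_pairs:
        snp = seed_snps[i % n_seed_snps]
        gene_id = level0_genes[i % n_level0]
        i += 1
        if (snp[0], gene_id) in seen_pairs:
            continue
        seen_pairs.add((snp[0], gene_id))
        cls = plant_pair(snp, annotation[gene_id], config.contacts_per_planted_pair,
                         planted_p())
        planted_pairs.append((snp[0], gene_id, cls))

    # --- shell genes, each with its own planted GRN eQTLs
    shells: list[list[str]] = [list(level0_genes)]
    shell_pairs: list[tuple[str, str, str, int]] = []
    offset = n_level0
    for level, size in enumerate(config.ppi_shell_sizes, start=1):
        members = gene_ids[offset : offset + size]
        offset += size
        shells.append(members)
        for gene_id in members:
            for snp in take_snps(int(rng.integers(1, 3))):
                cls = plant_pair(snp, annotation[gene_id],
                                 config.contacts_per_planted_pair, planted_p())
                shell_pairs.append((snp[0], gene_id, cls, level))
    decoy_genes = gene_ids[offset:]

    # --- null spatial pairs: contacts present, eQTL p uniform
    null_pairs: list[tuple[str, str]] = []
    for snp in take_snps(min(n_null, len(eqtl_pool) - cursor)):
        gene_id = gene_ids[int(rng.integers(0, len(gene_ids)))]
        if (snp[0], gene_id) in seen_pairs:
            continue
        seen_pairs.add((snp[0], gene_id))
        plant_pair(snp, annotation[gene_id], 1 + int(rng.integers(0, 2)),
                   float(max(rng.uniform(), 1e-12)))
        null_pairs.append((snp[0], gene_id))

    # --- spatial pairs from low-MAF variants (excluded by the GRN MAF filter)
    low_maf_rsids: list[str] = []
    for snp in take_snps(min(3, len(eqtl_pool) - cursor)):
        maf[snp[0]] = float(rng.uniform(0.005, 0.049))
        gene_id = gene_ids[int(rng.integers(0, len(gene_ids)))]
        plant_pair(snp, annotation[gene_id], 1, planted_p())
        low_maf_rsids.append(snp[0])

    # --- eQTL rows with no spatial support (dropped at the Hi-C join)
    for snp in take_snps(min(30, len(eqtl_pool) - cursor)):
        rsid, chrom, pos = snp
        eqtl_rows.append(
            dict(rsid=rsid, gene_id=gene_ids[int(rng.integers(0, len(gene_ids)))],
                 tissue=config.tissue, chrom=chrom, pos=pos, maf=maf[rsid],
                 nominal_p=float(max(rng.uniform(), 1e-12)),
                 effect_size=float(rng.uniform(0.1, 1.5)))
        )

    # --- background contacts, positional duplicates, low-mapq records
    for _ in range(config.background_contacts):
        c1 = chroms[int(rng.integers(0, len(chroms)))]
        c2 = chroms[int(rng.integers(0, len(chroms)))]
        f1 = index.locate(c1, int(rng.integers(0, chrom_len[c1])))
        f2 = index.locate(c2, int(rng.integers(0, chrom_len[c2])))
        writer.record(index, (c1, f1), (c2, f2))
    base = len(writer.lines)
    for _ in range(config.n_duplicate_records):
        # re-emit an existing record's positions under a fresh read name
        src = writer.lines[int(rng.integers(0, base))].split()
        writer.record(
            index, (src[2], int(src[4])), (src[7], int(src[9])),
            pos_override=(int(src[3]), int(src[8])),
        )
        # keep the duplicate's strands identical to the source record
        parts = writer.lines[-1].split()
        parts[1], parts[6] = src[1], src[6]
        writer.lines[-1] = " ".join(parts)
    for _ in range(config.n_low_mapq_records):
        c1 = chroms[int(rng.integers(0, len(chroms)))]
        f1 = index.locate(c1, int(rng.integers(0, chrom_len[c1])))
        writer.record(index, (c1, f1), (c1, f1), mapq=int(rng.integers(0, 30)))

    eqtls = pd.DataFrame(eqtl_rows).drop_duplicates(subset=["rsid", "gene_id"])
    ledger = TruthLedger(
        seed_trait=config.seed_trait,
        seed_snps=[s[0] for s in seed_snps],
        planted_pairs=planted_pairs,
        shell_pairs=shell_pairs,
        null_pairs=null_pairs,
        low_maf_rsids=low_maf_rsids,
        shells=shells,
        decoy_genes=list(decoy_genes),
        planted_trait=None,
        planted_trait_level=None,
        planted_trait_snps=[],
    )
    return writer.lines, eqtls, catalog_snps, ledger


# ---------------------------------------------------------------------------
# network truth: PPI shells + GWAS catalog traits
# ---------------------------------------------------------------------------

def generate_network_truth(
    config: SimulationConfig,
    catalog_snps: pd.DataFrame,
    eqtls: pd.DataFrame,
    ledger: TruthLedger,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Wire the PPI shells and assign catalog trait labels.

    Returns (ppi_links, protein_map, catalog) and updates the ledger with
    the planted trait in place.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 3]))
    protein_of = {g: f"P_{g}" for g in _all_genes(ledger)}

    def score() -> int:
        return int(rng.integers(700, 1001))

    edges: list[tuple[str, str, int]] = []
    shells = ledger.shells
    # level-0 internal edges (pairs) so seed subnetworks are non-trivial
    level0 = shells[0]
    for a, b in zip(level0[::2], level0[1::2]):
        edges.append((protein_of[a], protein_of[b], score()))
    # consecutive-shell wiring: each level-k gene touches 1-2 level-(k-1) genes
    for k in range(1, len(shells)):
        for gene in shells[k]:
            parents = rng.choice(shells[k - 1], size=min(len(shells[k - 1]),
                                                         int(rng.integers(1, 3))),
                                 replace=False)
            for parent in parents:
                edges.append((protein_of[gene], protein_of[parent], score()))
    # decoy edges strictly among leftover genes, plus rejected structure
    decoys = ledger.decoy_genes
    for _ in range(max(0, len(decoys) - 1)):
        a, b = rng.choice(decoys, size=2, replace=False)
        if a != b:
            edges.append((protein_of[a], protein_of[b], score()))
    if len(decoys) >= 2:
        a, b = decoys[0], decoys[1]
        edges.append((protein_of[a], protein_of[b], int(rng.integers(0, 700))))  # sub-threshold
        edges.append((protein_of[b], protein_of[a], score()))  # reciprocal duplicate
        edges.append((f"ALT_{a}", protein_of[b], score()))  # second protein of gene a
        edges.append(("P_UNMAPPED", protein_of[a], score()))  # unmapped protein

    ppi_links = pd.DataFrame(edges, columns=["protein1", "protein2", "combined_score"])
    mapping_rows = [(p, g) for g, p in sorted(protein_of.items())]
    if len(decoys) >= 2:
        mapping_rows.append((f"ALT_{decoys[0]}", decoys[0]))
    protein_map = pd.DataFrame(mapping_rows, columns=["protein_id", "gene_id"])

    # --- catalog traits
    catalog_rows: list[tuple[str, str, int, str, float]] = []
    snp_pos = {r.rsid: (r.chrom, r.pos) for r in catalog_snps.itertuples(index=False)}

    def add(rsid: str, trait: str, p: float) -> None:
        chrom, pos = snp_pos[rsid]
        catalog_rows.append((rsid, chrom, pos, trait, p))

    def assoc_p() -> float:
        return float(10 ** rng.uniform(-30, -8.5))

    # seed-condition rows: genome-wide significant for the seed SNPs,
    # plus sub-threshold rows that the strict p < 5e-8 filter must exclude
    for rsid in ledger.seed_snps:
        add(rsid, config.seed_trait, assoc_p())
    eqtl_rsids = set(eqtls["rsid"])
    non_eqtl = [r for r in catalog_snps["rsid"] if r not in eqtl_rsids]
    rng.shuffle(non_eqtl)
    sub_threshold = non_eqtl[:3]
    for rsid in sub_threshold:
        add(rsid, config.seed_trait, float(10 ** rng.uniform(-7.2, -5)))
    pad_cursor = 3

    # planted trait: over-samples the eQTLs of the planted level's genes
    planted_snps: list[str] = []
    if config.planted_trait_level is not None:
        level = config.planted_trait_level
        level_genes = set(shells[level])
        level_eqtls = sorted(
            set(eqtls.loc[eqtls["gene_id"].isin(level_genes), "rsid"])
        )
        n_members = max(1, int(round(config.planted_trait_overlap_fraction * len(level_eqtls))))
        members = list(rng.choice(level_eqtls, size=n_members, replace=False))
        n_pads = int(rng.integers(5, 15))
        pads = non_eqtl[pad_cursor : pad_cursor + n_pads]
        pad_cursor += n_pads
        planted_snps = sorted(members) + list(pads)
        for rsid in planted_snps:
            add(rsid, config.planted_trait, assoc_p())
        ledger.planted_trait = config.planted_trait
        ledger.planted_trait_level = level
        ledger.planted_trait_snps = planted_snps

    # scattered null traits over non-eQTL catalog SNPs
    lo, hi = config.trait_size_range
    for t in range(config.n_traits):
        size = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(catalog_snps), size=size, replace=False)
        for idx in chosen:
            add(catalog_snps["rsid"].iat[int(idx)], f"trait_{t:02d}", assoc_p())

    catalog = pd.DataFrame(
        catalog_rows, columns=["rsid", "chrom", "pos", "trait", "p"]
    ).drop_duplicates(subset=["rsid", "trait"], ignore_index=True)
    return ppi_links, protein_map, catalog


def _all_genes(ledger: TruthLedger) -> list[str]:
    out: list[str] = []
    for shell in ledger.shells:
        out.extend(shell)
    out.extend(ledger.decoy_genes)
    return out


# ---------------------------------------------------------------------------
# orchestration + writers
# ---------------------------------------------------------------------------

def generate_all(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate every pipeline input in memory, deterministically."""
    config = config or SimulationConfig()
    config.validate()
    genome, annotation = generate_genome(config)
    index = build_fragment_index(genome, config.enzyme)
    contact_lines, eqtls, catalog_snps, ledger = generate_spatial_truth(
        config, genome, annotation, index
    )
    ppi_links, protein_map, catalog = generate_network_truth(
        config, catalog_snps, eqtls, ledger
    )
    library = parse_contacts(contact_lines)
    return SyntheticDataset(
        config=config,
        genome=genome,
        annotation=annotation,
        index=index,
        contact_lines=contact_lines,
        library=library,
        eqtls=eqtls,
        catalog=catalog,
        ppi_links=ppi_links,
        protein_map=protein_map,
        ledger=ledger,
    )


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write all generated inputs as plain-text files (1-based positions)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("genome", "genome.fa"), ("genes", "genes.gtf"), ("contacts", "contacts.txt"),
        ("eqtls", "eqtls.tsv"), ("ppi_links", "ppi_links.tsv"),
        ("protein_map", "protein_map.tsv"), ("catalog", "gwas_catalog.tsv"),
        ("ledger", "truth_ledger.json"),
    ]}
    write_fasta(dataset.genome, paths["genome"])
    write_gtf(dataset.annotation, paths["genes"])
    paths["contacts"].write_text("\n".join(dataset.contact_lines) + "\n")
    eqtls = dataset.eqtls.copy()
    eqtls["pos"] = eqtls["pos"] + 1
    eqtls.to_csv(paths["eqtls"], sep="\t", index=False)
    dataset.ppi_links.to_csv(paths["ppi_links"], sep="\t", index=False)
    dataset.protein_map.to_csv(paths["protein_map"], sep="\t", index=False)
    catalog = dataset.catalog.copy()
    catalog["pos"] = catalog["pos"] + 1
    catalog.to_csv(paths["catalog"], sep="\t", index=False)
    dataset.ledger.to_json(paths["ledger"])
    return paths
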