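"""End-to-end orchestration: digest -> Hi-C QC -> GRN -> seed mapping ->
PPIN -> level enrichment -> bootstrap, with a machine- and human-readable
summary report.

All tunable thresholds live in :class:`RunConfig` (no stage hard-codes a
constant) and round-trip losslessly through a YAML config file.  Outputs
are plain TSV/JSON/BED with deterministic ordering, so re-running on
identical inputs reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import bootstrap as bootstrap_mod
from .annotation import GeneAnnotation, read_gtf
from .comorbidity import LevelEnrichment, enrichment_dataframe, run_multimorbid
from .genome_digest import EnzymeSpec, FragmentIndex, build_fragment_index, write_fragment_bed
from .hic import ContactLibrary, parse_contacts, qc_contact_library
from .ppin import load_ppi, seed_subnetworks, tissue_filter, write_edges_tsv
from .spatial_eqtl import (
    GRN,
    Variant,
    build_grn,
    call_interactions,
    candidate_pairs,
    eqtl_table_variants,
    filter_gwas_snps,
    read_eqtl_table,
    read_trait_associations,
    summarize_grn,
)
from .synthetic import SyntheticDataset

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_pipeline_dataset", "write_report"]

logger = logging.getLogger("comorbidnet")


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run.

    Thresholds default to the pipeline's standard operating values:
    genome-wide significance 5e-8, GRN FDR 0.05, seed-run FDR 0.05 with a
    0.01 headline tier, mapq >= 30, MAF >= 0.05, PPI combined score >=
    0.7, 1 Mb cis window, 4 expansion levels, 1,000 bootstrap iterations.
    """

    genome_fasta: str = ""
    genes_gtf: str = ""
    contacts: list[str] = field(default_factory=list)
    eqtls: str = ""
    gwas_catalog: str = ""
    ppi_links: str = ""
    protein_map: str = ""
    seed_trait: str = ""
    out_dir: str = "comorbidnet_run"

    gwas_p: float = 5e-8
    fdr_grn: float = 0.05
    fdr_seed: float = 0.05
    fdr_seed_headline: float = 0.01
    fdr_enrichment: float = 0.05
    mapq_min: int = 30
    maf_min: float = 0.05
    score_min: float = 0.7
    cis_window: int = 1_000_000
    max_level: int = 4
    bootstrap_iterations: int = 1000
    rng_seed: int = 0
    restriction_site: str = "AAGCTT"
    cut_offset: int = 1

    def validate(self) -> None:
        for name, value, lo, hi in [
            ("gwas_p", self.gwas_p, 0, 1), ("fdr_grn", self.fdr_grn, 0, 1),
            ("fdr_seed", self.fdr_seed, 0, 1), ("fdr_enrichment", self.fdr_enrichment, 0, 1),
            ("maf_min", self.maf_min, 0, 0.5), ("score_min", self.score_min, 0, 1),
        ]:
            if not (lo < value <= hi):
                raise ValueError(f"{name}={value} outside ({lo}, {hi}]")
        if self.mapq_min < 0 or self.max_level < 0 or self.bootstrap_iterations < 1:
            raise ValueError("mapq_min/max_level/bootstrap_iterations out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @property
    def enzyme(self) -> EnzymeSpec:
        return EnzymeSpec(self.restriction_site, self.cut_offset)


@dataclass
class PipelineResult:
    config: RunConfig
    qc: dict
    grn: GRN
    grn_summary: dict
    seed_snps: list[str]
    seed_interactions: list
    lsppin_stats: dict
    subnetworks: list[set[str]]
    singletons: set[str]
    enrichment: list[LevelEnrichment]
    bootstrap: list
    report: dict


def _md5(path: str | Path) -> str:
    digest = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline_dataset(
    dataset: SyntheticDataset,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs (no file I/O)."""
    config = config or RunConfig()
    config.validate()
    if not config.seed_trait:
        config.seed_trait = dataset.ledger.seed_trait
    return _run_stages(
        config,
        index=dataset.index,
        library=dataset.library,
        annotation=dataset.annotation,
        eqtls=dataset.eqtls,
        catalog=dataset.catalog,
        ppi_links=dataset.ppi_links,
        protein_map=dataset.protein_map,
    )


def _run_stages(
    config: RunConfig,
    index: FragmentIndex,
    library: ContactLibrary,
    annotation: GeneAnnotation,
    eqtls: pd.DataFrame,
    catalog: pd.DataFrame,
    ppi_links: pd.DataFrame,
    protein_map: pd.DataFrame,
) -> PipelineResult:
    timings: dict[str, float] = {}

    def tick(stage: str, t0: float) -> None:
        timings[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %-12s %.3fs", stage, timings[stage])

    t0 = time.perf_counter()
    qc_pass, qc = qc_contact_library(library)
    tick("hic_qc", t0)

    t0 = time.perf_counter()
    variants = eqtl_table_variants(eqtls)
    grn = build_grn(
        variants, index, library, annotation, eqtls,
        maf_min=config.maf_min, fdr_threshold=config.fdr_grn,
        cis_window=config.cis_window,
    )
    grn_summary = summarize_grn(grn, annotation)
    tick("build_grn", t0)

    t0 = time.perf_counter()
    seed_variants = filter_gwas_snps(catalog, config.seed_trait, config.gwas_p)
    # seed variants may lack eQTL-table coordinates; catalog carries them
    snp_map = {v.rsid: v for v in seed_variants}
    pairs = candidate_pairs(seed_variants, index, library, annotation)
    seed_interactions = call_interactions(
        pairs, eqtls, snps=snp_map, genes=annotation,
        fdr_threshold=config.fdr_seed, fdr_grouping="global",
        cis_window=config.cis_window,
    )
    tick("map_seed", t0)

    t0 = time.perf_counter()
    full_ppi = load_ppi(ppi_links, protein_map, score_min=config.score_min)
    lsppin = tissue_filter(full_ppi, grn)
    seed_genes = {it.gene_id for it in seed_interactions}
    subnetworks, singletons = seed_subnetworks(lsppin, seed_genes)
    lsppin_stats = {
        "full_nodes": full_ppi.number_of_nodes(),
        "full_edges": full_ppi.number_of_edges(),
        "lsppin_nodes": lsppin.number_of_nodes(),
        "lsppin_edges": lsppin.number_of_edges(),
        "node_retention": lsppin.graph["node_retention"],
        "edge_retention": lsppin.graph["edge_retention"],
        "unmapped_proteins": full_ppi.graph["unmapped_proteins"],
    }
    tick("ppin", t0)

    t0 = time.perf_counter()
    seed_rsids = sorted({it.rsid for it in seed_interactions})
    enrichment = run_multimorbid(
        seed_rsids, grn, lsppin, catalog,
        max_level=config.max_level, fdr_threshold=config.fdr_enrichment,
    )
    tick("multimorbid", t0)

    t0 = time.perf_counter()
    boot = bootstrap_mod.bootstrap_gene_specificity(
        observed_genes=sorted(seed_genes),
        seed_size=len(snp_map),
        catalog=catalog,
        index=index,
        library=library,
        genes=annotation,
        eqtls=eqtls,
        iterations=config.bootstrap_iterations,
        rng_seed=config.rng_seed,
        fdr_threshold=config.fdr_seed,
    )
    tick("bootstrap", t0)

    result = PipelineResult(
        config=config,
        qc={**qc.to_dict(), "pass": qc_pass},
        grn=grn,
        grn_summary=grn_summary,
        seed_snps=sorted(snp_map),
        seed_interactions=seed_interactions,
        lsppin_stats=lsppin_stats,
        subnetworks=subnetworks,
        singletons=singletons,
        enrichment=enrichment,
        bootstrap=boot,
        report={},
    )
    result.report = write_report(result, timings=timings)
    return result


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-based run: load inputs named in the config, run, write outputs."""
    config.validate()
    inputs = {
        "genome_fasta": config.genome_fasta,
        "genes_gtf": config.genes_gtf,
        "eqtls": config.eqtls,
        "gwas_catalog": config.gwas_catalog,
        "ppi_links": config.ppi_links,
        "protein_map": config.protein_map,
        **{f"contacts[{i}]": c for i, c in enumerate(config.contacts)},
    }
    missing = [f"{name}: {path}" for name, path in inputs.items() if not path or not Path(path).exists()]
    if missing:
        raise FileNotFoundError("missing input file(s): " + "; ".join(missing))

    index = build_fragment_index(config.genome_fasta, config.enzyme)
    library = parse_contacts(list(config.contacts), mapq_min=config.mapq_min)
    annotation = read_gtf(config.genes_gtf)
    eqtls = read_eqtl_table(config.eqtls)
    catalog = read_trait_associations(config.gwas_catalog)
    ppi_links = pd.read_csv(config.ppi_links, sep="\t")
    protein_map = pd.read_csv(config.protein_map, sep="\t")

    result = _run_stages(
        config, index, library, annotation, eqtls, catalog, ppi_links, protein_map
    )
    result.report["input_checksums"] = {
        name: _md5(path) for name, path in inputs.items()
    }

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fragment_bed(index, out / "fragments.bed")
    library.write_qc_json(out / "qc.json")
    library.write_pairs_tsv(out / "contact_pairs.tsv")
    result.grn.write_tsv(out / "grn.tsv")
    GRN(result.seed_interactions).write_tsv(out / "seed_interactions.tsv")
    write_edges_tsv_from_stats(result, out)
    enrichment_dataframe(result.enrichment).to_csv(
        out / "enrichment.tsv", sep="\t", index=False
    )
    bootstrap_mod.results_dataframe(result.bootstrap).to_csv(
        out / "bootstrap.tsv", sep="\t", index=False
    )
    (out / "report.json").write_text(json.dumps(result.report, indent=2, sort_keys=True) + "\n")
    (out / "report.txt").write_text(render_report_text(result.report))
    config.to_yaml(out / "config.yaml")
    return result


def write_edges_tsv_from_stats(result: PipelineResult, out: Path) -> None:
    rows = [
        {"component": i, "genes": ",".join(sorted(c))}
        for i, c in enumerate(result.subnetworks)
    ]
    (out / "subnetworks.json").write_text(
        json.dumps(
            {"subnetworks": rows, "singletons": sorted(result.singletons)}, indent=2
        )
        + "\n"
    )


def write_report(result: PipelineResult, timings: dict | None = None) -> dict:
    """Assemble the summary report from stage outputs."""
    enrich_df = enrichment_dataframe(result.enrichment)
    flagged = enrich_df[enrich_df["flagged"]] if not enrich_df.empty else enrich_df
    headline = [
        it for it in result.seed_interactions
        if it.adjusted_p < result.config.fdr_seed_headline
    ]
    report: dict[str, Any] = {
        "config": asdict(result.config),
        "hic_qc": result.qc,
        "grn": result.grn_summary,
        "seed_run": {
            "trait": result.config.seed_trait,
            "n_seed_snps": len(result.seed_snps),
            "n_interactions": len(result.seed_interactions),
            "n_interactions_headline_tier": len(headline),
            "n_eqtls": len({it.rsid for it in result.seed_interactions}),
            "n_genes": len({it.gene_id for it in result.seed_interactions}),
        },
        "ppin": result.lsppin_stats,
        "subnetworks": {
            "n_subnetworks": len(result.subnetworks),
            "sizes": [len(c) for c in result.subnetworks],
            "n_singletons": len(result.singletons),
        },
        "enrichment": {
            "levels": [
                {
                    "level": res.level,
                    "n_genes": len(res.genes),
                    "n_eqtls": len(res.eqtls),
                    "n_traits_tested": len(res.table),
                    "flagged_traits": res.flagged_traits,
                }
                for res in result.enrichment
            ],
            "n_flagged_total": int(flagged.shape[0]),
        },
        "bootstrap": {
            "iterations": result.config.bootstrap_iterations,
            "n_genes": len(result.bootstrap),
            "max_empirical_p": max((r.empirical_p for r in result.bootstrap), default=None),
            "note": "empirical_p of 0 means below 1/iterations",
        },
    }
    if timings:
        report["stage_seconds"] = timings
    return report


def render_report_text(report: dict) -> str:
    lines = ["comorbidnet pipeline report", "=" * 28, ""]
    qc = report["hic_qc"]
    lines += [
        f"Hi-C QC: {qc['retained_records']}/{qc['total_records']} records retained, "
        f"{qc['unique_contacts']} unique contacts "
        f"(dup rate {qc['duplication_rate']:.3f}, pass={qc['pass']})",
        "",
        f"GRN: {report['grn']['n_interactions']} interactions, "
        f"{report['grn']['n_eqtls']} eQTLs, {report['grn']['n_genes']} genes; "
        f"classes {report['grn']['class_counts']}",
        "",
        f"Seed run ({report['seed_run']['trait']}): "
        f"{report['seed_run']['n_interactions']} significant interactions "
        f"({report['seed_run']['n_interactions_headline_tier']} at the headline tier), "
        f"{report['seed_run']['n_eqtls']} eQTLs, {report['seed_run']['n_genes']} genes",
        "",
        f"LSPPIN: {report['ppin']['lsppin_nodes']}/{report['ppin']['full_nodes']} nodes, "
        f"{report['ppin']['lsppin_edges']}/{report['ppin']['full_edges']} edges retained",
        "",
        "Per-level flagged traits:",
    ]
    for level in report["enrichment"]["levels"]:
        flagged = ", ".join(level["flagged_traits"]) or "-"
        lines.append(
            f"  level {level['level']}: {level['n_genes']} genes, "
            f"{level['n_eqtls']} eQTLs, flagged: {flagged}"
        )
    lines.append("")
    return "\n".join(lines)
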