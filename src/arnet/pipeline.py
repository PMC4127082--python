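"""End-to-end orchestration: simulate -> GWAS -> meta -> loci -> coexpression
-> eSNP -> integration -> pathway, with a manifest for reproducibility.

Every stage writes TSV outputs into the run directory; the manifest records
the configuration hash, master seed, package version, and per-stage row
counts. Re-running with an identical configuration reproduces identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, coexpression, esnp, gwas, integrate, io, pathway
from .simulate import SimulationConfig, simulate_expression, simulate_gene_sets, \
    simulate_genotypes, simulate_phenotype


@dataclass
class RunConfig:
    """All stage parameters with the study's printed thresholds as defaults.

    Thresholds: suggestive loci at p <= 1e-6, genome-wide significance at
    p <= 5e-8, 250 kb module tagging, 1 Mb cis window, 10% eSNP FDR with
    p <= 1e-4, and disease association of eSNPs at p <= 0.01.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_pcs: int = 10
    suggestive_p: float = 1e-6
    genome_wide_p: float = 5e-8
    clump_window_bp: int = 500_000
    tag_window_bp: int = 250_000
    cis_window_bp: int = 1_000_000
    esnp_fdr: float = 0.10
    esnp_p_max: float = 1e-4
    disease_p: float = 0.01
    min_module_size: int = 30
    cut_span: float = 0.99
    cohesion_ratio: float = 3.0
    soft_power: float | None = None  # None = choose by scale-free fit
    expression_is_log_scale: bool = True  # simulator output needs no log2
    randomize_mode: str | None = None  # None | "labels" | "values"
    subgroup: str | None = None  # phenotype column to stratify on, e.g. "asthma"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulation=sim, **raw)


def _locus_frame(loci) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"index_snp": l.index_snp, "chrom": l.chrom, "pos": l.pos, "p": l.p,
             "tier": l.tier, "n_clumped": len(l.clumped_snps)}
            for l in loci
        ],
        columns=["index_snp", "chrom", "pos", "p", "tier", "n_clumped"],
    )


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage on a simulated cohort and write stage outputs.

    Returns the in-memory results keyed by stage name. Raises on the first
    failing stage after writing the partial manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.simulation.seed,
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    results: dict = {}

    def _record(stage: str, n_rows: int) -> None:
        manifest["stages"][stage] = {"rows": int(n_rows)}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    stage = "simulate"
    try:
        genotypes = simulate_genotypes(config.simulation)
        phenotype = simulate_phenotype(genotypes, config.simulation)
        expr, truth = simulate_expression(genotypes, config.simulation)
        io.write_dosage_tsv(genotypes, out_dir / "dosages.tsv")
        io.write_snp_map_tsv(genotypes.snp_map, out_dir / "snp_map.tsv")
        io.write_groups_tsv(genotypes.groups, out_dir / "groups.tsv")
        io.write_vcf(genotypes, out_dir / "genotypes.vcf")
        io.write_bed(expr.genes, out_dir / "genes.bed")
        io.write_phenotype_tsv(phenotype, out_dir / "phenotype.tsv")
        io.write_expression_tsv(expr, out_dir / "expression.tsv")
        io.write_ground_truth(truth, out_dir)
        results.update(genotypes=genotypes, phenotype=phenotype, expr=expr, truth=truth)
        _record(stage, genotypes.n_subjects)

        stage = "gwas"
        subgroup = None
        if config.subgroup is not None:
            subgroup = phenotype.table[config.subgroup].astype(bool)
        by_group = gwas.gwas_by_group(
            genotypes, phenotype, n_pcs=config.n_pcs, subgroup=subgroup
        )
        all_groups = pd.concat(by_group.values(), ignore_index=True)
        all_groups.to_csv(out_dir / "gwas_by_group.tsv", sep="\t", index=False)
        results["gwas_by_group"] = by_group
        _record(stage, len(all_groups))

        stage = "meta"
        meta = gwas.meta_analyze(by_group)
        meta.to_csv(out_dir / "gwas_meta.tsv", sep="\t", index=False)
        inflation = gwas.genomic_inflation(meta["p"])
        (out_dir / "inflation.json").write_text(json.dumps(inflation))
        gwas.qq_coordinates(meta["p"]).to_csv(out_dir / "qq_meta.tsv", sep="\t", index=False)
        results["meta"] = meta
        results["inflation"] = inflation
        _record(stage, len(meta))

        stage = "loci"
        candidates = pd.concat([all_groups, meta], ignore_index=True)
        best = candidates.loc[candidates["status"] == "ok"].sort_values(
            ["p", "chrom", "pos"], kind="mergesort"
        ).drop_duplicates("snp_id", keep="first")
        loci = gwas.select_loci(
            best,
            suggestive_p=config.suggestive_p,
            genome_wide_p=config.genome_wide_p,
            clump_window_bp=config.clump_window_bp,
        )
        _locus_frame(loci).to_csv(out_dir / "loci.tsv", sep="\t", index=False)
        results["loci"] = loci
        _record(stage, len(loci))

        stage = "coexpress"
        processed = coexpression.preprocess_expression(
            expr, log2=not config.expression_is_log_scale
        )
        if config.randomize_mode is not None:
            processed = coexpression.randomize(
                processed, config.randomize_mode, seed=config.simulation.seed
            )
        if config.soft_power is None:
            beta, fit = coexpression.pick_soft_threshold(processed)
        else:
            beta, fit = float(config.soft_power), None
        network = coexpression.compute_tom(processed, beta=beta)
        network.scale_free_fit = fit
        modules = coexpression.detect_modules(
            network,
            min_module_size=config.min_module_size,
            cut_span=config.cut_span,
            cohesion_ratio=config.cohesion_ratio,
        )
        module_table = pd.DataFrame(
            {"module": modules.labels, "connectivity": network.connectivity}
        )
        module_table.to_csv(out_dir / "modules.tsv", sep="\t", index_label="gene_id")
        if fit is not None:
            fit.to_csv(out_dir / "scale_free_fit.tsv", sep="\t", index=False)
        (out_dir / "dendrogram.nwk").write_text(
            io.linkage_to_newick(modules.linkage_matrix, modules.gene_order) + "\n"
        )
        results["network"] = network
        results["modules"] = modules
        _record(stage, len(modules.labels))

        stage = "esnp"
        pairs = esnp.cis_pairs(
            genotypes.snp_map, expr.annotated(), window_bp=config.cis_window_bp
        )
        scanned = esnp.esnp_scan(genotypes, processed, pairs)
        called = esnp.call_esnps(scanned, fdr=config.esnp_fdr, p_max=config.esnp_p_max)
        called.to_csv(out_dir / "esnps.tsv", sep="\t", index=False)
        results["esnps"] = called
        _record(stage, len(called))

        stage = "integrate"
        tags = integrate.tag_modules(
            loci, modules, expr.annotated(), window_bp=config.tag_window_bp
        )
        tags.to_csv(out_dir / "module_tags.tsv", sep="\t", index=False)
        if len(loci) and len(tags):
            tag_enrich = integrate.tagging_enrichment(
                tags, loci, modules, expr.annotated(),
                snp_positions=genotypes.snp_map, window_bp=config.tag_window_bp,
            )
        else:
            tag_enrich = pd.DataFrame(columns=integrate.ENRICH_COLUMNS)
        tag_enrich.to_csv(out_dir / "tagging_enrichment.tsv", sep="\t", index=False)
        candidate_modules = sorted(tags["module"].unique()) if len(tags) else modules.modules
        disease_enrich = integrate.ar_esnp_module_enrichment(
            called, meta, modules,
            candidate_modules=candidate_modules, disease_p=config.disease_p,
        )
        disease_enrich.to_csv(out_dir / "disease_esnp_enrichment.tsv", sep="\t", index=False)
        results["tags"] = tags
        results["tagging_enrichment"] = tag_enrich
        results["disease_esnp_enrichment"] = disease_enrich
        _record(stage, len(tags))

        stage = "pathway"
        collection = simulate_gene_sets(truth, config.simulation)
        universe = set(modules.labels.index)
        module_map = {m: set(modules.genes_in(m)) for m in modules.modules}
        if module_map:
            path_enrich = pathway.enrich_modules(module_map, collection, universe)
        else:
            path_enrich = pd.DataFrame(columns=pathway.ENRICH_COLUMNS)
        path_enrich.to_csv(out_dir / "pathway_enrichment.tsv", sep="\t", index=False)
        results["pathway_enrichment"] = path_enrich
        _record(stage, len(path_enrich))
    except Exception as err:  # preserve the partial manifest with the failure
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    manifest["completed"] = True
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
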