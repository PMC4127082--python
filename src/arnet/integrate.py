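"""Integration of GWAS loci, coexpression modules, and eSNPs.

Three statistics connect the layers:

* module tagging — a locus tags a module when the module contains a gene
  within 250 kb (inclusive) of the locus index SNP;
* tagging enrichment — for a module, the observed count of tagging loci is
  compared to an exact-binomial null whose background probability is the
  fraction of all tested SNP positions lying within the window of any
  module gene, so fold = observed / expected is exactly reproducible;
* disease-eSNP enrichment — a one-sided Fisher's exact test of module
  membership against carriage of a disease-associated eSNP (an eSNP whose
  SNP is also nominally associated with the trait, p <= 0.01), over the
  expression-profiled gene universe.

FDR across the tested modules uses Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._types import Locus
from .coexpression import GREY, ModuleAssignment
from .esnp import _point_to_interval_bp

TAG_WINDOW_BP = 250_000

TAG_COLUMNS = ["index_snp", "locus_p", "module", "witness_gene", "distance_bp"]
ENRICH_COLUMNS = ["module", "observed", "expected", "fold", "p", "q"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _gene_distances(locus_pos: int, genes: pd.DataFrame) -> np.ndarray:
    start = genes["start"].to_numpy(dtype=np.int64)
    end = genes["end"].to_numpy(dtype=np.int64)
    return _point_to_interval_bp(np.int64(locus_pos - 1), start, end)


def tag_modules(
    loci: list[Locus],
    modules: ModuleAssignment,
    genes: pd.DataFrame,
    window_bp: int = TAG_WINDOW_BP,
) -> pd.DataFrame:
    """Emit a (locus, module) tag for every module with a gene in the window.

    One locus may tag several modules; the nearest member gene is recorded
    as the witness. Genes lacking coordinates are excluded (their count is
    stored in the frame's ``n_unannotated`` attribute). Grey (unassigned)
    genes never generate tags.
    """
    annotated = modules.labels.index.intersection(genes.index)
    n_unannotated = len(modules.labels.index) - len(annotated)
    labels = modules.labels.loc[annotated]
    labels = labels[labels != GREY]

    rows = []
    for locus in loci:
        same_chrom = genes.loc[labels.index]
        same_chrom = same_chrom[same_chrom["chrom"].astype(str) == str(locus.chrom)]
        if same_chrom.empty:
            continue
        dist = _gene_distances(locus.pos, same_chrom)
        near = dist <= window_bp
        if not near.any():
            continue
        sub = pd.DataFrame(
            {"gene_id": same_chrom.index[near], "distance_bp": dist[near],
             "module": labels.loc[same_chrom.index[near]].to_numpy()}
        )
        for module, grp in sub.groupby("module", sort=True):
            witness = grp.sort_values(["distance_bp", "gene_id"]).iloc[0]
            rows.append(
                (locus.index_snp, locus.p, module, witness["gene_id"],
                 int(witness["distance_bp"]))
            )
    out = pd.DataFrame(rows, columns=TAG_COLUMNS)
    out.attrs["n_unannotated"] = n_unannotated
    return out


def tagging_enrichment(
    tags: pd.DataFrame,
    loci: list[Locus],
    modules: ModuleAssignment,
    genes: pd.DataFrame,
    snp_positions: pd.DataFrame | None = None,
    window_bp: int = TAG_WINDOW_BP,
) -> pd.DataFrame:
    """Exact-binomial enrichment of tagging-locus counts per tagged module.

    The background probability p0 for module M is the fraction of candidate
    SNP positions (``snp_positions``: the tested SNP map, chrom/pos) lying
    within ``window_bp`` of any M gene; expected = p0 * n_loci and the
    one-sided p is the upper binomial tail at the observed count.
    """
    if len(loci) == 0:
        raise ValueError("need at least one locus")
    if snp_positions is None:
        raise ValueError("snp_positions (the tested SNP map) is required for the null")
    n_loci = len(loci)

    rows = []
    for module in sorted(tags["module"].unique()):
        observed = int(tags.loc[tags["module"] == module, "index_snp"].nunique())
        member_genes = modules.genes_in(module).intersection(genes.index)
        gsub = genes.loc[member_genes]
        hit = np.zeros(len(snp_positions), dtype=bool)
        for chrom, chrom_genes in gsub.groupby(gsub["chrom"].astype(str)):
            on_chrom = snp_positions["chrom"].astype(str) == chrom
            if not on_chrom.any():
                continue
            pos0 = snp_positions.loc[on_chrom, "pos"].to_numpy(dtype=np.int64) - 1
            start = chrom_genes["start"].to_numpy(dtype=np.int64)
            end = chrom_genes["end"].to_numpy(dtype=np.int64)
            dist = _point_to_interval_bp(pos0[:, None], start[None, :], end[None, :])
            hit[np.asarray(on_chrom)] = (dist <= window_bp).any(axis=1)
        p0 = hit.mean()
        if p0 == 0 and observed > 0:
            raise ValueError(
                f"module {module} tagged {observed} loci but no tested SNP lies in "
                "its window: SNP map and gene annotation are inconsistent"
            )
        expected = p0 * n_loci
        fold = observed / expected if expected > 0 else 0.0
        p = float(stats.binom.sf(observed - 1, n_loci, p0)) if observed > 0 else 1.0
        rows.append({"module": module, "observed": observed, "expected": expected,
                     "fold": fold, "p": p})
    out = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:-1])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


@dataclass
class FisherEnrichment:
    """One module's 2x2 Fisher enrichment with its counts preserved."""

    module: str
    observed: int
    expected: float
    fold: float
    p: float
    table: tuple[tuple[int, int], tuple[int, int]]


def fisher_enrichment_2x2(
    in_module_carriers: int,
    module_size: int,
    total_carriers: int,
    universe_size: int,
) -> tuple[float, float]:
    """(fold, one-sided p) for a 2x2 membership x carriage table.

    fold = (in-module carrier fraction) / (universe carrier fraction);
    p is the one-sided (enrichment) Fisher's exact tail.
    """
    a = in_module_carriers
    table = [
        [a, module_size - a],
        [total_carriers - a, universe_size - module_size - (total_carriers - a)],
    ]
    if min(min(row) for row in table) < 0:
        raise ValueError("inconsistent 2x2 counts")
    if a == 0:
        fold = 0.0
    else:
        fold = (a / module_size) / (total_carriers / universe_size)
    _, p = stats.fisher_exact(table, alternative="greater")
    return fold, float(p)


def ar_esnp_module_enrichment(
    esnps: pd.DataFrame,
    gwas: pd.DataFrame,
    modules: ModuleAssignment,
    candidate_modules: list[str] | None = None,
    disease_p: float = 0.01,
    universe: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-module Fisher enrichment for disease-associated eSNP genes.

    A gene carries a disease eSNP iff some flagged eSNP pair targets it and
    that SNP's disease-association p is <= ``disease_p``. The 2x2 table
    crosses module membership with carriage over the expression-profiled
    gene universe; candidate modules default to every non-grey module.
    """
    if universe is None:
        universe = modules.labels.index
    universe = pd.Index(universe)
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    if candidate_modules is None:
        candidate_modules = modules.modules

    disease_snps = set(gwas.loc[gwas["p"] <= disease_p, "snp_id"])
    hits = esnps[esnps["is_esnp"] & esnps["snp_id"].isin(disease_snps)]
    carriers = pd.Index(hits["gene_id"].unique()).intersection(universe)

    labels = modules.labels.reindex(universe).fillna(GREY)
    rows = []
    for module in candidate_modules:
        member = labels == module
        module_size = int(member.sum())
        a = int(member.loc[carriers].sum()) if len(carriers) else 0
        if module_size == 0:
            continue
        expected = module_size * len(carriers) / len(universe)
        fold, p = fisher_enrichment_2x2(a, module_size, len(carriers), len(universe))
        if len(carriers) == 0:
            p = 1.0
        rows.append({"module": module, "observed": a, "expected": expected,
                     "fold": fold, "p": p})
    out = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:-1])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out
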