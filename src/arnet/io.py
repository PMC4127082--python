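"""Readers and writers for the pipeline's standard formats.

Coordinate conventions are normalized at the boundary: VCF and SNP-map
positions are 1-based points, BED gene intervals are 0-based half-open,
and every reader returns the internal convention documented in
:mod:`arnet._types`. TSV is the interchange format between stages.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._types import ExpressionMatrix, GenotypeMatrix, PhenotypeTable

GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


# ---------------------------------------------------------------- genotypes

def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    genotypes.dosages.to_csv(path, sep="\t")


def write_snp_map_tsv(snp_map: pd.DataFrame, path) -> None:
    snp_map.to_csv(path, sep="\t", index_label="snp_id")


def write_groups_tsv(groups: pd.Series, path) -> None:
    groups.rename("group").to_csv(path, sep="\t", index_label="subject_id")


def read_genotypes_tsv(dosage_path, snp_map_path, groups_path=None) -> GenotypeMatrix:
    dosages = pd.read_csv(dosage_path, sep="\t", index_col=0)
    dosages.index.name = "subject_id"
    dosages.columns.name = "snp_id"
    snp_map = pd.read_csv(snp_map_path, sep="\t", index_col="snp_id")
    snp_map["chrom"] = snp_map["chrom"].astype(str)
    if groups_path is not None:
        groups = pd.read_csv(groups_path, sep="\t", index_col="subject_id")["group"]
    else:
        groups = pd.Series("all", index=dosages.index, name="group")
    return GenotypeMatrix(dosages, snp_map.loc[dosages.columns], groups.loc[dosages.index])


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT calls derived from the dosages."""
    subjects = list(genotypes.dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(subjects) + "\n")
        dos = genotypes.dosages.to_numpy()
        for j, snp_id in enumerate(genotypes.snp_ids):
            rec = genotypes.snp_map.loc[snp_id]
            calls = "\t".join(GT_STRINGS[int(d)] for d in dos[:, j])
            fh.write(f"{rec['chrom']}\t{int(rec['pos'])}\t{snp_id}\t{rec['ref']}\t"
                     f"{rec['alt']}\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path, groups: pd.Series | None = None) -> GenotypeMatrix:
    """Read GT calls from a VCF into an additive dosage matrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    subjects = pd.Index(vcf.samples, name="subject_id")
    rows, ids, chroms, poss, refs, alts = [], [], [], [], [], []
    for var in vcf:
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0/1/2 = dosage, 3 = missing
        if (gt == 3).any():
            raise ValueError(f"missing genotypes at {var.ID or var.POS} are not supported")
        rows.append(gt)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
    snp_ids = pd.Index(ids, name="snp_id")
    dosages = pd.DataFrame(np.array(rows).T, index=subjects, columns=snp_ids)
    snp_map = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts}, index=snp_ids
    )
    if groups is None:
        groups = pd.Series("all", index=subjects, name="group")
    return GenotypeMatrix(dosages, snp_map, groups.loc[subjects])


# -------------------------------------------------------------------- genes

def write_bed(genes: pd.DataFrame, path) -> None:
    """Write gene intervals as BED (0-based half-open), name = gene id."""
    out = genes[["chrom", "start", "end"]].copy()
    out["name"] = genes.index
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    genes = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene_id"],
    ).set_index("gene_id")
    genes["chrom"] = genes["chrom"].astype(str)
    return genes


# ----------------------------------------------------- expression/phenotype

def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path, genes: pd.DataFrame) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ExpressionMatrix(values, genes)


def write_phenotype_tsv(phenotype: PhenotypeTable, path) -> None:
    phenotype.table.to_csv(path, sep="\t", index_label="subject_id")


def read_phenotype_tsv(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t", index_col="subject_id"))


# ------------------------------------------------------------- ground truth

def write_ground_truth(truth, out_dir) -> None:
    out_dir = Path(out_dir)
    truth.planted_esnp_pairs.to_csv(out_dir / "truth_esnp_pairs.tsv", sep="\t", index=False)
    truth.planted_module_labels.rename("module").to_csv(
        out_dir / "truth_modules.tsv", sep="\t", index_label="gene_id"
    )
    pd.Series(truth.causal_snp_ids, name="snp_id").to_csv(
        out_dir / "truth_causal_snps.tsv", sep="\t", index=False
    )
    (out_dir / "truth_disease_module.txt").write_text(str(truth.disease_module_id) + "\n")


# ---------------------------------------------------------------- dendrogram

def linkage_to_newick(z: np.ndarray, labels) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    import sys

    labels = list(labels)
    n = len(labels)
    # pathological chain-shaped trees recurse ~n deep
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 4 * n + 100))

    def node(i: int, parent_height: float) -> str:
        length = parent_height - (0.0 if i < n else z[i - n, 2])
        if i < n:
            return f"{labels[i]}:{length:.6g}"
        a, b = int(z[i - n, 0]), int(z[i - n, 1])
        h = z[i - n, 2]
        return f"({node(a, h)},{node(b, h)}):{length:.6g}"

    if n == 1:
        return f"{labels[0]};"
    root = 2 * n - 2
    h = z[-1, 2]
    a, b = int(z[-1, 0]), int(z[-1, 1])
    return f"({node(a, h)},{node(b, h)});"


# ------------------------------------------------------------- cohort table

def load_cohort_table() -> pd.DataFrame:
    """Per-study subject counts of the multi-center cohort design the
    simulator emulates (subjects, females, cases, asthma, ancestry groups)."""
    ref = resources.files("arnet.data").joinpath("cohort_summary.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="study")
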