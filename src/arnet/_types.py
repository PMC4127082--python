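"""Core in-memory containers shared across the pipeline stages.

All containers are thin wrappers around pandas objects with the alignment
and coordinate conventions fixed once:

* genotype dosages are additive counts of the alternate allele in {0, 1, 2},
  subjects in rows, SNPs in columns;
* SNP positions are 1-based points (VCF convention);
* gene intervals are 0-based half-open (BED convention) and are normalized
  to that convention by every reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_MAP_COLUMNS = ("chrom", "pos", "ref", "alt")
GENE_COLUMNS = ("chrom", "start", "end")


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive dosage matrix with its SNP map and group labels.

    Parameters
    ----------
    dosages : DataFrame, subjects x SNPs, integer values in {0, 1, 2}.
    snp_map : DataFrame indexed by SNP id with columns ``chrom`` (str),
        ``pos`` (1-based int), ``ref``, ``alt``.
    groups : Series mapping subject id -> group label (e.g. ancestry group).
    """

    dosages: pd.DataFrame
    snp_map: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.snp_map.index):
            raise ValueError("dosage columns and snp_map index must match")
        if not self.dosages.index.equals(self.groups.index):
            raise ValueError("dosage rows and group labels must match")
        missing = [c for c in SNP_MAP_COLUMNS if c not in self.snp_map.columns]
        if missing:
            raise ValueError(f"snp_map missing columns: {missing}")
        vals = self.dosages.to_numpy()
        if vals.size and not np.isin(np.unique(vals), [0, 1, 2]).all():
            raise ValueError("dosages must lie in {0, 1, 2}")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    def subset_subjects(self, subjects) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.loc[subjects], self.snp_map, self.groups.loc[subjects]
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus BED-convention gene annotation.

    ``genes`` is indexed by gene id with columns ``chrom``, ``start``, ``end``
    (0-based half-open). Annotation may cover a superset of the measured genes.
    """

    values: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"gene annotation missing columns: {missing}")
        if (self.genes["end"] <= self.genes["start"]).any():
            raise ValueError("gene intervals must satisfy start < end")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def annotated(self) -> pd.DataFrame:
        """Annotation restricted and ordered to the measured genes."""
        keep = self.values.index.intersection(self.genes.index)
        return self.genes.loc[keep]


@dataclass
class PhenotypeTable:
    """Binary outcome plus covariates, one row per subject.

    Columns: ``status`` in {0, 1}, ``age`` (years), ``sex`` (0/1), and
    optionally extra covariates/subgroup flags (e.g. ``asthma``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("status", "age", "sex"):
            if col not in self.table.columns:
                raise ValueError(f"phenotype table missing column {col!r}")
        vals = set(self.table["status"].unique())
        if not vals <= {0, 1}:
            raise ValueError("status must be binary 0/1")

    @property
    def status(self) -> pd.Series:
        return self.table["status"]

    @property
    def subjects(self) -> pd.Index:
        return self.table.index


@dataclass
class GroundTruth:
    """Record of everything planted by the simulator.

    ``planted_esnp_pairs`` rows: (snp_id, gene_id, beta). The disease module
    is the planted module whose cis-eSNP SNPs also carry phenotype effects.
    """

    causal_snp_ids: list[str]
    planted_module_labels: pd.Series  # gene id -> module label (int or name)
    planted_esnp_pairs: pd.DataFrame  # columns snp_id, gene_id, beta
    disease_module_id: object

    def __post_init__(self) -> None:
        if self.disease_module_id is None:
            return  # nothing planted
        labels = set(self.planted_module_labels.unique())
        if self.disease_module_id not in labels:
            raise ValueError("disease_module_id not among planted module labels")


@dataclass
class Locus:
    """An association peak retained by greedy positional clumping."""

    index_snp: str
    chrom: str
    pos: int
    p: float
    tier: str  # "genome_wide" or "suggestive"
    clumped_snps: list[str] = field(default_factory=list)
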