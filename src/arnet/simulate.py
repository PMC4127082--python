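"""Synthetic cohort generator with planted, recoverable structure.

Emulates the design of a multi-center case/control study of allergic
rhinitis: several ancestry groups with Balding-Nichols allele-frequency
divergence and block LD, a binary phenotype from a logistic model (target
prevalence near 48%, the case fraction of the cohort the package models),
and an expression matrix with planted coexpression modules and planted
cis-eSNP effects. One module — the "disease module" — carries cis-eSNPs
whose SNPs also receive phenotype effects, so every downstream stage has a
ground truth to recover.

All genes live on one simulated chromosome at fixed spacing, which makes
the 250 kb tagging and 1 Mb cis-window logic exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from ._types import ExpressionMatrix, GenotypeMatrix, GroundTruth, PhenotypeTable

CHROM = "1"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; the defaults are the demo cohort.

    The demo mirrors the emulated study design at desk scale: three ancestry
    groups, a ~48% baseline case prevalence, 200 expression-profiled subjects
    drawn from a single group, five planted coexpression modules of 50 genes
    at within-module correlation 0.7, and ten planted cis-eSNPs in one module
    whose SNPs also carry phenotype effects.
    """

    n_subjects_per_group: int = 250
    n_groups: int = 3
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    fst: float = 0.05
    ld_block_size: int = 10
    ld_rho: float = 0.5
    n_genes: int = 300
    n_modules: int = 5
    module_sizes: list[int] | None = None
    module_cor: float = 0.7
    noise_sd: float = 1.0
    n_cis_esnps: int = 10
    esnp_beta: float = 1.0
    n_causal_snps: int = 10
    causal_or: float = 2.0
    baseline_prevalence: float = 0.48
    n_expression_samples: int = 200
    age_range: tuple[float, float] = (5.0, 60.0)
    age_log_or_per_year: float = 0.01
    sex_log_or: float = 0.2
    gene_spacing: int = 1_000_000
    gene_length: int = 10_000
    cis_window_bp: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            self.module_sizes = [50] * self.n_modules
        self.validate()

    def validate(self) -> None:
        def _positive(name: str) -> None:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

        for name in (
            "n_subjects_per_group", "n_groups", "n_snps", "n_genes",
            "ld_block_size", "gene_spacing", "gene_length", "causal_or",
            "cis_window_bp",
        ):
            _positive(name)
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 <= lo <= hi <= 0.5, got {self.maf_range}")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must lie in [0, 1), got {self.fst}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError(f"ld_rho must lie in [0, 1), got {self.ld_rho}")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes must sum to at most n_genes")
        if not 0.0 < self.module_cor < 1.0:
            raise ValueError(f"module_cor must lie in (0, 1), got {self.module_cor}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError(
                f"baseline_prevalence must lie in (0, 1), got {self.baseline_prevalence}"
            )
        if self.n_causal_snps > self.n_snps:
            raise ValueError("n_causal_snps must not exceed n_snps")
        if self.n_causal_snps < self.n_cis_esnps:
            raise ValueError("n_causal_snps must be >= n_cis_esnps (eSNP SNPs are causal)")
        if self.module_sizes and self.n_cis_esnps > self.module_sizes[0]:
            raise ValueError("n_cis_esnps must not exceed the disease module size")

    def replace(self, **kw) -> "SimulationConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kw)
        return SimulationConfig(**current)


def _streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    """One master seed, split into an independent stream per stage."""
    names = ("genotypes", "phenotype", "expression", "plan", "genesets")
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _snp_positions(config: SimulationConfig) -> np.ndarray:
    """1-based SNP positions evenly spread over the simulated chromosome."""
    genome = config.n_genes * config.gene_spacing
    spacing = max(genome // (config.n_snps + 1), 1)
    return (np.arange(config.n_snps) + 1) * spacing


def gene_annotation(config: SimulationConfig) -> pd.DataFrame:
    """BED-convention gene table: gene i at [i*spacing + 1000, +gene_length)."""
    ids = [f"G{i:04d}" for i in range(config.n_genes)]
    start = np.arange(config.n_genes) * config.gene_spacing + 1000
    return pd.DataFrame(
        {"chrom": CHROM, "start": start, "end": start + config.gene_length},
        index=pd.Index(ids, name="gene_id"),
    )


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a subjects x SNPs dosage matrix with group structure and block LD.

    Per-group allele frequencies follow a Balding-Nichols model: an ancestral
    frequency p drawn uniformly from ``maf_range`` and group frequencies from
    Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``fst`` (degenerate at p for F = 0).
    LD is induced with a latent Gaussian copula: within each block of
    ``ld_block_size`` SNPs the two haplotype latents share an equicorrelated
    factor at correlation ``ld_rho`` and are thresholded at the group
    frequency quantile, so marginal dosages stay Binomial(2, p_group).
    """
    config.validate()
    rng = _streams(config)["genotypes"]
    n, m = config.n_subjects_per_group, config.n_snps

    p_anc = rng.uniform(*config.maf_range, size=m)
    block_ids = np.arange(m) // config.ld_block_size
    n_blocks = block_ids.max() + 1

    group_names = [f"g{g + 1}" for g in range(config.n_groups)]
    dosage_parts, subject_ids, group_labels = [], [], []
    for g, gname in enumerate(group_names):
        if config.fst > 0:
            f = config.fst
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            ok = (p_anc > 0) & (p_anc < 1)
            p_g = np.where(ok, rng.beta(np.where(ok, a, 1), np.where(ok, b, 1)), p_anc)
        else:
            p_g = p_anc
        thresh = norm.ppf(p_g)  # -inf at p=0: no alt alleles

        shared = rng.standard_normal((n, 2, n_blocks))[:, :, block_ids]
        noise = rng.standard_normal((n, 2, m))
        latent = np.sqrt(config.ld_rho) * shared + np.sqrt(1 - config.ld_rho) * noise
        dosage_parts.append((latent < thresh).sum(axis=1).astype(np.int8))
        subject_ids.extend(f"{gname}_{i:04d}" for i in range(n))
        group_labels.extend([gname] * n)

    snp_ids = pd.Index([f"rs{j + 1:05d}" for j in range(m)], name="snp_id")
    subjects = pd.Index(subject_ids, name="subject_id")
    dosages = pd.DataFrame(np.vstack(dosage_parts), index=subjects, columns=snp_ids)
    snp_map = pd.DataFrame(
        {"chrom": CHROM, "pos": _snp_positions(config), "ref": "A", "alt": "G",
         "maf_ancestral": p_anc},
        index=snp_ids,
    )
    return GenotypeMatrix(dosages, snp_map, pd.Series(group_labels, index=subjects))


def _plan_plants(genotypes: GenotypeMatrix, config: SimulationConfig):
    """Deterministically plan module labels, eSNP pairs, and causal SNPs.

    Shared by the phenotype and expression stages so that the disease
    module's cis-eSNP SNPs are exactly the phenotype's first causal SNPs.
    """
    rng = _streams(config)["plan"]
    genes = gene_annotation(config)
    gene_order = rng.permutation(config.n_genes)

    labels, start = {}, 0
    for k, size in enumerate(config.module_sizes):
        for gi in gene_order[start:start + size]:
            labels[genes.index[gi]] = f"M{k + 1}"
        start += size
    module_labels = pd.Series(labels, name="module", dtype=object)
    disease_module = "M1" if config.module_sizes else None

    snp_pos = genotypes.snp_map["pos"].to_numpy()
    poly = genotypes.dosages.to_numpy().std(axis=0) > 0
    disease_genes = module_labels.index[module_labels == disease_module]
    esnp_genes = list(disease_genes[: config.n_cis_esnps])

    used: set[int] = set()
    pairs = []
    for gid in esnp_genes:
        mid = (genes.loc[gid, "start"] + genes.loc[gid, "end"]) // 2
        dist = np.abs(snp_pos - mid)
        order = np.argsort(dist, kind="stable")
        j = next(
            (j for j in order if poly[j] and j not in used and dist[j] <= config.cis_window_bp),
            None,
        )
        if j is None:
            raise ValueError(f"no polymorphic SNP within the cis window of gene {gid}")
        used.add(j)
        pairs.append((genotypes.snp_ids[j], gid, config.esnp_beta))
    esnp_pairs = pd.DataFrame(pairs, columns=["snp_id", "gene_id", "beta"])

    causal = list(esnp_pairs["snp_id"])
    extra = config.n_causal_snps - len(causal)
    if extra > 0:
        candidates = [j for j in range(config.n_snps) if poly[j] and j not in used]
        picked = rng.choice(len(candidates), size=extra, replace=False)
        causal.extend(genotypes.snp_ids[candidates[j]] for j in sorted(picked))

    truth = GroundTruth(
        causal_snp_ids=causal,
        planted_module_labels=module_labels,
        planted_esnp_pairs=esnp_pairs,
        disease_module_id=disease_module,
    )
    return truth


def plan_ground_truth(genotypes: GenotypeMatrix, config: SimulationConfig) -> GroundTruth:
    """Public accessor for the planted structure implied by a config."""
    return _plan_plants(genotypes, config)


def simulate_phenotype(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> PhenotypeTable:
    """Draw a binary outcome from a logistic model with SNP and covariate effects.

    The intercept is logit(``baseline_prevalence``); causal dosages and the
    covariates age (uniform over ``age_range``) and sex (Bernoulli(1/2)) enter
    the linear predictor centered, so the realized prevalence stays near the
    baseline. Each causal SNP contributes log(``causal_or``) per alternate
    allele. An ``asthma`` flag correlated with case status is included as a
    generic subgroup variable.
    """
    config.validate()
    rng = _streams(config)["phenotype"]
    truth = _plan_plants(genotypes, config)
    n = genotypes.n_subjects

    age = rng.uniform(*config.age_range, size=n)
    sex = rng.integers(0, 2, size=n)

    lp = np.full(n, logit(config.baseline_prevalence))
    if truth.causal_snp_ids:
        x = genotypes.dosages[truth.causal_snp_ids].to_numpy(dtype=float)
        x = x - x.mean(axis=0)
        lp += x.sum(axis=1) * np.log(config.causal_or)
    lp += config.age_log_or_per_year * (age - age.mean())
    lp += config.sex_log_or * (sex - 0.5)
    status = (rng.uniform(size=n) < expit(lp)).astype(int)

    # comorbidity-style subgroup flag: more likely among cases
    asthma = (rng.uniform(size=n) < np.where(status == 1, 0.7, 0.4)).astype(int)
    table = pd.DataFrame(
        {"status": status, "age": age, "sex": sex, "asthma": asthma},
        index=genotypes.dosages.index,
    )
    return PhenotypeTable(table)


def simulate_expression(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw a genes x samples matrix with planted modules and cis-eSNP effects.

    Each module has a standard-normal latent eigengene; member genes are
    loading * eigengene + N(0, noise_sd) with the loading calibrated so the
    expected within-module correlation equals ``module_cor``
    (loading = noise_sd * sqrt(c / (1 - c)); loading 1 when noise_sd = 0).
    Planted eSNP pairs add ``esnp_beta`` * dosage to the target gene.
    Background genes are independent noise. Samples are the first
    ``n_expression_samples`` subjects of the first group, mirroring
    expression profiling restricted to a single study center.
    """
    config.validate()
    rng = _streams(config)["expression"]
    truth = _plan_plants(genotypes, config)

    first_group = genotypes.groups.iloc[0]
    in_first = genotypes.groups.index[genotypes.groups == first_group]
    samples = (in_first if len(in_first) >= config.n_expression_samples
               else genotypes.dosages.index)[: config.n_expression_samples]
    ns = len(samples)

    genes = gene_annotation(config)
    bg_sd = config.noise_sd if config.noise_sd > 0 else 1.0
    values = rng.standard_normal((config.n_genes, ns)) * bg_sd
    eigengenes = rng.standard_normal((config.n_modules, ns))
    gene_index = {g: i for i, g in enumerate(genes.index)}

    # Per-gene eigengene correlations r_i vary around sqrt(module_cor), so
    # pairwise within-module correlation r_i*r_j has mean module_cor while
    # connectivity spreads as it does in real coexpression data.
    center = np.sqrt(config.module_cor)
    delta = min(0.15, 0.98 - center, center - 0.05)
    for gid, label in truth.planted_module_labels.items():
        k = int(str(label)[1:]) - 1
        if config.noise_sd > 0:
            r = rng.uniform(center - delta, center + delta)
            loading = config.noise_sd * r / np.sqrt(1 - r * r)
        else:
            loading = 1.0
        noise = rng.standard_normal(ns) * config.noise_sd
        values[gene_index[gid]] = loading * eigengenes[k] + noise

    dosage = genotypes.dosages.loc[samples]
    for row in truth.planted_esnp_pairs.itertuples(index=False):
        values[gene_index[row.gene_id]] += row.beta * dosage[row.snp_id].to_numpy()

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes.index, columns=samples), genes
    )
    return expr, truth


def simulate_gene_sets(
    truth: GroundTruth,
    config: SimulationConfig,
    n_random_sets: int = 20,
    module_overlap: float = 0.8,
):
    """Build a gene-set collection with one set per planted module.

    Each planted module gets a themed set sharing ``module_overlap`` of its
    genes (the rest replaced with random genes, emulating imperfect
    annotation); the disease module's set is named ``MITOCHONDRION_LIKE``.
    ``n_random_sets`` additional sets of random genes act as nulls.
    """
    from .pathway import GeneSetCollection

    rng = _streams(config)["genesets"]
    genes = gene_annotation(config).index
    labels = truth.planted_module_labels

    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    for k, label in enumerate(sorted(labels.unique())):
        members = list(labels.index[labels == label])
        n_keep = max(1, int(round(module_overlap * len(members))))
        keep = [members[i] for i in rng.choice(len(members), size=n_keep, replace=False)]
        pool = [g for g in genes if g not in set(members)]
        fill = [pool[i] for i in rng.choice(len(pool), size=len(members) - n_keep,
                                            replace=False)]
        name = ("MITOCHONDRION_LIKE" if label == truth.disease_module_id
                else f"PLANTED_SET_{label}")
        sets[name] = frozenset(keep + fill)
        descriptions[name] = f"synthetic set overlapping planted module {label}"
    set_size = int(np.mean(config.module_sizes)) if config.module_sizes else 30
    for r in range(n_random_sets):
        pick = rng.choice(len(genes), size=min(set_size, len(genes)), replace=False)
        sets[f"RANDOM_SET_{r + 1:02d}"] = frozenset(genes[i] for i in pick)
        descriptions[f"RANDOM_SET_{r + 1:02d}"] = "synthetic random null set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)
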