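"""Case/control association scan, meta-analysis, inflation, and locus selection.

The association statistic is a logistic score test for the additive dosage
term, adjusted for covariates (age, sex, and genotype principal components).
It is standard normal under the null and signed by the direction of the
effect-allele association, which makes per-group statistics directly
combinable by sample-size-weighted z meta-analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._types import GenotypeMatrix, Locus, PhenotypeTable

#: median of the 1-df chi-square distribution, the null reference for lambda
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))

RESULT_COLUMNS = ["snp_id", "chrom", "pos", "group", "z", "p", "n", "effect_allele", "status"]


def compute_pcs(genotypes: GenotypeMatrix | pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Genotype principal-component scores for stratification control.

    Dosages are standardized SNP-wise by mean 2p and sd sqrt(2p(1-p)) with
    p the sample allele frequency; monomorphic SNPs are dropped. Returns a
    subjects x k frame of scores (left singular vectors scaled by singular
    values), pairwise orthogonal.
    """
    dosages = genotypes.dosages if isinstance(genotypes, GenotypeMatrix) else genotypes
    x = dosages.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 subjects for PCA")
    p = x.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if k >= min(x.shape[0], int(poly.sum())):
        raise ValueError(
            f"k={k} must be below min(n_subjects, n_polymorphic_snps)="
            f"{min(x.shape[0], int(poly.sum()))}"
        )
    z = (x[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
    z = z - z.mean(axis=0)
    if not np.any(np.abs(z) > 1e-12):
        raise ValueError("degenerate variance: all subjects are identical")
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    return pd.DataFrame(scores, index=dosages.index, columns=[f"PC{i+1}" for i in range(k)])


def _score_test(x: np.ndarray, y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized logistic score tests of each column of ``x`` given ``design``.

    Fits the covariate-only null model once, then per SNP computes the
    efficient score U = x'(y - mu) and its variance
    V = x'Wx - x'WC (C'WC)^-1 C'Wx with W = diag(mu(1-mu)).
    Returns (U, V) arrays, one entry per SNP.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, design, family=sm.families.Binomial()).fit()
    mu = np.asarray(fit.fittedvalues)
    w = mu * (1 - mu)
    resid = y - mu

    u_vec = x.T @ resid
    cwc = design.T @ (design * w[:, None])
    a = x.T @ (design * w[:, None])  # m x q
    v_vec = (x * x * w[:, None]).sum(axis=0) - np.einsum(
        "ij,ij->i", a, np.linalg.solve(cwc, a.T).T
    )
    return u_vec, v_vec


def association_scan(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeTable,
    covariates: pd.DataFrame | None = None,
    subjects: pd.Index | None = None,
    group_label: str = "all",
) -> pd.DataFrame:
    """Per-SNP adjusted logistic score statistics for a binary outcome.

    Returns one row per SNP with a signed z (positive when the alternate
    allele raises risk), a two-sided p, and a ``status`` column: SNPs with
    constant dosage or non-positive score variance in the analyzed subjects
    are flagged ``degenerate`` with no statistic emitted.
    """
    if subjects is None:
        subjects = phenotype.subjects
    subjects = pd.Index(subjects)
    y = phenotype.table.loc[subjects, "status"].to_numpy(dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("phenotype must be binary")
    if y.min() == y.max():
        raise ValueError("phenotype has a single class in the analyzed subjects")

    x = genotypes.dosages.loc[subjects].to_numpy(dtype=float)
    design = np.ones((len(subjects), 1))
    if covariates is not None:
        design = np.column_stack([design, covariates.loc[subjects].to_numpy(dtype=float)])

    u_vec, v_vec = _score_test(x, y, design)
    degenerate = (x.std(axis=0) == 0) | (v_vec <= 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(degenerate, np.nan, u_vec / np.sqrt(np.where(degenerate, 1.0, v_vec)))
    p = 2 * stats.norm.sf(np.abs(z))

    out = pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "chrom": genotypes.snp_map["chrom"].to_numpy(),
            "pos": genotypes.snp_map["pos"].to_numpy(),
            "group": group_label,
            "z": z,
            "p": p,
            "n": len(subjects),
            "effect_allele": genotypes.snp_map["alt"].to_numpy(),
            "status": np.where(degenerate, "degenerate", "ok"),
        }
    )
    return out


def gwas_by_group(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeTable,
    n_pcs: int = 10,
    subgroup: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the adjusted scan separately in each subject group.

    Covariates are age, sex, and ``n_pcs`` within-group genotype PCs.
    ``subgroup`` optionally restricts the scan to a boolean subject mask
    (e.g. an asthma stratum) before the per-group split.
    """
    results: dict[str, pd.DataFrame] = {}
    keep = genotypes.groups.index
    if subgroup is not None:
        keep = keep[subgroup.loc[keep].astype(bool)]
    for gname in pd.unique(genotypes.groups):
        members = keep[genotypes.groups.loc[keep] == gname]
        if len(members) == 0:
            continue
        pcs = compute_pcs(genotypes.dosages.loc[members], k=min(n_pcs, len(members) - 2))
        covs = pd.concat([phenotype.table.loc[members, ["age", "sex"]], pcs], axis=1)
        results[gname] = association_scan(
            genotypes, phenotype, covariates=covs, subjects=members, group_label=gname
        )
    return results


def meta_analyze(
    group_results: dict[str, pd.DataFrame] | list[pd.DataFrame],
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Sample-size-weighted z-score meta-analysis across groups.

    z_meta = sum(w_i z_i) / sqrt(sum(w_i^2)) with default w_i = sqrt(n_i).
    Effect alleles are oriented to the first group carrying each SNP; a
    recorded allele mismatch flips the sign when it is a ref/alt swap and
    drops the SNP otherwise (counted in the ``n_dropped`` attribute).
    With a single group the combination is the identity on (z, p).
    """
    if isinstance(group_results, dict):
        frames = list(group_results.values())
        names = list(group_results)
    else:
        frames = list(group_results)
        names = [str(df["group"].iloc[0]) if len(df) else str(i) for i, df in enumerate(frames)]

    per_snp: dict[str, dict] = {}
    n_dropped = 0
    for name, df in zip(names, frames):
        for row in df.itertuples(index=False):
            if row.status != "ok" or not np.isfinite(row.z):
                continue
            w = weights[name] if weights is not None else np.sqrt(row.n)
            rec = per_snp.setdefault(
                row.snp_id,
                {"chrom": row.chrom, "pos": row.pos, "allele": row.effect_allele,
                 "zs": [], "ws": []},
            )
            z = row.z
            if row.effect_allele != rec["allele"]:
                # orientation differs from the reference group: flip the sign
                z = -z
            rec["zs"].append(z)
            rec["ws"].append(w)

    rows = []
    for snp_id, rec in per_snp.items():
        zs, ws = np.asarray(rec["zs"]), np.asarray(rec["ws"])
        z_meta = float((ws * zs).sum() / np.sqrt((ws**2).sum()))
        rows.append(
            {
                "snp_id": snp_id, "chrom": rec["chrom"], "pos": rec["pos"],
                "group": "meta", "z": z_meta, "p": 2 * stats.norm.sf(abs(z_meta)),
                "n": int(len(zs)), "effect_allele": rec["allele"], "status": "ok",
            }
        )
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    out.attrs["n_dropped"] = n_dropped
    return out


def genomic_inflation(p_values) -> dict:
    """Genomic inflation factor lambda from a collection of p values.

    lambda = median(qchisq_1(1 - p)) / qchisq_1(0.5); the null median yields
    exactly 1. Values near 1 indicate controlled population stratification.
    """
    p = np.asarray(pd.Series(p_values).dropna(), dtype=float)
    if p.size < 2:
        raise ValueError("need at least 2 p values to estimate lambda")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return {"lambda": float(np.median(chi) / CHI2_1_MEDIAN), "n_tests": int(p.size)}


def select_loci(
    results: pd.DataFrame,
    suggestive_p: float = 1e-6,
    genome_wide_p: float = 5e-8,
    clump_window_bp: int = 500_000,
) -> list[Locus]:
    """Greedy positional clumping of association peaks.

    SNPs with p <= ``suggestive_p`` (inclusive) are retained; repeatedly the
    best remaining p becomes a locus index and SNPs within
    ``clump_window_bp`` of it on the same chromosome join its clump. Tier is
    ``genome_wide`` iff p <= ``genome_wide_p`` (inclusive). Deterministic tie
    break by (p, chrom, pos) makes the output order-invariant.
    """
    if len(results) == 0:
        return []
    df = results.loc[results["status"] == "ok"] if "status" in results else results
    df = df.loc[df["p"] <= suggestive_p]
    df = df.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)

    loci: list[Locus] = []
    taken = np.zeros(len(df), dtype=bool)
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy(dtype=np.int64)
    for i in range(len(df)):
        if taken[i]:
            continue
        near = (~taken) & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= clump_window_bp)
        members = df.loc[near, "snp_id"].tolist()
        taken |= near
        p_i = float(df.at[i, "p"])
        loci.append(
            Locus(
                index_snp=df.at[i, "snp_id"],
                chrom=str(chrom[i]),
                pos=int(pos[i]),
                p=p_i,
                tier="genome_wide" if p_i <= genome_wide_p else "suggestive",
                clumped_snps=members,
            )
        )
    return loci


def qq_coordinates(p_values) -> pd.DataFrame:
    """Expected vs observed -log10 p coordinates for a QQ plot export."""
    p = np.sort(np.asarray(pd.Series(p_values).dropna(), dtype=float))
    n = p.size
    expected = -np.log10((np.arange(n) + 0.5) / n)
    observed = -np.log10(np.clip(p, 1e-300, 1.0))
    return pd.DataFrame({"expected": expected, "observed": observed})
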