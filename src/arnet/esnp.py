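"""Cis expression-SNP (eSNP) mapping.

A SNP/gene pair is testable when the SNP lies within the cis window
(default 1 Mb, inclusive) of the gene body. For each pair, expression is
regressed on additive dosage and the score statistic n * R^2 is referred
to a 1-df chi-square (a 2-df genotype-class variant is available). A pair
is called an eSNP when its Benjamini-Hochberg q value is at or below the
FDR level (default 10%) and its p value is at or below the point threshold
(default 1e-4) — both inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._types import ExpressionMatrix, GenotypeMatrix

CIS_WINDOW_BP = 1_000_000

PAIR_COLUMNS = ["snp_id", "gene_id", "distance_bp"]
RESULT_COLUMNS = PAIR_COLUMNS + ["statistic", "df", "p", "q", "is_esnp", "status"]


def _point_to_interval_bp(pos0: np.ndarray, start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Distance from 0-based points to 0-based half-open intervals (0 inside)."""
    below = np.clip(start - pos0, 0, None)
    above = np.clip(pos0 - (end - 1), 0, None)
    return below + above


def cis_pairs(
    snp_map: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = CIS_WINDOW_BP,
) -> pd.DataFrame:
    """Enumerate SNP/gene pairs within ``window_bp`` of each other.

    ``snp_map`` carries 1-based SNP positions; ``genes`` carries 0-based
    half-open intervals. Distance is measured from the SNP to the nearest
    base of the gene body (0 inside) and the window bound is inclusive.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    snp_chroms = set(snp_map["chrom"].astype(str))
    gene_chroms = set(genes["chrom"].astype(str))
    if snp_chroms and gene_chroms and not (snp_chroms & gene_chroms):
        raise ValueError(
            "no shared chromosome names between SNP map and gene annotation "
            f"(SNPs: {sorted(snp_chroms)[:3]}..., genes: {sorted(gene_chroms)[:3]}...); "
            "normalize naming conventions first"
        )
    out = []
    for chrom in sorted(snp_chroms & gene_chroms):
        snps = snp_map[snp_map["chrom"].astype(str) == chrom]
        gs = genes[genes["chrom"].astype(str) == chrom]
        if snps.empty or gs.empty:
            continue
        pos0 = snps["pos"].to_numpy(dtype=np.int64) - 1  # 1-based point -> 0-based
        start = gs["start"].to_numpy(dtype=np.int64)
        end = gs["end"].to_numpy(dtype=np.int64)
        dist = _point_to_interval_bp(pos0[:, None], start[None, :], end[None, :])
        si, gi = np.nonzero(dist <= window_bp)
        out.append(
            pd.DataFrame(
                {
                    "snp_id": snps.index.to_numpy()[si],
                    "gene_id": gs.index.to_numpy()[gi],
                    "distance_bp": dist[si, gi],
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(out, ignore_index=True).sort_values(
        ["snp_id", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)


def esnp_scan(
    genotypes: GenotypeMatrix,
    expr: ExpressionMatrix,
    pairs: pd.DataFrame,
    df: int = 1,
) -> pd.DataFrame:
    """Test each cis pair for association of expression with dosage.

    With ``df=1`` the statistic is n * R^2 from the additive regression of
    expression on dosage; with ``df=2`` dosage enters as two genotype-class
    indicators. Statistics are chi-square distributed under the null. Pairs
    whose SNP has fewer than two genotype classes among the shared subjects
    are flagged ``degenerate`` and left untested; constant expression
    yields statistic 0, p = 1.
    """
    if df not in (1, 2):
        raise ValueError("df must be 1 (additive) or 2 (genotype classes)")
    shared = expr.values.columns.intersection(genotypes.dosages.index)
    if len(shared) == 0:
        raise ValueError("no shared subjects between genotypes and expression")
    dos = genotypes.dosages.loc[shared]
    ex = expr.values[shared]
    n = len(shared)

    rows = []
    for rec in pairs.itertuples(index=False):
        if rec.snp_id not in dos.columns or rec.gene_id not in ex.index:
            continue
        x = dos[rec.snp_id].to_numpy(dtype=float)
        y = ex.loc[rec.gene_id].to_numpy(dtype=float)
        classes = np.unique(x)
        if len(classes) < 2:
            rows.append((rec.snp_id, rec.gene_id, rec.distance_bp,
                         np.nan, df, np.nan, "degenerate"))
            continue
        if y.std() == 0:
            rows.append((rec.snp_id, rec.gene_id, rec.distance_bp, 0.0, df, 1.0, "ok"))
            continue
        if df == 1:
            r = np.corrcoef(x, y)[0, 1]
            r2 = r * r
            used_df = 1
        else:
            # R^2 of the one-way genotype-class fit; df = classes - 1
            yc = y - y.mean()
            ss_tot = (yc**2).sum()
            ss_between = sum(
                (x == c).sum() * (y[x == c].mean() - y.mean()) ** 2 for c in classes
            )
            r2 = ss_between / ss_tot
            used_df = len(classes) - 1
        statistic = n * r2
        rows.append((rec.snp_id, rec.gene_id, rec.distance_bp, statistic, used_df,
                     float(stats.chi2.sf(statistic, used_df)), "ok"))
    out = pd.DataFrame(
        rows, columns=["snp_id", "gene_id", "distance_bp", "statistic", "df", "p", "status"]
    )
    out["q"] = np.nan
    out["is_esnp"] = False
    return out[RESULT_COLUMNS]


def call_esnps(
    results: pd.DataFrame,
    fdr: float = 0.10,
    p_max: float = 1e-4,
) -> pd.DataFrame:
    """Set BH q values over all tested pairs and flag eSNPs.

    A pair is an eSNP iff q <= ``fdr`` and p <= ``p_max`` (both inclusive).
    """
    out = results.copy()
    if len(out) == 0:
        return out
    tested = out["status"].eq("ok") & out["p"].notna()
    p = out.loc[tested, "p"].to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    out["q"] = np.nan
    out["is_esnp"] = False
    if tested.any():
        _, q, _, _ = multipletests(p, method="fdr_bh")
        out.loc[tested, "q"] = q
        out.loc[tested, "is_esnp"] = (out.loc[tested, "q"] <= fdr) & (
            out.loc[tested, "p"] <= p_max
        )
    return out
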