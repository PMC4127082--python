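"""Association-scan, meta-analysis, inflation, and locus-selection checks.

Closed forms are asserted exactly; calibration claims use null simulations
with analytic tolerances (binomial standard errors, chi-square medians).
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from arnet import gwas
from arnet._types import GenotypeMatrix, PhenotypeTable
from arnet.simulate import SimulationConfig, simulate_genotypes, simulate_phenotype


def _null_config(**kw):
    base = dict(n_subjects_per_group=300, n_groups=1, n_snps=2000, fst=0.0,
                ld_rho=0.0, n_genes=50, module_sizes=[], n_modules=0,
                n_cis_esnps=0, n_causal_snps=0, seed=101)
    base.update(kw)
    return SimulationConfig(**base)


def _toy_genotypes(dosage_array, positions=None, chrom="1"):
    dosage_array = np.asarray(dosage_array)
    n, m = dosage_array.shape
    subjects = pd.Index([f"s{i}" for i in range(n)], name="subject_id")
    snps = pd.Index([f"snp{j}" for j in range(m)], name="snp_id")
    if positions is None:
        positions = (np.arange(m) + 1) * 1000
    snp_map = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "G"}, index=snps
    )
    groups = pd.Series("all", index=subjects)
    return GenotypeMatrix(
        pd.DataFrame(dosage_array, index=subjects, columns=snps), snp_map, groups
    )


# ------------------------------------------------------------ principal components

def test_pc1_separates_divergent_groups():
    cfg = _null_config(n_groups=2, fst=0.1, n_snps=500, n_subjects_per_group=150)
    g = simulate_genotypes(cfg)
    pcs = gwas.compute_pcs(g, k=4)
    group_num = (g.groups == "g2").astype(float)
    r = np.corrcoef(pcs["PC1"], group_num)[0, 1]
    assert abs(r) > 0.9


def test_pc_scores_are_pairwise_orthogonal():
    cfg = _null_config(n_snps=300)
    g = simulate_genotypes(cfg)
    pcs = gwas.compute_pcs(g, k=5).to_numpy()
    gram = pcs.T @ pcs
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()


def test_pc_errors_on_identical_subjects_and_excess_k():
    dosages = np.ones((10, 20), dtype=int)  # identical rows, polymorphic? no
    g = _toy_genotypes(dosages)
    with pytest.raises(ValueError):
        gwas.compute_pcs(g, k=2)
    cfg = _null_config(n_snps=30, n_subjects_per_group=10)
    g2 = simulate_genotypes(cfg)
    with pytest.raises(ValueError, match="k="):
        gwas.compute_pcs(g2, k=10)


# ----------------------------------------------------------------- association scan

@pytest.fixture(scope="module")
def null_scan():
    """Null GWAS: no genetic effects, covariate-only phenotype, 10^4 SNPs."""
    cfg = _null_config(n_snps=10_000, n_subjects_per_group=600, seed=103)
    g = simulate_genotypes(cfg)
    ph = simulate_phenotype(g, cfg)
    pcs = gwas.compute_pcs(g, k=5)
    covs = pd.concat([ph.table[["age", "sex"]], pcs], axis=1)
    return gwas.association_scan(g, ph, covariates=covs)


def test_null_p_values_are_uniform(null_scan):
    ok = null_scan[null_scan["status"] == "ok"]
    ks = stats.kstest(ok["p"], "uniform")
    assert ks.pvalue > 0.01


def test_null_lambda_near_one(null_scan):
    ok = null_scan[null_scan["status"] == "ok"]
    lam = gwas.genomic_inflation(ok["p"])["lambda"]
    assert 0.9 <= lam <= 1.1


def test_null_type_one_error_controlled(null_scan):
    ok = null_scan[null_scan["status"] == "ok"]
    frac = (ok["p"] <= 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / len(ok))
    assert abs(frac - 0.05) <= 3 * se


def test_planted_snp_power_and_sign():
    """OR 2.0 risk allele at n = 2000: p < 1e-4 with a positive z in >= 90%
    of 50 seeded replicates."""
    rng = np.random.default_rng(2024)
    hits = 0
    for _ in range(50):
        n = 2000
        x = rng.binomial(2, 0.3, size=n)
        age = rng.uniform(10, 50, size=n)
        sex = rng.integers(0, 2, size=n)
        lp = np.log(0.48 / 0.52) + np.log(2.0) * (x - x.mean())
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-lp))).astype(int)
        g = _toy_genotypes(x[:, None])
        ph = PhenotypeTable(pd.DataFrame(
            {"status": y, "age": age, "sex": sex}, index=g.dosages.index
        ))
        covs = ph.table[["age", "sex"]]
        res = gwas.association_scan(g, ph, covariates=covs)
        row = res.iloc[0]
        hits += (row["p"] < 1e-4) and (row["z"] > 0)
    assert hits >= 45


def test_constant_dosage_snp_is_flagged_degenerate():
    rng = np.random.default_rng(0)
    x = np.column_stack([rng.integers(0, 3, 50), np.ones(50, dtype=int)])
    g = _toy_genotypes(x)
    ph = PhenotypeTable(pd.DataFrame(
        {"status": rng.integers(0, 2, 50), "age": rng.uniform(5, 60, 50),
         "sex": rng.integers(0, 2, 50)}, index=g.dosages.index
    ))
    res = gwas.association_scan(g, ph)
    assert res.loc[1, "status"] == "degenerate"
    assert np.isnan(res.loc[1, "z"])
    assert res.loc[0, "status"] == "ok"


def test_scan_rejects_non_binary_phenotype():
    rng = np.random.default_rng(1)
    g = _toy_genotypes(rng.integers(0, 3, (30, 3)))
    table = pd.DataFrame(
        {"status": np.zeros(30, dtype=int), "age": rng.uniform(5, 60, 30),
         "sex": rng.integers(0, 2, 30)}, index=g.dosages.index
    )
    with pytest.raises(ValueError, match="single class"):
        gwas.association_scan(g, PhenotypeTable(table))


# ------------------------------------------------------------------- meta-analysis

def _result_frame(z_list, n_list, group):
    return pd.DataFrame({
        "snp_id": "rs1", "chrom": "1", "pos": 100, "group": group,
        "z": z_list, "p": 2 * stats.norm.sf(np.abs(z_list)), "n": n_list,
        "effect_allele": "G", "status": "ok",
    }, index=range(len(z_list) if np.ndim(z_list) else 1))


def test_meta_two_equal_groups_equal_z_gives_sqrt2():
    z = 1.7
    frames = {g: _result_frame([z], [400], g) for g in ("a", "b")}
    out = gwas.meta_analyze(frames)
    assert out.loc[0, "z"] == pytest.approx(np.sqrt(2) * z, abs=1e-12)


def test_meta_equal_and_opposite_cancels():
    frames = {"a": _result_frame([2.0], [400], "a"),
              "b": _result_frame([-2.0], [400], "b")}
    out = gwas.meta_analyze(frames)
    assert out.loc[0, "z"] == pytest.approx(0.0, abs=1e-12)
    assert out.loc[0, "p"] == pytest.approx(1.0, abs=1e-12)


def test_meta_three_group_hand_arithmetic():
    zs, ns = [2.0, 1.0, -0.5], [400, 900, 100]
    frames = {f"g{i}": _result_frame([z], [n], f"g{i}")
              for i, (z, n) in enumerate(zip(zs, ns))}
    out = gwas.meta_analyze(frames)
    w = np.sqrt(ns)
    expected = (w * np.array(zs)).sum() / np.sqrt((w**2).sum())
    assert out.loc[0, "z"] == pytest.approx(expected, abs=1e-12)


def test_meta_single_group_is_identity():
    frame = _result_frame([1.234], [250], "only")
    out = gwas.meta_analyze({"only": frame})
    assert out.loc[0, "z"] == pytest.approx(1.234, abs=1e-12)
    assert out.loc[0, "p"] == pytest.approx(frame.loc[0, "p"], abs=1e-12)


def test_meta_flips_sign_on_swapped_effect_allele():
    a = _result_frame([1.5], [400], "a")
    b = _result_frame([-1.5], [400], "b")
    b["effect_allele"] = "A"  # opposite orientation: -z on allele A == +z on G
    out = gwas.meta_analyze({"a": a, "b": b})
    assert out.loc[0, "z"] == pytest.approx(np.sqrt(2) * 1.5, abs=1e-12)


# ---------------------------------------------------------------- genomic inflation

def test_lambda_exactly_one_at_null_median():
    assert gwas.genomic_inflation([0.5] * 200)["lambda"] == pytest.approx(1.0, abs=1e-12)


def test_lambda_on_uniform_p():
    rng = np.random.default_rng(5)
    lam = gwas.genomic_inflation(rng.uniform(size=100_000))["lambda"]
    assert lam == pytest.approx(1.0, abs=0.02)


def test_lambda_detects_scaled_null():
    rng = np.random.default_rng(6)
    z = np.sqrt(1.2) * rng.standard_normal(100_000)
    p = 2 * stats.norm.sf(np.abs(z))
    lam = gwas.genomic_inflation(p)["lambda"]
    assert lam == pytest.approx(1.2, abs=0.03)


def test_lambda_requires_at_least_two_values():
    with pytest.raises(ValueError):
        gwas.genomic_inflation([0.5])


# ------------------------------------------------------------------ locus selection

def _scan_frame(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "p"]).assign(
        group="meta", z=1.0, n=100, effect_allele="G", status="ok"
    )


def test_genome_wide_tier_at_printed_threshold():
    df = _scan_frame([("rs1", "1", 1000, 2.0e-8)])
    loci = gwas.select_loci(df)
    assert len(loci) == 1 and loci[0].tier == "genome_wide"


def test_suggestive_threshold_is_inclusive():
    df = _scan_frame([("rs1", "1", 1000, 1.0e-6), ("rs2", "1", 5_000_000, 1.1e-6)])
    loci = gwas.select_loci(df)
    assert [l.index_snp for l in loci] == ["rs1"]
    assert loci[0].tier == "suggestive"


def test_exact_5e8_is_genome_wide():
    df = _scan_frame([("rs1", "1", 1000, 5.0e-8)])
    assert gwas.select_loci(df)[0].tier == "genome_wide"


def test_nearby_snps_clump_to_single_locus():
    df = _scan_frame([("rs1", "1", 100_000, 1e-9), ("rs2", "1", 110_000, 1e-7)])
    loci = gwas.select_loci(df, clump_window_bp=500_000)
    assert len(loci) == 1
    assert loci[0].index_snp == "rs1"
    assert set(loci[0].clumped_snps) == {"rs1", "rs2"}


def test_locus_selection_is_order_invariant():
    rows = [(f"rs{i}", "1", int(p), 10 ** -(6 + i % 3)) for i, p in
            enumerate(np.linspace(1e5, 9e6, 12))]
    df = _scan_frame(rows)
    loci_fwd = gwas.select_loci(df)
    loci_rev = gwas.select_loci(df.iloc[::-1].reset_index(drop=True))
    key = lambda ls: [(l.index_snp, tuple(sorted(l.clumped_snps))) for l in ls]
    assert key(loci_fwd) == key(loci_rev)


def test_empty_results_give_empty_loci():
    assert gwas.select_loci(_scan_frame([])) == []
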