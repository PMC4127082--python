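"""Locus-module tagging and enrichment statistics.

Exact-test p values are validated against exhaustive hypergeometric and
binomial tail summations; fold arithmetic against hand evaluation; the
end-to-end ground-truth recovery and its randomized negative control run
on the demo simulation.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from arnet import coexpression as cx
from arnet import esnp as esnp_mod
from arnet import integrate
from arnet._types import Locus
from conftest import small_module_assignment


def hypergeom_tail(a, module_size, total_carriers, universe):
    """Exhaustive one-sided tail: P(X >= a) by direct summation."""
    upper = min(module_size, total_carriers)
    return sum(
        stats.hypergeom.pmf(x, universe, total_carriers, module_size)
        for x in range(a, upper + 1)
    )


def _locus(snp, pos, p=1e-7, chrom="1"):
    return Locus(index_snp=snp, chrom=chrom, pos=pos, p=p, tier="suggestive",
                 clumped_snps=[snp])


def _genes(coords):
    return pd.DataFrame(
        {"chrom": "1", "start": [s for s, _ in coords.values()],
         "end": [e for _, e in coords.values()]},
        index=pd.Index(coords.keys(), name="gene_id"),
    )


# ---------------------------------------------------------------------- tagging

def test_gene_within_window_is_tagged():
    modules = small_module_assignment({"gA": "brown"})
    genes = _genes({"gA": (1_200_000, 1_210_000)})
    tags = integrate.tag_modules([_locus("rs1", 1_000_000)], modules, genes)
    assert len(tags) == 1
    assert tags.loc[0, "module"] == "brown"
    # locus 1-based 1_000_000 -> 0-based 999_999; gene starts at 1_200_000
    assert tags.loc[0, "distance_bp"] == 200_001


def test_gene_one_base_past_window_is_not_tagged():
    modules = small_module_assignment({"gA": "brown"})
    # locus 0-based 999_999; gene start 1_249_999 -> distance exactly 250_000
    genes = _genes({"gA": (1_249_999, 1_260_000)})
    tags = integrate.tag_modules([_locus("rs1", 1_000_000)], modules, genes)
    assert tags.loc[0, "distance_bp"] == 250_000  # inclusive boundary

    genes2 = _genes({"gA": (1_250_000, 1_260_000)})  # one base further
    tags2 = integrate.tag_modules([_locus("rs1", 1_000_000)], modules, genes2)
    assert len(tags2) == 0


def test_one_locus_can_tag_several_modules():
    modules = small_module_assignment({"gA": "brown", "gB": "pink"})
    genes = _genes({"gA": (1_100_000, 1_110_000), "gB": (900_000, 910_000)})
    tags = integrate.tag_modules([_locus("rs1", 1_000_000)], modules, genes)
    assert sorted(tags["module"]) == ["brown", "pink"]


def test_nearest_module_gene_is_the_witness():
    modules = small_module_assignment({"gA": "brown", "gB": "brown"})
    genes = _genes({"gA": (1_200_000, 1_210_000), "gB": (1_050_000, 1_060_000)})
    tags = integrate.tag_modules([_locus("rs1", 1_000_000)], modules, genes)
    assert len(tags) == 1
    assert tags.loc[0, "witness_gene"] == "gB"


def test_grey_genes_never_tag():
    modules = small_module_assignment({"gA": cx.GREY})
    genes = _genes({"gA": (1_000_000, 1_010_000)})
    tags = integrate.tag_modules([_locus("rs1", 1_000_000)], modules, genes)
    assert len(tags) == 0


# ----------------------------------------------------------- tagging enrichment

def _tag_frame(module, snps):
    return pd.DataFrame({
        "index_snp": snps, "locus_p": 1e-7, "module": module,
        "witness_gene": "gX", "distance_bp": 1000,
    })


def test_tagging_enrichment_reproduces_printed_fold_arithmetic():
    """6 of 22 loci tagging one module with background probability
    6 / (22 * 4.0) gives exactly 4.0-fold enrichment; the tail p comes from
    the exact binomial."""
    n_loci, observed, fold_target = 22, 6, 4.0
    p0 = observed / (n_loci * fold_target)  # 3/44
    # 44 candidate SNP positions, exactly 3 within the window of module genes
    positions = [1_000_000 + i for i in range(3)] + [50_000_000 + i * 3_000_000
                                                     for i in range(41)]
    snp_positions = pd.DataFrame({"chrom": "1", "pos": positions})
    modules = small_module_assignment({"gA": "brown"})
    genes = _genes({"gA": (1_000_000, 1_010_000)})
    loci = [_locus(f"rs{i}", 10_000_000 + i * 1_000_000) for i in range(n_loci)]
    tags = _tag_frame("brown", [f"rs{i}" for i in range(observed)])

    out = integrate.tagging_enrichment(tags, loci, modules, genes,
                                       snp_positions=snp_positions)
    row = out.iloc[0]
    assert row["expected"] == pytest.approx(p0 * n_loci)
    assert row["fold"] == pytest.approx(fold_target)
    exact_tail = sum(stats.binom.pmf(x, n_loci, p0) for x in range(observed, n_loci + 1))
    assert row["p"] == pytest.approx(exact_tail, rel=1e-10)


def test_tagging_enrichment_fold_one_when_observed_equals_expected():
    # p0 = 1/2 via 2 candidate positions, 1 inside the window; 2 loci, 1 tags
    snp_positions = pd.DataFrame({"chrom": "1", "pos": [1_000_000, 90_000_000]})
    modules = small_module_assignment({"gA": "brown"})
    genes = _genes({"gA": (1_000_000, 1_010_000)})
    loci = [_locus("rs1", 1_000_000), _locus("rs2", 90_000_000)]
    out = integrate.tagging_enrichment(_tag_frame("brown", ["rs1"]), loci,
                                       modules, genes, snp_positions=snp_positions)
    assert out.iloc[0]["fold"] == pytest.approx(1.0)


def test_tagging_enrichment_detects_annotation_inconsistency():
    snp_positions = pd.DataFrame({"chrom": "1", "pos": [90_000_000]})
    modules = small_module_assignment({"gA": "brown"})
    genes = _genes({"gA": (1_000_000, 1_010_000)})
    loci = [_locus("rs1", 1_000_000)]
    with pytest.raises(ValueError, match="inconsistent"):
        integrate.tagging_enrichment(_tag_frame("brown", ["rs1"]), loci,
                                     modules, genes, snp_positions=snp_positions)


# ----------------------------------------------------- disease-eSNP enrichment

def _enrichment_inputs(universe_size, module_size, carriers_in, carriers_out):
    gene_ids = [f"g{i}" for i in range(universe_size)]
    labels = {g: ("brown" if i < module_size else cx.GREY)
              for i, g in enumerate(gene_ids)}
    modules = small_module_assignment(labels)
    carrier_genes = (gene_ids[:carriers_in]
                     + gene_ids[module_size:module_size + carriers_out])
    esnps = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(len(carrier_genes))],
        "gene_id": carrier_genes, "distance_bp": 0, "statistic": 30.0,
        "df": 1, "p": 1e-8, "q": 1e-6, "is_esnp": True, "status": "ok",
    })
    gwas = pd.DataFrame({"snp_id": esnps["snp_id"], "p": 1e-4})
    return esnps, gwas, modules


def test_fisher_enrichment_matches_hypergeometric_oracle():
    """30 of 100 module genes vs 70 of 900 background genes: fold 3.0 and a
    one-sided p equal to the exhaustive hypergeometric tail."""
    esnps, gwas, modules = _enrichment_inputs(1000, 100, 30, 70)
    out = integrate.ar_esnp_module_enrichment(esnps, gwas, modules,
                                              candidate_modules=["brown"])
    row = out.iloc[0]
    assert row["fold"] == pytest.approx((30 / 100) / (100 / 1000))
    assert row["p"] == pytest.approx(hypergeom_tail(30, 100, 100, 1000), rel=1e-9)


def test_no_disease_esnps_gives_null_result():
    esnps, gwas, modules = _enrichment_inputs(200, 50, 10, 10)
    gwas["p"] = 0.5  # no eSNP is disease-associated at 0.01
    out = integrate.ar_esnp_module_enrichment(esnps, gwas, modules,
                                              candidate_modules=["brown"])
    assert out.iloc[0]["fold"] == 0.0
    assert out.iloc[0]["p"] == 1.0


def test_disease_p_threshold_is_inclusive():
    esnps, gwas, modules = _enrichment_inputs(200, 50, 5, 0)
    gwas["p"] = 0.01  # exactly at the nominal-association threshold
    out = integrate.ar_esnp_module_enrichment(esnps, gwas, modules,
                                              candidate_modules=["brown"])
    assert out.iloc[0]["observed"] == 5


def test_fold_is_scale_invariant():
    _, p1 = integrate.fisher_enrichment_2x2(6, 20, 30, 200)
    fold1, _ = integrate.fisher_enrichment_2x2(6, 20, 30, 200)
    fold2, _ = integrate.fisher_enrichment_2x2(12, 40, 60, 400)
    assert fold1 == pytest.approx(fold2)


@pytest.mark.parametrize("seed", range(30))
def test_fisher_p_equals_exhaustive_tail_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    universe = int(rng.integers(10, 51))
    module = int(rng.integers(1, universe))
    carriers = int(rng.integers(0, universe + 1))
    a_max = min(module, carriers)
    a_min = max(0, module + carriers - universe)
    a = int(rng.integers(a_min, a_max + 1))
    _, p = integrate.fisher_enrichment_2x2(a, module, carriers, universe)
    assert p == pytest.approx(hypergeom_tail(a, module, carriers, universe),
                              rel=1e-9, abs=1e-12)


# -------------------------------------------------------------------- BH adjust

def test_bh_single_p_unchanged():
    assert integrate.bh_adjust([0.123])[0] == pytest.approx(0.123)


def test_bh_ties_all_equal():
    assert np.allclose(integrate.bh_adjust([0.2, 0.2, 0.2]), 0.2)


def test_bh_hand_evaluated_step_up():
    assert np.allclose(integrate.bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        integrate.bh_adjust([0.5, 1.2])


def test_bh_never_below_raw_p():
    rng = np.random.default_rng(12)
    p = rng.uniform(size=40)
    q = integrate.bh_adjust(p)
    assert (q >= p - 1e-12).all()
    assert (q <= 1.0 + 1e-12).all()


# ------------------------------------------------------ end-to-end ground truth

def test_demo_disease_module_has_best_enrichment_q(demo_run):
    """With planted disease eSNPs, the integration ranks the planted module
    first by disease-eSNP enrichment q."""
    results, _ = demo_run
    truth = results["truth"]
    enrich = results["disease_esnp_enrichment"]
    assert len(enrich) >= 1
    labels = results["modules"].labels
    disease_genes = truth.planted_module_labels.index[
        truth.planted_module_labels == truth.disease_module_id
    ]
    detected_name = labels.loc[disease_genes].mode()[0]
    best = enrich.sort_values(["q", "p"]).iloc[0]
    assert best["module"] == detected_name


def test_randomized_expression_is_a_negative_control(randomized_control_nonsig_count):
    """Values-mode randomization: the planted disease module is not called
    enriched (q > 0.05, or not even a candidate) in >= 90% of 20 replicates."""
    assert randomized_control_nonsig_count >= 18
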