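# arnet

Integrated GWAS, weighted coexpression-network, and cis-eSNP analysis of a
binary trait, with a synthetic multi-center cohort generator.

## The problem

Genome-wide association studies of complex allergic disease — the motivating
case is allergic rhinitis in an ethnically diverse, multi-center cohort —
rarely explain a trait on their own: individual loci pass or miss stringent
thresholds without revealing which biology they touch. One productive
strategy integrates the GWAS with expression data from a disease-relevant
tissue collected from the *same* genotyped subjects:

1. **Per-group GWAS + meta-analysis.** Within each ancestry group, each SNP
   gets a logistic score statistic `z` for the additive dosage term, adjusted
   for age, sex, and genotype principal components; `z ~ N(0,1)` under the
   null and carries the direction of effect. Groups are combined by
   sample-size-weighted z meta-analysis,
   `z_meta = Σ w_i z_i / sqrt(Σ w_i²)` with `w_i = sqrt(n_i)`. Calibration is
   monitored with the genomic inflation factor
   `λ = median(χ²_obs) / median(χ²_1)`. Loci are greedily clumped peaks with
   `p ≤ 1e-6` (suggestive) or `p ≤ 5e-8` (genome-wide).
2. **Coexpression network.** From the expression matrix (log2 +
   quantile-normalized), the unsigned weighted network `a_ij = |cor|^β` (β
   chosen for approximate scale-free topology) is summarized by the
   topological overlap matrix
   `TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 − a_ij)`, and genes are
   partitioned into color-named modules by cutting the average-linkage
   dendrogram of `1 − TOM`.
3. **cis-eSNP scan.** Every SNP within 1 Mb of a gene body is tested for
   association with that gene's expression (1-df chi-square on `n·R²`);
   eSNPs are pairs with BH-FDR `q ≤ 0.10` and `p ≤ 1e-4`.
4. **Integration.** A locus *tags* a module if the module has a gene within
   250 kb of the locus; per-module tagging counts get an exact-binomial
   enrichment (fold = observed/expected). Tagged modules are tested by
   one-sided Fisher's exact for enrichment of genes carrying
   *disease-associated* eSNPs (eSNP whose SNP also has trait `p ≤ 0.01`),
   and annotated by GMT gene-set enrichment.

Because the cohort data behind such studies are typically not public, the
package ships a first-class simulator that plants the entire causal chain —
population structure, LD, a logistic phenotype at ~48% prevalence, five
coexpression modules, and cis-eSNPs in one "disease module" whose SNPs also
affect the phenotype — so every stage can be validated against ground truth.

## Worked example

```bash
arnet run-all --out demo_run --seed 0
```

prints the per-stage row counts

```json
{
  "simulate": 750, "gwas": 6000, "meta": 2000, "loci": 2,
  "coexpress": 300, "esnp": 4015, "integrate": 2, "pathway": 125
}
```

i.e. 750 simulated subjects in 3 groups, 2000 SNPs scanned per group and
meta-analyzed, 2 suggestive loci, 300 genes networked, 4015 cis pairs
tested, and 2 locus→module tags. In `demo_run/`,
`disease_esnp_enrichment.tsv` then shows the planted disease module as the
top (here: only) candidate:

```
module  observed  expected  fold  p             q
yellow  8         1.333     6.0   3.62e-07      3.62e-07
```

— the module carrying the planted cis-eSNPs is 6-fold enriched for
disease-associated eSNP genes, and `pathway_enrichment.tsv` identifies its
`MITOCHONDRION_LIKE` gene set at `q ≈ 2e-29`. The same objects are available
from Python via `arnet.run_pipeline(arnet.RunConfig(), "demo_run")`.

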