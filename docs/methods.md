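# Methods

This note documents the models, defaults, and design choices behind each
stage, what the synthetic data do and do not emulate, and the numerical
conventions used throughout.

## Coordinate conventions

SNP positions are 1-based points (VCF/SNP-map convention); gene intervals
are 0-based half-open (BED convention). Every reader normalizes to these at
the boundary. Distance from a SNP to a gene is measured from the SNP's
0-based position to the nearest base of the gene body, 0 inside the body.
All window rules — the 1 Mb cis window, the 250 kb tagging window, and the
locus thresholds `p ≤ 1e-6` / `p ≤ 5e-8` — are inclusive (`≤`).

## Synthetic cohort

The simulator emulates a multi-center case/control design at desk scale.
Defaults (the "demo" configuration):

| parameter | default | meaning |
|---|---|---|
| `n_subjects_per_group` × `n_groups` | 250 × 3 | three ancestry groups |
| `n_snps` | 2000 | SNPs on one simulated chromosome |
| `maf_range` | (0.05, 0.5) | ancestral allele frequencies, uniform |
| `fst` | 0.05 | Balding–Nichols divergence between groups |
| `ld_block_size`, `ld_rho` | 10, 0.5 | equicorrelated latent blocks |
| `n_genes`, `module_sizes` | 300, 5 × 50 | planted modules + background |
| `module_cor` | 0.7 | mean within-module correlation |
| `n_cis_esnps`, `esnp_beta` | 10, 1.0 | planted cis effects (per allele) |
| `n_causal_snps`, `causal_or` | 10, 2.0 | phenotype effects (per allele) |
| `baseline_prevalence` | 0.48 | case fraction of the emulated cohort |
| `n_expression_samples` | 200 | profiled subjects, first group only |

**Genotypes.** Ancestral MAF `p ~ U(maf_range)` per SNP; group frequency
`p_g ~ Beta(p(1−F)/F, (1−p)(1−F)/F)` (Balding–Nichols; degenerate at `F=0`).
LD comes from a latent Gaussian copula: within each block the two haplotype
latents share an equicorrelated factor at `ld_rho` and are thresholded at
`Φ⁻¹(p_g)`, so marginals stay `Binomial(2, p_g)` while neighboring SNPs are
correlated. This is deliberately simple: no recombination maps, no
imputation uncertainty — LD realism only matters here as a correlation
structure, not as a population-genetic model.

**Phenotype.** Logistic model with intercept `logit(0.48)`; centered causal
dosages contribute `log(causal_or)` per allele; age (`U(5, 60)` years,
+0.01 log-odds/year) and sex (Bernoulli(1/2), +0.2 log-odds) are the
adjustment covariates; an `asthma` flag correlated with case status serves
as a generic subgroup variable. Centering keeps the realized prevalence
near the baseline. `causal_or = 2.0` is at the strong end of realistic GWAS
effects; it is what makes suggestive loci reachable at n = 750.

**Expression.** Each module has a standard-normal latent eigengene; gene
`i`'s correlation with it is drawn uniformly around `sqrt(module_cor)`
(half-width ≈ 0.14), so pairwise within-module correlations average exactly
`module_cor` while connectivity varies across genes as it does in real
coexpression data (with identical loadings the connectivity distribution
degenerates to atoms and scale-free diagnostics are meaningless). Planted
eSNP pairs add `esnp_beta · dosage`; the pairs sit in module M1 (the
"disease module") and their SNPs are exactly the first phenotype-causal
SNPs, creating the full GWAS→module→eSNP chain. Background genes are
independent noise. Genes sit at fixed 1 Mb spacing on the simulated
chromosome, making window logic exactly testable.

**What the simulator does not emulate:** array noise models, batch and
cell-composition effects, trans effects, correlated modules, non-Gaussian
expression marginals, realistic LD decay. Passing tests demonstrate that
the statistical machinery recovers planted structure under the stated
model — not that it would perform identically on microarray data.

**Determinism.** One master seed is split (`numpy.random.SeedSequence.spawn`)
into independent streams per stage (genotypes, phenotype, expression, the
plant "plan", gene sets), so each stage is reproducible in isolation and
identical configurations give bit-identical outputs.

## GWAS

The per-SNP statistic is the efficient score test for the additive dosage
term in a logistic model, computed from one covariate-only null fit:
`U = x'(y − μ̂)`, `V = x'Wx − x'WC (C'WC)⁻¹ C'Wx`, `z = U/√V`. This matches
the contract of a signed standard-normal statistic without asserting any
particular program's internals, and vectorizes across SNPs. Covariates are
age, sex, and 10 within-group genotype PCs by default (PCs from
dosages standardized by mean `2p̂`, sd `sqrt(2p̂(1−p̂))`). SNPs with constant
dosage or non-positive score variance are flagged `degenerate`, excluded
from λ, and carry no statistic.

Meta-analysis combines group z-scores with `w_i = sqrt(n_i)` weights;
inverse-variance weighting is not used because score tests carry no
per-study effect standard errors. Allele mismatches between groups are
resolved by sign flips (biallelic swap); with one group the combination is
the identity.

λ uses `median(χ²_1.isf(p)) / χ²_1.ppf(0.5)`; the constant 0.4549 enters
only through scipy.

Locus selection is greedy positional clumping (default window 500 kb): best
p becomes an index, same-chromosome SNPs within the window join its clump.
LD-aware clumping is deliberately out of scope; ties break deterministically
by (p, chrom, pos), making the output order-invariant.

## Coexpression network

Preprocessing: optional log2 (refused on non-positive input), then quantile
normalization (each sample mapped rank-wise onto the mean sorted vector;
fractional ranks for ties interpolate the reference).

The network is unsigned Pearson (`|cor|^β`, rank-based available). β is the
smallest candidate power whose connectivity distribution fits
`log10(freq) ~ log10(k)` with `R² ≥ 0.8` and negative slope (10 equal-width
bins), falling back to 6 — the convention for choosing approximate
scale-free topology. TOM is computed exactly as
`(l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with a zero-diagonal adjacency so
`(A²)_ij = l_ij`.

**Module detection** is a simplified, parameterized variant of dynamic tree
cut, chosen after the obvious simplifications failed on their own test
cases. Two facts drive the design: (i) as β grows, *all* dissimilarities
compress toward 1, so absolute height thresholds and absolute height gaps
are scale-fragile; (ii) uncorrelated genes form a continuum near
dissimilarity 1 in which any cut produces large but meaningless clusters.
The implementation therefore (a) cuts the average-linkage tree of `1 − TOM`
at an adaptive height — `cut_span = 0.99` of the way from the 5th-percentile
merge height to the maximum, tracking the tree's own scale; and (b) keeps a
cluster (≥ `min_module_size` = 30 genes) only if it is *cohesive*: its mean
within-cluster TOM must exceed `cohesion_ratio = 3` times its mean TOM to
all other genes. Noise slices have a ratio near 1 and are rejected, so pure
noise yields no modules; genuine modules sit far above 3 at any reasonable
β. Leftover genes join the module they cohere with under the same ratio
rule, else stay grey. A 1e-9 floor on the cut keeps numerically flat trees
(all genes identical) in one module. Labels are color names ranked by size
(turquoise, blue, brown, …), `grey` reserved for unassigned — a
reproducible vocabulary, with no claim of identity to any particular
study's modules.

Randomization controls: `labels` permutes gene identifiers only (breaks the
annotation link); `values` permutes each gene's samples independently
(destroys inter-gene correlation). On randomized values the network loses
an order of magnitude of mean connectivity and yields no modules. Note that
the binned scale-free `R²` itself is *not* a reliable degradation readout:
pure-noise connectivity decays near-exponentially, which the log-log fit
often scores higher than modular data — the connectivity collapse and the
absence of modules are the meaningful diagnostics.

## cis-eSNPs

Pairs are enumerated within 1 Mb of the gene body (not the TSS — the rule
references the gene, and the body makes the boundary exact); the statistic
is `n·R²` from the additive regression of expression on dosage, 1-df
chi-square under the null, with a 2-df genotype-class option
(`df = #classes − 1`). Constant expression gives statistic 0, p 1;
degenerate genotypes are flagged untested. Calling: BH over all tested
pairs, `is_esnp ⇔ q ≤ 0.10 ∧ p ≤ 1e-4`, both inclusive. No covariates in
the expression model — expression samples come from a single simulated
group, so stratification is not at issue; real data would warrant expression
PCs, a documented limitation.

## Integration

Tagging: locus position = index SNP position (not clump extent); a module
is tagged when any member gene's interval lies within 250 kb; the nearest
member is recorded as witness; one locus may tag several modules; grey
never tags.

Tagging enrichment: the null must be explicit to make fold reproducible.
For module M, `p₀` = fraction of all *tested SNP positions* within 250 kb
of any M gene; `expected = p₀ · n_loci`; `fold = observed/expected`; p is
the one-sided exact binomial upper tail. This treats loci as draws from the
tested SNP positions — a documented stand-in for the (unstated) null behind
fold-enrichment figures of this kind.

Disease-eSNP enrichment: over the expression-profiled gene universe, the
2×2 table crosses module membership with carriage of a disease-associated
eSNP (some flagged pair targets the gene and its SNP has trait `p ≤ 0.01`);
one-sided Fisher's exact; `fold` = in-module carrier fraction / universe
carrier fraction; BH across candidate modules (those tagged by ≥ 1 locus).
All enrichment tests are one-sided because only enrichment is claimed.

## Pathway enrichment

Plain GMT-driven one-sided Fisher's exact over a configurable universe
(default: annotated genes on the expression matrix), BH across all
(module, set) tests. This replaces web-based annotation tools while keeping
the statistical contract; GO-graph propagation is out of scope. The
pipeline's demo gene sets are generated from the simulation's own ground
truth (each planted module yields a set with 80% overlap plus random
filler, named `MITOCHONDRION_LIKE` for the disease module, plus 20 random
null sets), so set recovery is a measurable property rather than an
accident of a fixture; a tiny static GMT ships for parser demonstrations.

## Problem sizes

The shipped defaults — 750 subjects, 2000 SNPs, 300 genes, 200 expression
samples, 10 planted eSNPs — are the package's demo scale, chosen so the
full pipeline runs in seconds while every downstream quantity (loci,
modules, eSNP calls, enrichments) remains statistically resolvable.
Calibration checks use 10⁴ null SNP tests and 50 null eSNP replicates; the
randomized negative control uses 20 replicates.

## Known limitations

- The dynamic-cut variant is a simplification; deeply nested or strongly
  unequal-size module structures may be split or merged differently than by
  the full published hybrid algorithm.
- The tagging-enrichment null conditions on SNP positions, not on LD
  structure; with strong LD the binomial tail is anti-conservative.
- Score tests lose accuracy in tiny strata or near-separation; such SNPs
  are flagged rather than rescued.
- eSNP models are unadjusted (see above); trans effects are out of scope.
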