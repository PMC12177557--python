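# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Synthetic cohorts

The generator emulates the data structure of a genotyped outbred cohort
with bulk blood RNA-seq: by default 255 samples in six batches with
balanced sexes, biallelic SNPs with MAF ≥ 0.05 on one autosome, and
negative-binomially distributed gene counts with library sizes drawn
uniformly between 20M and 60M reads.

**Genotypes.** Each diploid individual is two mosaics of
`n_founder_haplotypes` (default 30) founder haplotypes; mosaic block
lengths are exponential with mean `block_length_mean` (default 500 kb).
Founder alleles themselves persist along the chromosome as a Markov
chain with persistence length `ld_decay` (default 300 kb): at each
variant an allele is redrawn from the variant's founder frequency with
probability `1 − exp(−d/ld_decay)` for inter-variant distance d. The
mosaic alone would give within-block dosage correlations of order
1/n_founders; the persistence layer is what creates the blockwise
r² ≈ 1 structure that windowed pruning, proxy-hit evaluation and
top-SNP ties require. Realized LD at default settings: adjacent-variant
mean r² ≈ 0.6 with ~40% of pairs above 0.7, decaying below 0.01 beyond
~2.5 Mb. Variants whose sample MAF falls below the floor are dropped;
missing calls are injected at rate `missing_rate` (default 1%)
afterwards, so the floor is enforced on complete data.

**Expression.** Gene g, sample j counts are NB with mean
`libsize_j/10⁶ · 2^η_gj` and dispersion 0.05 (variance = m + 0.05 m²),
where η collects a N(5, 1.5²) baseline log2-cpm, sex and batch effects
(SD 0.1 each), a polygenic term u ~ N(0, G) scaled so it contributes
`h2_polygenic` (default 0.2) of the non-count log2 noise, residual
N(0, 0.4²) log2 noise, and the planted effects. Because the link is
log2, planted β are directly in log2-cpm units per alt allele.

**Planted effects.** Cis effects sit within 1 Mb of a gene's TSS with
β ~ N(0, cis_beta_sd), or ±`cis_beta_fixed`, or — for calibrated study
conditions — scaled so the variant explains `cis_r2_target` of the
gene's expression variance. The calibration divides the target variance
ratio by the gene's *realized* non-cis log2 variance plus the
delta-method NB counting noise `(1/m̄ + φ)/ln²2`; this keeps the
realized variance explained centred on the target regardless of the
causal variant's allele frequency. Hotspots are specified as
(variant index, number of target genes, β); targets are drawn from
genes more than 2 Mb away and receive the effect with random sign.
Hotspots are planted before cis effects so the calibration sees them.
All planted effects are recorded in a `TruthTable` whose variant ids
are validated against the emitted genotype matrix.

**Traits.** `simulate_trait` builds effect·dosage + polygenic +
residual, standardized to unit variance; the acceptance simulations use
an exact-variance variant (residual orthogonalized against the causal
dosage) so "variance explained" is a planted condition rather than a
random outcome.

**What is not emulated.** No reference sequence or read-level
simulation; no sex chromosomes; no population stratification beyond the
shared founder pool; no expression-count correlation between genes
other than through planted genetics; library composition effects only
arise from the planted differential effects themselves. Passing tests
therefore demonstrate the correctness of the statistical machinery
under the stated generative model, not robustness to artefacts (batch
confounding, mapping bias, composition shifts) that real cohorts add.

## Normalization

TMM follows the Robinson–Oshlack estimator: reference column = the one
whose 75th-percentile cpm is closest to the mean across samples; M and
A computed over genes positive in both columns; 30% of each M tail and
5% of each A tail trimmed (average ranks for ties); factor =
2^(weighted mean M) with inverse delta-method binomial variances as
weights; factors rescaled to geometric mean 1. A column whose M values
are all below 10⁻⁶ in magnitude gets factor 1 directly, which makes
pure depth scaling an exact no-op. Raw zeros become missing *before*
the log2-cpm transform, so no pseudo-count is needed (default prior 0;
an explicit prior is accepted). The expression filter keeps genes whose
cpm exceeds 10/L_min (L_min = smallest library in millions, an input
that defaults to the observed minimum) in strictly more than 35% of
non-missing samples — ties at exactly 35% fail. The outlier screen per
gene: if Shapiro–Wilk p < 0.01, mask the single sample whose removal
maximizes the leave-one-out p, provided that p reaches 0.01; repeat up
to 3 times. Values are masked per gene (the sample's other genes are
untouched); at least 8 non-missing values are required.

## Genotype QC and multiple testing

MAF is computed on non-missing calls; the missingness rule is strict
("more than 10%"). Pruning works per chromosome on mean-imputed
dosages with composite r² (squared Pearson correlation): windows of
0.5 Mb anchored at retained variants, the later-positioned member of a
violating pair removed (equal positions: lower MAF removed), anchor
advanced by 10 retained variants. Because a sidestep of 10 can leave
violating pairs between anchors, sweeps repeat until stable and a final
sidestep-1 sweep enforces the postcondition — the emitted set never
contains a within-window pair with r² > 0.7, and pruning is idempotent.
The per-test threshold is α divided by the surviving count.

## Mixed-model association

REML profiles the likelihood over λ = σ²g/(σ²g+σ²e) after one
eigendecomposition of G (Yang-style GRM on mean-imputed dosages,
monomorphic variants excluded), with β and the overall scale profiled
out analytically. A 32-point grid locates the basin; bounded scalar
minimization refines λ to a 10⁻⁶ bracket; λ is clamped to [0, 1−10⁻⁶].
The genetic variance is retained only if the boundary likelihood-ratio
statistic against σ²g = 0 exceeds 2.706 (5% critical value of the
½χ²₀+½χ²₁ mixture); otherwise the fit falls back to ordinary least
squares, the same behavior the large-cohort GWAS tools adopt. This
fallback also keeps the two-step scan and a per-SNP joint refit
consistent: without it, the ratio is weakly identified at small n and
the two estimates wander independently on a flat likelihood surface.

The scan holds the ratio λ at the null estimate, rotates each SNP into
the eigenbasis, projects out the fixed effects, and re-estimates the
residual scale per SNP; the Wald statistic uses a t(n−p−1) reference by
default (`use_t=False` switches to the normal reference). With an
identity GRM this collapses exactly to ordinary simple/multiple
regression. Constant or covariate-collinear variants yield p = 1 with a
`degenerate` flag. Missing phenotype values are dropped casewise; the
eigendecomposition cache is keyed by the analysis subset, so complete
phenotypes share a single decomposition.

At desk scale the GRM must contain enough independent LD blocks that a
tested variant's own block is a negligible GRM fraction; the acceptance
simulations use 3,000 variants over 120 Mb for this reason (proximal
contamination shrinks planted signals when a 50–800-variant GRM is
reused for the scan). This mirrors, scaled down, the reference regime
of millions of GRM variants.

## eQTL rules

Region grouping splits a gene's position-sorted significant SNPs at
gaps ≥ 1,000,000 bp ("less than 1 Mb apart" read strictly), discards
clusters with fewer than 3 SNPs, extends survivors 0.5 Mb per side
(floored at position 1, capped at the chromosome end when known), and
selects the top variant by smallest p with position as the
deterministic tie-break. The cis label uses distance to the nearest
gene-body boundary (0 inside the gene), inclusive at exactly 1 Mb, same
chromosome required; a region is cis if any member SNP is cis.
Hotspots count distinct associated genes per variant (≥ 10);
top-hotspots count regions in which the variant is top (≥ 10). QTL
overlap intersects closed intervals of the extended eQTL coordinates
with QTL intervals on the same chromosome.

## Colocalization

Per SNP, the Wakefield log approximate Bayes factor is
`0.5·log(1−r) + z²r/2` with r = W/(V+W), V = se², W = prior_sd²
(default prior_sd 0.15, appropriate for z-standardized quantitative
traits). Hypothesis evidence uses log-sum-exp accumulation: S1, S2 over
single-trait ABFs, S12 over their products; H3 = log-difference
exp(S1+S2) − exp(S12), floored at −∞ with a warning if numerically
negative. Priors default to p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ (the cited
convention for this class of analysis) and are validated against the
region's SNP count. Posteriors are emitted as fractions in [0, 1]; the
95% credible set is the smallest descending-posterior prefix reaching
0.95, ties broken by position. Scans are aligned by inner join on
variant id; records with non-positive standard errors are dropped
first.

## PCIT

For every trio the three first-order partial correlations are computed;
the tolerance ε is the mean of the partial-to-marginal ratios, skipping
ratios whose marginal |r| < 10⁻¹² (if all three are skipped, ε = 1). An
edge (x,y) is removed only when it is dominated — |r_xy| < |ε·r_xz| and
|r_xy| < |ε·r_yz| — for *every* third variable z. Zero-variance
variables and perfectly correlated pairs are rejected (partial
correlations undefined). Correlations use pairwise-complete samples, so
traits with missing values can be appended as extra variables.

## Problem sizes and determinism

Everything is deterministic given the configured seeds; pipeline reruns
are byte-identical. The test and acceptance simulations use cohorts of
n = 60–500 with 50–10,000 variants and 40–80 genes, and 30–50
replicates per stochastic rate — sizes at which every stochastic check
has comfortable margins while the whole suite runs in about a minute.
The null-calibration check uses 10,000 SNP tests on one phenotype
(n = 400, λ = 0.3); planted-recovery uses n = 255, matching the
reference cohort size.

## Known limitations

- The P3D scan and a per-SNP joint REML refit agree only where the
  variance ratio is well identified; at n ≈ 60 the REML surface is
  nearly flat and refit estimates are themselves unstable, which is why
  the refit-agreement check uses unstructured phenotypes and a
  genome-panel GRM.
- The LRT fallback makes small-n fits prefer OLS; genuinely heritable
  phenotypes at n ≲ 100 may be scanned without the polygenic term.
- TMM equivariance under depth scaling is exact only on noise-free
  input; with composition noise the delta-method weights depend on
  depth, as in the reference estimator.
- The colocalization module assumes at most one causal variant per
  trait per region; multi-causal fine-mapping is out of scope.
- PCIT is O(n³) in variables; intended for hotspot-sized gene sets
  (tens), not whole transcriptomes.
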