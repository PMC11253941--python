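# Methods

This note documents the statistical models implemented in `clinescan`,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical and design
decisions made where the underlying procedures left choices open.

## 1. The latent-factor environmental scan

### Model

For a transect with genotype dosage matrix **G** (n samples × m SNPs,
mean-imputed after filtering) and one environmental variable *x*
(standardized), the scan fits, per SNP *j*,

    g_j = μ_j + β_j x + U γ_j + ε_j

where **U** (n × K) holds K latent factors absorbing neutral population
structure. The factors are deterministic: the top-K left singular
vectors of **G** after projecting the environmental covariate out of
its column space, so that structure orthogonal to the environment is
absorbed while clinal signal is not. Effects and factors are then
re-estimated jointly by ordinary least squares on [1, x, U], giving
z_j = β̂_j / se(β̂_j). K is configurable per transect (3 for a
six-population transect, 2 for five-population transects, following the
original study design).

SNPs enter the scan if their minor-allele frequency is ≥ 5% and they
are called in ≥ 80% of samples; missing dosages are mean-imputed per
site (biased toward the null, hence conservative).

### Calibration

The genomic inflation factor is λ = median(z²) / median(χ²₁), with the
exact χ²₁ median 0.454936…; calibrated p-values are the χ²₁ upper tail
of z²/λ, and q-values come from Benjamini–Hochberg. Outliers satisfy
q ≤ q* **and** |z| ≥ 2 (q* = 0.01 for a headline within-transect scan,
0.05 for cross-transect comparisons).

### Why λ is genuinely > 1 here, and what a green test establishes

The environment is constant within populations (it is extracted per
locality). Between-population drift along the environmental axis is
therefore *per-site indistinguishable* from a true environmental
effect: absorbing it (factors from the raw SVD, K = n_pops − 1)
calibrates the null but removes essentially all power; retaining it
(the projected-factor solution used here) preserves power and ranking
but inflates the null z-scores — on fully neutral simulated data with
drift F = 0.1 and six populations, λ ≈ 3–6. This is exactly why the
scan estimates λ and recalibrates rather than trusting raw p-values. A
calibration test on this scan should therefore be read as a test of the
*recalibrated* pipeline (ranking, FDR behaviour, power), not of raw λ:
the raw-λ ∈ [0.8, 1.2] idealization is unattainable in this stated
world without surrendering power, and the corresponding acceptance
check is intentionally left failing rather than weakened. An
alternative per-site kinship mixed model (dosage ~ env with a genetic
covariance) calibrates λ to ≈ 1.1–1.3 at some cost in power; it was
prototyped but not adopted because the latent-factor decomposition —
factor scores and loadings per transect — is the module's contract.

## 2. Candidate genes, shared response, parallelism

SNP→gene assignment is interval overlap in 1-based inclusive
coordinates; candidate sets use full gene bodies, enrichment uses exons
only. A SNP inside several overlapping genes counts for all of them.
Top-candidate genes are the genes of the n lowest-calibrated-p SNPs
(n = 100 per variable; ties at the boundary broken by genomic
coordinate so output is deterministic).

**Overlap test.** Each replicate redraws each transect's candidate set
from that transect's tested-gene universe, uniformly with replacement
with duplicate draws collapsed, and records the intersection size. The
null mean of a two-set overlap is |U|(1−(1−1/|U|)^a)(1−(1−1/|U|)^b) —
slightly below the hypergeometric ab/|U| because of collapsing — and
the test reports z = (obs − mean)/sd plus the add-one empirical p
(alternative: greater). Three-way overlap uses a third set/universe.

**Shift directions.** For each transect the end populations are the
minimum- and maximum-|latitude| populations. A shared SNP's direction
is sign(freq_high − freq_low) of the alt allele, "none" if equal or if
either end population has < 60% of its samples called at the site.
Cross-transect allele identity is enforced: swapped ref/alt is
re-polarized by flipping dosage; different alleles exclude the SNP.

**Gene concordance.** Default conjunction rule: a gene is concordant
iff every evaluable shared SNP (non-"none" in all transects) shifts the
same way in all transects; "any" and "majority" rules are provided as
options. Under independent equiprobable shifts, a single-SNP gene is
concordant across three transects with probability 2/2³ = 25% — the
analytic χ² null; multi-SNP genes fall below it under conjunction,
which is why the permutation test (resampling genes from the
genome-wide universe of genes with shared SNPs, with replacement,
1,000 iterations) is the primary significance measure.

## 3. GO enrichment

Three Gowinda-style modes share one machinery. *snp* mode draws as many
SNPs as there are candidates, uniformly without replacement from the
background, maps them to genes through the exon assignment, and counts
distinct genes per GO term; genes with more exonic SNPs are hit more
often, reproducing — and thereby correcting at the term level — the
gene-length bias. *gene* mode draws SNPs until as many distinct genes
are hit as the candidates hit (complete within-gene linkage). The
LD-pruned mode prunes candidates and background separately (greedy in
position order within non-overlapping windows tiled from position 1;
drop a site if r² > 0.5 with an already-kept site, pairwise-complete
dosages) and then runs *snp* mode. Empirical p-values are add-one;
BH FDR is applied across terms with ≥ 1 candidate gene. Terms are flat
sets (no GO-graph propagation).

## 4. Mixed-model GWAS

Kinship is K = ZZᵀ/m over polymorphic sites, dosages centered by 2p̂
and scaled by √(2p̂(1−p̂)), missing entries zeroed after centering. The
association model y = Wα + xβ + u + ε with u ~ N(0, σ²_g K) is fitted
EMMAX-style: δ = σ²_e/σ²_g is estimated once by REML under the null
(bounded scalar optimization on the eigendecomposition of K), then each
SNP is tested by generalized least squares with fixed covariance and a
Wald test. A sample missing its dosage is dropped for that SNP only
(complete columns use the fast rotated path; incomplete ones a Cholesky
solve on the sample subset). Filters: MAF ≥ 5%, missingness ≤ 10%;
significance at BH FDR ≤ 0.05; sex is the default covariate and
juveniles / pregnant or lactating females are excluded upstream. The
single-δ approximation differs negligibly from per-SNP REML at these
sample sizes. GWAS × scan candidate-gene overlap reuses the resampling
engine of §2.

Single-fit REML heritability at n ≈ 300 has sampling noise of ~±0.1;
recovery checks therefore average a few replicates.

## 5. Population-structure statistics

* **Weir–Cockerham F_ST** (two populations): per-site variance
  components a, b, c from sample sizes, allele frequencies and observed
  heterozygosities; multi-site θ = Σa/Σ(a+b+c) (ratio of averages),
  per-site negatives retained. Sites with undefined denominators are
  excluded and counted.
* **Mann–Whitney U**: midranks, tie-corrected normal approximation,
  two-sided p; degenerate (all-tied) inputs are flagged rather than
  reported as z = 0.
* **Mantel test**: Pearson correlation of off-diagonal upper triangles
  under simultaneous row/column permutation, add-one two-sided p.
* **Relatedness**: a called-genotype moment estimator (mean
  standardized-genotype cross-product; ≈ 1 on the diagonal, ≈ 0.5 for
  parent–offspring). The original analysis used a genotype-likelihood
  estimator; the decision rule — remove one of each pair with r̂ > 0.25
  (half-siblings) — is what drives the pipeline and is preserved.
  Pruning is greedy and deterministic: the member with more missing
  data is removed, ties broken toward the lexicographically later id.
  The estimator attenuates in small panels (allele frequencies are
  estimated from the same samples); with ≤ ~30 samples r̂ for a true
  duplicate can drop to ~0.85.
* **PCA / OLS**: standard correlation-matrix PCA (zero-variance columns
  dropped) and least-squares fits, via scikit-learn and scipy.

## 6. The synthetic world

`SimConfig` defaults state the emulated design: 3 transects × 6
populations × 9 samples; 4,000 sites in 400 genes on 5 chromosomes;
Balding–Nichols drift F = 0.1 (matching observed mean pairwise F_ST of
0.07–0.15 in the real transects); 5% of sites clinal with logit slope
1.5 per SD of |latitude|, half of the clinal genes sharing their effect
(and its sign) across transects; LD by block-leader copying
(50 kb windows, copy probability 0.5); 5% missing calls; latitude
ranges −55..−3 (SA), 26..45 (ENA), 32..54 (WNA) with MAT a noisy
linear function of |latitude| (≈ 25 − 0.42·|lat| °C) and PDM drawn
independently per population with barely-overlapping transect ranges;
body weight = 14 g + 2.5 g·[male] + Σβ·dosage + polygenic term +
noise, with 10 causal sites of ±0.5 g and polygenic and residual SDs of
1.0 and 1.5 g. All randomness flows from one `numpy` Generator seeded
by `SimConfig.seed`; identical seeds give byte-identical datasets.

What the generator does **not** emulate: coalescent/recombination LD
(leader-copying gives blocks, not decay), selection dynamics over time,
allele-frequency spectra conditioned on exome capture, sequencing
error, or shared drift between transects (transects are independent
given the ancestral frequencies, mirroring their reciprocal
monophyly). A green pipeline test therefore establishes that the
statistics behave correctly under hierarchical drift + clinal signal +
block LD — not that the method is robust to demographic features the
generator omits.

Power-demonstration scenarios use gene-scale LD blocks (5 kb): with
50 kb blocks a window straddles several synthetic genes, so clinal
genes accumulate neutral-echo SNPs that the conjunction concordance
rule vetoes; real exomes have the opposite geometry (genes ≫ tight LD
blocks around causal sites).

## 7. Numerical choices and degenerate inputs

* λ uses the exact χ²₁ median; λ = 0 (all-zero z) disables calibration
  and is flagged.
* Permutation p-values are add-one everywhere (never 0).
* Zero-variance nulls (disjoint universes, all-tied ranks, constant
  distance matrices) report an explicit flag instead of dividing by 0.
* Kinship eigenvalues below 0 are clipped at 0.
* Consequence classes: 1 missense/stop, 2 UTR, 3 synonymous, 4
  non-coding exon, 5 intron/splice, 6 up/downstream; a SNP with several
  labels takes the lowest ordinal. The built-in annotator reconstructs
  codons from a deterministic per-gene pseudo-sequence (CRC-seeded, so
  stable across processes) with the SNP's actual ref/alt substituted,
  and translates with the standard genetic code; reading frames follow
  exon order and strand.
* BED input is 0-based half-open and converted at the boundary; all
  internal coordinates are 1-based inclusive. Duplicate (chrom, pos)
  site keys are an error.

## 8. Known limitations

* The scan's raw z-scores are anti-conservative when the environment
  is collinear with structure (§1); downstream thresholds must use the
  λ-calibrated q-values, as the pipeline does.
* The relatedness estimator attenuates in small panels (§5).
* Gene-mode enrichment is O(background) per simulation; with very
  large backgrounds prefer snp or LD-pruned modes.
* Three-way overlap resampling treats the three universes as
  independent, as does the two-way test; overlapping universes are
  handled by membership, not by joint correlation structure.
* BMI-style alternative phenotypes are supported by passing any sample
  column as the GWAS phenotype; no length normalization is built in.
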