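# Methods

## The pooled caQTL model

A chromatin-accessibility QTL (caQTL) is a variant whose alleles differ in
local chromatin openness. In a pooled design, many genotyped cell lines are
combined and ATAC-seq is performed once on the pool. Because ATAC-seq reads
originate preferentially from open chromatin, a cis-acting allele that
increases accessibility is over-represented among the reads covering it.
The caQTL signal at SNP *i* is therefore a shift between two allele
frequencies:

- the **post-ATAC frequency** `p̂ᵢ = mᵢ/nᵢ`, estimated from the minor- and
  total-read counts at the SNP, and
- the **pre-ATAC frequency** `pᵢ = Σⱼ wⱼ Gᵢⱼ`, the frequency implied by the
  pool's genotypic composition, where `Gᵢⱼ ∈ {0, 0.5, 1}` is individual
  *j*'s minor-allele dosage and `wⱼ` its pooling weight.

The weights `wⱼ` are *effective* pool proportions: they absorb pipetting
variation and global (trans-acting) differences in total open chromatin
between samples, because a sample with more open chromatin contributes more
reads at every SNP. Estimating weights from the assay output itself, rather
than sequencing the pre-ATAC pool, removes this class of trans variation
from the cis test.

## Weight estimation (`pool_weights`)

Assuming most SNPs are not caQTLs, each testable SNP contributes one noisy
observation of the linear model `E[p̂ᵢ] = Σⱼ wⱼ Gᵢⱼ`. The sum-to-one
constraint is imposed by substituting `wₙ = 1 − Σⱼ<ₙ wⱼ`, giving an
intercept-free regression of `p̂ᵢ − Gᵢₙ` on the differenced predictors
`Gᵢⱼ − Gᵢₙ` (j = 1..n−1). The reference individual *n* is the last after a
canonical sort by sample ID, making results independent of input order.
No 0 ≤ w ≤ 1 constraint is enforced; estimates outside the range raise a
warning flag but are retained.

Three regression weighting modes are provided:

- `variance` (default): weights ∝ nᵢ, i.e. residual variance ∝ 1/nᵢ, the
  inverse-variance rule implied by binomial sampling error;
- `literal`: weights ∝ nᵢ^(−1/2);
- `none`: ordinary least squares.

The two non-trivial modes reflect a genuine ambiguity in how
depth-dependent weighting can be phrased; in practice the estimates are
nearly identical (the fit is heavily over-determined), so the default is
the variance-motivated rule and all modes are tested to recover noiseless
inputs to machine precision.

Individuals genotypically identical to the reference over the SNPs used
produce all-zero predictor columns; they are collapsed with the reference
and the leftover weight is split equally (with a log message). Identical
*non*-reference pairs make the design rank deficient and raise a hard error
naming the pair. If every individual is identical, weights are uniform 1/n.

The regression covariance Σ of the free weights (from the WLS fit) feeds
the downstream variance of the pre-ATAC estimate.

## Pre-ATAC frequency and variance (`pre_freq`)

`p̂ᵢ_pre = Σⱼ ŵⱼ Gᵢⱼ`, clipped to [0, 1] with the raw value kept in
diagnostics. Treating the free weights as approximately multivariate
normal, the variance is the quadratic form `vᵢ = dᵀ Σ d` with
`dⱼ = Gᵢⱼ − g_ref,ᵢ`. This differenced form is algebraically identical to
the expanded three-term double sum over Σ entries but avoids the
catastrophic cancellation of evaluating three large terms; a literal
triple-sum implementation is retained as a test oracle. When all genotypes
at a SNP coincide, d = 0 and vᵢ = 0 exactly — the pre-ATAC frequency is the
same under any weights, so weight uncertainty contributes nothing.

## The significance test (`caqtl_test`)

Conditional on depth nᵢ (empirically Poisson after duplicate removal, so
binomial sampling of reads is appropriate), `mᵢ ~ Bin(nᵢ, pᵢ)` with
`pᵢ = pᵢ_pre` under the null. The two-sided p-value uses a **distance
rule**: sum the binomial probabilities of every outcome *j* whose frequency
j/n lies as far or further from the null frequency as the observed m/n.
(This is distance in frequency space, not likelihood ordering; the two
differ for asymmetric null frequencies. The rule reproduces the canonical
toy case p_pre = 0.5, n = 10, m = 3 → inclusion set {0,1,2,3,7,8,9,10},
p = 352/1024 = 0.34375.)

Because p̂_pre is itself an estimate, the reported p-value integrates the
exact p-value over a normal prior on the null frequency, truncated to
[0, 1]:

    pv = (1/C) ∫₀¹ φ(p; p̂_pre, v) pv_exact(p; n, m) dp,
    C  = ∫₀¹ φ(p; p̂_pre, v) dp.

Plugging in p̂_pre while ignoring v gives optimistic p-values; a Z-test on
the standardized difference is anti-conservative at small n or small p and
is retained only as a comparator (`naive_z_pv`).

**Quadrature.** For fixed (n, m), pv_exact(p) is piecewise smooth in p with
jump discontinuities exactly at p = (k + m)/(2n), k ∈ ℤ (where the tail cut
points of the inclusion set cross integers). The integral is computed by
splitting [0, 1] ∩ [p̂_pre ± 10σ] at those breakpoints and applying
12-point Gauss–Legendre quadrature on each smooth piece; between
breakpoints the integrand is an analytic function (Gaussian × polynomial
tail sums), so the result is accurate to ~1e-10 and stable under refinement
(doubling the rule order changes fixture cases by < 1e-10). A generic
fixed-grid rule was rejected because jump discontinuities destroy its
convergence order. The omitted normal mass outside ±10σ is below machine
precision; C uses the untruncated Φ difference. Variances below a floor of
1e-12 (configurable) collapse the prior to the plain exact test; C
underflowing to zero (prior mass entirely outside [0, 1]) is a hard error.

**Calibration.** The distance-rule p-value is an exact test and therefore
*super-uniform* under the null: P(pv < α) ≤ α, with a deficit of roughly
half the probability atom at the α crossing. Mixing over Poisson depths,
allele frequencies and the prior integration smooths but does not remove
this: at the package's standard null conditions the measured rejection
fraction at α = 0.05 is ≈ 0.044–0.045 rather than 0.050, and the p-value
distribution has an atom near pv = 1 (the most probable outcome). This
slight conservatism is a property of exact tests, not an implementation
artifact; the test never exceeds its nominal level, which is the property
that matters for FDR control of the calls.

**Testability filter.** A SNP is testable in a pool if its replicate-summed
depth is ≥ 20 reads and the pool minor-allele frequency exceeds 0.01
(strict). caQTLs are called at pv < 5×10⁻⁴ (strict) per population.

## Multi-population combining (`multipop`)

Populations differ in LD structure, so causal variants associate
consistently across them while tag SNPs drop out where LD breaks down.
Per-SNP evidence is combined with Fisher's method, `X² = −2 Σᵢ ln pᵢ`,
compared to chi-square with df = 2k. SNPs untested in a population
contribute p = 1 (ln 1 = 0); by default k counts *all* populations
(consistent with that substitution), with a "tested-only" df option since
the convention is not uniquely determined. Shared caQTLs are combined
p < 5×10⁻⁶ (strict). Direction concordance requires every population
significant at 5×10⁻⁴ to agree on the more accessible allele; the summary
fraction is taken over shared caQTLs significant in ≥ 2 populations.

Pairwise sharing uses the Storey π₁ = 1 − π̂₀ statistic with a single fixed
λ = 0.5 (π̂₀ = #{p > λ} / ((1−λ)N), clamped to [0, 1]); a λ-grid smoother
was deliberately not added, keeping the estimator transparent. Validation
enrichment is also reported per stratum of the number of significant
populations, as overlap fraction relative to the full testable background
(empty strata report missing, not zero).

## Enrichment and annotation analyses (`enrichment`)

Standard machinery around the calls: fold enrichment with two-sided
Fisher's exact p; direction agreement with external QTLs across p-value
cutoffs; Pearson correlation of signed effect sizes (with optional
orientation harmonization); chromatin-state composition with
read-depth-matched controls (greedy one-to-one matching within
|log₂ depth ratio| < 0.5, visiting caQTLs in seeded-random order and taking
the closest available control; unmatched caQTLs are dropped and counted);
motif position-wise caQTL density against information content
IC = 2 + Σ_b f_b log₂ f_b bits; MAF contrasts by Wilcoxon rank-sum with
lower-interpolation medians; LD r² as squared Pearson correlation of
dosage vectors (a genotype-based surrogate for haplotype r², adequate for
unphased inputs) with expansion above a strict r² threshold within a 1 Mb
window; and the paired allelic-difference harness (rank-sum p ×
n_parameters Bonferroni, capped at 1, default 4 parameters as used for
DNA-shape comparisons).

## Allele-specific contacts (`hic_eqtl`)

Long-range contact reads phased to each allele of a caQTL are compared with
a two-sided binomial test against 0.5 (default α = 0.05, configurable,
reported across a small α grid since no single threshold is canonical).
The open_more/closed_more ratio with a sign-test p measures whether the
more accessible allele makes more contacts. "No-interaction-effect" SNPs
require binomial p > 0.5 *and* ≥ 100 supporting reads, so absence of bias
is positively supported. The proximal (<10 kb) / distal (>100 kb) eQTL
enrichment contrast compares caQTLs against non-caQTLs (combined p > 0.5)
by Fisher's exact test, optionally restricted to the no-effect set — the
qualitative signature of interaction-mediated distal regulation is distal
enrichment that vanishes within the restricted set while proximal
enrichment persists. Entry into the contact analysis is gated on a strict
majority of tested populations agreeing with the pooled allelic direction.

## Synthetic data (`synthetic_data`)

The generator emulates the statistical structure of the pooled experiment,
not its sequence-level mechanics:

- **Genotypes**: ancestral minor-allele frequency per SNP ~ Uniform(0.05,
  0.5); per-population frequencies by a Balding–Nichols Beta draw with
  divergence F = 0.05 (F = 0 gives identical populations); Hardy–Weinberg
  Binomial(2, f)/2 dosages within population.
- **Pool composition**: Dirichlet(50) weights over ~100 individuals per
  pool (coefficient of variation ≈ 0.14 around equal pooling); optional
  log-normal per-individual trans scalars.
- **Reads**: depth per SNP/replicate ~ Poisson(100); minor reads binomial
  with success probability from the haplotype-mixture model
  `p_post = Σ_h u_h a_h x_h / Σ_h u_h a_h`, where each of the 2N haplotypes
  carries weight u_h = w_j t_j / 2 and allelic accessibility a_h = ρᵢ on
  minor haplotypes (1 otherwise). This model was chosen because the null
  (ρ = 1) reduces *exactly* to p_post = Σⱼ (wⱼtⱼ/Σwt) Gᵢⱼ and an isolated
  heterozygote shows allelic ratio ρ/(1+ρ). Two replicates are drawn
  i.i.d. (replicate library-size variation is not modelled).
- **Effects**: a fraction (5% in effect scenarios) of SNPs receive allelic
  fold-change ρ = 3 with random orientation; a log-normal effect model is
  also available.

All randomness derives from one master seed via labelled SeedSequence
splitting, so stages are reproducible independently of execution order.

What the generator does **not** emulate: mapping or reference bias (counts
are taken as post-filtering allele counts), LD between SNPs (sites are
independent, so LD-based analyses are exercised on constructed fixtures),
genotyping error, overdispersion beyond Poisson depth, or peak structure.
Passing tests therefore demonstrate correctness of the statistical
machinery under its stated model, not robustness to those real-data
artifacts.

## Problem sizes used in tests

The bundled checks run single-CPU at desk scale, chosen to make the Monte
Carlo tolerances meaningful: weight recovery at 100 individuals × 20,000
SNPs (depth 60); null calibration at ~21,000 SNPs (depth 100 × 2
replicates); the Monte-Carlo oracle for the integrated p-value at 10⁶
draws per fixture case; the end-to-end study at 10 populations × 100
individuals × 2,000 SNPs with 5% effects at ρ = 3. At those settings the
end-to-end run yields high recall at per-population p < 5×10⁻⁴ with
empirical FDR below 5%, and > 95% cross-population direction concordance
among shared caQTLs.

## Known limitations

- Genotype dosages are treated as exact; genotype uncertainty is not
  propagated.
- The binomial read model assumes dispersion ≈ 1; no negative-binomial
  generalization is provided.
- π₁ uses a single-λ estimator; no smoothing.
- LD r² is computed from unphased dosages, not haplotypes.
- Behaviour of the integrated test for p̂_pre exactly at 0 or 1 with
  non-zero variance follows mechanically from the truncated-normal prior;
  there is no external reference for this edge case.
- Replicate reproducibility (IDR-style) analyses are limited to keeping
  replicates separate in `merge_replicates`; no copula-mixture fitting.
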