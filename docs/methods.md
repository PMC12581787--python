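# Methods

`panelcraft` implements, as one coherent toolkit, the computational pipeline
around a targeted-genotyping (GBTS-style) SNP array for a diversity panel of
a perennial ornamental crop: panel design from a resequencing VCF and a
reference genome, minimal fingerprinting SNP sets, population
characterization, EMMAX-style mixed-model GWAS, and genomic prediction
(GBLUP and the Bayes alphabet) with GWAS-derived fixed effects. A built-in
simulator makes every stage exercisable without any external data. This
note records the models, the defaults and why they are what they are, the
numerical choices, and the limits of what the synthetic experiments show.

## The selection funnel (panel design)

Raw variants pass four stages, each a pure filter (stage output ⊆ stage
input, with counts logged to a funnel report):

1. **Quality filter** — missing rate < 0.2, site QUAL ≥ 50, MAF ≥ 0.15,
   drop unplaced contigs. Thresholds are the array-design conventions for
   diversity panels; all four are parameters. Site QUAL is used; per-call
   GQ is not consulted.
2. **Flank QC + redundancy** — the 201-bp SNP region (100 bp either side)
   must fit on the chromosome (SNPs near chromosome ends fail outright:
   fixed-length probes cannot be placed), have GC in [0.4, 0.6], contain no
   N, and be unique in the genome. Uniqueness is seed-and-extend: exact
   k-mer seeds (default k = 15) anchor ungapped diagonal alignments over
   the full region, on both strands, excluding the self-hit; a region is a
   duplicate when some alignment spans ≥ 60% of it with ≥ 60% identity
   ("similarity" is interpreted as matches/aligned-span, the span
   requirement as coverage). A brute-force sliding-window aligner with the
   same acceptance rule is provided for desk-scale genomes (≤ ~50 kb) and
   is the oracle in the tests. Because seeds are exact k-mers, sensitivity
   decays for copies near the 60% identity floor (an exact 15-mer becomes
   unlikely); agreement with the oracle is therefore asserted in the regime
   where both are reliable — high-identity planted copies against random
   background — and near-floor duplicates may be missed by the fast path.
3. **Probe windows** — 100-bp windows at 1-bp steps over the 301-bp
   neighbourhood (150 bp either side), i.e. 202 windows; each is flagged
   for GC bounds, N-freedom, uniqueness (same engine) and SNP containment.
   A SNP survives if at least one window passes GC + N + uniqueness;
   whether a probe must contain its SNP is left open by the design
   conventions, so containment is preferred but not required. The chosen
   probe is the qualified window preferring SNP containment, then GC
   closest to 0.5, then leftmost. Uniqueness, the expensive check, is
   evaluated lazily in that preference order and stops at the first
   qualified window.
4. **LD pruning** — windowed greedy pruning (window 100 SNPs, step 10,
   r² > 0.2), with r² the squared Pearson correlation of mean-imputed
   genotype codes; pairs with < 20 co-observed samples are skipped. Within
   a window the member of the worst pair with the lower MAF is dropped
   (tie: higher column index). After the stepped passes converge, unit-step
   sweeps repeat until no window at *any* offset contains a violating pair
   — this makes the documented post-condition (no in-window kept pair above
   r²_max) literally true, which stepped-only pruning does not guarantee.

A second stream of linkage-map SNPs is cross-referenced against the variant
table on (chrom, pos, ref, alt), passed through the same flank/probe screen,
and merged; loci in both streams are kept once with source labels united,
and conflicting alleles at a shared locus are an error.

Panel characterization reports adjacent-SNP distances per chromosome (pairs
never span chromosomes), the fraction of adjacent pairs above 500 kb
(denominator: within-chromosome adjacent pairs), per-chromosome counts and
their Pearson correlation with chromosome length, and SNP effect classes.
Effect classification distinguishes intergenic / intronic / UTR /
synonymous / nonsynonymous by locating the SNP against gene models and, in
CDS, translating the reference and alternate codons strand-aware from the
spliced CDS (frame-adjusted); splice and regulatory classes are out of
scope.

## Fingerprinting

A SNP distinguishes an unordered sample pair when both calls are present
and unequal — a heterozygote is its own class. Candidates for
allele-specific (KASP-style) assays require zero missingness, MAF ≥ 0.15,
exonic location and flank QC (a designability proxy; thermodynamics are out
of scope). Minimal discriminating sets are greedy set cover (pick the SNP
covering the most residual pairs; tie: locus order), which is within one
SNP of optimal on the small instances where exhaustive search is feasible
(provided, ≤ 20 candidates). Partial coverage is reported, never an error.

## Population characterization

* **p-distance**: mean per-site allele-sharing dissimilarity,
  Σ|gᵢ−gⱼ| / (2·co-observed sites), pairwise-complete.
* **Neighbor-joining**: Saitou–Nei agglomeration via scikit-bio, negative
  branch lengths clamped to zero; exact on additive matrices. Bootstrap
  support by site resampling (default 100 replicates at desk scale).
* **PCA**: eigendecomposition of centered, mean-imputed genotype columns
  (the only place imputation happens in this module); components ordered by
  eigenvalue, sign fixed so each component's largest-|loading| entry is
  positive.
* **π**: per-site unbiased expected heterozygosity 2p̂q̂·n/(n−1) (n =
  observed alleles), averaged over genotyped sites per group. Note this is
  diversity *at the panel's SNP sites*, not per-bp over the genome.
* **F_ST**: Weir–Cockerham (1984) variance components with observed
  heterozygosity, combined ratio-of-sums across sites (stable, standard);
  pairwise over groups; all-monomorphic pairs give NaN, small negative
  estimates are reported as-is.

Model-based ancestry (ADMIXTURE-style) is not implemented; group labels
come from the user or from k-means on PCA coordinates as a convenience.

## Mixed-model GWAS

Kinship is the simple-matching coefficient: per co-observed site the pair
scores 1 (equal codes), 0.5 (one allele apart) or 0 (opposite homozygotes),
averaged. The diploid scoring behind the named coefficient is a
convention and is isolated in one function.

The null model y = Xb + u + e, Var(u) = σ_g²K, is fitted once by REML:
spectral decomposition of K (after a 1e-8 ridge), one-dimensional
maximization of the restricted likelihood over log λ (λ = σ_g²/σ_e²) by a
49-point grid plus bounded Brent refinement (xatol 1e-10), which reproduces
δ = σ_e²/σ_g² to ≈1e-6. Each SNP (mean-imputed) is then tested by GLS with
V̂ = σ̂_g²K + σ̂_e²I held fixed — the EMMAX approximation — with Wald
(χ²₁) p-values; monomorphic SNPs yield NA rows. The first 3 genotype PCs
enter X by default. With K = I and a fixed unit variance the scan is
exactly per-SNP OLS (asserted to 1e-8); against variance-re-estimating OLS
the betas agree to 1e-8 and the standard errors differ only by the fixed-
vs-per-SNP residual-variance convention.

The significance threshold is the effective-test count rule: N = SNPs
surviving LD pruning at r² 0.1 (window 100, step 10), threshold
−log₁₀(1/N) = log₁₀N, with an optional working override applied as
min(threshold, override). No permutation thresholds by default.

Genotype-group trait tests (single-SNP classes 0/1/2, not multi-SNP
haplotypes) report class means/medians, one-way ANOVA and pairwise Welch
t-tests starred at 0.05/0.01/0.001. Pairwise LD uses the standard 2-locus
EM for haplotype frequencies from unphased diploids (allele margins fixed
at their MLEs), giving D, D′ and r²; a composite genotype-correlation r² is
the fallback if the EM solution degenerates. Haplotype "blocks" are
simplified to maximal runs of consecutive pairs with D′ ≥ 0.98.

## Genomic prediction

* **GRM**: VanRaden method 1, G = MMᵀ/(2Σp_k(1−p_k)) with M centered by
  2p_k, plus a 1e-8 ridge.
* **GBLUP**: same spectral REML as the GWAS null; GEBVs
  û = σ̂_g² G V̂⁻¹(y − Xβ̂); H² = σ_g²/(σ_g²+σ_e²). The core correctness
  oracle is the algebraic identity with ridge-regression marker effects
  (RR-BLUP) at shrinkage λ = c·σ_e²/σ_g², asserted to 1e-6.
* **Bayes alphabet**: Gibbs samplers for y = Xb + Wa + e. BayesA: marker
  effects with per-marker scaled-inverse-χ² variances (df 5, scale set so
  the prior genetic variance targets R² = 0.5 of phenotypic variance, the
  common heuristic of Bayesian-regression packages). BayesB adds a point
  mass at zero with exclusion probability π (default 0.99) and per-marker
  slab variances; BayesC shares one slab variance. Inclusion is sampled
  from the exact marginal Bayes factor of the marker's score statistic.
  Defaults 3000 iterations / 500 burn-in / thin 5; chains are bit-for-bit
  reproducible given the seed. With π → 0 BayesC approaches ridge and its
  GEBVs correlate > 0.95 with GBLUP on the same data.
* **Cross-validation**: repeated k-fold (default 5-fold; 10 repeats at desk
  scale — the full-scale convention is 100, available by argument). Masking
  is structural: the predictor callable receives only training phenotypes
  plus index sets, so test labels cannot leak (poisoning them provably
  leaves predictions unchanged). Held-out GBLUP GEBVs come from
  σ_g² G[test,train] V_train⁻¹ (y_train − X_train β̂). PA is the Pearson
  correlation of observed phenotype vs predicted GEBV per fold (not vs true
  breeding values); PC = PA/√H²; improvement% = 100·(after−before)/before.
* **Marker titration**: random subsets without replacement at requested
  sizes, one CV per size, fully seeded.
* **Fixed-effect integration**: genotype codes of GWAS-hit SNPs are
  appended to X (collinear columns dropped with a warning) and removed from
  the random-effect marker set — the removal avoids double-counting their
  variance; whether to remove is genuinely open and this package's choice.

## The simulator

The generator emulates the study design the toolkit targets, at desk scale:

| parameter | default | rationale |
|---|---|---|
| chromosomes × length | 15 × 100 kb | study karyotype; length scaled down so uniqueness scans stay desk-sized |
| samples | 220 | diversity-panel size |
| SNPs | 5 000 | keeps O(n²·m) statistics interactive |
| subpopulations / F_ST | 4 / 0.25 | observed between-group divergence scale |
| LD block | 5 kb, 10 founder haplotypes | windowed-pruning has realistic work to do |
| missing rate | 0.02 | array-grade missingness |
| QTN / h² | 50 / 0.4 | mid-range polygenic trait; printed heritabilities span 0.25–0.45 |

Subpopulation allele frequencies follow a Balding–Nichols model
(Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral p ~ U(0.1, 0.9)), whose
frequency variance F·p(1−p) makes the Weir–Cockerham estimator recover the
target in expectation. This is an *emulation chosen to hit an F_ST target*,
not a claim about any real population's history. LD comes from block-wise
founder-haplotype copying (cheap and controllable; no coalescent, no
recombination map): each individual's two haplotypes per block are random
founders. Founder pools are constructed so their allele frequency equals
the subpopulation frequency up to stochastic rounding — naive Bernoulli
founders would add pool-level drift of order (1−F)/K and bias F_ST upward
by several points. Duplicate segments are planted copies with a configured
per-base mismatch rate at recorded coordinates, giving the redundancy
filter true positives. Phenotypes are y = W_QTN·a + e with i.i.d. normal
effects and the noise rescaled so the realized sample heritability equals
the target exactly (the fitted H² is then an estimate of a known truth).
simulate_f1 draws one allele per parent per locus (missing parent → missing
offspring).

What the simulator does *not* have — and therefore what passing tests do
not show about real data: recombination gradients and long-range LD decay,
allele-frequency spectra shaped by selection or bottlenecks, genotyping
error correlated with probe performance, polyploidy, shared ancestry
between "subpopulations" beyond the star-shaped Balding–Nichols model, and
genotype-by-environment variance in phenotypes.

## Problem sizes used by the checks

The statistical-calibration checks run at: H² recovery n = 400, m = 4 000,
10 seeds (|mean error| ≤ 0.10); F_ST recovery n = 200, m = 5 000 at target
0.25 (±0.05); null-GWAS uniformity 10 seeds (KS at α = 0.01, ≥ 9/10); PA vs
h² over {0.1, 0.3, 0.5, 0.7} at n = 300, m = 1 500, 5-fold × 3 repeats
(r > 0.9); fixed-effect integration at n = 200, m = 800, 20 CV repeats
(paired one-sided t, p < 0.05). These sizes are the package's desk-scale
choices; all are parameters.

## Known limitations

* The seed-and-extend uniqueness filter under-detects duplicates close to
  the 60% identity floor (see above); lower k increases sensitivity at
  index-size cost.
* The EMMAX approximation fixes variance components at the null — per-SNP
  exact REML (GEMMA-style) is out of scope.
* Multi-locus GWAS (QTN detection with LOD thresholds) is not implemented;
  single-marker hits stand in as fixed-effect candidates for prediction.
* π is computed over assayed SNP sites, so values are not comparable to
  genome-wide per-bp diversity.
* Diploid only; polyploid inputs are rejected at the VCF reader.
* Haplotype-block calling is a D′-run simplification, not a
  confidence-interval block definition.
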