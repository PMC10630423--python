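# Methods

This note records the models implemented in `euradmix`, the defaults and why
they were chosen, what the synthetic cohorts do and do not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Generative model (`simdata`)

**Cluster frequencies.** The Balding–Nichols model: per SNP an ancestral
frequency *p* ~ Uniform(0.05, 0.95) (bounded away from 0/1 so no site is
monomorphic by construction), and per cluster *k* a frequency drawn
Beta(*p*(1−F_k)/F_k, (1−*p*)(1−F_k)/F_k), i.e. mean *p*, variance
F_k·*p*(1−*p*). Two clusters with drifts F_i, F_j then satisfy

  E[(p_i − p_j)²] = (F_i + F_j)·p(1−p),  E[p_i(1−p_j) + p_j(1−p_i)] = 2p(1−p),

so the ratio-of-sums Hudson F_ST converges to (F_i + F_j)/2. The drift matrix
the user supplies holds **pairwise F_ST targets**; per-cluster drifts are
solved from F_i + F_j = 2·d_ij. At K = 3 this system is exactly determined
(for the default targets 0.033 / 0.032 / 0.028 it gives cluster drifts
0.037 / 0.029 / 0.027); at K = 2 it is under-determined and drift is split
equally; at K > 3 nonnegative least squares is used. This parameterization
makes F_ST recovery a genuine end-to-end check of both the generator and the
estimator rather than a tautology about a single stored constant.

**Ancestry tracts.** Each haplotype's ancestry is a Markov jump process along
the genetic map: breakpoints Poisson with rate *G* per Morgan, each segment's
ancestry drawn independently from the individual's α (self-jumps allowed).
This is the stationary tract process implied by a single admixture pulse *G*
generations ago: the ancestry autocovariance decays exactly as exp(−G·d),
which is the model the weighted-LD dating fits, and the exit rate from
ancestry *k* is G(1−α_k), giving mean tract length 1/(G(1−α_k)) Morgans.

**Mating models.** Two modes:

* `assortment_r=None` (default): both haplotypes of an individual share the
  individual's α — the classic admixture model. When α varies across
  individuals this carries a Wahlund homozygosity excess (positive F_IT) at
  ancestry-differentiated SNPs.
* numeric `assortment_r`: the cohort is an offspring generation. Two parents'
  first-ancestry proportions are rank-coupled through a Gaussian copula at
  correlation *r*; each offspring haplotype is stationary at one parent's α.
  *r* = 0 is random mating (haplotype ancestries independent, F_IT centered
  at zero); *r* → 1 reproduces the shared-α excess. This separation exists
  because "no assortment" means different things for F_IT depending on
  whether the cohort is itself a random-mating generation.

**Geography.** The gradient sampler assigns latitude ~ U(36°, 60°) and
longitude ~ U(−10°, 30°); northern ancestry rises linearly with latitude and
the two southern ancestries split along longitude, with Gaussian jitter of
scale 0.08 before renormalization. This produces the ancestry–latitude rank
correlations the admixture demo reports.

**Default genome.** 22 chromosomes × 100 cM, uniform recombination at
1 cM/Mb, evenly spaced markers. Uniformity is a deliberate simplification:
it supports leave-one-chromosome-out jackknives with near-equal block sizes
and makes tract statistics analytic.

**What the generator does not emulate.** Background LD within ancestries
(alleles are independent given tracts), mutation/genotyping error, phasing
error (haplotypes are truth-phased), sex chromosomes, multi-pulse or
continuous admixture, and real marker ascertainment. Consequently: local
ancestry here is easier than on real data (no LD to confuse the HMM, no
switch errors), and dating is cleaner (no background-LD contamination below
`d_min`). Passing recovery tests validates estimator correctness under the
stated model, not robustness to those real-data complications.

## Formats and QC (`genio`)

VCF v4.2 biallelic SNPs (cyvcf2 reader; writer emits deterministic field
ordering so canonical files round-trip byte-identically), PLINK-style
4-column maps with linear bp→cM interpolation clamped at map ends,
whitespace `.Q`/`.P` matrices (Q rows renormalized only when within 1e-6 of
the simplex), TSV tables; gzip accepted everywhere.

QC defaults: `mind` 0.05 → `geno` 0.05 → `maf` 0.01 → HWE mid-p < 1e-6, in
that order (the order is a documented convention, applied sample-filter
first so SNP statistics are computed on retained individuals). The HWE test
is the exact conditional test on heterozygote counts with the mid-p
convention, which behaves well at small counts. LD pruning is greedy within
sliding windows (50 SNPs, step 10, r² > 0.8 drops the later SNP), never
crossing chromosome boundaries; missing genotypes are mean-imputed for the
r² computation only.

`qc_filter(exempt_ids=...)` can exempt named variants from the SNP-level
filters. The association demo exempts the focal variant: a SNP with a 0.9
inter-ancestry frequency difference fails the HWE filter in an admixed
cohort for structural (Wahlund) reasons, and dropping the variant under
study would be a silent analysis error.

## Relatedness (`relatedness`)

Method-of-moments IBD: observed IBS 0/1/2 counts are equated to their
expectations given allele frequencies under IBD 0/1/2, solved sequentially
(δ₀ from IBS0, δ₁ from IBS1, δ₂ by difference), clamped to [0,1] and
renormalized; Φ = ½δ₂ + ¼δ₁. No small-sample correction factors are applied;
tests pass generative frequencies, which keeps the estimator unbiased at the
scales used. Relatives (Φ ≥ 0.0884, first/second degree) form a graph from
which vertices are removed greedily by degree (ties → larger index removed
first, keeping smaller ids) until no edge remains. On sparse cohort-style
graphs this matches exact maximum-independent-set keep-sets; an exhaustive
oracle verifies near-optimality on random graphs ≤ 15 nodes.

## Structure (`structure`)

PCA standardizes genotypes by (g − 2p̂)/√(2p̂(1−p̂)) and takes the SVD; the
largest-magnitude loading per axis is made positive so runs are comparable.
Projection standardizes targets with the *reference* means/scales, so
reference samples project onto their own scores identically.

Hull coverage = area(hull(target) ∩ hull(ref)) / area(hull(ref)) on PC1–PC2
(shapely polygon clipping), bounded at 1; a raw hull-area ratio mode exists
behind a flag for diagnostic use. The cluster count uses the Tibshirani gap
statistic with uniform reference sets drawn in the data's principal-axis
bounding box (B = 50, k-means with 10 restarts and fixed seed) and the
standard "smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1}" rule; the elbow curve
is available as a diagnostic but never used as the decision rule. Mantel's
test permutes rows/columns of the second matrix and reports the one-sided
(1 + #{ρ_perm ≥ ρ})/(n_perm + 1) p-value.

## Global ancestry (`admixprop`)

The binomial admixture likelihood is maximized by FRAPPE-style alternating
EM updates of Q and P — simpler than quasi-Newton block relaxation with the
same stationary points. P is clamped to [1e-6, 1−1e-6]; Q is initialized
Dirichlet(1,…,1) and P from sample frequencies plus N(0, 0.05) noise; the
log-likelihood is asserted nondecreasing every iteration; convergence is a
relative change < 1e-6 (fits used inside cross-validation relax to 1e-5 /
500 iterations for runtime). Supervised samples have Q rows pinned to unit
vectors and inform P only. Missing genotypes are dropped from the per-entry
likelihood sum, not imputed.

Cross-validation masks a random 10% of genotype *entries* per fold (5
folds), refits, and scores masked entries by binomial deviance under the
fitted f_is; the best K is the argmin of mean deviance. The same masks are
used for every K within a fold, so the comparison is paired.

## Differentiation statistics (`popstats`)

Hudson F_ST is the ratio of sums Σ(p₁−p₂)² / Σ[p₁(1−p₂)+p₂(1−p₁)], with
p(1−p)/(n−1) numerator corrections only when haploid sample sizes are
supplied (cluster frequency vectors are used uncorrected). F_IT(s) = 1 −
H_obs/H_exp with H_exp = 2p̂(1−p̂) in the whole cohort; monomorphic SNPs are
NaN. The assortative-mating diagnostic is the Spearman correlation across
SNPs between per-SNP north–south F_ST and cohort F_IT (rank correlation: the
relation is monotone, not linear, and heavy-tailed per-SNP noise argues
against Pearson).

f3(A, B; C) = mean over SNPs of (c−a)(c−b) − ĥ_c/n_c with ĥ_c =
c(1−c)·n_c/(n_c−1) and n_c the number of sampled target chromosome copies —
the finite-sample correction that makes E[f3] = 0 when C is an unadmixed
sample from the (A=B) source. The convention was validated against the
algebraic identity f3 = −mean((a−b)²)/4 at C = (A+B)/2. SE by deleting
contiguous 500-SNP blocks (SNP-count blocks rather than cM so map-free
frequency vectors work); z ≤ −3 flags admixture.

## Local ancestry (`localanc`)

A two-state (North/South) haplotype HMM replaces the random-forest CRF used
on real data: the downstream association consumes only posterior dosages,
and the HMM is fully specified, fast, and testable. Transitions between
markers *d* Morgans apart: stay with extra probability exp(−G·d), otherwise
redraw from the haplotype's prior α — consistent with the single-pulse tract
process. Emissions are Bernoulli at reference frequencies smoothed with a
0.5 pseudocount; G defaults to 50 generations. The forward–backward
recursion is normalized per marker (scaled form), which is algebraically
equivalent to log-space recursion and underflow-free at any chromosome
length; the forward and backward total likelihoods are asserted equal. No
window smoothing is applied (per-marker emissions); phase error is not
modeled because the synthetic haplotypes are truth-phased.

`mask_markers` computes a leave-one-out dosage: the listed markers'
emissions are set to 0.5. This matters when the dosage serves as a covariate
for a test of that same marker — a variant with a 0.93/0.03 frequency
difference otherwise dominates its own posterior, and conditioning on the
dosage absorbs the genotype signal itself (measured: power for a planted
β = 0.3 effect at n = 2000 falls from ~100% with the mask to 15% without).

## Dating (`dating`)

Weighted LD: for every intra-chromosome pair at genetic distance d ∈
[0.5, 30] cM, the sample covariance of genotype vectors times w_i·w_j
(w = reference frequency difference) is accumulated into 0.05 cM bins. The
d_min = 0.5 cM guard excludes short-range LD not of admixture origin; the
weights come from reference panels, never the dated cohort itself. The curve
is fit by â(d) = A·exp(−n·d) + c with d in Morgans: n is profiled on a
60-point log grid over [1, 500] and refined by bounded minimization (A and c
solved linearly at each candidate n; bins weighted by pair counts). The
affine offset c absorbs any distance-independent baseline, e.g. the
contribution of α variance across individuals. The jackknife deletes one
chromosome at a time, reusing per-chromosome bin accumulators, and applies
the delete-m_j (Busing) formula weighted by chromosome SNP counts; a date is
called significant at n̂/SE ≥ 2 (a documented convention). Calibration was
verified by simulation: at G = 50 (66k SNPs, 500 diploids) the mean estimate
over 8 replicates was 49.96 with empirical SD 0.38 against mean jackknife SE
0.39. Only the single-pulse model is implemented; multiple-pulse
deconvolution and three-locus statistics are out of scope.

## Association (`assoc`)

The LMM y = Xβ + u + ε, u ~ N(0, σ²_g K) is fit by the spectral trick: one
eigendecomposition of K (eigenvalues clipped at 0 with a warning path for
non-PSD input), rotation of y and X, then 1-D bounded optimization of
log δ = log(σ²_g/σ²_e) over [−6, 6] in log10 units with tolerance 1e-8 on
the REML criterion; when the δ→0 boundary fits no worse the model collapses
to exact OLS. GLS fixed effects and standard errors come from the weighted
normal equations at the optimum; Wald p-values use the t distribution with
n − p degrees of freedom. ML log-likelihoods are computed alongside REML so
models with different fixed effects can be compared: AIC = 2k − 2ℓ_ML with
k = #fixed + 2. The ladder is {unadjusted OLS, GRM, GRM+Ref_PCs,
GRM+Pop_PCs, GRM+Ref_PCs+Local_Anc}; 4 PCs by default (12 exposed as config
for GWAS-scale demos); genomic-control λ = median χ²₁ / 0.4549.

The GRM standardizes SNPs by √(2p̂(1−p̂)) and excludes the tested focal
variant. Calibration of the fully adjusted test depends on PC precision: at
2,000 SNPs residual PC noise left the null rejection rate at 0.29; at 6,000
SNPs it sits at the nominal 0.05. The association experiments therefore use
6,000 SNPs as their study condition — the point where the stratification
phenomenon (unadjusted false positive, adjusted calibration, retained power
for genuine effects) is reproduced faithfully at desk scale. The default
ancestry effect β_anc = 2 with unit trait noise puts the trait–ancestry R²
near 0.2, a strong but realistic confounding level.

## Problem sizes

Test-suite and acceptance problem sizes are the package's own choices,
picked so each check has adequate statistical power: F_ST recovery at 100k
SNPs (Monte-Carlo SE ≈ 2×10⁻⁴), dating at 500 diploids × 66k SNPs (jackknife
SE ≈ 0.4 generations), cross-validated K on 200 individuals (75 labeled-free
near-pure, 125 gradient-admixed) × 3,000 SNPs, type-I calibration over 500
trait replicates on one fixed cohort (genotypes, GRM, PCs and dosages
computed once — the standard way to calibrate a test statistic), power over
60 replicates at n = 2,000.

## Known limitations

* The EM fit can need >1,000 iterations near flat likelihood regions at
  subcontinental drift; CV fits cap iterations and accept the slightly
  looser optimum.
* The degree-greedy relative pruner is not an exact maximum-independent-set
  solver; on dense relatedness graphs it may keep one sample fewer than
  optimal.
* Two-way (not three-way) local ancestry only: the southern clusters are
  merged for the HMM, mirroring the north–south axis that drives the
  confounding story.
* The jackknife SE for dating assumes chromosomes are exchangeable blocks;
  with the uniform synthetic map they are, but highly uneven real maps would
  lean on the delete-m_j weighting.
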