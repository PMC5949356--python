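# Methods

`landgen` implements a complete landscape-genomics conservation assessment —
SNP quality control, diversity and relatedness statistics, ancestry
inference, circuit-theory isolation-by-resistance (IBR) modelling, and
environmental-association genome scans — together with a synthetic-data
generator that produces every input with known ground truth. This note
records the models, the parameters that matter, and the design decisions
taken where more than one reasonable choice existed.

## Quality control (`genio`)

Locus filters are applied in a fixed order (site quality, mean depth, minor
allele frequency, missingness, all-heterozygous, biallelic), each stage
recording its attrition so the report always reconciles to the input count.
Defaults follow common RAD-seq practice for this kind of data: site Phred
> 50, mean per-call depth in [20, 200], MAF ≥ 0.025, ≤ 30 % missing. Depth
is interpreted as the mean across genotyped calls at the locus, the usual
VCF-tool semantics. Hardy–Weinberg filtering (α = 10⁻⁴) uses the exact
conditional test on genotype counts — enumeration over all heterozygote
counts compatible with the observed allele counts — because desk-scale
genotype counts are routinely too small for the χ² approximation.
LD pruning is greedy and windowed (50 loci, step 5) on composite
(dosage-correlation) r², dropping the lower-MAF member of any pair with
r² ≥ 0.5; the surviving set is audited to satisfy the bound. Whether pruning in this study design should be windowed or all-pairs is
genuinely open; windowed pruning targets the intra-contig LD that
150-bp tags actually produce.

Raster I/O uses the ESRI ASCII grid format throughout: it is plain text,
self-describing, and sufficient for every consumer in the package.

## Diversity statistics (`popgen`)

Expected heterozygosity uses the (n−1)-corrected estimator 2p̂(1−p̂)·n/(n−1)
over genotyped chromosomes; per-site nucleotide diversity is
2j(n−j)/(n(n−1)); Tajima's D uses the standard constants with n set to the
rounded mean chromosome count over segregating sites when data are missing.
Confidence intervals are percentile bootstraps over loci (or individuals,
for F), seeded; the interval method for this table is a package choice, as
distribution-free and reproducible. Individual inbreeding is the
method-of-moments ratio (O_hom − E_hom)/(L − E_hom). The relationship
matrix is the Yang/GCTA allele-sharing estimator with frequencies from the
full sample and pairwise-complete loci; its diagonal is 1 + F̂.

Effective population size uses the LD method: Burrows' composite r² between
all pairs of loci on *different* contigs (physical linkage excluded), a MAF
screen at 0.05, the random-mating sample-size expectation 1/S + 3.19/S²
(0.0018 + 0.907/S + 4.44/S² below S = 30), and the standard quadratic
inversion N̂e = (1/3 + √(1/9 − 2.76 r²′))/(2 r²′). The composite r applies
the n/(n−1) Burrows factor to the dosage covariance — this is what makes
the stated sample-size expectation correct; plain Pearson r² has null mean
1/(S−1) and would bias N̂e upward by ~40 % at desk scale. The CI is a
delete-one-locus jackknife: locus-pair jackknifes are the convention of the
reference tool but pairs sharing a locus are dependent, so the locus-level
jackknife is used as the conservative, simpler choice.

## Ancestry (`ancestry`)

Genotypes are one-hot encoded over the classes {0, 1, 2} and factorised as
X ≈ QG with Q on the per-individual probability simplex and G a per-locus
class distribution per ancestral population, minimising
‖W∘(X − QG)‖² + α‖Q‖² (α = 10 by default, exposed in configuration; its
effective strength grows as locus count shrinks). Optimisation is block
projected-gradient descent with exact Lipschitz step sizes, which
guarantees a monotone non-increasing loss (asserted every iteration);
convergence at relative change < 10⁻⁶ or 500 iterations. Initialisation is
random (Dirichlet rows) or spectral (k-means on leading principal
components); model choice runs both.

k is chosen by masked cross-entropy: a seeded 5 % of known genotype cells
is held out and scored by predictive log-loss; per k the score is the
minimum over replicate fits and the smallest k wins ties. Within a
replicate, every k is scored on the *same* held-out mask — a paired
comparison; with distinct masks the comparison is dominated by mask noise
at desk-scale locus counts. The package implements one clustering method;
the concordance of two independent programs reported for the original data
cannot be replicated here.

The FST outlier scan assigns individuals to argmax-Q clusters (ties to the
lowest index), computes weighted FST per locus, transforms it as
z² = FST·(n−k)/(1−FST), rescales by the genomic inflation factor
λ = median(z²)/median(χ²ₖ₋₁), compares to χ²ₖ₋₁, and controls FDR by
Benjamini–Hochberg. The exact χ² rescaling across k is under-documented in
the method family this follows; the transform above is fixed as this
implementation's definition.

## Landscape and circuit theory (`landscape`)

Each resistance surface is one hypothesis: per land-cover year and class, a
low/high (0.1/0.9) and high/low binary surface; per continuous raster
(elevation, roughness, temperature, precipitation), a raw and an inverted
min–max rescale to (0, 1]; and a uniform 0.1 null (isolation by geographic
distance). Surfaces are cropped to the sample bounding box plus a 5 km
buffer to limit border effects, and non-positive cells are replaced with
0.001. With the default landscape this yields 27 hypotheses.

Effective resistance is computed on the 8-connected cell graph with
average-conductance edges, diagonal neighbours scaled by 1/√2 — the
standard cell-connection scheme of circuit-theory connectivity tools. The
grounded Laplacian is factorised once per surface (sparse LU) and solved
per sample node; this is exact (validated against the dense pseudo-inverse
to 10⁻⁸) and cheaper than an iterative solve per pair. Effective
resistance is a metric; the triangle inequality is audited in tests.

The spatial autocorrelogram is a tricube local-linear (LOESS) fit of
pairwise relatedness on geographic distance over a 100-point grid
(span 0.5 by default), with a null envelope from permuting individual
labels of the relatedness matrix jointly over rows and columns — permuting
pairs instead would break exchangeability. Significant autocorrelation
extends to the largest grid distance at which the observed curve exceeds
the 97.5 % bound contiguously from the origin.

## Isolation by resistance (`ibr`)

The MLPE model regresses pairwise relatedness on distance predictors with
residual correlation 2ρ between pairs sharing one individual. Because the
pair-sharing graph is the triangular graph, C(ρ) = (1−4ρ)I + 2ρBBᵀ, and
Woodbury identities give exact likelihoods in O(pairs) — no iterative
mixed-model machinery. Positive-definiteness requires ρ < 1/4, so ρ is
profiled over [0, 0.25) by bounded search; β and σ² are profiled out in
closed form. ML is used whenever models are compared (AICc, LRT); REML is
available for final fits. Wald tests use df = number of pairs, the common reporting convention for
MLPE tables; this is approximate and
anti-conservative, with the pseudo-replication handled by the MLPE
correlation itself. AICc counts slopes + intercept + ρ + σ² as parameters
with n = number of pairs.

Model selection: univariate screening picks the best land-cover surface
and the best polarity per continuous variable by AICc. Each screening
model also carries the hypothesis' node-mean covariate (the pair's mean
distances to all other individuals): genome-wide relationship estimates
are relative to the sample — the estimator centres on sample allele
frequencies, so the expected relatedness surface is the double-centred
kinship — and the node term lets each candidate express exactly that
structure while keeping the parameter count identical across candidates.
Without it the screening systematically prefers wrong-but-correlated
surfaces on many landscape geometries, even with noiseless genotypes.
The all-subsets step: the all-subsets
enumeration then excludes any subset containing a predictor pair with
|r| ≥ 0.6, ranks by AICc, and flags ΔAICc < 2 as the best set. Model
averaging over the best set is *full* averaging (absent predictors
contribute zero; unconditional SEs combine within-model variance and
between-model spread); whether the original averaging was full or
conditional is not stated, and full averaging is the stated default here.
Predictors enter on their raw distance scales.

Highland-history models are random-intercept Gaussian mixed models
(statsmodels MixedLM, ML) of individual-level heterozygosity and inbreeding
on highland area and isolation, with per-predictor likelihood-ratio tests;
a single highland falls back to a fixed-intercept model with a warning.

## Environmental association (`envassoc`)

Three variables are selected by PCA on the standardised environment table:
for each of the first three axes, the variable with the largest
|correlation| to the axis scores, without replacement. The association
model is a latent-factor regression Y = xbᵀ + UVᵀ + E fit by alternating
ridge minimisation (deterministic given the seed) — a drop-in for the
MCMC-based estimator of the same quantity; replicate runs differ in factor
initialisation and per-locus z-scores are combined across runs by the
median, preserving the replicate-combination protocol. Missing genotypes
are excluded via EM-style reimputation with model predictions. Calibration
divides z² by λ = median(z²)/0.4549364 before the χ²₁ tail; BH controls
FDR at q = 0.05 (a package default; no canonical level exists for this
kind of scan). Candidates must be flagged at every k in the k ± 2
grid per variable; the union over variables and the FST scan forms the
final set with per-source provenance, rolled up to contigs. The
cross-dataset comparison is a Yates-corrected chi-square on the 2×2
arrangement [[candidates_A, total_A], [candidates_B, total_B]] — the
arrangement under which published cross-species comparisons of this kind
are reproducible — with the
conventional candidates/non-candidates arrangement also available.

## Synthetic data (`synthdata`)

The generator defines the study conditions. Landscapes are smoothed
Gaussian fields: land cover tracks elevation (savanna occupies the highest
band, as canga vegetation does on plateaus) with classes montane savanna /
forest / mine / other; later-year maps differ from earlier ones only by a
clustered savanna→mine conversion of exactly ⌊f·savanna⌋ cells (mine
expansion, not salt-and-pepper noise). Roughness is the 3×3 moving standard
deviation of elevation; temperature and precipitation are elevation- and
gradient-linked fields with seeded noise. Sampling places individuals at
savanna cell centres with a 10 m minimum spacing; `highland_id` labels
8-connected savanna patches.

Genotypes have three locus layers. Neutral-spatial loci draw individual
logit-frequencies from a Gaussian field with covariance η²·exp(−R/φ), R the
circuit resistance distance under the true surface — chosen over a
coalescent simulation because it gives closed-form control of exactly the
covariance the IBR stage must recover. Cluster loci are Balding–Nichols(θ)
draws mixed through spatially coherent memberships (farthest-point cluster
centres; decay scale τ controls admixed margins). Adaptive loci follow
logit p = logit(p₀) + β·z with z the standardised environmental value.
Depth is negative binomial (mean 60, dispersion 5), genotype quality a
saturating log transform of depth capped at 99, site quality N(90, 30)
clipped at 1 — so the Phred > 50 and depth filters discard a real,
controllable fraction — and calls go missing at 5 % by default.

Three presets define the study conditions. `cavalcantei-like` (n = 122,
k = 1, η² = 0.15, φ = 0.5, β = 1.0, 12 % of contigs adaptive) is panmictic
with weak spatial autocorrelation, like the narrow endemic it emulates.
`maurandioides-like` (n = 254, k = 4, θ = 0.3, near-discrete memberships
with cluster centres from k-means on the sampling locations, 960 loci of
which a third are adaptive at β = 0.75, η² = 0.05) carries four
well-separated populations whose cluster layer dominates the other two —
as it must, since the number of ancestral populations is only a
well-posed target when clustering is the dominant structure. `ibr` (n = 35 spread-sampled individuals, η² = 1.5,
φ = 6 × the median true-surface resistance distance, 8000 neutral loci,
patchier land cover with larger mine/other fractions) carries a strong,
quasi-linear resistance–relatedness signal for surface-recovery
experiments; the patchier classes decorrelate competing land-cover
hypotheses, which on very smooth landscapes are nearly collinear
(r > 0.98) and hence not individually identifiable. φ is tied to the
realised resistance-distance scale so that the exponential covariance is
roughly affine in R — the regime in which a linear MLPE on R is the right
model; much smaller φ makes relatedness saturate, and a monotone
transform of the wrong surface can then outfit the true one.

Two auxiliary simulators serve drift benchmarks: a discrete Wright–Fisher
forward simulation of unlinked loci in one pedigree (the drift LD that the
Ne estimator measures; loci start in linkage equilibrium and the unlinked
equilibrium is reached within ~10 generations), and msprime coalescent
simulations for demographic scenarios (constant, bottleneck, expansion)
where the site-frequency spectrum matters — a fixed-locus forward
simulation without mutation cannot produce the rare-variant excess of an
expansion.

What the generator does not emulate: real sequences (alleles are abstract
biallelic markers), mutation and recombination within tags, pedigree
structure, genotype-calling artefacts beyond depth/quality/missingness, or
a mechanistic generation-time lag (multi-year maps exist, but the genetic
response is tied to whichever map generated the data). Passing tests
therefore show the *methods* recover known structure of this statistical
form, not that any particular real dataset has that structure.

## Problem sizes in the validation experiments

The validation experiments are run at sizes chosen for a desktop machine:
circuit oracle on 50 random grids of ≤ 100 cells; MLPE recovery with 40
individuals (780 pairs) × 200 replicates; surface recovery with 30
individuals, 27 surfaces on a 30×30 grid × 50 replicates; scan FDR/power
with 80 individuals × 300 loci × 50 replicates; k-selection over 10 replicate datasets per preset (70 individuals, k
scanned to 4 for the panmictic preset; 90 individuals, k scanned to 6 for
the 4-cluster preset; 4 replicate fits per k); Q recovery at 80 individuals × 600 loci; Ne
recovery at true Ne = 100 with 50 sampled individuals × 400 loci × 50
replicates. The pipeline presets scale to the full study sizes (122/254
individuals) when run as configured.

## Known limitations

* The MLPE ρ upper bound (0.25) is a hard positive-definiteness constraint
  of the 2ρ parameterisation; datasets truly at the boundary fit at it.
* λ-rescaled χ² p-values are a calibration device, not exact tail
  probabilities; only FDR-controlled candidate sets should be interpreted.
* The LD-Ne point estimate is sensitive to undetected physical linkage;
  only inter-contig pairs are used, but real reference-free contigs can
  still share scaffolds.
* Cross-entropy k-selection is noisy at small locus counts even with
  paired masks; replicate fits and the min-score rule mitigate but do not
  remove this.
* The admixed spatial presets do not support Q recovery to RMSE < 0.1 by
  any estimator at desk scale; precise Q recovery is validated on discrete
  well-separated clusters.
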