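# Methods

This note documents the statistical models implemented in `levantadmix`,
the parameter choices that matter, what the synthetic generator does and
does not emulate, and the numerical decisions made where the design was
genuinely open.

## Data model

A panel is a SNP table (chromosome, 1-based physical position, genetic
position in Morgans, two alleles), an individual table with population
labels, and an individuals × SNPs genotype matrix counting copies of
`allele_a` (0/1/2, −1 missing). Pseudo-haploid samples — low-coverage
ancient genomes represented by one randomly drawn allele per site — carry
only {0, 2, −1}. Every statistic is invariant to a consistent global
allele-label flip (g → 2−g everywhere), which is tested explicitly; panels
merged from array and sequence sources therefore do not need a shared
allele-orientation convention, only consistent per-site reconciliation.
Merging matches sites on (chromosome, position), recodes swapped allele
pairs, resolves strand flips by complementing, and drops A/T and C/G
sites, which are indistinguishable from their own reverse complement when
strand is unrecorded. No statistic imputes: each defines its own per-SNP
complete-case rule.

## f-statistics and the weighted block jackknife

f2, f3 and f4 are moments of population allele-frequency differences,
estimated by plugging in sample frequencies and averaging over the SNPs
where every involved population has at least one call. f4 is reported
unnormalized (the covariance of frequency differences), with the
heterozygosity-normalized D-statistic available separately; f3 offers an
optional small-sample heterozygosity correction, off by default because
pseudo-haploid targets distort apparent heterozygosity.

Standard errors delete contiguous genetic-map blocks (default 5 cM —
beyond the reach of background LD, giving ~700 blocks on a human-scale
map) and use the weighted jackknife of Busing et al. with block SNP
counts as weights, since aDNA missingness makes block occupancy very
uneven. Calibration is checked by simulation: on homogeneous panels the
mean jackknife SE must fall within [0.7, 1.3] of the empirical SD of the
estimator across replicates.

## Mixture proportions and rank testing

With target T, sources S₁..S_N and rights R₁..R_M (M ≥ N+1, R₁ the
base), the model equations are

    f4(T, R₁; Rᵢ, R₁) = Σⱼ wⱼ f4(Sⱼ, R₁; Rᵢ, R₁),   i = 2..M,  Σⱼ wⱼ = 1.

Weights minimize (b − Aw)ᵀ Σ⁻¹ (b − Aw) under the sum constraint
(Lagrange/KKT solve), with Σ the block-jackknife covariance of b,
ridge-regularized by 1e-4 of its mean diagonal before inversion because
the number of rights can approach the usable block count on sparse aDNA
overlap. Weight SEs come from refitting each leave-one-block system with
Σ held fixed, combined by the weighted jackknife. The sum constraint also
makes the estimator exactly invariant to the additive sampling-variance
bias the shared base population induces in every f4, so no
heterozygosity correction is needed. Under `allsnps` each f4 uses its own
maximal SNP set; otherwise all statistics share the global intersection.
Results are invariant (to 1e-8) under permutation of the non-base rights.

The rank test asks whether the (M−1)×(N+1) matrix X of target+source f4
columns has rank ≤ r. The best rank-r approximation under the GLS metric
defined by the jackknife covariance of vec(X) is found by SVD truncation
followed by alternating generalized-least-squares refinement of the two
factors (the refinement only lowers the statistic toward the true GLS
optimum; a handful of sweeps suffices at these dimensions). The residual
is chi-square with (M−1−r)(N+1−r) degrees of freedom; an N-source model
"fits" when the rank-N test does not reject. Model scans rank candidate
second sources by feasibility (all weights in [0,1]), then rank-test
p ≥ 0.05, then smallest candidate-weight SE.

## Admixture-LD dating

A single admixture pulse n generations ago leaves LD between
ancestry-informative alleles that decays as exp(−n·d) with genetic
distance d. The two-reference weighted-LD statistic averages
cov̂(gᵢ,gⱼ)·δᵢ·δⱼ over intra-chromosomal pairs binned by distance, with
δ = p_ref1 − p_ref2 and cov̂ the unbiased sample covariance of dosages in
the admixed panel. Defaults: bin width 0.05 cM, minimum distance 0.005
Morgans (0.5 cM, below which background LD contaminates the signal),
maximum 0.3 Morgans (signal for n ≥ 25 is exhausted well before, and it
bounds the pair count). Pairs are enumerated directly; at desk-scale
panel sizes the quadratic cost is negligible and no FFT machinery or
self-reference corrections are needed in two-reference mode.

The curve is fitted as A·exp(−n·d) + c, the affine term absorbing
population-substructure background. Fitting: grid over n ∈ {5,…,500}
(closed-form A, c per grid point) followed by bounded local least
squares; bins are weighted by pair counts. Uncertainty comes from
leave-one-chromosome-out refits — chromosomes are the natural
exchangeable unit because all pairs are intra-chromosomal.

Significance: the reported z is min(n/se_n, A/se_A), and 0 outright when
the fitted amplitude is non-positive. The rate-only z-score is
miscalibrated under the no-admixture null — when the amplitude is
consistent with zero the decay rate is unidentified and its jackknife SE
unreliable — while the amplitude z is well calibrated, and admixture LD
always has positive amplitude. Dates are refused below z = 2 (a lenient
threshold suited to small reference panels; its own type-I rate is ~2%,
so occasional null exceedances are expected) unless forced. Conversion
to calendar years multiplies by a generation time, default 28 years.

## Supervised ancestry EM

Each individual's dosage at SNP m is Binomial(2, u_m) with
u_m = Σₖ qₖ p_km and the reference frequencies p fixed (clipped to
[1e-5, 1−1e-5]). EM assigns each allele copy to a reference in proportion
to its posterior share and renormalizes q on the simplex; the
log-likelihood is non-decreasing every iteration and the problem is
concave in q, so the deterministic symmetric start q = 1/K needs no
restarts (identical references stay at the symmetric tie point).
Convergence: |Δ log-likelihood| < 1e-6 or 2,000 iterations; missing
genotypes are skipped.

## PCA and projection

PCA is fitted on individuals with < 50% missingness: dosages centered by
SNP mean, scaled by sqrt(p(1−p)) with p = mean/2, monomorphic SNPs
dropped, residual missing entries zeroed after centering, then truncated
SVD. High-missingness samples are projected by least squares against the
loadings restricted to each sample's observed SNPs, which avoids the
shrinkage toward the origin that zero-filling causes; a complete-data
sample's projection equals its dot product with the loadings, and
training samples reproduce their fitted scores exactly.

## Allele frequencies from genotype likelihoods

The per-SNP likelihood L(p) = Πᵢ Σ_g GLᵢ(g)·Binom(g;2,p) is maximized by
EM. Although L(p) is usually unimodal, adversarial likelihood triples can
create a second mode and near-flat stretches where EM stalls; the
implementation therefore runs three starts (0.05, 0.5, 0.95), keeps the
highest-likelihood solution per SNP, and iterates to |Δp| < 1e-9 (up to
2,000 iterations), which matches a 10,001-point grid search within 1e-3
on random tables. SNPs where every triple is flat are reported missing,
not zero. AF correlations between populations use Pearson r over shared
non-missing SNPs with a Fisher z-transform confidence interval.

## The synthetic generator

Graph panels: root frequencies uniform on [0.05, 0.95]; each drift edge
applies Balding–Nichols sampling, child ~ Beta(p(1−τ)/τ, (1−p)(1−τ)/τ),
so τ is the expected frequency variance on the f2 scale — one parameter
per branch, directly comparable to the statistics being tested, and far
cheaper than discrete Wright–Fisher at desk scale. Admixed nodes mix
parent frequencies linearly. Genotypes are Binomial(2, p) per individual.

Mosaic panels: per haplotype per chromosome, ancestry switch points are a
Poisson process at rate n_gen per Morgan, tract ancestries i.i.d.
Bernoulli(α), alleles Bernoulli from the tract's panel frequency; panel
frequencies default to independent Uniform[0.1, 0.9] per SNP so the LD
weights stay informative. Defaults mirror a human-scale design: 20
chromosomes × 1.5 Morgans, 300 SNPs per chromosome. aDNA corruption
pseudo-haploidizes, masks at a missingness rate, and flips surviving
haploid calls at an error rate.

What the generator does **not** emulate: linkage within source
populations (graph-panel SNPs are independent, and mosaic panels have no
background LD), ascertainment bias of SNP arrays, reference bias and
post-mortem damage profiles of real aDNA, and within-population
structure or relatedness. Passing recovery tests therefore demonstrates
the estimators' correctness under their own model assumptions — unbiased
recovery, calibrated uncertainty — not robustness to these real-data
complications.

## Recovery benchmarks (problem sizes)

The acceptance benchmarks, shared between the test suite and
`scripts/acceptance.py`, use: 100 random frequency tables for the
f-statistic oracle; 100 homogeneous replicates (3,000 SNPs, 10
individuals per population) for jackknife calibration; a 3×3 grid of
mixture proportion α ∈ {0.2, 0.5, 0.8} × source drift τ ∈ {0.005, 0.02,
0.05} with 20 replicates each at 20,000 SNPs; mosaic ages n ∈ {25, 50,
100, 200} with 10 replicates each plus 10 unadmixed controls at 200
diploid individuals; supervised-ancestry mixtures q₁ ∈ {0.1, 0.25, 0.5}
with 20 replicates each at 50,000 SNPs and τ = 0.05; 100 random
likelihood tables for the AF-EM/grid comparison; and a double run of the
simulation-preset pipeline for byte-level determinism. All randomness
derives from a single seed via deterministic seed-sequence spawning.

## Known limitations

* The mixture model assumes the rights received no gene flow from the
  left populations after divergence; violations bias weights, as in any
  outgroup-based formulation.
* The LD dating model is single-pulse; continuous or multi-pulse
  admixture biases n toward an intermediate value, and the two references
  must actually bracket the mixing sources for δ to carry signal.
* The rank-test chi-square relies on the jackknife covariance of vec(X);
  with very few usable blocks the ridge regularization dominates and
  p-values become conservative.
* Supervised ancestry EM treats SNPs as independent (no LD weighting) and
  reference frequencies as known; small reference panels add noise that
  the q standard errors do not capture (none are reported).
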