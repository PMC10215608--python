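# Methods

This note documents the statistical content of each pipeline stage: the
models and estimators, their assumptions, the tunable parameters with
defaults and rationale, the design decisions taken where conventions
diverge, and what the synthetic-data tests do and do not demonstrate.

## Synthetic study generator

The generator produces every input the pipeline consumes, with planted
truth, so recovery can be measured exactly.

**Genotypes.** Background differentiation between the two groups
follows the Balding–Nichols model: per site an ancestral frequency
p ~ Uniform(0.05, 0.95), then each group draws its own frequency from
Beta(p(1−F)/F, (1−p)(1−F)/F), giving expected fixation index F between
groups with a single parameter. Genotypes are Binomial(2, group
frequency) — i.e. Hardy–Weinberg within groups, no linkage
disequilibrium, no mutation/recombination model. Sweeps are planted by
forcing a `sweep_intensity` fraction of a window's sites to alt
frequency ≤ 0.02 in the swept group only: the hard-sweep footprint
(divergence up, diversity and heterozygosity down) without haplotype
structure. Defaults — 50 diploids per group, five 1-Mb contigs with
2000 SNPs each (one SNP per 500 bp), background F_ST 0.05, intensity
0.9 — are the study conditions used throughout the tests and the
acceptance script; they keep per-window site counts near 200, ample for
stable window statistics, while the whole scan runs in seconds.

Because sites are exchangeable and unlinked, the simulation does not
reproduce LD decay, allele-frequency spectra under demography, or soft
sweeps. Passing tests therefore demonstrate estimator correctness and
the scan's behaviour under idealised hard sweeps, not performance on
real resequencing data.

**Pedigree and phenotypes.** A random-mating pedigree with equal-sized
discrete generations. Variances are scaled so σa² = h² and σe² = 1 − h²
(total 1). Founder breeding values are N(0, σa²); a non-founder's is
the parental mean plus Mendelian-sampling noise of variance σa²/2 —
parental inbreeding is deliberately ignored in that variance, a
simplification that is negligible for the shallow (3-generation)
pedigrees generated here. Phenotypes add four categorical fixed effects
(lactation-day class, lactation number, birth year, milking times;
level effects N(0, 0.5²)), one continuous covariate with coefficient
β = 0.5, and N(0, σe²) residual.

**qPCR tables.** Daily milk yields uniform on 1–4 L/day (a realistic
dairy-ewe span); reference-gene CT ~ N(20, 0.2). The causal gene's ΔCT
is 0.5 + slope·yield + N(0, noise_sd²) with default slope +1.2
cycles/(L/day) — positive because higher ΔCT means lower expression, so
this encodes expression falling with yield; null genes use slope 0.
Defaults (11 ewes, noise_sd 0.5) put the causal gene's R² in the ~0.8
neighbourhood typical of a strong expression–production relationship
at that sample size. Technical replicates (two per well) carry scatter
noise_sd/2, so the noise-free configuration is exactly linear and the
planted slope is recovered to machine precision.

## Variant QC

Filters are applied per site in a fixed order — call rate, MAF,
missingness, Hardy–Weinberg — with each failing site attributed to the
first filter it fails (the retained *set* is order-independent; only
the per-filter counts depend on order). Two profiles are built in:
`structure` (call rate ≥ 0.9, MAF ≥ 0.05, missing ≤ 0.05) and `scan`
(call rate ≥ 0.996, MAF ≥ 0.01, missing ≤ 0.1), both with HWE p ≥ 1e-6;
the two stages of a selection study typically use different
stringencies, and both are expressible through `QCConfig`.

The HWE test is the exact two-sided test: enumerate all heterozygote
counts consistent with the observed allele counts, and sum the
probabilities of configurations no more likely than the observed one
under the exact conditional distribution. It is computed by the
standard probability recurrence and verified against rational-arithmetic
enumeration for totals ≤ 30 at 1e-12.

LD pruning follows the PLINK `--indep 50 5 2` convention read as
pairwise r² (threshold 1 − 1/VIF = 0.5, configurable): sliding 50-SNP
windows advancing 5 SNPs within each contig; in a window, any pair with
r² above threshold loses its lower-MAF member (ties drop the higher
index). r² is the squared Pearson correlation of dosages over
pairwise-complete samples, zero when a site has no variance. Passes
repeat — windows re-laid over the survivors — until nothing is removed,
which makes the operation idempotent and guarantees no surviving
within-window pair exceeds the threshold.

## Population structure

The GRM is the GCTA form, G = (1/m) Σᵢ (xᵢⱼ−2pᵢ)(xᵢₖ−2pᵢ)/(2pᵢ(1−pᵢ)),
with per-site mean imputation of missing dosages (equivalent to
centring them at zero) and exclusion of monomorphic sites. PCA is an
eigendecomposition of G; coordinates are eigenvector·√eigenvalue, so
their Gram matrix reproduces the rank-k GRM approximation. Percent
variance explained is reported two ways: against the sum of all
positive eigenvalues (`pve`) and renormalised over the retained top-k
components (`pve_topk`) — published PC-variance figures are often the
latter, and reporting both removes the ambiguity. Negative eigenvalues
(possible for a sample GRM) are excluded from both denominators.

Distances for tree building are 1 − IBS/2 averaged over jointly called
sites. Neighbor joining is the classic Saitou–Nei algorithm; ties in
the Q-criterion are broken by the lexicographically smallest pair of
cluster labels (each cluster labelled by its smallest leaf) so output
is deterministic under permutation of input order. Negative branch
lengths are clamped to zero with the deficit moved to the sister branch
(Kuhner–Felsenstein), preserving path lengths through the join and
keeping the Newick output valid. On additive matrices the algorithm is
exact, which the tests verify by tree → distance → tree round trips.

## Selection scan

Windows start at 0, step, 2·step, … per contig, truncated at the contig
end; a 1-based SNP position p belongs to the 0-based half-open window
[s, e) iff s < p ≤ e. Defaults: 100-kb windows, 10-kb steps, minimum 10
SNPs per window (windows below that are excluded from every ranking to
avoid noise-driven outliers).

Per site, the Weir–Cockerham (1984) among/within variance components
are computed from per-group allele counts — the random-union-of-gametes
form of the estimator, appropriate when only allele counts (not
genotypic heterozygosity) enter the interface; it retains the
estimator's properties (fixed difference → 1, negative bias at equal
frequencies). The window estimate is the ratio of sums, not the mean of
per-site ratios. θπ uses the unbiased per-site heterozygosity summed
over the window and divided by window length in bp (division by the
number of variant sites is available by flag; the high/low ratio is
invariant to that choice whenever both groups share the site set). Hp
pools major/minor allele counts across the window's SNPs before forming
2·ΣnMAJ·ΣnMIN/(ΣnMAJ+ΣnMIN)²; ZHp standardises window Hp by the mean
and population SD over all defined windows of that group.

Candidate selection takes the empirical type-7 (linear-interpolation)
quantile per statistic over defined windows; a window passes a tail at
value ≥/≤ threshold, so ties at the threshold are retained. A statistic
that is constant across windows selects nothing — a degenerate
distribution has no extreme tail. Tail directions are configuration: a
sweep in the high-yield group *depresses* that group's diversity and
heterozygosity, so the default profile intersects F_ST upper tail,
log2 θπ-ratio lower tail and high-group ZHp lower tail, while
`ScanConfig.literal_tails()` takes upper tails everywhere for the
literal "highest 5% of all three" reading. Which group's ZHp enters the
intersection is `zhp_group` (default high). Step size defaults to 10 kb
(the Methods-style setting; a 15-kb variant is one keyword away).
Passing windows are merged when overlapping or bookended; both the
window count and the merged-region count are reported, since published
"overlapping region" tallies can refer to either.

## Annotation

Intervals are 0-based half-open everywhere inside the package;
GFF3's 1-based closed coordinates are converted at the I/O boundary
(gffutils parses the file; only `gene` features are kept). Overlap is
≥ 1 bp under half-open semantics, strand-agnostic, via an
endpoint-sorted sweep checked against all-pairs brute force.
Enrichment is the one-sided hypergeometric upper tail per term with
Benjamini–Hochberg correction across terms, over a user-supplied
term→gene map — a deliberately generic, offline replacement for
web-service GO/KEGG enrichment, with no claim to reproduce any specific
service's thresholds.

## Validation stage

ΔCT(e, g) = mean CT(e, g) − mean CT(e, reference), replicates averaged
first; higher ΔCT = lower relative expression. The construction is
invariant to a per-ewe plate offset.

The animal model y = Xb + xβ + Zu + e with var(u) = Aσa²,
var(e) = Iσe² is solved by Henderson's mixed-model equations with
λ = σe²/σa² = (1−h²)/h². A is built by the tabular method
(a_ii = 1 + 0.5·a_sd, a_ij = 0.5(a_js + a_jd)) in topological order
with cycle detection. Fixed factors enter with a sum-to-zero constraint
per factor (effects coding plus a global intercept) — chosen over
reference-level coding for symmetry, and recorded in the result so
solutions are comparable across parameterisations. The solve is dense
(the pedigrees handled here are small); the solution is checked against
the closed-form GLS estimator with V = ZAZ'σa² + Iσe² in the tests, and
the relative MME residual must be below 1e-8 or the solve errors out.
Variance components are not estimated (no REML): h² is a required
input, default 0.3, a typical dairy-sheep milk-yield heritability.
With own phenotypes only, EBV accuracy is ≈ √h², which is why the
recovery tests at h² = 0.5 demand correlation ≥ 0.6 with the true
breeding values.

OLS regressions (ΔCT vs yield, ΔCT vs estimated value, yield vs
estimate) use closed-form normal equations with R² = 1 − SSE/SST;
slope signs are reported so a "negative expression–production
relationship" (positive ΔCT slope) is directly assertable.

## Problem sizes and numerical choices

The test suite and acceptance script use the generator defaults above
(10 000 SNPs × 100 samples for the scan; ~500 windows; 501-animal
pedigree; 11-ewe qPCR tables, 100 seeds for null distributions).
Oracle comparisons are at 1e-12 for closed-form arithmetic, 1e-9 for
accumulated floating-point identities (ZHp standardisation, NJ round
trips, PCA orthonormality), 1e-6 for linear solves against independent
factorisations. Degenerate inputs are defined rather than left to
chance: monomorphic sites give HWE p = 1 and are excluded from the GRM;
zero-variance dosage pairs give r² = 0; windows with either group's
θπ = 0 are excluded from ratio ranking and counted; constant window
statistics select no candidates; a constant OLS response gives R² = 0
with a warning.

## Known limitations

* The genotype simulator has no linkage disequilibrium, so LD pruning
  and the scan's window correlation structure are only exercised on
  artificial correlation patterns, not realistic haplotypes.
* F_ST uses the allele-count (random-union-of-gametes) Weir–Cockerham
  form; with strong within-population departures from Hardy–Weinberg
  the full genotypic estimator would differ.
* The MME solver is dense and single-trait; it targets pedigrees of
  hundreds to a few thousand animals, not national evaluations, and
  does not estimate variance components.
* Ancestry-composition analysis (ADMIXTURE-style), haplotype statistics
  (iHS, XP-EHH) and tree bootstrapping are out of scope.
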