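# Methods

## Model

`cpelhap` analyses haplotype-dependent allele-specific DNA methylation
(hap-ASM) from allele-assigned bisulfite reads. Within one haplotype allele
spanning a genomic region with N CpG sites, the random methylation state
X = (X_1, ..., X_N), X_n in {0, 1}, is modelled by an inhomogeneous
one-dimensional Ising distribution

    p(x) = exp{-U(x)} / Z,
    U(x) = - sum_k alpha_k sum_{n in R_k} (2 x_n - 1)
           - beta sum_{n=1}^{N-1} (2 x_n - 1)(2 x_{n+1} - 1),

where the region is first divided into the minimum number K of equal-width,
non-overlapping subregions R_k of width at most 500 bp. Each subregion
carries a methylation-propensity field alpha_k (dimensionless; positive
values push its CpG sites toward methylation), and a single dimensionless
coupling beta captures the co-methylation of adjacent CpG sites (positive
beta favours equal neighbouring states). The model is a strictly positive
distribution over the 2^N methylation patterns for any finite parameters.

The number of CpG sites per analysed region is capped at N_max = 20:
haplotypes with more sites are divided into the minimum number of regions
with equal-as-possible site counts (first regions take the extra site).
Haplotype spans come from clusters of phased heterozygous SNPs, expanded
symmetrically on both sides by the average read length so nearby CpG sites
are included.

### Exact computation

Partition function, site marginals, read likelihoods and sampling all use
transfer-matrix recursions along the CpG chain in a rescaled (overflow-safe)
representation, so they are exact and linear in N and remain stable for
|alpha|, |beta| far beyond the fitting bounds. Likelihoods of partially
observed reads clamp only the observed sites in the forward pass, which
marginalizes the missing entries implicitly; an all-missing read has
probability one and is dropped before estimation. Sampling is exact
forward-filter/backward-sampling. The dense PDM over the 2^N states (used
by entropy and divergence summaries) is built by direct enumeration, which
is exact and affordable at N <= 20; the test suite uses independent
brute-force enumeration as the oracle for every transfer-matrix quantity.

State encoding: site 1 occupies the least significant bit of the pattern
index. CpG coordinates are the forward-strand position of the C; all
intervals are 0-based half-open (BED convention), and a CpG site belongs to
the subregion whose half-open interval contains it.

## Estimation

Parameters (alpha_1..alpha_K, beta) are estimated by maximizing the summed
log marginal likelihood of the allele's reads. The optimizer is simulated
annealing (Gaussian proposals with standard deviation 0.5 x temperature,
geometric cooling at rate 0.95 per iteration, parameters clipped to
alpha in [-10, 10], beta in [-5, 5]) followed by a bounded L-BFGS-B polish
with tight tolerances. The box bounds keep separated data (e.g. all reads
fully methylated) from driving estimates to infinity; such fits are flagged
`param_at_bound`. Defaults are 2000 iterations and 3 restarts. The
bootstrap-null and benchmark loops use a lighter schedule (400 iterations,
1 restart, same polish; `SaConfig.fast()`): the marginal likelihood of this
exponential-family chain is smooth and in practice unimodal at these sizes,
so the polish dominates the accuracy while the annealing guards against
rare bad basins. All fits are deterministic given `rng_seed`, and the
annealing configuration is recorded in the JSON model dumps.

The two non-parametric baselines are fitted as comparators: NPI estimates
a per-site methylation frequency from the reads observing that site (a
site with no coverage gets probability 0.5 and a flag) and multiplies them;
NPD estimates the empirical joint over full patterns from fully observed
reads only (an epiallele variant over windows of 4 CpG sites is available).
Neither applies pseudo-counts — unseen patterns get probability zero on
purpose, since that behaviour is part of what the model comparison
measures. Model preference uses the small-sample AIC,
AICc = -2 log L + 2 eta + 2 eta(eta+1)/(M-eta-1) with eta = K+1 (Ising),
N (NPI) or 2^N - 1 (NPD) free parameters and M observations, and the
Akaike weight W = exp(-D1/2) / (exp(-D1/2) + exp(-D2/2)); AICc is flagged
NA when M <= eta + 1.

## Summaries and test statistics

Per allele: the mean methylation level MML = E[(1/N) sum X_n] and the
normalized methylation entropy NME = H(X)/N with H in bits; both lie in
[0, 1]. Between alleles: the Jensen-Shannon distance (JSD), the square
root of the base-2 Jensen-Shannon divergence, a metric on [0, 1] that is 0
iff the two PDMs coincide and 1 iff they do not overlap. The three test
statistics are T_MML = |MML_1 - MML_2|, T_NME = |NME_1 - NME_2| and
T_PDM = (1/N) D^2(p1, p2) / h(X), where h(X) is the NME of the 1/2-1/2
allele mixture. With equiprobable alleles D^2 equals the mutual information
I(X; A) between state and allele of origin, so T_PDM is the uncertainty
coefficient — the fraction of methylation-pattern uncertainty explained by
the allele. All entropies use 0 log 0 = 0 (required for the empirical
zeros of NPI/NPD); natural logs appear only inside Z and likelihoods.

When a SNP creates or destroys a CpG site the two alleles have different
site sets. Each allele's model is estimated over its own sites, T_MML and
T_NME use each allele's own N, and JSD/T_PDM are computed after
marginalizing both PDMs onto the shared homozygous CpG set, with the
shared count as the N in T_PDM. This choice (rather than the full per-
allele N) keeps the uncertainty-coefficient identity exact on the compared
distribution; it is configurable through the shared-site arguments of
`haplotype_stats`.

## Hypothesis testing

The null hypothesis is that an observed statistic reflects estimation
variability in a homozygous region. The null distribution is estimated
empirically per CpG count N: L times, a true model with K_max(N) subregion
fields is drawn (alpha_k ~ Uniform(-2, 2), beta ~ Uniform(-1, 1) by
default, spanning the correlation regimes of the benchmarks), 5 reads per
allele are sampled from that single model, one model is fitted per allele,
and the statistic between the two fits is recorded. One simulation pass
serves all three statistics, and null samples are cached per
(N, configuration). P values are the plain exceedance fraction
(1/L) sum I[t_l >= t*] (ties count; smallest nonzero value 1/L, recorded in
output metadata), Benjamini-Hochberg correction is applied separately per
statistic, and haplotypes with Q <= 0.05 form the MML-hap, NME-hap and
PDM-hap lists.

In pure simulation K_max(N) defaults to ceil(max_region_span/500) with
max_region_span = 1000 bp — i.e. two subregions, clipped to at most N so
every field touches a site; in real runs it should be set from the cohort.
When evaluation haplotypes draw a random K <= K_max and random coverage
5..20 while the null was built at K_max and coverage 5, the resulting P
values are conservative (higher coverage shrinks the statistics), so the
Type I error stays below the nominal level; under matched conditions the
P values are uniform. Both regimes are exposed by `run_null_calibration`.

The tissue co-occurrence permutation test places the observed number K of
significant calls uniformly at random over the (tissue, haplotype) cells
(no duplicates, 1000 permutations by default) and reports the proportion
of permutations whose co-occurrence — the fraction of significant
haplotypes significant in more than one tissue — reaches the observed one.
Feature enrichment uses the sample odds ratio ad/bc (+inf when bc = 0 with
ad > 0) and the two-sided Fisher exact P on a 2x2 haplotype count table.

## Synthetic data and benchmarks

The generator samples reads directly from a known Ising model on a
synthetic layout (K subregions of exactly 500 bp, CpG sites evenly
spaced). Benchmark defaults mirror the study conditions: coverage 10-50
fully observed reads; N in {2,...,10}; the uncorrelated regime K = 1,
alpha_1 = 1, beta = 0; the correlated regime alpha_1 = 0 with beta in
{0.25, 0.5, 0.75, 1}; partial observation by masking a random subset of
reads (each read selected with probability p_read = 0.5 by default) and
removing each CpG state within a selected read with probability
p_site = 0.5 (rates are sweep parameters; reads left empty are dropped).
Goodness-of-fit is the JSD between fitted and true PDM; parameter recovery
reports medians and IQRs across replicate fits.

What the generator deliberately does not emulate: bisulfite conversion
errors, sequencing error in the methylation call, mapping or allele-
assignment mistakes, read-length structure (missingness is site-
independent rather than contiguous), and non-nearest-neighbour
correlation. Passing benchmarks therefore demonstrate correctness of
estimation and calibration under the model's own data-generating
assumptions, not robustness to those real-data artefacts.

Desk-scale problem sizes are the package defaults: 100 replicates per
benchmark cell, L = 500 null samples and 500 evaluation haplotypes per N
(1000 replicates would be a straightforward flag change; the qualitative
orderings and calibration bounds are stable at 100-500).

## Known limitations

* A single beta per region; no per-pair couplings, CpH methylation or
  strand asymmetry.
* No confidence intervals on (alpha, beta) or on the summaries.
* The dense-PDM summaries require N <= 20 (guaranteed by the N_max split).
* NPD's zero-probability patterns make its JSD-to-truth saturate quickly at
  large N; this is the documented behaviour of the baseline, not a defect.
* BAM ingestion is not included: reads enter via the flat TSV dialect
  produced by upstream allele-assignment tooling.
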