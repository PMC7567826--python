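# cpelhap

Haplotype-level detection of allele-specific DNA methylation (hap-ASM) from
whole-genome bisulfite sequencing reads that have been assigned to the two
alleles of phased SNP haplotypes.

Classical ASM callers either test each CpG site independently (ignoring the
strong correlation of neighbouring methylation states) or tabulate joint
patterns over tiny windows from fully observed reads only (starving
themselves of data). `cpelhap` instead models the joint methylation state
X = (X_1, ..., X_N) of all N CpG sites in a haplotype allele with an
inhomogeneous 1D Ising distribution

    p(x) = exp{-U(x)} / Z
    U(x) = - Σ_k α_k Σ_{n∈R_k} (2x_n - 1) - β Σ_n (2x_n - 1)(2x_{n+1} - 1)

with one methylation-propensity field α_k per ≤500 bp subregion and a
nearest-neighbour coupling β, fitted by maximum likelihood (simulated
annealing + bounded polish) from possibly partially observed reads. Each
allele is summarized by its mean methylation level (MML) and normalized
methylation entropy (NME), alleles are compared by the Jensen–Shannon
distance (JSD), and three statistics are tested against empirical
bootstrap nulls indexed by CpG count:

* `T_MML = |MML₁ − MML₂|` — imbalance in methylation level,
* `T_NME = |NME₁ − NME₂|` — imbalance in methylation stochasticity,
* `T_PDM = D²(p₁,p₂)/(N·h(X))` — the uncertainty coefficient: how much
  information the allele of origin carries about the methylation state.

P values are one-sided exceedance fractions over the bootstrap null,
BH-corrected per statistic; haplotypes at Q ≤ 0.05 form the MML-hap,
NME-hap and PDM-hap lists. Non-parametric baselines (NPI: independent
per-site frequencies; NPD: empirical joint over full patterns) are included
for model comparison via small-sample AIC and Akaike weights, together
with the simulation benchmarks that contrast the three estimators.

Intended users: methylation/epigenomics researchers with phased variant
calls (e.g. WhatsHap) and allele-assigned bisulfite reads (e.g.
Bismark + SNPsplit). Alignment and allele assignment are out of scope;
`cpelhap` consumes their outputs as a phased VCF, a BED of CpG sites and a
flat TSV of allele-tagged reads.

## Worked example

Fit both alleles of a 6-CpG haplotype and compare them:

```python
from cpelhap import (CpelModel, CpelML, NpiML, SaConfig, akaike_weight,
                     haplotype_stats, mml, nme)
from cpelhap.testing import null_region_layout

layout = null_region_layout(6, 1)                 # one 500-bp subregion
truth1 = CpelModel(layout, (1.0,), 0.5)           # hyper-methylated allele
truth2 = CpelModel(layout, (-0.5,), 0.5)          # hypo-methylated allele
reads1 = truth1.sample_reads(20, rng=1)
reads2 = truth2.sample_reads(20, rng=2)

fit1 = CpelML(reads1, layout).fit(SaConfig.fast(rng_seed=3))
fit2 = CpelML(reads2, layout).fit(SaConfig.fast(rng_seed=4))
print(fit1.summary())
st = haplotype_stats(fit1.pdm, fit2.pdm)
print(f"T_MML={st.t_mml:.3f} T_NME={st.t_nme:.3f} "
      f"JSD={st.jsd:.3f} T_PDM={st.t_pdm:.3f}")
npi = NpiML(reads1, layout).fit()
print(f"Akaike weight (CPEL vs NPI): {akaike_weight(fit1.aicc, npi.aicc):.3f}")
```

prints

```
CPEL allele fit
================================
CpG sites:        6
Reads used (M):   20
Free params (eta): 2
Log-likelihood:   -13.5681
AICc:             31.8420
alpha:            [0.5251]
beta:             1.1097
T_MML=0.842 T_NME=0.341 JSD=0.961 T_PDM=0.316
Akaike weight (CPEL vs NPI): 1.000
```

The fitted field/coupling reproduce allele 1's methylation landscape from
20 reads (MML 0.97 vs 0.13 for allele 2). The large T_MML and JSD say the
alleles differ strongly in level and in overall pattern distribution, and
T_PDM ≈ 0.32 means the allele of origin explains about a third of the
methylation-pattern uncertainty; the Akaike weight of 1.0 prefers the
Ising model over the independent-sites baseline for these reads. In a real
run these statistics would be referred to the bootstrap null via
`cpelhap.run_analysis`, which attaches P and Q values.

The same pipeline is scriptable from the shell:

```sh
cpelhap simulate --n-sites 6 --coverage 20 --n-haplotypes 10 --seed 1 \
        --out-prefix sim
cpelhap test --vcf phased.vcf --cpg-bed cpg.bed --tsv reads.tsv \
        --null-samples 500 --seed 1 --out-prefix results
cpelhap benchmark --suite fig3c --replicates 100 --seed 1 --out bench.tsv
```

`cpelhap test` writes `results.bed` (all haplotypes with summaries,
statistics, P and Q values) plus `results.{mml,nme,pdm}_haps.bed` filtered
at Q ≤ 0.05.

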