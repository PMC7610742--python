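# gwaspeaks

A toolkit for multi-phenotype genome-wide association studies (GWAS)
with X-chromosome-aware association testing, automated peak (hit)
extraction, cross-phenotype clustering of peaks by genetic-map
distance, and sex-stratified Fisher meta-analysis. It targets the
brain-imaging-genetics setting — thousands of imaging-derived
phenotypes scanned against a shared genotype set — but nothing in it is
specific to imaging: any samples × phenotypes matrix works.

## What it computes

**Phenotype cleaning.** Each phenotype vector has outliers masked at
6× the (unscaled) median absolute deviation from the median; subjects
missing ≥ 50 phenotypes are dropped; samples are split at random into
discovery (2/3) and replication (1/3) cohorts; then, per cohort, each
phenotype is quantile-normalised to a Gaussian via the rank-based
inverse normal transform Φ⁻¹((r − 3/8)/(m + 1/4)), residualised
against user-supplied confounds (plus genetic sex), and rescaled to
unit variance.

**Sex-aware variant QC.** Variants are filtered at MAF ≥ 0.001,
INFO ≥ 0.3 and Hardy–Weinberg −log₁₀ p ≤ 7 (Levene–Haldane exact
test). On the non-pseudoautosomal X, males carry one allele, so they
contribute half as much as females to MAF and INFO, and the HWE test
uses females only.

**Association.** Each (variant, phenotype) pair is tested by simple
OLS of the deconfounded phenotype on allele dosage, with β recorded
per copy of the alternate allele in phenotype-SD units. Non-PAR X
male dosages (raw ∈ [0,1]) are scaled by 2.0 to [0,2], the full
dosage-compensation coding. p-values are carried as −log₁₀ p
throughout, evaluated in log space, so they survive far below double
underflow.

**Peaks and clusters — the core algorithm.** A *peak* is a
supra-threshold association (−log₁₀ p > 7.5) surviving greedy
within-phenotype pruning at a 0.25 cM radius. Peaks from all
phenotypes are then aggregated per chromosome: build a binary max-heap
keyed on −log₁₀ p (linear-time heapify), repeatedly extract the
maximum (phenotype, variant) pair as a new cluster's lead, and delete
its 0.25 cM cover from the heap, assigning the removed pairs to the
cluster — O(n log n) total in the number of peaks. Every peak lands in
exactly one cluster. Clusters are flagged *replicated* when any member
reaches p < 0.05 in the held-out cohort, and *Bonferroni* when the
lead exceeds 7.5 + log₁₀(#phenotypes) (≈ 11.1 for 3,935 phenotypes).

**Sex-stratified meta-analysis.** Female-only and male-only scans are
combined with Fisher's method,

&nbsp;&nbsp;&nbsp;&nbsp;p = S<sub>χ²,4</sub>( −2(ln p_f + ln p_m) ),

an unweighted combination insensitive to the assumed
dosage-compensation model. Two-tailed z-tests compare β between the
sexes, sign concordance is summarised above a significance threshold,
and meta-scan clusters are matched to main-scan clusters within
0.25 cM.

**Synthetic cohorts.** A built-in simulator generates LD-blocked
dosages (Gaussian copula) on autosomes and X with correct ploidy
(females diploid; males haploid on non-PAR X, diploid on PARs), a
constant-rate genetic map, confounds, and phenotypes with planted
sparse effects — emitting the ground truth for recovery tests.

## Worked example

Run the whole chain on a simulated cohort (4,000 samples, 10
phenotypes, 3 planted causal variants each, chromosomes 1, 2 and X):

```python
from gwaspeaks.pipeline import RunConfig, run_pipeline

config = RunConfig(
    out_dir="example",
    simulate=True,
    sim={"seed": 7, "n_phenotypes": 10},
    genomewide_threshold=4.5,   # desk-scale significance threshold
)
result = run_pipeline(config)
stats = result.provenance["stages"]
print(f"discovery n = {stats['prep']['n_discovery']}, "
      f"replication n = {stats['prep']['n_replication']}")
print(f"variants passing QC: {stats['qc']['pass']} / {sum(stats['qc'].values())}")
print(f"peaks: {stats['gwas']['n_peaks']}")
print(f"clusters: {stats['cluster']['n_clusters']} "
      f"({stats['cluster']['n_replicated']} replicated)")
top = result.clusters[0]
print(f"top cluster: lead {top.lead.key.variant_id} "
      f"({top.lead.phenotype_id}, chr{top.lead.key.chromosome}, "
      f"-log10 p = {top.lead.neglog10p:.2f}, {len(top.members)} members)")
```

which prints

```
discovery n = 2666, replication n = 1334
variants passing QC: 450 / 450
peaks: 29
clusters: 13 (13 replicated)
top cluster: lead simX_72 (P0002, chrX, -log10 p = 18.64, 4 members)
```

The 29 peaks are supra-threshold associations surviving 0.25 cM
pruning within each phenotype; the 13 clusters group them across
phenotypes (the lead's −log₁₀ p is the cluster's strongest evidence),
and all 13 re-test at nominal significance in the held-out third of
the cohort. Artifacts (summary statistics per phenotype, QC metrics,
peak and cluster reports, provenance) land under `example/`.

The same stages are available from the shell:

```sh
gwaspeaks simulate --seed 7 --out fixtures/
gwaspeaks prep  --pheno fixtures/phenotypes.tsv --confounds fixtures/confounds.tsv --out prep/
gwaspeaks gwas  --pheno prep/discovery_pheno.tsv --dosages fixtures/dosages.tsv \
                --sex fixtures/sex.tsv --cohort prep/discovery.ids --out sumstats/
gwaspeaks peaks --sumstats sumstats/ --map fixtures/map.tsv --out peaks.tsv
gwaspeaks cluster --peaks peaks.tsv --n-phenotypes 20 --out clusters.tsv
```

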