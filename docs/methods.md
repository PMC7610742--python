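# Methods

This note records the statistical model behind each stage, the
numerical choices, what the synthetic cohort does and does not
emulate, and the design decisions taken where more than one defensible
option existed.

## Phenotype preparation

The cleaning chain is: outlier masking → sparse-subject removal →
cohort split → (per cohort) quantile normalisation → confound
residualisation → unit-variance rescale. Normalisation and confound
fits happen strictly per cohort so the replication cohort stays
untouched by discovery-side estimates.

**Outlier masking.** An entry is masked when |x − median| > 6·MAD,
where MAD is the raw median absolute deviation — deliberately without
the 1.4826 normal-consistency factor, so "6 MADs" means six times the
literal MAD. With MAD = 0 (a constant-majority vector) the strict
inequality masks only values different from the median, never the
whole vector. Masking is one-shot: it is not exactly idempotent in
pathological cases (removing points can shrink the recomputed MAD),
but on continuous data with gross outliers a second pass changes
nothing, which the tests check.

**Quantile normalisation.** Rank-based inverse normal transform with
Blom offsets: x_i → Φ⁻¹((r_i − 3/8)/(m + 1/4)) with average ranks for
ties. The output is mean-zero and monotone in rank; its sample SD is
slightly below 1 at finite m (≈ 0.71 at m = 3), which is why the exact
unit-variance guarantee is enforced after residualisation rather than
here.

**Residualisation.** Ordinary least squares of each phenotype on
[intercept | confounds] over that phenotype's non-missing rows, via
`numpy.linalg.lstsq` (rank-deficient confound sets are tolerated).
Genetic sex always joins the confound matrix in the pipeline.
Residuals are rescaled to unit sample SD (ddof = 1). A phenotype whose
residual SD collapses below 1e-10 of its data scale (e.g. a phenotype
equal to a confound) is either masked to all-missing or raised as an
error, per configuration; the pipeline default masks and records the
column in provenance.

**Cohort split.** Uniform random permutation with discovery size
⌊2N/3⌋. For N = 34,298 this gives 22,865 / 11,433. The split is a
pure function of (ids, fraction, seed).

## Variant QC

**Allele frequency.** Autosomes and PARs: alt frequency =
Σdosage / 2n. Non-PAR X: males are haploid, so each contributes one
allele (denominator 2n_f + n_m) — males count half as much as
females. MAF = min(f, 1 − f).

**INFO.** Defined as the ratio of the empirical dosage variance to
its Hardy–Weinberg expectation: deviations are taken about the HWE
mean (2p diploid, p haploid male), the expectation is 2p(1−p) per
diploid call and p(1−p) per haploid call, and non-PAR-X male terms are
half-weighted in numerator and denominator. Hard genotypes at HWE
proportions give INFO = 1; fully shrunk imputations give 0. The score
is clipped to [0, 1.1] (sampling noise can push it slightly above 1)
and is NaN for monomorphic variants, which then fail the filter. This
is a variance-ratio estimator computable from dosages alone; numerical
agreement with any particular imputation tool's INFO is not promised.

**Hardy–Weinberg.** Levene–Haldane exact test (no mid-p): conditional
on the minor-allele count, the heterozygote count's distribution is
evaluated in log space with log-gamma terms, and the two-sided p sums
all configurations no more likely than the observed one (with an
ulp-scale tolerance on the "no more likely" comparison). Dosages are
hard-called by rounding; calls further than 0.1 (configurable) from an
integer are excluded. On chromosome X — both PAR and non-PAR — the
test uses genetic females only, so adding males never changes it. The
exact test rather than a chi-square keeps the tail honest at the rare
MAFs where the filter actually bites.

**Thresholds.** MAF ≥ 0.001, INFO ≥ 0.3, HWE −log₁₀ p ≤ 7; boundary
values pass exactly as written. Rejections are tallied by the first
failing rule in that order, and survivors plus tallies partition the
input.

## Association scan

Simple OLS per variant with intercept, casewise deletion of missing
entries per variant (mean-imputation was rejected so the closed-form
OLS oracle in the tests stays exact). β is per alternate-allele copy;
the standard error uses residual variance with df = n − 2. Confound
degrees of freedom were spent upstream in phenotype residualisation,
so df = n − 2 is slightly anti-conservative at small n; at the sample
sizes this pipeline targets (thousands) the effect is negligible.

−log₁₀ p comes from the log survival function of the Student t (so
t ≈ 1e4 stays finite) and is capped at 320 to keep TSV round-trips
finite; perfect fits (zero residual variance) report the cap. Variants
with zero dosage variance in the cohort are flagged monomorphic and
not tested.

**X coding.** Non-PAR male dosages arrive raw in [0,1] and are scaled
by 2.0, the full-dosage-compensation (0,2) coding that makes one male
allele comparable to two female alleles. PARs are treated exactly like
autosomes. The coding is an exact linear rescale, so a male-only scan
under (0,2) coding has exactly half the β and an identical −log₁₀ p of
the (0,1) coding — a property the tests assert bit-exactly.

**Hit filter.** Summary statistics retain all variants with
MAF ≥ 0.001; hits (and Manhattan exports) additionally require
MAF ≥ 0.01.

## Peaks and clusters

Within one phenotype and chromosome, peak extraction repeatedly takes
the strongest remaining record with −log₁₀ p strictly above the
genome-wide threshold (7.5 by default) and removes every record within
0.25 cM, inclusive. Cross-phenotype clustering applies the same greedy
rule to the pooled peak set per chromosome, implemented as specified
for large inputs: an indexed binary max-heap (array-based, linear-time
bottom-up heapify, O(log n) extract-max and arbitrary delete via a
position table) keyed on −log₁₀ p, with the 0.25 cM cover located
through a cM-sorted array and binary search. The cover window is
widened by an ulp-scale pad and then filtered with the exact
|ΔcM| ≤ 0.25 predicate, so boundary membership is decided by the
distance itself rather than by rounding of `lead ± cover`.

Ties on −log₁₀ p break toward the smaller (bp, phenotype_id) — the
choice is arbitrary but fixed, making output deterministic and
comparable to the naive quadratic reference implementation the tests
run against. Cover removal operates on the peak set only, not on raw
variant records. Cluster output is ordered X first, then autosomes
ascending, then descending lead significance; within-chromosome order
is the extraction order, so it needs no extra sort.

Replication: a cluster replicates when at least one member's re-test
in the held-out cohort has two-sided p strictly below 0.05; members
untestable there (monomorphic, absent) count as non-significant and
are logged. Replication is non-directional (sign concordance is
reported separately by the sex-meta module). Bonferroni flag: lead
−log₁₀ p ≥ 7.5 + log₁₀(#phenotypes), unrounded internally. PAR and
non-PAR X peaks cluster together on the X heap using X-map cM
coordinates.

## Sex-stratified meta-analysis

Fisher's method with 2 scans: the statistic −2(ln p_f + ln p_m) is
chi-squared with 4 df under the null ("log" is the natural log; with
log₁₀ the statistic would not be chi-squared). Inputs are carried as
−log₁₀ p and converted by ln p = −ln(10)·nlp, and the chi-squared
survival function is evaluated as an even-df Poisson-series
log-sum-exp, so combined p-values far below 1e-308 are exact in log
space; for df 4 this equals the closed form q(1 − ln q), q = p_f·p_m,
to better than 1e-12 relative, which the tests verify against both
that closed form and scipy. The combination is deliberately
unweighted: it is insensitive to any relative scaling of the two
sex-separated regressions and therefore to the assumed
dosage-compensation model; no β-weighted variant is offered.

Sex differences in effect size use z = (β_f − β_m)/√(se_f² + se_m²)
with a two-tailed normal p. Sign concordance is the fraction of pairs
with β_f·β_m ≥ 0 (zero β counts as concordant) among pairs whose
stronger sex-specific −log₁₀ p reaches the threshold. Meta-scan
clusters match main-scan clusters when leads on the same chromosome
are within 0.25 cM, inclusive — the same boundary convention as the
cover rule.

## Synthetic cohort

The simulator is a first-class module, not a fixture: it defines the
study conditions under which the pipeline's recovery and calibration
are demonstrated.

Genotypes use a Gaussian copula: per haplotype, a latent normal mixes
a per-(sample, LD-block) factor (weight √r, r = 0.8 over blocks of 10
variants by default) with independent noise, thresholded at Φ⁻¹(p_v)
so each variant is marginally in Hardy–Weinberg at its target
frequency (uniform in [0.1, 0.5] by default) while block-mates are
correlated. Females get two haplotypes everywhere; males get one on
non-PAR X (raw dosage in [0,1]) and two on PARs and autosomes.
Shrink-to-mean dosage noise d = (1−a)·g + a·E[g] emulates imputation
uncertainty with INFO ≈ (1−a)², a = 0.05 by default. The genetic map
is constant-rate (1 cM/Mb) so cover distances are exactly controllable;
with the default 20 kb spacing a 150-variant chromosome spans 3 cM and
an LD block spans 0.2 cM, inside the 0.25 cM cover.

Phenotypes are Σ β_j·(encoded dosage)_j + confound loadings + N(0,1)
noise, standardised; defaults plant 3 causal variants per phenotype
with per-allele effects uniform in [0.15, 0.3] and random sign, 20
phenotypes, 2,000 samples per sex, 1% missingness in both genotypes
and phenotypes, and a 0.2% rate of injected gross outliers to exercise
the MAD mask. On non-PAR X the male genetic value uses the (0,2)
encoding times a dosage-compensation multiplier (1.0 — full XCI — by
default). Because phenotypes are standardised after adding the genetic
signal, realised per-allele effects are attenuated by the total-SD
factor (≈ 3% under the defaults), which matters for none of the
recovery checks; the unstandardised mode exists for exact
effect-recovery tests.

What the simulator does **not** emulate: population structure and
relatedness, realistic recombination maps, allele-frequency spectra
with rare variants, imputation-panel error structure, or sex
differences in allele frequency. Passing recovery tests therefore
demonstrate the pipeline's mechanics (QC, encoding, thresholding,
pruning, clustering, replication) under clean conditions, not
robustness to confounded real-world cohorts.

## Problem sizes in the tests and acceptance script

End-to-end recovery runs the full pipeline at n = 4,000 (20 seeds in
the tests, 10 in the acceptance script, each with a matched global-null
condition), 20 phenotypes, 450 variants over chromosomes 1, 2 and X,
with the genome-wide threshold lowered to 4.5 — the calibration
appropriate to ~2,700 discovery samples and 9,000 tests, where 7.5
would have near-zero power for the planted effect sizes. Under these
conditions ≈ 99% of planted causal variants lie within 0.25 cM of a
replicated-cluster lead, and the global null yields zero replicated
clusters in the tested seeds. Null calibration uses 10,000
variant-phenotype tests (type-I rate at −log₁₀ p > 2), 50,000 Fisher
pairs (KS against uniform), and 10,000 HWE-simulated variants at
n = 500 (rejection rate at −log₁₀ p > 7 below 0.1%). Heap-vs-naive
clustering equivalence runs 1,000 random instances of up to 500 peaks
with ties injected on a coarse significance grid.

## Known limitations

- Confounds are regressed from phenotypes only, not genotypes; with
  strong genotype-confound correlation this differs from a joint model.
- No mixed-model or relatedness correction; the intended input is a
  maximal unrelated subset.
- The INFO estimator is variance-ratio ("machine-r²" style); tools
  that infer ploidy differently may disagree numerically.
- BGEN is not parsed natively; convert to VCF-with-DS or a TSV dosage
  matrix first.
- The genetic map is a required input for clustering (desk maps from
  SHAPEIT/plink distributions work); no map is bundled, since cM
  coordinates depend on the map release.
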