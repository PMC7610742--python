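"""Sex-aware variant quality control: MAF, INFO and exact HWE filters.

On the non-pseudoautosomal X, genetic males carry a single allele, so
they contribute half as much as females to allele frequency and INFO;
the Hardy-Weinberg test is computed on genetic females only.  Default
thresholds: MAF >= 0.001, INFO >= 0.3, HWE -log10 p <= 7, with boundary
values passing exactly as written.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .io_formats import DosageSet
from .variants import REGION_X_NONPAR, VariantKey


class QCError(ValueError):
    pass


def allele_freq_sex_aware(dosages: DosageSet, variant_index: int) -> tuple[float, float]:
    """(alt_freq, maf) with haploid male handling on non-PAR X.

    Autosomes/PARs: alt_freq = sum(dosage) / (2 * n_nonmissing).
    Non-PAR X: each male contributes one allele (raw dosage in [0,1]),
    so the denominator is 2*n_females + n_males.
    """
    key = dosages.variants[variant_index]
    row = dosages.dosages[variant_index]
    obs = np.isfinite(row)
    if not obs.any():
        raise QCError(f"{key.variant_id}: all dosages missing")
    if key.region == REGION_X_NONPAR:
        female = dosages.is_female()
        n_alleles = 2 * int((obs & female).sum()) + int((obs & ~female).sum())
    else:
        n_alleles = 2 * int(obs.sum())
    alt_freq = float(np.nansum(row) / n_alleles)
    return alt_freq, min(alt_freq, 1.0 - alt_freq)


def info_score(dosages: DosageSet, variant_index: int) -> float:
    """Imputation-quality INFO: empirical dosage variance over its HWE expectation.

    Variance is taken about the HWE mean (2p diploid, p haploid); the
    expectation is 2p(1-p) per diploid call and p(1-p) per haploid male
    call, with non-PAR-X male terms half-weighted in both numerator and
    denominator.  Clipped to [0, 1.1].  Monomorphic variants (maf = 0)
    have an undefined score and return NaN.
    """
    key = dosages.variants[variant_index]
    row = dosages.dosages[variant_index]
    p, maf = allele_freq_sex_aware(dosages, variant_index)
    if maf <= 0.0:
        return float("nan")
    obs = np.isfinite(row)
    pq = p * (1.0 - p)
    if key.region == REGION_X_NONPAR:
        female = dosages.is_female()
        f = obs & female
        m = obs & ~female
        num = np.sum((row[f] - 2 * p) ** 2) + 0.5 * np.sum((row[m] - p) ** 2)
        den = f.sum() * 2 * pq + 0.5 * m.sum() * pq
    else:
        num = np.sum((row[obs] - 2 * p) ** 2)
        den = obs.sum() * 2 * pq
    return float(np.clip(num / den, 0.0, 1.1))


def _hwe_exact_neglog10p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Levene-Haldane exact test on genotype counts, returned as -log10 p.

    Conditional on the allele counts, the heterozygote count follows the
    Levene-Haldane distribution; the two-sided p sums the probabilities
    of all heterozygote configurations no more likely than the observed
    one (no mid-p).  Evaluated in log space via gammaln.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n < 2:
        raise QCError("need >= 2 usable genotypes for the HWE exact test")
    n_alt = 2 * n_hom_alt + n_het
    n1 = min(n_alt, 2 * n - n_alt)  # minor allele count
    if n1 == 0:
        return 0.0  # monomorphic: single attainable configuration, p = 1
    hets = np.arange(n1 % 2, n1 + 1, 2)
    hom_minor = (n1 - hets) // 2
    hom_major = n - hets - hom_minor
    # log P(n_het = h | n, n1), constant terms dropped before normalisation
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
    )
    logp -= logsumexp(logp)
    obs_logp = logp[np.searchsorted(hets, n_het)]
    # tolerate rounding when comparing "no more likely than observed"
    tail = logsumexp(logp[logp <= obs_logp + 1e-9])
    return float(max(0.0, -tail / np.log(10.0)))


def hard_call_genotypes(row: np.ndarray, max_distance: float = 0.1) -> np.ndarray:
    """Round dosages to the nearest integer genotype; uncallable -> NaN."""
    g = np.round(row)
    callable_ = np.isfinite(row) & (np.abs(row - g) <= max_distance)
    out = np.where(callable_, g, np.nan)
    return out


def hwe_neglog10p(
    dosages: DosageSet, variant_index: int, max_call_distance: float = 0.1
) -> float:
    """Exact-test HWE -log10 p for one variant (females only on chromosome X)."""
    key = dosages.variants[variant_index]
    row = dosages.dosages[variant_index]
    if key.is_x:
        row = row[dosages.is_female()]
    g = hard_call_genotypes(row, max_call_distance)
    g = g[np.isfinite(g)]
    counts = [int((g == k).sum()) for k in (0, 1, 2)]
    return _hwe_exact_neglog10p(*counts)


@dataclass
class QCThresholds:
    maf_min: float = 0.001
    info_min: float = 0.3
    hwe_max: float = 7.0


@dataclass
class VariantQCMetrics:
    key: VariantKey
    maf: float
    info: float
    hwe_neglog10p: float

    def passes(self, thresholds: QCThresholds) -> tuple[bool, str | None]:
        """(pass, first failing rule); boundary values pass (>= / <=)."""
        if not (self.maf >= thresholds.maf_min):
            return False, "maf"
        if not (np.isfinite(self.info) and self.info >= thresholds.info_min):
            return False, "info"
        if not (self.hwe_neglog10p <= thresholds.hwe_max):
            return False, "hwe"
        return True, None


def compute_metrics(dosages: DosageSet) -> list[VariantQCMetrics]:
    out = []
    for i, key in enumerate(dosages.variants):
        _, maf = allele_freq_sex_aware(dosages, i)
        out.append(
            VariantQCMetrics(
                key=key,
                maf=maf,
                info=info_score(dosages, i),
                hwe_neglog10p=hwe_neglog10p(dosages, i),
            )
        )
    return out


def apply_filters(
    metrics: list[VariantQCMetrics], thresholds: QCThresholds | None = None
) -> tuple[list[VariantKey], dict[str, int]]:
    """Surviving variant keys plus per-rule rejection tallies."""
    thresholds = thresholds or QCThresholds()
    surviving: list[VariantKey] = []
    tallies = {"pass": 0, "maf": 0, "info": 0, "hwe": 0}
    for m in metrics:
        ok, reason = m.passes(thresholds)
        if ok:
            surviving.append(m.key)
            tallies["pass"] += 1
        else:
            tallies[reason] += 1
    return surviving, tallies
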