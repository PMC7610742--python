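"""Independent reference implementations used only by the tests.

These deliberately take different computational routes from the package
(naive quadratic greedy instead of heap + bisect; recurrence-based
exact HWE instead of log-gamma closed form; closed-form df-4 Fisher
tail instead of the even-df series) so agreement is evidence, not
tautology.
"""

from __future__ import annotations

import numpy as np

from gwaspeaks.peaks_clustering import Peak
from gwaspeaks.variants import chromosome_sort_key


def naive_greedy_clusters(peaks: list[Peak], cover_cM: float = 0.25):
    """Quadratic greedy max-first cover clustering.

    Returns clusters as lists of (phenotype_id, variant_id) with the
    lead first, in the same chromosome-then-extraction order the
    package promises.
    """
    out = []
    for chrom in sorted({p.key.chromosome for p in peaks}, key=chromosome_sort_key):
        chrom_peaks = [p for p in peaks if p.key.chromosome == chrom]
        alive = [True] * len(chrom_peaks)
        while any(alive):
            lead_i = min(
                (i for i in range(len(chrom_peaks)) if alive[i]),
                key=lambda i: chrom_peaks[i].sort_key(),
            )
            lead = chrom_peaks[lead_i]
            member_is = [
                i
                for i in range(len(chrom_peaks))
                if alive[i] and abs(chrom_peaks[i].cM - lead.cM) <= cover_cM
            ]
            for i in member_is:
                alive[i] = False
            member_is.sort(key=lambda i: chrom_peaks[i].sort_key())
            members = [lead_i] + [i for i in member_is if i != lead_i]
            out.append([(chrom_peaks[i].phenotype_id, chrom_peaks[i].key.variant_id)
                        for i in members])
    return out


def hwe_exact_pvalue_recurrence(obs_hom1: int, obs_het: int, obs_hom2: int) -> float:
    """Exact Hardy-Weinberg p by the heterozygote-count recurrence.

    Builds the Levene-Haldane distribution with the standard two-term
    ratio recurrence in plain floating point, then sums probabilities
    no greater than the observed configuration's.
    """
    n = obs_hom1 + obs_het + obs_hom2
    rare = 2 * min(obs_hom1, obs_hom2) + obs_het
    if rare == 0:
        return 1.0
    mid = int(rare * (2 * n - rare) / (2 * n))
    if (mid % 2) != (rare % 2):
        mid += 1
    probs = {mid: 1.0}
    het = mid
    while het >= 2:
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        probs[het - 2] = probs[het] * het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        het -= 2
    het = mid
    while het <= rare - 2:
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        probs[het + 2] = probs[het] * 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
        het += 2
    total = sum(probs.values())
    obs_p = probs[obs_het] / total
    return min(1.0, sum(v / total for v in probs.values() if v / total <= obs_p * (1 + 1e-9)))


def fisher_df4_closed_form_log(neglog10p_f, neglog10p_m):
    """ln of the combined p via the df-4 closed form q(1 - ln q)."""
    ln_q = -np.log(10.0) * (np.asarray(neglog10p_f, float) + np.asarray(neglog10p_m, float))
    return ln_q + np.log1p(-ln_q)


def random_peak_instance(rng: np.random.Generator, max_peaks: int = 500,
                         with_ties: bool = True, n_chroms: int = 2) -> list[Peak]:
    """Random peak set with tie-prone -log10 p values for oracle comparisons."""
    from gwaspeaks.variants import make_variant_key

    n = int(rng.integers(1, max_peaks + 1))
    chroms = rng.choice([str(c + 1) for c in range(n_chroms)], size=n)
    peaks = []
    for i in range(n):
        bp = int(rng.integers(1, 5_000_000))
        if with_ties:
            nlp = 7.5 + float(rng.integers(0, 12)) * 0.5  # coarse grid forces ties
        else:
            nlp = 7.5 + float(rng.uniform(0, 20))
        peaks.append(
            Peak(
                phenotype_id=f"P{int(rng.integers(0, 20)):02d}",
                key=make_variant_key(f"v{i}", chroms[i], bp, "A", "G"),
                cM=float(np.round(rng.uniform(0, 5), 3)),
                neglog10p=nlp,
                beta=0.1,
                se=0.01,
            )
        )
    return peaks
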