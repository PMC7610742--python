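"""Sex-stratified scans: Fisher meta-analysis, beta-difference z-tests,
sign concordance, and meta-vs-main cluster overlap.

The meta-analysis combines the female-only and male-only scan p-values
with Fisher's method: -2(ln p_f + ln p_m) is chi-squared with 4 degrees
of freedom under the null.  It is deliberately unweighted — insensitive
to any relative scaling of the two sex-separated regressions, hence to
the assumed dosage-compensation model.  All p-values are carried as
-log10 p and combined in log space, so inputs far below double
underflow remain usable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp, xlogy

from .assoc_scan import AssocResult
from .peaks_clustering import Cluster
from .variants import VariantKey

_LN10 = math.log(10.0)


class MetaError(ValueError):
    pass


def _chi2_logsf_even_df(x, df: int):
    """log survival function of chi-squared with even df.

    For df = 2k, S(x) = e^{-x/2} * sum_{j<k} (x/2)^j / j!; evaluated as
    a log-sum-exp so it stays accurate for p far below underflow.
    """
    if df % 2 or df < 2:
        raise ValueError("even df >= 2 required")
    k = df // 2
    x = np.asarray(x, dtype=float)
    half = np.atleast_1d(x / 2.0)
    j = np.arange(k)[:, None]
    with np.errstate(divide="ignore"):
        terms = xlogy(j, half[None, :]) - gammaln(j + 1)
    out = logsumexp(terms, axis=0) - half
    out = np.minimum(out, 0.0)
    return out if np.ndim(x) else float(out[0])


def fisher_combine_neglog10(neglog10p_f, neglog10p_m):
    """Combined -log10 p of Fisher's method (df 4) from per-sex -log10 p."""
    nf = np.asarray(neglog10p_f, dtype=float)
    nm = np.asarray(neglog10p_m, dtype=float)
    if np.any(nf < 0) or np.any(nm < 0):
        raise MetaError("-log10 p inputs must be >= 0")
    stat = 2.0 * _LN10 * (nf + nm)  # = -2(ln p_f + ln p_m)
    return -_chi2_logsf_even_df(stat, 4) / _LN10


def fisher_combine(p_f: float, p_m: float) -> tuple[float, float]:
    """(combined p, combined -log10 p) from two p-values in (0, 1]."""
    if not (0.0 < p_f <= 1.0 and 0.0 < p_m <= 1.0):
        raise MetaError(f"p-values must lie in (0, 1], got ({p_f}, {p_m})")
    nlp = float(fisher_combine_neglog10(-math.log10(p_f), -math.log10(p_m)))
    return 10.0 ** (-nlp), nlp


@dataclass(frozen=True)
class SexScanPair:
    """Female and male association results for the same (variant, phenotype)."""

    female: AssocResult
    male: AssocResult

    def __post_init__(self):
        if (
            self.female.key.variant_id != self.male.key.variant_id
            or self.female.phenotype_id != self.male.phenotype_id
        ):
            raise MetaError("sex-scan pair must share variant and phenotype")


@dataclass
class MetaResult:
    key: VariantKey
    phenotype_id: str
    neglog10p_f: float
    neglog10p_m: float
    combined_neglog10p: float


def meta_scan(
    female_results: list[AssocResult], male_results: list[AssocResult]
) -> list[MetaResult]:
    """Fisher-combine matched female/male results (untestable pairs skipped)."""
    male_by_id = {(r.phenotype_id, r.key.variant_id): r for r in male_results}
    out: list[MetaResult] = []
    for f in female_results:
        m = male_by_id.get((f.phenotype_id, f.key.variant_id))
        if m is None or f.monomorphic or m.monomorphic:
            continue
        out.append(
            MetaResult(
                key=f.key,
                phenotype_id=f.phenotype_id,
                neglog10p_f=f.neglog10p,
                neglog10p_m=m.neglog10p,
                combined_neglog10p=float(
                    fisher_combine_neglog10(f.neglog10p, m.neglog10p)
                ),
            )
        )
    return out


def beta_diff_ztest(pair: SexScanPair) -> float:
    """Two-tailed z-test p for a female/male difference in beta."""
    se_f, se_m = pair.female.se, pair.male.se
    if se_f <= 0 or se_m <= 0:
        raise MetaError("both standard errors must be positive")
    z = (pair.female.beta - pair.male.beta) / math.hypot(se_f, se_m)
    return float(2.0 * stats.norm.sf(abs(z)))


def sign_concordance(pairs: list[SexScanPair], neglog10p_min: float) -> float:
    """Fraction of sex-scan pairs with matching beta signs.

    Restricted to pairs where the stronger sex-specific -log10 p reaches
    ``neglog10p_min``; a zero beta counts as concordant with either sign.
    """
    selected = [
        p for p in pairs
        if max(p.female.neglog10p, p.male.neglog10p) >= neglog10p_min
    ]
    if not selected:
        raise MetaError(
            f"no pairs reach -log10 p >= {neglog10p_min}; concordance undefined"
        )
    ok = sum(1 for p in selected if p.female.beta * p.male.beta >= 0)
    return ok / len(selected)


def cluster_overlap(
    meta_clusters: list[Cluster],
    main_clusters: list[Cluster],
    tol_cM: float = 0.25,
) -> tuple[list[tuple[Cluster, Cluster]], list[Cluster], list[Cluster]]:
    """Match meta-analysis clusters to main-scan clusters by lead distance.

    A meta cluster matches when some main cluster on the same chromosome
    has its lead within ``tol_cM`` (inclusive) of the meta lead; the
    nearest such main cluster is reported.  Returns (matched pairs,
    unmatched meta clusters, unmatched main clusters).
    """
    matched: list[tuple[Cluster, Cluster]] = []
    meta_orphans: list[Cluster] = []
    hit_main: set[int] = set()
    for mc in meta_clusters:
        best, best_d = None, None
        for i, main in enumerate(main_clusters):
            if main.lead.key.chromosome != mc.lead.key.chromosome:
                continue
            d = abs(main.lead.cM - mc.lead.cM)
            if d <= tol_cM and (best_d is None or d < best_d):
                best, best_d = i, d
        if best is None:
            meta_orphans.append(mc)
        else:
            matched.append((mc, main_clusters[best]))
            hit_main.add(best)
    main_orphans = [c for i, c in enumerate(main_clusters) if i not in hit_main]
    return matched, meta_orphans, main_orphans
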