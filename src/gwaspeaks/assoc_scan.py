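"""Per-variant linear association with X-chromosome dosage encoding.

Phenotypes arrive already residualized against confounds and scaled to
unit variance, so each test is a simple OLS of phenotype on encoded
dosage with an intercept (df = n - 2).  Effects are recorded in the
direction of the alternate allele, in phenotype SD units per allele
copy.  Non-PAR X male dosages, raw in [0, 1], are scaled by 2.0 so both
sexes lie in [0, 2] under full dosage compensation; autosomal and PAR
dosages are not scaled.  p-values are emitted as -log10 p via the
log-space Student-t tail, capped for finite round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import DosageSet, MALE, normalize_sex
from .variants import REGION_X_NONPAR, VariantKey

_LN10 = np.log(10.0)

#: -log10 p cap keeping TSV round-trips finite
NEGLOG10P_CAP = 320.0


@dataclass
class AssocResult:
    key: VariantKey
    phenotype_id: str
    beta: float
    se: float
    neglog10p: float
    n: int
    monomorphic: bool = False


def encode_x_dosage(raw, sex, region: str):
    """Encode dosages for association: non-PAR X males scaled by 2.0.

    ``raw`` male non-PAR dosages must lie in [0, 1] (one allele copy);
    everything else, already in [0, 2], passes through unchanged.
    """
    raw_arr = np.asarray(raw, dtype=float)
    scalar = raw_arr.ndim == 0
    raw_arr = np.atleast_1d(raw_arr).copy()
    sex_arr = np.atleast_1d(np.asarray(sex, dtype=object))
    if sex_arr.size == 1 and raw_arr.size > 1:
        sex_arr = np.repeat(sex_arr, raw_arr.size)
    sex_arr = np.array([normalize_sex(s) for s in sex_arr], dtype=object)
    obs = np.isfinite(raw_arr)
    male = sex_arr == MALE
    if region == REGION_X_NONPAR:
        if np.any(obs & male & ((raw_arr < 0) | (raw_arr > 1))):
            raise ValueError("non-PAR male raw dosage outside [0, 1]")
        if np.any(obs & ~male & ((raw_arr < 0) | (raw_arr > 2))):
            raise ValueError("female dosage outside [0, 2]")
        raw_arr[male] = 2.0 * raw_arr[male]
    else:
        if np.any(obs & ((raw_arr < 0) | (raw_arr > 2))):
            raise ValueError("dosage outside [0, 2]")
    return float(raw_arr[0]) if scalar else raw_arr


def encoded_dosage_matrix(dosages: DosageSet) -> np.ndarray:
    """All variants' association-ready dosages (non-PAR X males doubled)."""
    G = dosages.dosages.copy()
    male = ~dosages.is_female()
    for i, key in enumerate(dosages.variants):
        if key.region == REGION_X_NONPAR:
            G[i, male] = encode_x_dosage(dosages.dosages[i, male], [MALE] * male.sum(),
                                         REGION_X_NONPAR)
    return G


def neglog10p_from_t(t: np.ndarray, df: np.ndarray, cap: float = NEGLOG10P_CAP) -> np.ndarray:
    """Two-sided -log10 p from a t statistic, evaluated in log space."""
    t = np.asarray(t, dtype=float)
    df = np.asarray(df, dtype=float)
    with np.errstate(invalid="ignore"):
        logp = np.log(2.0) + stats.t.logsf(np.abs(t), df)
    nlp = -logp / _LN10
    nlp = np.where(np.isfinite(t), nlp, cap)  # perfect fits: se -> 0
    return np.minimum(nlp, cap)


def ols_scan_matrix(
    G: np.ndarray, y: np.ndarray, cap: float = NEGLOG10P_CAP
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised simple OLS of ``y`` on each row of ``G`` with intercept.

    Missing entries (NaN in either input) are deleted casewise per
    variant.  Returns (beta, se, neglog10p, n, monomorphic) arrays.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    valid = np.isfinite(G) & np.isfinite(y)[None, :]
    Gz = np.where(valid, G, 0.0)
    yz = np.where(np.isfinite(y), y, 0.0)
    n = valid.sum(axis=1).astype(float)
    Sg = Gz.sum(axis=1)
    Sy = valid @ yz
    Sgg = (Gz * Gz).sum(axis=1)
    Sgy = Gz @ yz
    Syy = valid @ (yz * yz)
    with np.errstate(invalid="ignore", divide="ignore"):
        Sxx = Sgg - Sg * Sg / n
        Sxy = Sgy - Sg * Sy / n
        Syy_c = Syy - Sy * Sy / n
        mono = (n < 3) | (Sxx <= 1e-12 * np.maximum(n, 1.0))
        beta = np.where(mono, np.nan, Sxy / np.where(Sxx > 0, Sxx, np.nan))
        sse = np.maximum(Syy_c - beta * Sxy, 0.0)
        df = n - 2.0
        s2 = sse / df
        se = np.sqrt(s2 / Sxx)
        t = beta / se
        nlp = neglog10p_from_t(t, df, cap=cap)
    nlp = np.where(mono, np.nan, nlp)
    return beta, se, nlp, n.astype(int), mono


def linear_scan(
    pheno_residuals,
    dosages: DosageSet,
    cohort_ids=None,
    phenotype_id: str = "phenotype",
    cap: float = NEGLOG10P_CAP,
) -> list[AssocResult]:
    """Association of one residualized phenotype with every variant.

    ``pheno_residuals`` is a pandas Series indexed by sample id (or an
    array aligned to the dosage samples); ``cohort_ids`` restricts to a
    sub-cohort.  Monomorphic variants in the cohort are flagged and
    carry NaN statistics rather than a test.
    """
    import pandas as pd

    if cohort_ids is not None:
        dosages = dosages.subset_samples(list(cohort_ids))
    if isinstance(pheno_residuals, pd.Series):
        y = pheno_residuals.reindex(dosages.sample_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(pheno_residuals, dtype=float)
        if y.shape[0] != dosages.n_samples:
            raise ValueError("phenotype vector not aligned to dosage samples")
    G = encoded_dosage_matrix(dosages)
    beta, se, nlp, n, mono = ols_scan_matrix(G, y, cap=cap)
    return [
        AssocResult(
            key=key,
            phenotype_id=phenotype_id,
            beta=float(beta[i]),
            se=float(se[i]),
            neglog10p=float(nlp[i]) if not mono[i] else float("nan"),
            n=int(n[i]),
            monomorphic=bool(mono[i]),
        )
        for i, key in enumerate(dosages.variants)
    ]


def hit_filter(
    results: list[AssocResult], maf_table: dict[str, float], maf_min: float = 0.01
) -> list[AssocResult]:
    """Drop results below the hit-level MAF threshold (default 0.01).

    The full summary-statistics output keeps everything down to the QC
    floor (MAF >= 0.001); this stricter filter applies only to hits and
    Manhattan exports.  Every variant must appear in ``maf_table``.
    """
    out = []
    for r in results:
        try:
            maf = maf_table[r.key.variant_id]
        except KeyError:
            raise KeyError(f"variant {r.key.variant_id} absent from MAF table") from None
        if maf >= maf_min:
            out.append(r)
    return out


def results_to_records(results: list[AssocResult]):
    """AssocResults -> SumStatsRecords (monomorphic entries dropped)."""
    from .io_formats import SumStatsRecord

    return [
        SumStatsRecord(key=r.key, beta=r.beta, se=r.se, neglog10p=r.neglog10p, n=r.n)
        for r in results
        if not r.monomorphic
    ]
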