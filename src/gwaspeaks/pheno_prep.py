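"""Phenotype cleaning for multi-phenotype GWAS.

The cleaning chain mirrors the standard imaging-genetics preparation:

1. per-phenotype outlier masking at 6x the (unscaled) median absolute
   deviation from the median;
2. dropping subjects missing 50 or more phenotypes;
3. a random 2/3 : 1/3 discovery/replication split;
4. per cohort: rank-based inverse normal (quantile) transformation with
   Blom offsets, least-squares confound residualization, and a final
   rescale to unit variance.

Steps 4 run independently per cohort so no information leaks across the
discovery/replication boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class PhenotypeError(ValueError):
    pass


def mask_outliers_mad(values, n_mads: float = 6.0) -> np.ndarray:
    """Set entries further than ``n_mads`` x MAD from the median to NaN.

    MAD is the unscaled median absolute deviation (no 1.4826 normal
    consistency factor).  With MAD = 0 (constant-majority vectors) the
    strict ``>`` comparison masks only values that differ from the
    median, never the whole vector.
    """
    x = np.asarray(values, dtype=float).copy()
    obs = np.isfinite(x)
    if obs.sum() < 2:
        raise PhenotypeError("need >= 2 non-missing values for MAD masking")
    med = np.median(x[obs])
    mad = np.median(np.abs(x[obs] - med))
    x[obs & (np.abs(x - med) > n_mads * mad)] = np.nan
    return x


def drop_sparse_subjects(pheno: pd.DataFrame, max_missing: int = 50) -> pd.DataFrame:
    """Drop rows (subjects) with ``max_missing`` or more missing phenotypes."""
    n_missing = pheno.isna().sum(axis=1)
    return pheno.loc[n_missing < max_missing]


def quantile_normalize(values) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offsets.

    Non-missing entries are replaced by Phi^-1((r - 3/8)/(m + 1/4)) of
    their average ranks r among the m non-missing values; ties share a
    rank and therefore an output value.  The result is monotone in rank
    with mean ~0; its sample SD approaches 1 only as m grows (the exact
    unit-variance rescale happens after residualization).
    """
    x = np.asarray(values, dtype=float).copy()
    obs = np.isfinite(x)
    m = int(obs.sum())
    if m < 3:
        raise PhenotypeError(f"need >= 3 non-missing values to quantile normalise, got {m}")
    ranks = stats.rankdata(x[obs], method="average")
    x[obs] = stats.norm.ppf((ranks - 0.375) / (m + 0.25))
    return x


@dataclass
class CleanPhenotypes:
    """Cleaned phenotype matrix plus per-phenotype usable counts and provenance."""

    matrix: pd.DataFrame
    n_used: pd.Series
    provenance: dict = field(default_factory=dict)


def residualize(
    pheno: pd.DataFrame,
    confounds: pd.DataFrame | None,
    on_degenerate: str = "mask",
    rescale: bool = True,
) -> CleanPhenotypes:
    """Replace each phenotype by its confound residuals, rescaled to unit SD.

    Residuals are least-squares against [intercept | confounds] on each
    phenotype's non-missing rows (rank deficiency tolerated via lstsq).
    A phenotype whose residual variance degenerates to ~0 (e.g. equal to
    a confound column) is set all-missing (``on_degenerate="mask"``) or
    raises (``"error"``).
    """
    if on_degenerate not in ("mask", "error"):
        raise ValueError("on_degenerate must be 'mask' or 'error'")
    if confounds is not None:
        confounds = confounds.loc[pheno.index]
        C = confounds.to_numpy(dtype=float)
    else:
        C = np.empty((len(pheno), 0))
    out = pheno.copy()
    n_used = {}
    degenerate = []
    for col in pheno.columns:
        y = pheno[col].to_numpy(dtype=float)
        obs = np.isfinite(y) & np.all(np.isfinite(C), axis=1)
        n = int(obs.sum())
        if n == 0:
            raise PhenotypeError(f"{col}: no usable rows after confound alignment")
        X = np.column_stack([np.ones(n), C[obs]])
        coef, *_ = np.linalg.lstsq(X, y[obs], rcond=None)
        resid = y[obs] - X @ coef
        sd = resid.std(ddof=1) if n > 1 else 0.0
        vals = np.full(y.shape, np.nan)
        if sd < 1e-10 * max(1.0, np.abs(y[obs]).std() or 1.0):
            if on_degenerate == "error":
                raise PhenotypeError(f"{col}: degenerate residual variance")
            degenerate.append(col)
            n = 0
        else:
            vals[obs] = resid / sd if rescale else resid
        out[col] = vals
        n_used[col] = n
    return CleanPhenotypes(
        matrix=out,
        n_used=pd.Series(n_used),
        provenance={"degenerate_phenotypes": degenerate},
    )


@dataclass
class CohortSplit:
    """Disjoint discovery/replication sample-id lists (|discovery| = floor(f*N))."""

    discovery_ids: list
    replication_ids: list
    seed: int


def split_cohorts(sample_ids, fraction: float = 2.0 / 3.0, seed: int = 0) -> CohortSplit:
    """Uniformly random split with discovery size floor(fraction * N)."""
    ids = list(sample_ids)
    if len(set(ids)) != len(ids):
        raise PhenotypeError("sample ids must be unique")
    n = len(ids)
    if n < 2:
        raise PhenotypeError("need at least 2 samples to split")
    n_disc = math.floor(fraction * n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return CohortSplit(
        discovery_ids=[ids[i] for i in sorted(perm[:n_disc])],
        replication_ids=[ids[i] for i in sorted(perm[n_disc:])],
        seed=seed,
    )


def clean_phenotypes(
    pheno: pd.DataFrame,
    confounds: pd.DataFrame | None = None,
    split_seed: int = 0,
    max_missing: int = 50,
    n_mads: float = 6.0,
    fraction: float = 2.0 / 3.0,
    on_degenerate: str = "mask",
) -> tuple[CleanPhenotypes, CleanPhenotypes, CohortSplit]:
    """Full cleaning chain; returns (discovery, replication, split).

    Outlier masking and sparse-subject dropping happen on the pooled
    matrix; quantile normalization and confound residualization are fit
    per cohort.
    """
    masked = pheno.copy()
    n_outliers = 0
    for col in masked.columns:
        before = masked[col].notna().sum()
        masked[col] = mask_outliers_mad(masked[col].to_numpy(), n_mads=n_mads)
        n_outliers += before - masked[col].notna().sum()
    kept = drop_sparse_subjects(masked, max_missing=max_missing)
    n_dropped = len(masked) - len(kept)
    split = split_cohorts(kept.index, fraction=fraction, seed=split_seed)

    def _per_cohort(ids) -> CleanPhenotypes:
        sub = kept.loc[ids].copy()
        for col in sub.columns:
            sub[col] = quantile_normalize(sub[col].to_numpy())
        conf = confounds.loc[ids] if confounds is not None else None
        cleaned = residualize(sub, conf, on_degenerate=on_degenerate)
        cleaned.provenance.update(
            masked_outliers=int(n_outliers), dropped_subjects=int(n_dropped)
        )
        return cleaned

    return _per_cohort(split.discovery_ids), _per_cohort(split.replication_ids), split
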