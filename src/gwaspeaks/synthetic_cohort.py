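"""Synthetic cohort generator: LD-blocked genotypes with correct X
ploidy, a constant-rate genetic map, confounds, and many phenotypes
with planted sparse effects.

Genotypes come from a Gaussian copula: each allele's latent normal
mixes a per-(sample, LD-block) factor with independent noise, then is
thresholded at the allele frequency quantile, so Hardy-Weinberg holds
marginally while alleles within a block are correlated.  Females are
diploid everywhere; males are haploid on non-PAR X (raw dosage in
[0, 1]) and diploid on PARs and autosomes.  Optional shrink-to-mean
dosage noise lowers the INFO score below 1; the genetic map has a
constant cM/Mb rate so cover distances are exactly controllable.

Phenotypes are a sparse linear genetic signal plus confound loadings
plus unit-normal noise, with configurable missingness and injected
gross outliers.  The planted truth is returned for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_scan import encoded_dosage_matrix
from .io_formats import FEMALE, MALE, DosageSet
from .variants import GRCH37_PAR, GeneticMap, ParIntervals, make_variant_key


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a desk-scale stand-in for a biobank imaging-GWAS
    cohort: 4,000 samples split evenly by sex, three chromosomes (two
    autosomes and X) of LD-blocked common variants, 20 phenotypes with
    3 planted causal variants each and per-allele effects of 0.15-0.3
    phenotype SDs, shared confounds, 1% missingness and mild dosage
    uncertainty.
    """

    n_female: int = 2000
    n_male: int = 2000
    variants_per_chromosome: dict[str, int] = field(
        default_factory=lambda: {"1": 150, "2": 150, "X": 150}
    )
    ld_block_size: int = 10
    within_block_r: float = 0.8
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_phenotypes: int = 20
    n_causal: int = 3
    effect_size_range: tuple[float, float] = (0.15, 0.3)
    n_confounds: int = 2
    confound_sd: float = 0.5
    missing_rate: float = 0.01
    pheno_missing_rate: float = 0.01
    outlier_rate: float = 0.002
    dosage_noise: float = 0.05
    dc_multiplier: float = 1.0  # male non-PAR X effect scaling; 1.0 = full XCI
    sex_effect_multiplier: float = 1.0  # global male genetic-effect multiplier
    bp_spacing: int = 20_000
    x_par_fraction: float = 0.1
    cm_per_mb: float = 1.0
    standardize_phenotypes: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("missing_rate", "pheno_missing_rate", "outlier_rate",
                     "dosage_noise", "within_block_r", "x_par_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise SimulationError(f"maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.seed is None:
            raise SimulationError("seed is mandatory")


@dataclass
class SimTruth:
    """Planted ground truth: causal (phenotype, variant, beta) plus loadings."""

    effects: list[tuple[str, str, float]]  # (phenotype_id, variant_id, true beta)
    confound_loadings: dict[str, list[float]]
    dc_multiplier: float
    sex_effect_multiplier: float

    def causal_variants(self, phenotype_id: str | None = None) -> list[str]:
        return sorted(
            {v for p, v, _ in self.effects if phenotype_id in (None, p)}
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _sample_alleles(
    rng: np.random.Generator,
    freqs: np.ndarray,
    n_samples: int,
    n_hap: np.ndarray,
    block_ids: np.ndarray,
    r: float,
) -> np.ndarray:
    """Genotype counts with blockwise latent correlation r.

    ``n_hap`` is the per-sample haplotype count (1 or 2).  Each
    haplotype h of sample s draws latents z_jv = sqrt(r) u_{s,h,block} +
    sqrt(1-r) e; allele = 1 where z < Phi^-1(freq_v).
    """
    n_variants = freqs.size
    thresh = stats.norm.ppf(freqs)
    blocks = np.unique(block_ids)
    geno = np.zeros((n_variants, n_samples))
    max_hap = int(n_hap.max())
    for h in range(max_hap):
        has = n_hap > h
        u = rng.standard_normal((blocks.size, n_samples))
        e = rng.standard_normal((n_variants, n_samples))
        z = np.sqrt(r) * u[np.searchsorted(blocks, block_ids)] + np.sqrt(1.0 - r) * e
        geno += (z < thresh[:, None]) & has[None, :]
    return geno


def simulate_genotypes(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    par: ParIntervals = GRCH37_PAR,
) -> tuple[DosageSet, GeneticMap]:
    """Draw the cohort's dosages and the matching constant-rate genetic map."""
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_female + config.n_male
    sample_ids = np.array([f"S{i:06d}" for i in range(n)], dtype=object)
    sex = np.array([FEMALE] * config.n_female + [MALE] * config.n_male, dtype=object)
    female = sex == FEMALE

    variants = []
    rows = []
    gmap = GeneticMap()
    for chrom, n_var in config.variants_per_chromosome.items():
        if chrom == "X":
            n_par = int(round(config.x_par_fraction * n_var))
            par_bps = [par.par1[0] + 100 + i * config.bp_spacing for i in range(n_par)]
            if par_bps and par_bps[-1] > par.par1[1]:
                raise SimulationError("PAR1 too small for requested PAR variants")
            nonpar_start = 10_000_000
            bps = par_bps + [
                nonpar_start + i * config.bp_spacing for i in range(n_var - n_par)
            ]
        else:
            bps = [1_000_000 + i * config.bp_spacing for i in range(n_var)]
        bps = np.asarray(sorted(bps))
        freqs = rng.uniform(*config.maf_range, size=n_var)
        block_ids = np.arange(n_var) // max(1, config.ld_block_size)
        keys = [
            make_variant_key(f"sim{chrom}_{i}", chrom, int(bps[i]), "A", "G", par=par)
            for i in range(n_var)
        ]
        haploid_male = np.array([k.region == "X_nonPAR" for k in keys])
        n_hap_diploid = np.full(n, 2)
        geno = np.empty((n_var, n))
        # diploid variants in one pass; haploid-male (non-PAR X) separately
        if (~haploid_male).any():
            geno[~haploid_male] = _sample_alleles(
                rng, freqs[~haploid_male], n, n_hap_diploid,
                block_ids[~haploid_male], config.within_block_r,
            )
        if haploid_male.any():
            n_hap = np.where(female, 2, 1)
            geno[haploid_male] = _sample_alleles(
                rng, freqs[haploid_male], n, n_hap,
                block_ids[haploid_male], config.within_block_r,
            )
        # shrink-to-mean dosage uncertainty: INFO ~ (1 - noise)^2
        if config.dosage_noise > 0:
            mean = np.where(
                haploid_male[:, None] & ~female[None, :],
                freqs[:, None],
                2.0 * freqs[:, None],
            )
            geno = (1.0 - config.dosage_noise) * geno + config.dosage_noise * mean
        if config.missing_rate > 0:
            geno[rng.random(geno.shape) < config.missing_rate] = np.nan
        variants.extend(keys)
        rows.append(geno)
        lo, hi = int(bps[0]) - config.bp_spacing, int(bps[-1]) + config.bp_spacing
        gmap.add_chromosome(
            chrom,
            np.array([lo, hi], dtype=float),
            np.array([lo, hi], dtype=float) * config.cm_per_mb / 1e6,
        )
    dosages = DosageSet(
        variants=variants,
        sample_ids=sample_ids,
        sex=sex,
        dosages=np.vstack(rows),
    )
    return dosages, gmap


def simulate_phenotypes(
    dosages: DosageSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    truth_spec: list[tuple[str, str, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Phenotype and confound matrices plus the planted truth.

    Each phenotype is a sum of planted per-allele effects on encoded
    dosages (male non-PAR X values additionally scaled by the
    dosage-compensation multiplier), confound loadings, and unit-normal
    noise; optionally standardized.  ``truth_spec`` fixes the causal
    structure explicitly; otherwise ``n_causal`` variants per phenotype
    are drawn with effects uniform in ``effect_size_range`` and random
    sign.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n = dosages.n_samples
    by_id = {k.variant_id: i for i, k in enumerate(dosages.variants)}
    pheno_ids = [f"P{j:04d}" for j in range(config.n_phenotypes)]

    if truth_spec is None:
        lo, hi = config.effect_size_range
        truth_spec = []
        for pid in pheno_ids:
            chosen = rng.choice(len(dosages.variants), size=config.n_causal, replace=False)
            for ci in chosen:
                beta = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
                truth_spec.append((pid, dosages.variants[ci].variant_id, float(beta)))
    else:
        for pid, vid, _ in truth_spec:
            if vid not in by_id:
                raise SimulationError(f"truth references unknown variant {vid}")
        pheno_ids = sorted({pid for pid, _, _ in truth_spec}) or pheno_ids

    G = encoded_dosage_matrix(dosages)
    G_imputed = np.where(np.isfinite(G), G, np.nanmean(G, axis=1, keepdims=True))
    male = ~dosages.is_female()

    confounds = rng.standard_normal((n, config.n_confounds))
    conf_df = pd.DataFrame(
        confounds,
        index=list(dosages.sample_ids),
        columns=[f"C{j}" for j in range(config.n_confounds)],
    )
    loadings = {
        pid: list(rng.normal(0.0, config.confound_sd, size=config.n_confounds))
        for pid in pheno_ids
    }

    effects_by_pheno: dict[str, list[tuple[str, float]]] = {pid: [] for pid in pheno_ids}
    for pid, vid, beta in truth_spec:
        effects_by_pheno[pid].append((vid, beta))

    Y = np.empty((n, len(pheno_ids)))
    for j, pid in enumerate(pheno_ids):
        genetic = np.zeros(n)
        for vid, beta in effects_by_pheno[pid]:
            i = by_id[vid]
            g = G_imputed[i].copy()
            mult = np.ones(n)
            if dosages.variants[i].region == "X_nonPAR":
                mult[male] = config.dc_multiplier
            mult[male] *= config.sex_effect_multiplier
            genetic += beta * g * mult
        y = genetic + confounds @ np.asarray(loadings[pid]) + rng.standard_normal(n)
        if config.standardize_phenotypes:
            y = (y - y.mean()) / y.std(ddof=0)
        Y[:, j] = y

    if config.outlier_rate > 0:
        hit = rng.random(Y.shape) < config.outlier_rate
        Y = np.where(hit, Y + np.sign(Y + 1e-12) * 10.0, Y)
    if config.pheno_missing_rate > 0:
        Y[rng.random(Y.shape) < config.pheno_missing_rate] = np.nan

    pheno_df = pd.DataFrame(Y, index=list(dosages.sample_ids), columns=pheno_ids)
    truth = SimTruth(
        effects=list(truth_spec),
        confound_loadings=loadings,
        dc_multiplier=config.dc_multiplier,
        sex_effect_multiplier=config.sex_effect_multiplier,
    )
    return pheno_df, conf_df, truth


def simulate_cohort(
    config: SimConfig,
) -> tuple[DosageSet, GeneticMap, pd.DataFrame, pd.DataFrame, SimTruth]:
    """One call for the full fixture: genotypes, map, phenotypes, confounds, truth."""
    rng = np.random.default_rng(config.seed)
    dosages, gmap = simulate_genotypes(config, rng)
    pheno, conf, truth = simulate_phenotypes(dosages, config, rng)
    return dosages, gmap, pheno, conf, truth
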