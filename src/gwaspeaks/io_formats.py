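"""Readers and writers for on-disk artifacts.

Formats are all plain text: summary-statistics TSV (one file per
phenotype; column names mapped through a configurable dialect so the
header conventions of public GWAS servers load unedited), dosage sets (VCF with a per-sample DS
field, read through cyvcf2, or a plain TSV matrix), phenotype/confound
matrices (TSV, first column sample id), sample-sex tables, peak and
cluster reports.

p-values are carried as -log10 p throughout so associations beyond
double-precision underflow (p < 1e-308) survive round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import (
    GRCH37_PAR,
    ParIntervals,
    VariantKey,
    make_variant_key,
)


class SumStatsFormatError(ValueError):
    """Structural problem in a summary-statistics file (bad header/row)."""


class ReconciliationError(ValueError):
    """Sample ids disagree between paired input files."""


@dataclass(frozen=True)
class SumStatsRecord:
    """One variant's association result for one phenotype.

    ``beta`` is the effect per alternate-allele copy in phenotype SD
    units (sign follows the alternate allele); ``neglog10p`` is the
    -log10 two-sided p.
    """

    key: VariantKey
    beta: float
    se: float
    neglog10p: float
    n: int

    def __post_init__(self):
        if self.se < 0:
            raise ValueError(f"{self.key.variant_id}: se < 0")
        if self.neglog10p < 0:
            raise ValueError(f"{self.key.variant_id}: neglog10p < 0")
        if self.n < 1:
            raise ValueError(f"{self.key.variant_id}: n < 1")


#: canonical column -> accepted header names (lower-cased), first wins
DEFAULT_SUMSTATS_SYNONYMS: dict[str, tuple[str, ...]] = {
    "variant_id": ("variant_id", "rsid", "snp", "id"),
    "chromosome": ("chromosome", "chr", "chrom"),
    "bp": ("bp", "pos", "position", "pos(b37)"),
    "ref_allele": ("ref_allele", "a1", "ref", "allele1"),
    "alt_allele": ("alt_allele", "a2", "alt", "allele2"),
    "beta": ("beta", "effect"),
    "se": ("se", "stderr", "standard_error"),
    "neglog10p": ("neglog10p", "pval(-log10)", "minus_log10_p", "log10p", "mlog10p"),
    "n": ("n", "n_samples", "nsamples"),
}

_CANONICAL_ORDER = [
    "variant_id", "chromosome", "bp", "ref_allele", "alt_allele",
    "beta", "se", "neglog10p", "n",
]

_REQUIRED = [c for c in _CANONICAL_ORDER if c != "n"]


@dataclass
class SumStatsDialect:
    """Column mapping for summary-statistics files.

    ``overrides`` maps canonical names to the actual header in the file;
    anything not overridden is resolved through the synonym table.
    ``default_n`` fills the sample count when the file has no n column.
    """

    overrides: dict[str, str] = field(default_factory=dict)
    default_n: int | None = None

    def resolve(self, columns: list[str], path) -> dict[str, str]:
        lowered = {c.lower(): c for c in columns}
        mapping: dict[str, str] = {}
        for canon, synonyms in DEFAULT_SUMSTATS_SYNONYMS.items():
            if canon in self.overrides:
                actual = self.overrides[canon]
                if actual not in columns:
                    raise SumStatsFormatError(
                        f"{path}: dialect maps {canon!r} to missing column {actual!r}"
                    )
                mapping[canon] = actual
                continue
            for cand in synonyms:
                if cand in lowered:
                    mapping[canon] = lowered[cand]
                    break
        missing = [c for c in _REQUIRED if c not in mapping]
        if missing:
            raise SumStatsFormatError(f"{path}: missing mandatory column(s) {missing}")
        return mapping


def _clean_number(raw: object) -> float:
    # tolerate the unicode minus that typeset tables carry
    return float(str(raw).replace("−", "-").replace(",", ""))


def read_sumstats(
    path,
    dialect: SumStatsDialect | None = None,
    par: ParIntervals = GRCH37_PAR,
) -> list[SumStatsRecord]:
    """Read one phenotype's summary statistics, in file order.

    Malformed rows raise with their 1-based line number; chromosome
    aliases ("23", "XY", "chrX") normalise to X with the PAR region
    resolved from position.
    """
    dialect = dialect or SumStatsDialect()
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping = dialect.resolve(list(df.columns), path)
    records: list[SumStatsRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        r = dict(zip(df.columns, row))
        try:
            key = make_variant_key(
                r[mapping["variant_id"]],
                r[mapping["chromosome"]],
                int(_clean_number(r[mapping["bp"]])),
                r[mapping["ref_allele"]],
                r[mapping["alt_allele"]],
                par=par,
            )
            if "n" in mapping:
                n = int(_clean_number(r[mapping["n"]]))
            elif dialect.default_n is not None:
                n = dialect.default_n
            else:
                n = 1
            rec = SumStatsRecord(
                key=key,
                beta=_clean_number(r[mapping["beta"]]),
                se=_clean_number(r[mapping["se"]]),
                neglog10p=_clean_number(r[mapping["neglog10p"]]),
                n=n,
            )
        except (ValueError, TypeError) as exc:
            raise SumStatsFormatError(f"{path}: line {line_no}: {exc}") from exc
        records.append(rec)
    return records


def sumstats_to_frame(records: list[SumStatsRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [r.key.variant_id for r in records],
            "chromosome": [r.key.chromosome for r in records],
            "bp": [r.key.bp for r in records],
            "ref_allele": [r.key.ref_allele for r in records],
            "alt_allele": [r.key.alt_allele for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "neglog10p": [r.neglog10p for r in records],
            "n": [r.n for r in records],
        }
    )


def frame_to_sumstats(df: pd.DataFrame, par: ParIntervals = GRCH37_PAR) -> list[SumStatsRecord]:
    return [
        SumStatsRecord(
            key=make_variant_key(
                r.variant_id, r.chromosome, r.bp, r.ref_allele, r.alt_allele, par=par
            ),
            beta=float(r.beta),
            se=float(r.se),
            neglog10p=float(r.neglog10p),
            n=int(r.n),
        )
        for r in df.itertuples(index=False)
    ]


def write_sumstats(records: list[SumStatsRecord], path) -> None:
    sumstats_to_frame(records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# dosage sets

FEMALE = "female"
MALE = "male"
_SEX_ALIASES = {"f": FEMALE, "female": FEMALE, "2": FEMALE,
                "m": MALE, "male": MALE, "1": MALE}


def normalize_sex(label: object) -> str:
    try:
        return _SEX_ALIASES[str(label).strip().lower()]
    except KeyError:
        raise ValueError(f"unrecognised sex label {label!r}") from None


@dataclass
class DosageSet:
    """Per-variant dosage vectors for a sexed cohort.

    ``dosages`` is (n_variants, n_samples) with NaN for missing calls.
    Autosomal/PAR dosages live in [0, 2]; non-PAR male calls are raw
    haploid dosages in [0, 1] (encode with
    :func:`gwaspeaks.assoc_scan.encode_x_dosage` before association).
    """

    variants: list[VariantKey]
    sample_ids: np.ndarray
    sex: np.ndarray  # "female"/"male" per sample
    dosages: np.ndarray

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.sex = np.asarray([normalize_sex(s) for s in self.sex], dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.variants), len(self.sample_ids)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} != "
                f"({len(self.variants)}, {len(self.sample_ids)})"
            )
        if len(self.sex) != len(self.sample_ids):
            raise ValueError("sex must be defined for every sample")
        self._validate_ranges()

    def _validate_ranges(self):
        female = self.sex == FEMALE
        for i, key in enumerate(self.variants):
            row = self.dosages[i]
            obs = np.isfinite(row)
            if key.region == "X_nonPAR":
                hi = np.where(female, 2.0, 1.0)
            else:
                hi = np.full(row.shape, 2.0)
            bad = obs & ((row < 0) | (row > hi + 1e-9))
            if bad.any():
                j = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"{key.variant_id}: dosage {row[j]:g} outside ploidy range "
                    f"for {self.sex[j]} sample {self.sample_ids[j]}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def is_female(self) -> np.ndarray:
        return self.sex == FEMALE

    def subset_samples(self, sample_ids) -> "DosageSet":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ReconciliationError(
                f"samples absent from dosage set: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        idx = np.array([index[s] for s in sample_ids], dtype=int)
        return DosageSet(
            variants=self.variants,
            sample_ids=self.sample_ids[idx],
            sex=self.sex[idx],
            dosages=self.dosages[:, idx],
        )


def read_sex_table(path) -> pd.Series:
    """sample_id -> female/male from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    if "sample_id" not in df.columns or "sex" not in df.columns:
        raise SumStatsFormatError(f"{path}: need sample_id and sex columns")
    return pd.Series(
        [normalize_sex(s) for s in df["sex"]], index=df["sample_id"].to_numpy(), name="sex"
    )


def write_sex_table(sample_ids, sex, path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "sex": sex}).to_csv(path, sep="\t", index=False)


def read_dosages(path, format: str, sex: pd.Series, par: ParIntervals = GRCH37_PAR) -> DosageSet:
    """Load a dosage set from ``vcf_ds`` (per-sample DS field) or ``tsv``."""
    if format == "vcf_ds":
        return _read_dosages_vcf(path, sex, par)
    if format == "tsv":
        return _read_dosages_tsv(path, sex, par)
    raise ValueError(f"unknown dosage format {format!r}")


def _sex_for(sample_ids, sex: pd.Series, path) -> np.ndarray:
    missing = [s for s in sample_ids if s not in sex.index]
    if missing:
        raise ReconciliationError(f"{path}: samples without sex assignment: {missing[:10]}")
    return sex.loc[list(sample_ids)].to_numpy()


def _read_dosages_vcf(path, sex: pd.Series, par: ParIntervals) -> DosageSet:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = np.asarray(vcf.samples, dtype=object)
    variants: list[VariantKey] = []
    rows = []
    for rec in vcf:
        ds = rec.format("DS")
        if ds is None:
            raise SumStatsFormatError(
                f"{path}: record {rec.ID or rec.POS} lacks a DS format field"
            )
        vec = np.asarray(ds, dtype=float).reshape(-1)[: len(sample_ids)].copy()
        vec[vec < 0] = np.nan  # cyvcf2 encodes missing as negative sentinel
        alt = rec.ALT[0] if rec.ALT else "."
        variants.append(
            make_variant_key(rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM, rec.POS,
                             rec.REF, alt, par=par)
        )
        rows.append(vec)
    return DosageSet(
        variants=variants,
        sample_ids=sample_ids,
        sex=_sex_for(sample_ids, sex, path),
        dosages=np.asarray(rows, dtype=float).reshape(len(variants), len(sample_ids)),
    )


_DOSAGE_META = ["variant_id", "chromosome", "bp", "ref_allele", "alt_allele"]


def _read_dosages_tsv(path, sex: pd.Series, par: ParIntervals) -> DosageSet:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _DOSAGE_META if c not in df.columns]
    if missing:
        raise SumStatsFormatError(f"{path}: missing column(s) {missing}")
    sample_ids = np.asarray([c for c in df.columns if c not in _DOSAGE_META], dtype=object)
    variants = [
        make_variant_key(r.variant_id, r.chromosome, r.bp, r.ref_allele, r.alt_allele, par=par)
        for r in df[_DOSAGE_META].itertuples(index=False)
    ]
    return DosageSet(
        variants=variants,
        sample_ids=sample_ids,
        sex=_sex_for(sample_ids, sex, path),
        dosages=df[list(sample_ids)].to_numpy(dtype=float),
    )


def write_dosages_tsv(ds: DosageSet, path) -> None:
    meta = pd.DataFrame(
        {
            "variant_id": [k.variant_id for k in ds.variants],
            "chromosome": [k.chromosome for k in ds.variants],
            "bp": [k.bp for k in ds.variants],
            "ref_allele": [k.ref_allele for k in ds.variants],
            "alt_allele": [k.alt_allele for k in ds.variants],
        }
    )
    body = pd.DataFrame(ds.dosages, columns=list(ds.sample_ids))
    pd.concat([meta, body], axis=1).to_csv(path, sep="\t", index=False)


def write_dosages_vcf(ds: DosageSet, path) -> None:
    """Minimal VCFv4.2 emission with a DS FORMAT field (text output only)."""
    order = sorted(range(len(ds.variants)),
                   key=lambda i: (ds.variants[i].chromosome, ds.variants[i].bp))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for chrom in dict.fromkeys(ds.variants[i].chromosome for i in order):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in ds.sample_ids) + "\n")
        for i in order:
            k = ds.variants[i]
            vals = ["." if not np.isfinite(d) else f"{d:.6g}" for d in ds.dosages[i]]
            fh.write(
                f"{k.chromosome}\t{k.bp}\t{k.variant_id}\t{k.ref_allele}\t{k.alt_allele}"
                f"\t.\t.\t.\tDS\t" + "\t".join(vals) + "\n"
            )


# ---------------------------------------------------------------------------
# phenotype / confound matrices


def read_phenotypes(path) -> pd.DataFrame:
    """Samples x phenotypes TSV, first column the sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ReconciliationError(f"{path}: duplicate sample ids {dups[:10]}")
    if df.columns.has_duplicates:
        raise ReconciliationError(f"{path}: duplicate phenotype ids")
    df.index = df.index.astype(str)
    return df.astype(float)


read_confounds = read_phenotypes


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def reconcile_samples(dosage_ids, pheno_ids) -> list[str]:
    """Shared sample ids; raises listing offenders when either side is empty-handed."""
    dset, pset = set(dosage_ids), set(pheno_ids)
    shared = [s for s in pheno_ids if s in dset]
    if not shared:
        raise ReconciliationError(
            f"no shared samples; dosage-only {sorted(dset - pset)[:5]}, "
            f"phenotype-only {sorted(pset - dset)[:5]}"
        )
    return shared


# ---------------------------------------------------------------------------
# peak / cluster reports (columns mirror the lead-association tables:
# cluster #, lead rsid, phenotype, position, alleles, -log10 P, N_SNPs)

_PEAK_COLS = [
    "phenotype_id", "variant_id", "chromosome", "bp", "ref_allele", "alt_allele",
    "cM", "neglog10p", "beta", "se",
]


def write_peaks(peaks, path) -> None:
    from .peaks_clustering import Peak  # local import to avoid a cycle

    rows = [
        (
            p.phenotype_id, p.key.variant_id, p.key.chromosome, p.key.bp,
            p.key.ref_allele, p.key.alt_allele, p.cM, p.neglog10p, p.beta, p.se,
        )
        for p in peaks
    ]
    pd.DataFrame(rows, columns=_PEAK_COLS).to_csv(path, sep="\t", index=False)


def read_peaks(path, par: ParIntervals = GRCH37_PAR):
    from .peaks_clustering import Peak

    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "phenotype_id": str})
    return [
        Peak(
            phenotype_id=r.phenotype_id,
            key=make_variant_key(r.variant_id, r.chromosome, r.bp,
                                 r.ref_allele, r.alt_allele, par=par),
            cM=float(r.cM),
            neglog10p=float(r.neglog10p),
            beta=float(r.beta),
            se=float(r.se),
        )
        for r in df.itertuples(index=False)
    ]


_CLUSTER_COLS = ["cluster", "role", "n_snps", "replicated", "bonferroni"] + _PEAK_COLS


def write_cluster_report(clusters, path) -> None:
    rows = []
    for c in clusters:
        for p in c.members:
            role = "lead" if p is c.lead else "member"
            rows.append(
                (
                    c.cluster_id, role, len(c.members), c.replicated, c.bonferroni,
                    p.phenotype_id, p.key.variant_id, p.key.chromosome, p.key.bp,
                    p.key.ref_allele, p.key.alt_allele, p.cM, p.neglog10p, p.beta, p.se,
                )
            )
    pd.DataFrame(rows, columns=_CLUSTER_COLS).to_csv(path, sep="\t", index=False)


def read_cluster_report(path, par: ParIntervals = GRCH37_PAR):
    from .peaks_clustering import Cluster, Peak

    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "phenotype_id": str})
    clusters = []
    for cid, sub in df.groupby("cluster", sort=False):
        members, lead = [], None
        for r in sub.itertuples(index=False):
            p = Peak(
                phenotype_id=r.phenotype_id,
                key=make_variant_key(r.variant_id, r.chromosome, r.bp,
                                     r.ref_allele, r.alt_allele, par=par),
                cM=float(r.cM),
                neglog10p=float(r.neglog10p),
                beta=float(r.beta),
                se=float(r.se),
            )
            members.append(p)
            if r.role == "lead":
                lead = p
        first = sub.iloc[0]
        clusters.append(
            Cluster(
                cluster_id=int(cid),
                lead=lead,
                members=members,
                replicated=bool(first.replicated),
                bonferroni=bool(first.bonferroni),
            )
        )
    return clusters
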