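"""End-to-end orchestration: simulate -> prep -> qc -> gwas -> peaks ->
cluster -> meta -> report, driven by a YAML run configuration.

Every stage writes plain TSV/JSON artifacts; reruns with the same
configuration and seeds are byte-identical.  The provenance report
echoes every threshold that affects output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import assoc_scan, io_formats, peaks_clustering, pheno_prep, variant_qc
from .io_formats import DosageSet, write_cluster_report, write_peaks, write_sumstats
from .synthetic_cohort import SimConfig, simulate_cohort
from .variants import GeneticMap, read_genetic_map, write_genetic_map

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, outputs and thresholds for one pipeline run."""

    out_dir: str = "run_out"
    # either simulate...
    simulate: bool = True
    sim: dict = field(default_factory=dict)
    # ...or point at files
    dosages_path: str | None = None
    dosages_format: str = "tsv"
    sex_path: str | None = None
    phenotypes_path: str | None = None
    confounds_path: str | None = None
    genetic_map_path: str | None = None

    split_seed: int = 0
    max_missing: int = 50
    qc_maf_min: float = 0.001
    qc_info_min: float = 0.3
    qc_hwe_max: float = 7.0
    hit_maf_min: float = 0.01
    genomewide_threshold: float = 7.5
    cover_cM: float = 0.25
    replication_alpha: float = 0.05
    run_meta: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown field(s) {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate:
            for name in ("dosages_path", "sex_path", "phenotypes_path",
                         "genetic_map_path"):
                p = getattr(self, name)
                if p is None:
                    raise PipelineError("config", f"missing required field {name}")
                if not Path(p).exists():
                    raise PipelineError("config", f"{name}: no such file {p}")


def export_manhattan_table(
    records: list[io_formats.SumStatsRecord],
    gmap: GeneticMap,
    peaks: list[peaks_clustering.Peak],
    clusters: list[peaks_clustering.Cluster] | None = None,
    phenotype_id: str | None = None,
) -> pd.DataFrame:
    """Per-variant Manhattan data: (chromosome, bp, cM, -log10 p, is_peak, cluster_id).

    One row per (already MAF-filtered) record; rows matching a peak of
    this phenotype are flagged and carry the peak's cluster id when a
    clustering is supplied.
    """
    peak_ids = {
        (p.phenotype_id, p.key.variant_id) for p in peaks
    }
    cluster_of: dict[tuple[str, str], int] = {}
    for c in clusters or []:
        for m in c.members:
            cluster_of[(m.phenotype_id, m.key.variant_id)] = c.cluster_id
    rows = []
    for r in records:
        tag = (phenotype_id, r.key.variant_id)
        is_peak = tag in peak_ids
        rows.append(
            (
                r.key.chromosome,
                r.key.bp,
                float(gmap.interpolate(r.key.chromosome, r.key.bp)),
                r.neglog10p,
                is_peak,
                cluster_of.get(tag, pd.NA) if is_peak else pd.NA,
            )
        )
    return pd.DataFrame(
        rows, columns=["chromosome", "bp", "cM", "neglog10p", "is_peak", "cluster_id"]
    )


@dataclass
class PipelineResult:
    clusters: list
    peaks: list
    n_phenotypes: int
    provenance: dict
    truth: object | None = None
    gmap: GeneticMap | None = None
    variants: list | None = None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages in order; artifacts land under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {
        "thresholds": {
            "split_seed": config.split_seed,
            "max_missing": config.max_missing,
            "qc_maf_min": config.qc_maf_min,
            "qc_info_min": config.qc_info_min,
            "qc_hwe_max": config.qc_hwe_max,
            "hit_maf_min": config.hit_maf_min,
            "genomewide_threshold": config.genomewide_threshold,
            "cover_cM": config.cover_cM,
            "replication_alpha": config.replication_alpha,
        },
        "stages": {},
    }

    truth = None
    try:
        if config.simulate:
            sim_cfg = SimConfig(**config.sim)
            dosages, gmap, pheno, confounds, truth = simulate_cohort(sim_cfg)
            truth.to_json(out / "truth.json")
            write_genetic_map(gmap, out / "map.tsv")
            io_formats.write_sex_table(dosages.sample_ids, dosages.sex, out / "sex.tsv")
            provenance["thresholds"]["sim_seed"] = sim_cfg.seed
        else:
            sex = io_formats.read_sex_table(config.sex_path)
            dosages = io_formats.read_dosages(
                config.dosages_path, config.dosages_format, sex
            )
            pheno = io_formats.read_phenotypes(config.phenotypes_path)
            confounds = (
                io_formats.read_confounds(config.confounds_path)
                if config.confounds_path
                else None
            )
            gmap = read_genetic_map(config.genetic_map_path)
            shared = io_formats.reconcile_samples(dosages.sample_ids, pheno.index)
            dosages = dosages.subset_samples(shared)
            pheno = pheno.loc[shared]
            if confounds is not None:
                confounds = confounds.loc[shared]
        all_variants = list(dosages.variants)
        provenance["stages"]["input"] = {
            "n_samples": int(dosages.n_samples),
            "n_variants": len(dosages.variants),
            "n_phenotypes": int(pheno.shape[1]),
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc

    # sex joins the confound model, as in any pooled-sex scan
    try:
        sex_col = pd.Series(
            (dosages.sex == io_formats.MALE).astype(float), index=list(dosages.sample_ids)
        )
        if confounds is None:
            confounds = pd.DataFrame({"sex": sex_col})
        else:
            confounds = confounds.copy()
            confounds["sex"] = sex_col
        disc, repl, split = pheno_prep.clean_phenotypes(
            pheno,
            confounds,
            split_seed=config.split_seed,
            max_missing=config.max_missing,
        )
        pd.Series(split.discovery_ids).to_csv(
            out / "discovery.ids", index=False, header=False
        )
        pd.Series(split.replication_ids).to_csv(
            out / "replication.ids", index=False, header=False
        )
        provenance["stages"]["prep"] = {
            "n_discovery": len(split.discovery_ids),
            "n_replication": len(split.replication_ids),
            **disc.provenance,
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("prep", str(exc)) from exc

    try:
        disc_dosages = dosages.subset_samples(split.discovery_ids)
        metrics = variant_qc.compute_metrics(disc_dosages)
        thresholds = variant_qc.QCThresholds(
            maf_min=config.qc_maf_min,
            info_min=config.qc_info_min,
            hwe_max=config.qc_hwe_max,
        )
        surviving, tallies = variant_qc.apply_filters(metrics, thresholds)
        keep = {k.variant_id for k in surviving}
        maf_table = {m.key.variant_id: m.maf for m in metrics}
        keep_idx = [i for i, k in enumerate(dosages.variants) if k.variant_id in keep]
        dosages = DosageSet(
            variants=[dosages.variants[i] for i in keep_idx],
            sample_ids=dosages.sample_ids,
            sex=dosages.sex,
            dosages=dosages.dosages[keep_idx],
        )
        pd.DataFrame(
            {
                "variant_id": [m.key.variant_id for m in metrics],
                "maf": [m.maf for m in metrics],
                "info": [m.info for m in metrics],
                "hwe_neglog10p": [m.hwe_neglog10p for m in metrics],
                "pass": [m.key.variant_id in keep for m in metrics],
            }
        ).to_csv(out / "qc_metrics.tsv", sep="\t", index=False)
        provenance["stages"]["qc"] = tallies
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("qc", str(exc)) from exc

    try:
        thresholds_pc = peaks_clustering.Thresholds(
            genomewide=config.genomewide_threshold,
            cover_cM=config.cover_cM,
            n_phenotypes=pheno.shape[1],
        )
        sumstats_dir = out / "sumstats"
        sumstats_dir.mkdir(exist_ok=True)
        all_peaks: list[peaks_clustering.Peak] = []
        rep_nlp: dict[tuple[str, str], float] = {}
        for pid in disc.matrix.columns:
            results = assoc_scan.linear_scan(
                disc.matrix[pid], dosages, split.discovery_ids, phenotype_id=pid
            )
            records = assoc_scan.results_to_records(results)
            write_sumstats(records, sumstats_dir / f"{pid}.tsv")
            hits = assoc_scan.results_to_records(
                assoc_scan.hit_filter(results, maf_table, config.hit_maf_min)
            )
            all_peaks.extend(
                peaks_clustering.extract_peaks(hits, gmap, thresholds_pc, pid)
            )
        # replication re-test restricted to peak variants
        peak_vids = {p.key.variant_id for p in all_peaks}
        rep_idx = [i for i, k in enumerate(dosages.variants) if k.variant_id in peak_vids]
        if rep_idx:
            rep_dosages = DosageSet(
                variants=[dosages.variants[i] for i in rep_idx],
                sample_ids=dosages.sample_ids,
                sex=dosages.sex,
                dosages=dosages.dosages[rep_idx],
            )
            for pid in repl.matrix.columns:
                rep_results = assoc_scan.linear_scan(
                    repl.matrix[pid], rep_dosages, split.replication_ids, phenotype_id=pid
                )
                for r in rep_results:
                    if not r.monomorphic:
                        rep_nlp[(pid, r.key.variant_id)] = r.neglog10p
        write_peaks(all_peaks, out / "peaks.tsv")
        provenance["stages"]["gwas"] = {"n_peaks": len(all_peaks)}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("gwas", str(exc)) from exc

    try:
        clusters = peaks_clustering.cluster_peaks(all_peaks, thresholds_pc)
        peaks_clustering.annotate_bonferroni(clusters, thresholds_pc)
        peaks_clustering.tag_replication(
            clusters, rep_nlp, alpha=config.replication_alpha
        )
        write_cluster_report(clusters, out / "clusters.tsv")
        provenance["stages"]["cluster"] = {
            "n_clusters": len(clusters),
            "n_replicated": sum(c.replicated for c in clusters),
            "n_bonferroni": sum(c.bonferroni for c in clusters),
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("cluster", str(exc)) from exc

    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    return PipelineResult(
        clusters=clusters,
        peaks=all_peaks,
        n_phenotypes=int(pheno.shape[1]),
        provenance=provenance,
        truth=truth,
        gmap=gmap,
        variants=all_variants,
    )
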