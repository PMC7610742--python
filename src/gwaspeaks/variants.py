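"""Variant identity, X-chromosome regions and genetic-map coordinates.

Chromosome labels are normalised to ``"1".."22"`` and ``"X"``; the X
chromosome is subdivided into the two pseudoautosomal regions (PAR1/PAR2,
diploid in both sexes) and the non-pseudoautosomal region (haploid in
males).  PAR boundaries default to GRCh37/hg19 and are configurable.
Genetic maps give the bp -> centimorgan coordinate used for peak pruning
and cross-phenotype clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES = tuple(str(i) for i in range(1, 23))
CHROMOSOMES = AUTOSOMES + ("X",)

#: labels accepted as aliases for chromosome X ("23"/"25" are plink codes,
#: "XY" marks pseudoautosomal variants in some pipelines)
_X_ALIASES = {"x", "23", "25", "xy", "chrx"}

REGION_AUTOSOME = "autosome"
REGION_X_NONPAR = "X_nonPAR"
REGION_X_PAR1 = "X_PAR1"
REGION_X_PAR2 = "X_PAR2"

X_REGIONS = (REGION_X_NONPAR, REGION_X_PAR1, REGION_X_PAR2)


class ChromosomeError(ValueError):
    """Unrecognised or unsupported chromosome label."""


class GeneticMapError(ValueError):
    """Invalid genetic map or lookup on a chromosome absent from the map."""


def normalize_chromosome(label: object) -> str:
    """Map a chromosome label to the canonical ``1..22`` / ``X`` form."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.lower() in _X_ALIASES:
        return "X"
    if s in AUTOSOMES:
        return s
    raise ChromosomeError(f"unsupported chromosome label: {label!r}")


@dataclass(frozen=True)
class ParIntervals:
    """1-based inclusive PAR intervals on chromosome X (GRCh37 defaults)."""

    par1: tuple[int, int] = (60_001, 2_699_520)
    par2: tuple[int, int] = (154_931_044, 155_260_560)

    def region_of(self, chromosome: str, bp: int) -> str:
        chromosome = normalize_chromosome(chromosome)
        if chromosome != "X":
            return REGION_AUTOSOME
        if self.par1[0] <= bp <= self.par1[1]:
            return REGION_X_PAR1
        if self.par2[0] <= bp <= self.par2[1]:
            return REGION_X_PAR2
        return REGION_X_NONPAR


GRCH37_PAR = ParIntervals()


@dataclass(frozen=True)
class VariantKey:
    """Identity of one variant: id, normalised chromosome, position, alleles.

    ``region`` is a pure function of (chromosome, bp) given the PAR
    intervals; use :func:`make_variant_key` rather than the raw
    constructor so it is assigned consistently.
    """

    variant_id: str
    chromosome: str
    bp: int
    ref_allele: str
    alt_allele: str
    region: str

    @property
    def is_x(self) -> bool:
        return self.chromosome == "X"

    @property
    def diploid_everywhere(self) -> bool:
        """True where both sexes carry two copies (autosomes and PARs)."""
        return self.region != REGION_X_NONPAR


def make_variant_key(
    variant_id: str,
    chromosome: object,
    bp: int,
    ref_allele: str,
    alt_allele: str,
    par: ParIntervals = GRCH37_PAR,
) -> VariantKey:
    bp = int(bp)
    if bp < 1:
        raise ValueError(f"bp must be >= 1, got {bp} for {variant_id}")
    chromosome = normalize_chromosome(chromosome)
    return VariantKey(
        variant_id=str(variant_id),
        chromosome=chromosome,
        bp=bp,
        ref_allele=str(ref_allele).upper(),
        alt_allele=str(alt_allele).upper(),
        region=par.region_of(chromosome, bp),
    )


def chromosome_sort_key(chromosome: str) -> int:
    """Report ordering: X first, then autosomes ascending."""
    return 0 if chromosome == "X" else int(chromosome)


@dataclass
class GeneticMap:
    """Per-chromosome piecewise-linear bp -> cM interpolator.

    Anchors must have strictly increasing bp and non-decreasing cM, with
    at least two anchors per chromosome.  Queries outside the anchored
    range extrapolate along the boundary segment, floored at 0 cM.
    """

    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def add_chromosome(self, chromosome: object, bp: np.ndarray, cM: np.ndarray) -> None:
        chromosome = normalize_chromosome(chromosome)
        bp = np.asarray(bp, dtype=float)
        cM = np.asarray(cM, dtype=float)
        if bp.size < 2:
            raise GeneticMapError(
                f"chromosome {chromosome}: need >= 2 map anchors, got {bp.size}"
            )
        if not np.all(np.diff(bp) > 0):
            raise GeneticMapError(f"chromosome {chromosome}: bp anchors not strictly increasing")
        if not np.all(np.diff(cM) >= 0):
            raise GeneticMapError(f"chromosome {chromosome}: cM anchors decrease")
        self.anchors[chromosome] = (bp, cM)

    def chromosomes(self) -> list[str]:
        return sorted(self.anchors, key=chromosome_sort_key)

    def interpolate(self, chromosome: object, bp) -> np.ndarray | float:
        """cM coordinate(s) for position(s) on one chromosome."""
        chromosome = normalize_chromosome(chromosome)
        try:
            xs, ys = self.anchors[chromosome]
        except KeyError:
            raise GeneticMapError(f"chromosome {chromosome} absent from genetic map") from None
        q = np.asarray(bp, dtype=float)
        scalar = q.ndim == 0
        q = np.atleast_1d(q)
        out = np.interp(q, xs, ys)
        # extrapolate along the boundary segments, clipped at 0 cM
        lo = q < xs[0]
        if lo.any():
            slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
            out[lo] = ys[0] + slope * (q[lo] - xs[0])
        hi = q > xs[-1]
        if hi.any():
            slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            out[hi] = ys[-1] + slope * (q[hi] - xs[-1])
        out = np.maximum(out, 0.0)
        return float(out[0]) if scalar else out


def interpolate_cM(gmap: GeneticMap, key: VariantKey) -> float:
    """Genetic-map coordinate of one variant."""
    return float(gmap.interpolate(key.chromosome, key.bp))


_MAP_POSITION_COLS = ("position", "pos", "bp", "position(b37)")
_MAP_CM_COLS = ("cm", "genetic_map(cm)", "genetic_map", "map(cm)", "cm_pos")
_MAP_CHROM_COLS = ("chromosome", "chr", "chrom")


def _find_column(columns: list[str], wanted: tuple[str, ...], what: str, path) -> str:
    lowered = {c.lower(): c for c in columns}
    for cand in wanted:
        if cand in lowered:
            return lowered[cand]
    raise GeneticMapError(f"{path}: no {what} column among {list(columns)}")


def read_genetic_map(path, chromosome: object | None = None) -> GeneticMap:
    """Read a genetic map TSV (SHAPEIT/plink-style columns).

    Requires a position column and a cumulative-cM column; a rate column,
    if present, is ignored.  A chromosome column is required unless the
    file holds a single chromosome passed via ``chromosome=``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = list(df.columns)
    pos_col = _find_column(cols, _MAP_POSITION_COLS, "position", path)
    cm_col = _find_column(cols, _MAP_CM_COLS, "cM", path)
    gmap = GeneticMap()
    if chromosome is not None:
        gmap.add_chromosome(chromosome, df[pos_col].to_numpy(), df[cm_col].to_numpy())
        return gmap
    chrom_col = _find_column(cols, _MAP_CHROM_COLS, "chromosome", path)
    for chrom, sub in df.groupby(chrom_col, sort=False):
        gmap.add_chromosome(chrom, sub[pos_col].to_numpy(), sub[cm_col].to_numpy())
    return gmap


def write_genetic_map(gmap: GeneticMap, path) -> None:
    rows = []
    for chrom in gmap.chromosomes():
        bp, cm = gmap.anchors[chrom]
        for b, c in zip(bp, cm):
            rows.append((chrom, int(b), c))
    pd.DataFrame(rows, columns=["chromosome", "position", "cM"]).to_csv(
        path, sep="\t", index=False
    )
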