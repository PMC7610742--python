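"""Peak extraction and cross-phenotype greedy clustering in cM space.

A *peak* (hit) is a supra-threshold (phenotype, variant) association
surviving greedy within-phenotype pruning: repeatedly take the
strongest remaining supra-threshold record and discard everything
within 0.25 cM of it.  Peaks from all phenotypes are then aggregated
into *clusters* with the same greedy rule run per chromosome over a
binary max-heap keyed on -log10 p: extract the maximum pair as a new
cluster's lead, remove its 0.25 cM-cover from the heap and assign the
removed pairs to the cluster, until the heap is empty.  With a
linear-time heapify and O(log n) extraction/deletion the total work is
O(n log n) in the number of peaks.

Ties on -log10 p break toward the smaller (bp, phenotype_id), making
the output deterministic.  The 0.25 cM cover is inclusive: boundary
peaks join the cluster.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass

import numpy as np

from .io_formats import SumStatsRecord
from .variants import GeneticMap, VariantKey, chromosome_sort_key

logger = logging.getLogger(__name__)

GENOMEWIDE_NEGLOG10P = 7.5
COVER_CM = 0.25
REPLICATION_ALPHA = 0.05


def bonferroni_threshold(n_phenotypes: int) -> float:
    """GWAS threshold Bonferroni-corrected for the number of phenotypes.

    7.5 + log10(n), unrounded (display rounds to one decimal; for 3,935
    phenotypes this prints as 11.1).
    """
    if n_phenotypes < 1:
        raise ValueError(f"n_phenotypes must be >= 1, got {n_phenotypes}")
    return GENOMEWIDE_NEGLOG10P + math.log10(n_phenotypes)


@dataclass
class Thresholds:
    genomewide: float = GENOMEWIDE_NEGLOG10P
    cover_cM: float = COVER_CM
    n_phenotypes: int = 1

    @property
    def bonferroni(self) -> float:
        return self.genomewide + math.log10(self.n_phenotypes)


@dataclass(frozen=True)
class Peak:
    """One supra-threshold (phenotype, variant) pair with its cM coordinate."""

    phenotype_id: str
    key: VariantKey
    cM: float
    neglog10p: float
    beta: float
    se: float

    def sort_key(self):
        """Max-priority order: higher -log10 p first, ties to smaller (bp, phenotype)."""
        return (-self.neglog10p, self.key.bp, self.phenotype_id)


@dataclass
class Cluster:
    """A lead peak plus all member peaks within the cM cover of the lead."""

    cluster_id: int
    lead: Peak
    members: list[Peak]
    replicated: bool = False
    bonferroni: bool = False


class _IndexedMaxHeap:
    """Binary max-heap over item ids with O(n) build and O(log n) delete.

    Keys are compared so that the *smallest* ``sort_key`` tuple is the
    maximum-priority element (tuples start with -neglog10p).  ``pos``
    tracks each id's slot so arbitrary ids can be removed when a
    cM-cover is deleted.
    """

    def __init__(self, keys: list[tuple]):
        self.keys = keys
        self.heap = list(range(len(keys)))
        self.pos = list(range(len(keys)))
        for i in range(len(self.heap) // 2 - 1, -1, -1):  # linear-time heapify
            self._sift_down(i)

    def __len__(self) -> int:
        return len(self.heap)

    def _less(self, a: int, b: int) -> bool:
        return self.keys[self.heap[a]] < self.keys[self.heap[b]]

    def _swap(self, i: int, j: int) -> None:
        h = self.heap
        h[i], h[j] = h[j], h[i]
        self.pos[h[i]] = i
        self.pos[h[j]] = j

    def _sift_down(self, i: int) -> None:
        n = len(self.heap)
        while True:
            left, right = 2 * i + 1, 2 * i + 2
            best = i
            if left < n and self._less(left, best):
                best = left
            if right < n and self._less(right, best):
                best = right
            if best == i:
                return
            self._swap(i, best)
            i = best

    def _sift_up(self, i: int) -> None:
        while i > 0:
            parent = (i - 1) // 2
            if not self._less(i, parent):
                return
            self._swap(i, parent)
            i = parent

    def extract_max(self) -> int:
        """Remove and return the maximum-priority item id."""
        top = self.heap[0]
        self._delete_slot(0)
        return top

    def remove(self, item: int) -> None:
        self._delete_slot(self.pos[item])

    def _delete_slot(self, i: int) -> None:
        last = len(self.heap) - 1
        self._swap(i, last)
        removed = self.heap.pop()
        self.pos[removed] = -1
        if i <= last - 1 and i < len(self.heap):
            self._sift_down(i)
            self._sift_up(i)


def _greedy_cover(peaks: list[Peak], cover_cM: float) -> list[tuple[int, list[int]]]:
    """Greedy max-first cM-cover clustering of one chromosome's peaks.

    Returns (lead_index, member_indices) groups in extraction order;
    member lists include the lead and are ordered by descending
    priority.  The cover is inclusive (|dcM| <= cover_cM).
    """
    if not peaks:
        return []
    order = sorted(range(len(peaks)), key=lambda i: peaks[i].cM)
    cms = [peaks[i].cM for i in order]
    heap = _IndexedMaxHeap([p.sort_key() for p in peaks])
    alive = [True] * len(peaks)
    groups: list[tuple[int, list[int]]] = []
    while len(heap):
        lead = heap.extract_max()
        alive[lead] = False
        # widen the bisect window by an ulp-scale pad, then apply the exact
        # inclusive |dcM| <= cover predicate, so boundary peaks are decided
        # by the distance itself and not by rounding of cM +/- cover
        pad = 1e-9 * max(1.0, abs(peaks[lead].cM))
        lo = bisect_left(cms, peaks[lead].cM - cover_cM - pad)
        hi = bisect_right(cms, peaks[lead].cM + cover_cM + pad)
        members = [lead]
        covered = []
        for r in range(lo, hi):
            idx = order[r]
            if alive[idx] and abs(peaks[idx].cM - peaks[lead].cM) <= cover_cM:
                heap.remove(idx)
                alive[idx] = False
                covered.append(idx)
        members.extend(sorted(covered, key=lambda i: peaks[i].sort_key()))
        groups.append((lead, members))
    return groups


def record_to_peak(record: SumStatsRecord, gmap: GeneticMap, phenotype_id: str) -> Peak:
    return Peak(
        phenotype_id=phenotype_id,
        key=record.key,
        cM=float(gmap.interpolate(record.key.chromosome, record.key.bp)),
        neglog10p=record.neglog10p,
        beta=record.beta,
        se=record.se,
    )


def extract_peaks(
    records: list[SumStatsRecord],
    gmap: GeneticMap,
    thresholds: Thresholds | None = None,
    phenotype_id: str = "phenotype",
) -> list[Peak]:
    """Within-phenotype hits: greedy max-first pruning at the cM cover.

    Records with -log10 p strictly above the genome-wide threshold are
    processed per chromosome: the strongest is emitted as a peak and
    everything within the cover removed, until none remain.  Callers
    apply the hit-level MAF filter upstream.
    """
    thresholds = thresholds or Thresholds()
    supra = [r for r in records if r.neglog10p > thresholds.genomewide]
    by_chrom: dict[str, list[Peak]] = {}
    for r in supra:
        by_chrom.setdefault(r.key.chromosome, []).append(
            record_to_peak(r, gmap, phenotype_id)
        )
    peaks: list[Peak] = []
    for chrom in sorted(by_chrom, key=chromosome_sort_key):
        for lead, _members in _greedy_cover(by_chrom[chrom], thresholds.cover_cM):
            peaks.append(by_chrom[chrom][lead])
    return peaks


def cluster_peaks(peaks: list[Peak], thresholds: Thresholds | None = None) -> list[Cluster]:
    """Aggregate peaks from all phenotypes into clusters, per chromosome.

    Every peak is assigned to exactly one cluster; the lead is the
    member with maximum -log10 p.  Output order: chromosome (X first,
    then autosomes ascending), then descending lead -log10 p.
    """
    thresholds = thresholds or Thresholds()
    for p in peaks:
        if not np.isfinite(p.cM):
            raise ValueError(f"peak {p.phenotype_id}/{p.key.variant_id} lacks a cM coordinate")
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.key.chromosome, []).append(p)
    clusters: list[Cluster] = []
    for chrom in sorted(by_chrom, key=chromosome_sort_key):
        chrom_peaks = by_chrom[chrom]
        for lead, members in _greedy_cover(chrom_peaks, thresholds.cover_cM):
            clusters.append(
                Cluster(
                    cluster_id=len(clusters) + 1,
                    lead=chrom_peaks[lead],
                    members=[chrom_peaks[i] for i in members],
                )
            )
    return clusters


def annotate_bonferroni(clusters: list[Cluster], thresholds: Thresholds) -> list[Cluster]:
    """Flag clusters whose lead reaches the Bonferroni-corrected threshold."""
    for c in clusters:
        c.bonferroni = c.lead.neglog10p >= thresholds.bonferroni
    return clusters


def tag_replication(
    clusters: list[Cluster],
    replication_neglog10p: dict[tuple[str, str], float],
    alpha: float = REPLICATION_ALPHA,
) -> list[Cluster]:
    """Mark clusters replicated when any member reaches nominal significance.

    ``replication_neglog10p`` maps (phenotype_id, variant_id) to the
    member's -log10 p in the held-out cohort; replication means
    two-sided p strictly below ``alpha``.  Members untestable in
    replication (monomorphic, missing) count as non-significant and are
    logged.
    """
    cut = -math.log10(alpha)
    for c in clusters:
        replicated = False
        for p in c.members:
            rep = replication_neglog10p.get((p.phenotype_id, p.key.variant_id))
            if rep is None or not np.isfinite(rep):
                logger.warning(
                    "cluster %d: member %s/%s untestable in replication; "
                    "treated as non-significant",
                    c.cluster_id, p.phenotype_id, p.key.variant_id,
                )
                continue
            if rep > cut:
                replicated = True
                break
        c.replicated = replicated
        if not c.members:
            logger.warning("cluster %d has no members", c.cluster_id)
    return clusters
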