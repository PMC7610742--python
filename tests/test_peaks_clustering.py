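import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gwaspeaks.io_formats import SumStatsRecord
from gwaspeaks.peaks_clustering import (
    Cluster,
    Peak,
    Thresholds,
    _IndexedMaxHeap,
    annotate_bonferroni,
    bonferroni_threshold,
    cluster_peaks,
    extract_peaks,
    tag_replication,
)
from gwaspeaks.variants import GeneticMap, make_variant_key

from oracles import naive_greedy_clusters, random_peak_instance


def _peak(pid, chrom, bp, cM, nlp):
    return Peak(
        phenotype_id=pid,
        key=make_variant_key(f"{pid}_{bp}", chrom, bp, "A", "G"),
        cM=cM,
        neglog10p=nlp,
        beta=0.1,
        se=0.01,
    )


def _flat_map():
    gmap = GeneticMap()
    gmap.add_chromosome("1", [1.0, 10e6], [1e-6, 10.0])  # 1 cM per Mb
    return gmap


def _record(bp, nlp, chrom="1"):
    return SumStatsRecord(
        key=make_variant_key(f"v{bp}", chrom, bp, "A", "G"),
        beta=0.1, se=0.01, neglog10p=nlp, n=100,
    )


class TestBonferroniThreshold:
    def test_many_phenotypes_prints_11_1(self):
        assert round(bonferroni_threshold(3935), 1) == 11.1

    def test_single_phenotype_identity(self):
        assert bonferroni_threshold(1) == 7.5

    def test_power_of_ten(self):
        assert bonferroni_threshold(10) == pytest.approx(8.5)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestIndexedHeap:
    def test_extract_order_is_sorted(self, rng):
        keys = [tuple(k) for k in rng.integers(0, 10, size=(200, 3))]
        heap = _IndexedMaxHeap(keys)
        out = []
        while len(heap):
            out.append(keys[heap.extract_max()])
        assert out == sorted(keys)

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 6), st.integers(0, 50)), min_size=1,
                    max_size=64))
    def test_extraction_total_order_property(self, keys):
        heap = _IndexedMaxHeap(keys)
        out = [keys[heap.extract_max()] for _ in range(len(keys))]
        assert out == sorted(keys)

    def test_arbitrary_removal(self, rng):
        keys = [(int(k),) for k in rng.permutation(100)]
        heap = _IndexedMaxHeap(keys)
        removed = set(rng.choice(100, size=40, replace=False).tolist())
        for item in removed:
            heap.remove(item)
        survivors = []
        while len(heap):
            survivors.append(heap.extract_max())
        assert sorted(survivors) == sorted(set(range(100)) - removed)
        assert [keys[i] for i in survivors] == sorted(keys[i] for i in survivors)


class TestExtractPeaks:
    def test_cover_removal_example(self):
        """Records at 1.0/1.1/1.4 cM: 1.1 is covered by 1.0; 1.4 survives."""
        records = [_record(1_000_000, 10.0), _record(1_100_000, 9.0),
                   _record(1_400_000, 8.0)]
        peaks = extract_peaks(records, _flat_map(), Thresholds(), "ph")
        assert [p.cM for p in peaks] == pytest.approx([1.0, 1.4])

    def test_all_subthreshold_empty(self):
        records = [_record(1_000_000, 7.5), _record(2_000_000, 3.0)]
        assert extract_peaks(records, _flat_map(), Thresholds(), "ph") == []

    def test_single_supra_record_is_itself(self):
        records = [_record(1_000_000, 8.0)]
        (peak,) = extract_peaks(records, _flat_map(), Thresholds(), "ph")
        assert peak.key.variant_id == "v1000000"

    def test_within_phenotype_separation(self, rng):
        """No two emitted peaks for one phenotype sit within the cover."""
        records = [
            _record(int(bp), float(nlp))
            for bp, nlp in zip(
                rng.choice(np.arange(1, 5_000_000), size=300, replace=False),
                rng.uniform(6, 20, size=300),
            )
        ]
        peaks = extract_peaks(records, _flat_map(), Thresholds(), "ph")
        cms = sorted(p.cM for p in peaks)
        assert all(b - a > 0.25 for a, b in zip(cms, cms[1:]))

    def test_threshold_monotonicity(self, rng):
        records = [
            _record(int(bp), float(nlp))
            for bp, nlp in zip(
                rng.choice(np.arange(1, 5_000_000), size=200, replace=False),
                rng.uniform(6, 14, size=200),
            )
        ]
        counts = [
            len(extract_peaks(records, _flat_map(), Thresholds(genomewide=t), "ph"))
            for t in (7.5, 9.0, 11.0, 13.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestClusterPeaks:
    def test_three_phenotype_example(self):
        peaks = [
            _peak("phenoA", "1", 1, 10.0, 12.0),
            _peak("phenoB", "1", 2, 10.2, 9.0),
            _peak("phenoC", "1", 3, 10.5, 8.0),
        ]
        clusters = cluster_peaks(peaks)
        assert len(clusters) == 2
        assert clusters[0].lead.phenotype_id == "phenoA"
        assert [p.phenotype_id for p in clusters[0].members] == ["phenoA", "phenoB"]
        assert clusters[1].lead.phenotype_id == "phenoC"

    def test_all_within_cover_single_cluster(self):
        peaks = [_peak(f"p{i}", "1", i + 1, 5.0 + 0.01 * i, 8.0 + i) for i in range(5)]
        (cluster,) = cluster_peaks(peaks)
        assert len(cluster.members) == 5

    def test_chromosomes_never_co_cluster(self):
        peaks = [_peak("a", "1", 1, 1.0, 9.0), _peak("b", "2", 1, 1.0, 8.0)]
        clusters = cluster_peaks(peaks)
        assert len(clusters) == 2

    def test_boundary_cover_inclusive(self):
        peaks = [_peak("a", "1", 1, 1.0, 9.0), _peak("b", "1", 2, 1.25, 8.0)]
        (cluster,) = cluster_peaks(peaks)
        assert len(cluster.members) == 2

    def test_missing_cm_raises(self):
        bad = _peak("a", "1", 1, float("nan"), 9.0)
        with pytest.raises(ValueError):
            cluster_peaks([bad])

    def test_matches_naive_oracle_on_random_instances(self, rng):
        for _ in range(150):
            peaks = random_peak_instance(rng, max_peaks=120)
            got = [
                [(m.phenotype_id, m.key.variant_id) for m in c.members]
                for c in cluster_peaks(peaks)
            ]
            assert got == naive_greedy_clusters(peaks)

    def test_partition_and_lead_dominance(self, rng):
        peaks = random_peak_instance(rng, max_peaks=400)
        clusters = cluster_peaks(peaks)
        seen = [(m.phenotype_id, m.key.variant_id) for c in clusters for m in c.members]
        assert len(seen) == len(peaks)
        assert len(set(seen)) == len(seen)
        for c in clusters:
            assert all(m.neglog10p <= c.lead.neglog10p for m in c.members)
            assert all(abs(m.cM - c.lead.cM) <= 0.25 for m in c.members)

    def test_output_ordering(self):
        peaks = [
            _peak("a", "2", 1, 1.0, 8.0),
            _peak("b", "1", 1, 1.0, 9.0),
            _peak("c", "X", 10_000_000, 1.0, 7.6),
            _peak("d", "1", 3_000_000, 4.0, 12.0),
        ]
        clusters = cluster_peaks(peaks)
        chroms = [c.lead.key.chromosome for c in clusters]
        assert chroms == ["X", "1", "1", "2"]
        # within chromosome 1: descending lead significance
        assert clusters[1].lead.neglog10p >= clusters[2].lead.neglog10p
        assert [c.cluster_id for c in clusters] == [1, 2, 3, 4]


class TestReplicationAndBonferroni:
    def _clusters(self):
        peaks = [_peak("a", "1", 1, 1.0, 12.0), _peak("b", "1", 2, 1.1, 9.0)]
        return cluster_peaks(peaks)

    def test_one_member_nominal_significance(self):
        clusters = self._clusters()
        rep = {("a", "a_1"): 1.0, ("b", "b_2"): -np.log10(0.04)}
        tag_replication(clusters, rep)
        assert clusters[0].replicated

    def test_exact_alpha_boundary_not_replicated(self):
        clusters = self._clusters()
        rep = {("a", "a_1"): -np.log10(0.05), ("b", "b_2"): -np.log10(0.05)}
        tag_replication(clusters, rep)
        assert not clusters[0].replicated

    def test_untestable_members_nonsignificant(self, caplog):
        clusters = self._clusters()
        tag_replication(clusters, {})
        assert not clusters[0].replicated

    def test_bonferroni_annotation(self):
        clusters = self._clusters()
        annotate_bonferroni(clusters, Thresholds(n_phenotypes=1000))  # cut 10.5
        assert clusters[0].bonferroni  # lead 12.0
        peaks = [_peak("a", "1", 1, 1.0, 9.0)]
        weak = cluster_peaks(peaks)
        annotate_bonferroni(weak, Thresholds(n_phenotypes=1000))
        assert not weak[0].bonferroni
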