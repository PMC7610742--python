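import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gwaspeaks.assoc_scan import AssocResult, ols_scan_matrix
from gwaspeaks.peaks_clustering import Peak
from gwaspeaks.sex_meta import (
    MetaError,
    SexScanPair,
    _chi2_logsf_even_df,
    beta_diff_ztest,
    cluster_overlap,
    fisher_combine,
    fisher_combine_neglog10,
    meta_scan,
    sign_concordance,
)
from gwaspeaks.variants import make_variant_key

from oracles import fisher_df4_closed_form_log

_KEY = make_variant_key("rs1", "X", 10_000_000, "A", "G")


def _pair(beta_f, beta_m, se_f=0.1, se_m=0.1, nlp_f=8.0, nlp_m=8.0):
    return SexScanPair(
        female=AssocResult(_KEY, "ph", beta_f, se_f, nlp_f, 100),
        male=AssocResult(_KEY, "ph", beta_m, se_m, nlp_m, 100),
    )


class TestFisherCombine:
    def test_unit_pvalues_combine_to_one(self):
        p, nlp = fisher_combine(1.0, 1.0)
        assert p == pytest.approx(1.0)
        assert nlp == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        """p_f = p_m = 0.05 -> q(1 - ln q) with q = 0.0025 ~= 0.01748."""
        p, _ = fisher_combine(0.05, 0.05)
        q = 0.0025
        assert p == pytest.approx(q * (1 - np.log(q)), rel=1e-10)
        assert p == pytest.approx(0.017479, abs=5e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(MetaError):
            fisher_combine(0.0, 0.5)
        with pytest.raises(MetaError):
            fisher_combine(0.5, 1.5)

    def test_monotone_in_each_argument(self):
        grid = np.linspace(0.2, 15.0, 40)  # -log10 p grid
        fixed = 3.0
        combined = fisher_combine_neglog10(grid, fixed)
        assert np.all(np.diff(combined) > 0)
        combined_t = fisher_combine_neglog10(fixed, grid)
        np.testing.assert_allclose(combined, combined_t, rtol=1e-12)

    def test_matches_df4_closed_form_to_1e12(self):
        """Series tail == q(1 - ln q) across p in [1e-300, 1], 1e-12 relative."""
        nlp = np.linspace(0.0, 150.0, 301)
        nf, nm = np.meshgrid(nlp, nlp)
        nf, nm = nf.ravel(), nm.ravel()
        ours_lnp = -np.log(10.0) * fisher_combine_neglog10(nf, nm)
        closed = fisher_df4_closed_form_log(nf, nm)
        # |d ln p| <= 1e-12 is relative error 1e-12 on p itself
        assert np.max(np.abs(ours_lnp - closed)) < 1e-12 + 1e-13 * np.max(np.abs(closed))

    def test_agrees_with_scipy_chi2(self):
        x = np.array([0.1, 1.0, 10.0, 100.0, 500.0])
        np.testing.assert_allclose(
            _chi2_logsf_even_df(x, 4), stats.chi2.logsf(x, 4), rtol=1e-12, atol=1e-12
        )
        np.testing.assert_allclose(
            _chi2_logsf_even_df(x, 2), stats.chi2.logsf(x, 2), rtol=1e-12, atol=1e-12
        )

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(0.0, 250.0), st.floats(0.0, 250.0))
    def test_combined_bounded_by_inputs(self, nf, nm):
        """0 <= combined -log10 p <= nlp_f + nlp_m (since p >= p_f * p_m)."""
        c = float(fisher_combine_neglog10(nf, nm))
        assert 0.0 <= c <= nf + nm + 1e-9

    def test_null_uniformity(self, rng):
        """Combined p of independent uniforms is uniform (KS)."""
        pf, pm = rng.uniform(size=(2, 20_000))
        combined_nlp = fisher_combine_neglog10(-np.log10(pf), -np.log10(pm))
        combined_p = 10.0 ** (-combined_nlp)
        stat = stats.kstest(combined_p, "uniform").statistic
        assert stat < 0.01


class TestBetaDiffZtest:
    def test_equal_betas_p_one(self):
        assert beta_diff_ztest(_pair(0.2, 0.2)) == pytest.approx(1.0)

    def test_unit_z_example(self):
        se = np.sqrt(0.5)
        p = beta_diff_ztest(_pair(1.0, 0.0, se_f=se, se_m=se))
        assert p == pytest.approx(2 * stats.norm.sf(1.0), rel=1e-12)
        assert p == pytest.approx(0.3173, abs=1e-4)

    def test_sex_swap_symmetric(self):
        a = beta_diff_ztest(_pair(0.3, -0.1, se_f=0.05, se_m=0.2))
        b = beta_diff_ztest(_pair(-0.1, 0.3, se_f=0.2, se_m=0.05))
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_se_rejected(self):
        with pytest.raises(MetaError):
            beta_diff_ztest(_pair(0.1, 0.2, se_f=0.0))

    def test_mismatched_pair_rejected(self):
        other = make_variant_key("rs2", "X", 10_000_500, "A", "G")
        with pytest.raises(MetaError):
            SexScanPair(
                female=AssocResult(_KEY, "ph", 0.1, 0.1, 8.0, 100),
                male=AssocResult(other, "ph", 0.1, 0.1, 8.0, 100),
            )


class TestSignConcordance:
    def test_all_same_sign(self):
        pairs = [_pair(0.1, 0.2), _pair(-0.3, -0.1)]
        assert sign_concordance(pairs, 7.5) == 1.0

    def test_one_of_four_discordant(self):
        pairs = [_pair(0.1, 0.2), _pair(0.1, 0.3), _pair(-0.2, -0.1), _pair(0.1, -0.1)]
        assert sign_concordance(pairs, 7.5) == 0.75

    def test_zero_beta_concordant(self):
        assert sign_concordance([_pair(0.0, -0.5)], 7.5) == 1.0

    def test_threshold_filters_on_stronger_sex(self):
        pairs = [_pair(0.1, -0.1, nlp_f=3.0, nlp_m=9.0), _pair(0.1, 0.1, nlp_f=3.0, nlp_m=3.0)]
        assert sign_concordance(pairs, 7.5) == 0.0  # only the first survives

    def test_empty_selection_undefined(self):
        with pytest.raises(MetaError):
            sign_concordance([_pair(0.1, 0.1, nlp_f=1.0, nlp_m=1.0)], 7.5)

    def test_shared_effect_simulation_concordance_exceeds_99pct(self):
        """Equal true betas in both sexes: signs at -log10 p >= 7.5 nearly always match."""
        rng = np.random.default_rng(17)
        n, beta_star = 2000, 0.15
        pairs = []
        for _ in range(500):
            pf_stats, pm_stats = [], []
            for _sex in range(2):
                g = rng.binomial(2, 0.3, size=n).astype(float)
                y = beta_star * g + rng.standard_normal(n)
                beta, se, nlp, *_ = ols_scan_matrix(g[None, :], y)
                (pf_stats if _sex == 0 else pm_stats).extend([beta[0], se[0], nlp[0]])
            pairs.append(
                SexScanPair(
                    female=AssocResult(_KEY, "ph", pf_stats[0], pf_stats[1], pf_stats[2], n),
                    male=AssocResult(_KEY, "ph", pm_stats[0], pm_stats[1], pm_stats[2], n),
                )
            )
        assert sign_concordance(pairs, 7.5) > 0.99


class TestClusterOverlap:
    def _cluster(self, cid, chrom, cM, nlp=9.0):
        peak = Peak(
            phenotype_id=f"p{cid}",
            key=make_variant_key(f"v{cid}", chrom, int(cM * 1e6) + 1, "A", "G"),
            cM=cM, neglog10p=nlp, beta=0.1, se=0.01,
        )
        from gwaspeaks.peaks_clustering import Cluster

        return Cluster(cluster_id=cid, lead=peak, members=[peak])

    def test_identical_sets_all_match(self):
        main = [self._cluster(1, "X", 1.0), self._cluster(2, "X", 5.0)]
        matched, meta_orphans, main_orphans = cluster_overlap(main, main)
        assert len(matched) == 2
        assert not meta_orphans and not main_orphans

    def test_beyond_tolerance_unmatched(self):
        meta = [self._cluster(1, "X", 1.3)]
        main = [self._cluster(2, "X", 1.0)]
        matched, meta_orphans, _ = cluster_overlap(meta, main)
        assert not matched and len(meta_orphans) == 1

    def test_boundary_inclusive(self):
        meta = [self._cluster(1, "X", 1.25)]
        main = [self._cluster(2, "X", 1.0)]
        matched, *_ = cluster_overlap(meta, main)
        assert len(matched) == 1

    def test_chromosome_must_agree(self):
        meta = [self._cluster(1, "1", 1.0)]
        main = [self._cluster(2, "2", 1.0)]
        matched, meta_orphans, main_orphans = cluster_overlap(meta, main)
        assert not matched and len(meta_orphans) == 1 and len(main_orphans) == 1


def test_meta_power_ordering_on_x():
    """With equal per-allele effects in both sexes, the Fisher meta of the
    sex-separated X scans keeps pace with the pooled scan (median -log10 p
    within 0.1)."""
    rng = np.random.default_rng(23)
    n, p, beta = 1000, 0.3, 0.08
    meta_nlp, pooled_nlp = [], []
    for _ in range(500):
        gf = rng.binomial(2, p, size=n).astype(float)
        gm_raw = rng.binomial(1, p, size=n).astype(float)
        gm_enc = 2.0 * gm_raw  # (0,2)-encoded male non-PAR dosage
        yf = beta * gf + rng.standard_normal(n)
        # equal effect per physical allele copy: the (0,2)-coded pooled scan
        # is mis-scaled for males, which Fisher's method is insensitive to
        ym = beta * gm_raw + rng.standard_normal(n)
        _, _, nf, *_ = ols_scan_matrix(gf[None, :], yf)
        _, _, nm, *_ = ols_scan_matrix(gm_enc[None, :], ym)
        meta_nlp.append(float(fisher_combine_neglog10(nf[0], nm[0])))
        g_all = np.concatenate([gf, gm_enc])[None, :]
        y_all = np.concatenate([yf, ym])
        _, _, np_, *_ = ols_scan_matrix(g_all, y_all)
        pooled_nlp.append(np_[0])
    assert np.median(meta_nlp) >= np.median(pooled_nlp) - 0.1


def test_meta_scan_matches_elementwise_combination():
    f = [AssocResult(_KEY, "ph", 0.1, 0.05, 4.0, 100)]
    m = [AssocResult(_KEY, "ph", 0.2, 0.05, 6.0, 100)]
    (res,) = meta_scan(f, m)
    assert res.combined_neglog10p == pytest.approx(
        float(fisher_combine_neglog10(4.0, 6.0))
    )
    # monomorphic partners are skipped
    m_mono = [AssocResult(_KEY, "ph", np.nan, np.nan, np.nan, 100, monomorphic=True)]
    assert meta_scan(f, m_mono) == []
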