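import numpy as np
import pandas as pd
import pytest

import hemeascn as h
from hemeascn.ascn import compute_logor, select_het_snps
from hemeascn.cnfit import expected_logor, expected_logr


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        cfg = dict(seed=3, purity=0.5, n_snps=2000,
                   somatic=[h.SomaticSpec("1", 1_000_000, 0.3)])
        a = h.simulate_case(h.SimConfig(**cfg))
        b = h.simulate_case(h.SimConfig(**cfg))
        pd.testing.assert_frame_equal(a.snp_matrix.loci, b.snp_matrix.loci)
        pd.testing.assert_frame_equal(a.snp_matrix.ref_counts, b.snp_matrix.ref_counts)
        pd.testing.assert_frame_equal(a.snp_matrix.alt_counts, b.snp_matrix.alt_counts)
        assert a.variants == b.variants

    def test_different_seed_differs(self):
        a = h.simulate_case(h.SimConfig(seed=1, n_snps=500))
        b = h.simulate_case(h.SimConfig(seed=2, n_snps=500))
        assert not a.snp_matrix.alt_counts.equals(b.snp_matrix.alt_counts)


class TestCalibration:
    def test_mean_depth_within_two_percent(self):
        cfg = h.SimConfig(seed=8, n_snps=6000, depth_mean=500, purity=0.0)
        case = h.simulate_case(cfg)
        for s in ("TUMOR", "NORMAL", "UNMATCHED1"):
            assert case.snp_matrix.depth(s).mean() == pytest.approx(500, rel=0.02)

    def test_het_fraction_matches_hardy_weinberg(self):
        # Beta(2,2) allele frequencies: E[2p(1-p)] = 2(E[p] - E[p^2]) = 0.4
        cfg = h.SimConfig(seed=9, n_snps=8000)
        case = h.simulate_case(cfg)
        het = (case.truth.host_genotypes == 1).mean()
        assert het == pytest.approx(0.4, abs=0.03)

    def test_null_case_has_no_allelic_signal(self):
        """purity 0, donor fraction 0: the tumor aliquot is statistically a
        matched normal (logOR unbiased, |mean| < 0.1 over >=1000 hets)."""
        cfg = h.SimConfig(seed=10, purity=0.0, n_snps=6000, depth_mean=400)
        sm = h.simulate_case(cfg).snp_matrix
        het = select_het_snps(sm.ref("NORMAL"), sm.alt("NORMAL"))
        assert het.sum() >= 1000
        lt = compute_logor(sm.ref("TUMOR"), sm.alt("TUMOR"),
                           sm.ref("NORMAL"), sm.alt("NORMAL"), het)
        assert abs(np.nanmean(lt.logor[het])) < 0.1

    def test_cnloh_segment_matches_expected_logor(self):
        """(tcn 2, lcn 0) at purity 0.8: mean het |logOR| tracks the model
        expectation log2(1.8/0.2)."""
        cfg = h.SimConfig(seed=12, purity=0.8, n_snps=8000, depth_mean=600,
                          segments=[h.SegmentSpec("1", 1, 249_000_000, 2, 0)])
        case = h.simulate_case(cfg)
        sm = case.snp_matrix
        het = select_het_snps(sm.ref("NORMAL"), sm.alt("NORMAL"))
        in_seg = (sm.loci["chrom"] == "1").to_numpy() & het
        lt = compute_logor(sm.ref("TUMOR"), sm.alt("TUMOR"),
                           sm.ref("NORMAL"), sm.alt("NORMAL"), het)
        observed = np.nanmean(np.abs(lt.logor[in_seg]))
        assert observed == pytest.approx(expected_logor(2, 0, 0.8), abs=0.1)

    def test_infeasible_profile_rejected(self):
        with pytest.raises(ValueError, match="lcn"):
            h.SegmentSpec("1", 1, 100, 2, 2)
        with pytest.raises(ValueError, match="purity"):
            h.SimConfig(purity=0.8, donor_fraction=0.4)


class TestDilutionSeries:
    BASE = dict(seed=30, purity=1.0, n_snps=1500,
                segments=[h.SegmentSpec("13", 17_900_001, 115_169_878, 1, 0)])

    def test_five_fractions_give_five_cases(self):
        cases = h.simulate_dilution_series(h.SimConfig(**self.BASE),
                                           [1, 0.5, 0.25, 0.125, 0.0625])
        assert len(cases) == 5
        assert [round(c.config.purity, 4) for _, c in cases] == \
            [1, 0.5, 0.25, 0.125, 0.0625]

    def test_fraction_one_equals_base_case(self):
        base_cfg = h.SimConfig(**self.BASE)
        base = h.simulate_case(base_cfg)
        (_, diluted), = h.simulate_dilution_series(h.SimConfig(**self.BASE), [1.0])
        pd.testing.assert_frame_equal(base.snp_matrix.alt_counts,
                                      diluted.snp_matrix.alt_counts)

    def test_expected_logr_magnitude_decreases_monotonically(self):
        mags = [abs(expected_logr(1, 1.0 * f, 2))
                for f in (1, 0.5, 0.25, 0.125, 0.0625)]
        assert all(a > b for a, b in zip(mags, mags[1:]))

    def test_requires_an_scna(self):
        with pytest.raises(ValueError, match="SCNA"):
            h.simulate_dilution_series(h.SimConfig(seed=1), [0.5])


class TestChimerism:
    def test_tumor_allele_fraction_tracks_donor_genotype(self):
        """At host-het/donor-hom SNPs on diploid background the tumor-sample
        allele fraction regresses on the donor genotype with slope ~delta."""
        delta = 0.3
        cfg = h.SimConfig(seed=31, purity=0.4, donor_fraction=delta,
                          n_donors=1, n_snps=8000)
        case = h.simulate_case(cfg)
        sm = case.snp_matrix
        g_h, g_d = case.truth.host_genotypes, case.truth.donor_genotypes[0]
        sel = (g_h == 1) & ((g_d == 0) | (g_d == 2))
        f_obs = sm.alt("TUMOR")[sel] / np.maximum(sm.depth("TUMOR")[sel], 1)
        x = g_d[sel] / 2 - 0.5
        slope = np.polyfit(x, f_obs - 0.5, 1)[0]
        assert slope == pytest.approx(delta, abs=0.05)

    def test_chimera_fit_equals_nonchimeric_fit(self):
        """Donor chimerism is absorbed into the normal-cell term: a chimeric
        case analyzed with the host/donor het intersection recovers the same
        (tcn, lcn) and purity as the non-chimeric tumor."""
        segs = [h.SegmentSpec("13", 17_900_001, 115_169_878, 2, 0),
                h.SegmentSpec("5", 1, 90_000_000, 3, 1)]
        plain = h.simulate_case(h.SimConfig(seed=32, purity=0.5, n_snps=6000,
                                            segments=segs))
        chimeric = h.simulate_case(h.SimConfig(seed=32, purity=0.5,
                                               donor_fraction=0.4, n_donors=1,
                                               n_snps=6000, segments=segs))
        res_p = h.analyze_case(plain.snp_matrix, plain.variants)
        res_c = h.analyze_case(chimeric.snp_matrix, chimeric.variants)
        assert abs(res_p.fit.purity - res_c.fit.purity) <= 0.03
        states_p = {(s.chrom, s.tcn, s.lcn) for s in res_p.fit.segments
                    if s.tcn != 2 or s.lcn != 1}
        states_c = {(s.chrom, s.tcn, s.lcn) for s in res_c.fit.segments
                    if s.tcn != 2 or s.lcn != 1}
        assert {(c, t, l) for c, t, l in states_p if l is not None} \
            == {(c, t, l) for c, t, l in states_c if l is not None}
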