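import numpy as np
import pandas as pd
import pytest

import hemeascn as h
from hemeascn.cnfit import (ArmCall, GeneCall, PurityPloidyFit, call_arm_level,
                            call_cnloh, call_gene_level, detect_wgd,
                            expected_logor, expected_logr, fit_purity_ploidy)
from hemeascn.io import IntervalSet
from hemeascn.segment import Segment, estimate_diplogr, segment_bivariate

from .conftest import exact_state_fraction, make_variant


class TestExpectedTracks:
    @pytest.mark.parametrize("rho", [0.1, 0.5, 0.9])
    def test_copy_equal_ploidy_is_zero(self, rho):
        assert expected_logr(2, rho, 2) == pytest.approx(0.0)
        assert expected_logr(3.5, rho, 3.5) == pytest.approx(0.0)

    def test_hand_values(self):
        assert expected_logr(4, 0.6, 2) == pytest.approx(np.log2(3.2 / 2.0), abs=1e-9)
        assert expected_logor(2, 0, 0.5) == pytest.approx(np.log2(1.5 / 0.5), abs=1e-9)

    def test_divergent_logor_capped(self):
        assert expected_logor(2, 0, 1.0) == 10.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            expected_logr(2, 0.0, 2)
        with pytest.raises(ValueError):
            expected_logr(2, 0.5, 0)


def _segment(chrom, start, end, num_mark, logr, logor2, n_het, **kw):
    return Segment(chrom, start, end, num_mark, logr, logor2, n_het, **kw)


def _model_segments(rho, states, n_mark=300, n_het=120):
    """Noise-free segments generated from the expected-track model."""
    segs = []
    for i, (tcn, lcn) in enumerate(states):
        e_r = expected_logr(tcn, rho, 2)
        e_or = expected_logor(tcn - lcn, lcn, rho)
        segs.append(_segment(str(i + 1), 1, 100_000_000, n_mark, e_r, e_or**2, n_het))
    return segs


class TestPurityPloidyFit:
    def test_model_generated_segments_recovered_exactly(self):
        rho = 0.6
        states = [(2, 1), (2, 1), (3, 1), (1, 0), (2, 0), (4, 2)]
        fit = fit_purity_ploidy(_model_segments(rho, states), diplogr=0.0)
        assert fit.purity == pytest.approx(rho, abs=0.01)
        assert [(s.tcn, s.lcn) for s in fit.segments] == states

    def test_simulated_case_recovery(self, standard_case, standard_result):
        fit = standard_result.fit
        assert abs(fit.purity - standard_case.truth.purity) <= 0.05
        assert exact_state_fraction(standard_case, fit) == 1.0

    def test_low_het_segments_get_logr_only_tcn(self):
        segs = _model_segments(0.6, [(2, 1), (3, 1), (1, 0)])
        segs.append(_segment("9", 1, 10_000_000, 40,
                             expected_logr(4, 0.6, 2), 0.0, 2))
        fit = fit_purity_ploidy(segs, diplogr=0.0)
        assert fit.segments[-1].tcn == 4
        assert fit.segments[-1].lcn is None

    def test_pure_normal_flagged_quiet(self):
        segs = _model_segments(0.5, [(2, 1)] * 8)
        fit = fit_purity_ploidy(segs, diplogr=0.0)
        assert fit.quiet and fit.low_confidence
        assert np.isnan(fit.purity)
        assert all(s.tcn == 2 and s.lcn == 1 for s in fit.segments)

    def test_deep_dilution_below_sensitivity_suppresses_calls(self):
        """A 6.25% tumor-fraction dilution is flagged below the validated
        20% sensitivity floor and emits no SCNA."""
        base = h.SimConfig(seed=77, purity=1.0, n_snps=6000,
                           segments=[h.SegmentSpec("13", 17_900_001, 115_169_878, 1, 0)])
        (_, case), = h.simulate_dilution_series(base, [0.0625])
        from hemeascn.resources import default_arm_table
        res = h.analyze_case(case.snp_matrix, case.variants,
                             arms=default_arm_table(base.chroms))
        assert res.fit.quiet or res.fit.below_sensitivity
        assert res.arm_calls == []

    def test_no_informative_segments_errors(self):
        segs = [_segment("1", 1, 100, 50, 0.0, 0.0, 3)]
        with pytest.raises(ValueError, match="heterozygous"):
            fit_purity_ploidy(segs, diplogr=0.0)


def _fit_with(states_and_lengths, wgd=None):
    segs = []
    for i, (tcn, lcn, length) in enumerate(states_and_lengths):
        segs.append(_segment("1" if i == 0 else str(min(i + 1, 22)), 1, length,
                             max(10, length // 10**6), 0.0, 0.0, 50,
                             tcn=tcn, lcn=lcn))
    return PurityPloidyFit(purity=0.6, ploidy=2.0, diplogr=0.0,
                           segments=segs, loss=0.0, wgd=wgd)


class TestWgd:
    def test_major_two_genome_wide_is_wgd(self):
        fit = _fit_with([(3, 1, 100_000_000)] * 4)
        assert detect_wgd(fit) is True

    def test_diploid_genome_not_wgd(self):
        fit = _fit_with([(2, 1, 100_000_000)] * 4)
        assert detect_wgd(fit) is False

    def test_exactly_half_is_not_wgd(self):
        fit = _fit_with([(4, 2, 100_000_000), (2, 1, 100_000_000)])
        assert detect_wgd(fit) is False

    def test_insufficient_lcn_coverage_returns_none(self):
        fit = _fit_with([(2, 1, 10_000_000)])
        fit.segments.append(_segment("2", 1, 100_000_000, 100, 0.0, 0.0, 0,
                                     tcn=2, lcn=None))
        with pytest.warns(UserWarning, match="WGD"):
            assert detect_wgd(fit) is None


class TestCnloh:
    @pytest.mark.parametrize("tcn,lcn,wgd,expected", [
        (2, 0, False, True),    # the defining copy-neutral LOH state
        (2, 1, False, False),   # heterozygosity retained
        (1, 0, False, False),   # a loss, not copy-neutral
        (4, 0, True, True),     # copy-neutral relative to a doubled genome
        (2, 0, True, False),
    ])
    def test_cnloh_rule(self, tcn, lcn, wgd, expected):
        fit = _fit_with([(tcn, lcn, 100_000_000)], wgd=wgd)
        call_cnloh(fit)
        assert fit.segments[0].cnloh is expected


class TestGeneCalls:
    def _genes(self):
        return IntervalSet(pd.DataFrame(
            [{"chrom": "1", "start": 10, "end": 1_000_000, "name": "GENE1"}]))

    def _single_segment_fit(self, tcn, lcn, wgd=False):
        fit = _fit_with([(tcn, lcn, 100_000_000)], wgd=wgd)
        call_cnloh(fit)
        return fit

    def test_amp_threshold_without_wgd(self):
        calls = call_gene_level(self._single_segment_fit(5, 2), self._genes())
        assert [c.call for c in calls] == ["AMP"]

    def test_amp_needs_more_than_six_with_wgd(self):
        assert call_gene_level(self._single_segment_fit(6, 2, wgd=True),
                               self._genes()) == []
        calls = call_gene_level(self._single_segment_fit(7, 2, wgd=True),
                                self._genes())
        assert [c.call for c in calls] == ["AMP"]

    def test_homdel(self):
        calls = call_gene_level(self._single_segment_fit(0, 0), self._genes())
        assert [c.call for c in calls] == ["HOMDEL"]

    def test_hetloss_requires_cooccurring_variant(self):
        fit = self._single_segment_fit(1, 0)
        mutation = make_variant(gene="GENE1", chrom="1", pos=500)
        with_var = call_gene_level(fit, self._genes(), [mutation])
        without = call_gene_level(fit, self._genes(), [])
        assert [c.call for c in with_var] == ["HETLOSS"]
        assert without == []

    def test_cnloh_annotated_per_gene(self):
        calls = call_gene_level(self._single_segment_fit(2, 0), self._genes())
        assert [c.call for c in calls] == ["CNLOH"]

    def test_uncovered_gene_skipped_with_warning(self):
        genes = IntervalSet(pd.DataFrame(
            [{"chrom": "21", "start": 10, "end": 1000, "name": "FARAWAY"}]))
        with pytest.warns(UserWarning, match="FARAWAY"):
            assert call_gene_level(self._single_segment_fit(2, 1), genes) == []

    def test_calls_are_deterministic(self):
        fit = self._single_segment_fit(5, 2)
        a = call_gene_level(fit, self._genes())
        b = call_gene_level(fit, self._genes())
        assert a == b


class TestArmCalls:
    def _arms(self):
        return pd.DataFrame([
            {"chrom": "13", "arm": "q", "start": 1, "end": 100_000_000,
             "arm_length": 100_000_000},
            {"chrom": "8", "arm": "p", "start": 1, "end": 45_000_000,
             "arm_length": 45_000_000},
            {"chrom": "8", "arm": "q", "start": 45_000_001, "end": 146_000_000,
             "arm_length": 101_000_000},
        ])

    def _fit(self, segs):
        fit = PurityPloidyFit(purity=0.6, ploidy=2.0, diplogr=0.0,
                              segments=segs, loss=0.0, wgd=False)
        call_cnloh(fit)
        return fit

    def test_sixty_percent_loss_called_forty_not(self):
        sixty = self._fit([_segment("13", 1, 60_000_000, 100, -0.5, 0.2, 50,
                                    tcn=1, lcn=0)])
        forty = self._fit([_segment("13", 1, 40_000_000, 100, -0.5, 0.2, 50,
                                    tcn=1, lcn=0)])
        assert [(c.chrom, c.arm, c.call) for c in call_arm_level(sixty, self._arms())] \
            == [("13", "q", "LOSS")]
        assert call_arm_level(forty, self._arms()) == []

    def test_trisomy_calls_both_arms(self):
        fit = self._fit([_segment("8", 1, 146_000_000, 300, 0.4, 0.2, 120,
                                  tcn=3, lcn=1)])
        calls = {(c.chrom, c.arm, c.call) for c in call_arm_level(fit, self._arms())}
        assert calls == {("8", "p", "GAIN"), ("8", "q", "GAIN")}
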