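from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemeascn as h
from hemeascn.filters import (FilterConfig, apply_common_filters,
                              apply_tier_filters, population_triage,
                              run_cascade)
from hemeascn.io import Role

from .conftest import make_variant

CFG = FilterConfig()


def brute_force_verdict(v, unmatched_vaf, matched_vaf, cfg=CFG):
    """Independent rule-by-rule oracle for the matched-mode cascade."""
    vaf = Fraction(v.tumor_alt, v.tumor_depth) if v.tumor_depth else Fraction(0)
    rules = []
    if unmatched_vaf is not None and vaf < Fraction(5) * Fraction(str(unmatched_vaf)):
        rules.append("unmatched_ratio")
    if v.tumor_depth < 20:
        rules.append("min_depth")
    if v.tumor_alt < 5:
        rules.append("min_alt")
    if vaf < Fraction(1, 100):
        rules.append("min_vaf")
    if not Fraction(str(v.pon_fraction)) < Fraction(1, 5):
        rules.append("panel_of_normals")
    if v.hotspot:
        if v.tumor_alt < 8:
            rules.append("min_alt_hotspot")
        if vaf < Fraction(1, 50):
            rules.append("min_vaf_hotspot")
    else:
        if v.tumor_alt < 10:
            rules.append("min_alt_nonhotspot")
        if vaf < Fraction(1, 20):
            rules.append("min_vaf_nonhotspot")
        if matched_vaf is None:
            rules.append("no_matched_normal")
        elif vaf == 0 or Fraction(str(matched_vaf)) / vaf > Fraction(7, 20):
            rules.append("germline_ratio")
    return "PASS" if not rules else "FAIL", set(rules)


class TestCommonFilters:
    def test_clean_variant_passes(self):
        v = make_variant(depth=100, alt=10)
        res = apply_common_filters(v, 0.01)
        assert res.verdict == "PASS" and res.failed_rules == []

    @pytest.mark.parametrize("kwargs,unmatched,rule", [
        (dict(depth=19, alt=10), 0.0, "min_depth"),
        (dict(depth=100, alt=4), 0.0, "min_alt"),
        (dict(depth=1000, alt=9), 0.0, "min_vaf"),
        (dict(depth=100, alt=10, pon=0.20), 0.0, "panel_of_normals"),
        (dict(depth=100, alt=10), 0.03, "unmatched_ratio"),
    ])
    def test_each_rule_fires(self, kwargs, unmatched, rule):
        res = apply_common_filters(make_variant(**kwargs), unmatched)
        assert res.verdict == "FAIL" and rule in res.failed_rules

    @pytest.mark.parametrize("depth,alt,unmatched,pon,passes", [
        (20, 5, 0.0, 0.0, True),     # every threshold exactly at its boundary
        (19, 5, 0.0, 0.0, False),    # one read below the depth floor
        (100, 5, 0.01, 0.0, True),   # VAF exactly 5x the unmatched VAF
        (100, 5, Fraction(1, 99), 0.0, False),  # just above the 5x bound
        (100, 10, 0.0, 5 / 25, False),  # PoN at exactly 20%: strict <
        (100, 10, 0.0, 4 / 25, True),
        (500, 5, 0.0, 0.0, True),    # VAF exactly 1%
        (501, 5, 0.0, 0.0, False),   # VAF just below 1%
    ])
    def test_boundary_audit(self, depth, alt, unmatched, pon, passes):
        res = apply_common_filters(make_variant(depth=depth, alt=alt, pon=pon),
                                   unmatched)
        assert (res.verdict == "PASS") is passes


class TestTierFilters:
    def test_hotspot_boundary(self):
        v = make_variant(depth=400, alt=8, hotspot=True)  # VAF exactly 2%
        assert apply_tier_filters(v).verdict == "PASS"
        v = make_variant(depth=400, alt=7, hotspot=True)
        res = apply_tier_filters(v)
        assert set(res.failed_rules) == {"min_alt_hotspot", "min_vaf_hotspot"}

    def test_nonhotspot_alt_floor(self):
        v = make_variant(depth=100, alt=9)
        res = apply_tier_filters(v, matched_normal_vaf=0.0)
        assert res.failed_rules == ["min_alt_nonhotspot"]

    def test_germline_ratio_interpretation(self):
        v = make_variant(depth=100, alt=40)  # tumor VAF 0.40
        assert "germline_ratio" in apply_tier_filters(
            v, matched_normal_vaf=0.20).failed_rules  # ratio 0.5 > 0.35
        assert apply_tier_filters(v, matched_normal_vaf=0.10).verdict == "PASS"

    def test_literal_both_below_rule_behind_switch(self):
        cfg = FilterConfig(literal_matched_rule=True)
        v = make_variant(depth=100, alt=40)
        res = apply_tier_filters(v, cfg, matched_normal_vaf=0.10)
        assert "germline_ratio" in res.failed_rules  # tumor VAF 0.40 > 0.35

    def test_missing_matched_normal(self):
        v = make_variant(depth=100, alt=20)
        assert "no_matched_normal" in apply_tier_filters(v).failed_rules
        assert apply_tier_filters(v, require_matched=False).verdict == "PASS"


class TestPopulationTriage:
    @pytest.mark.parametrize("af,label", [
        (0.02, "GERMLINE_LIKELY"),
        (0.005, "RETAINED"),
        (None, "RETAINED"),
    ])
    def test_triage(self, af, label):
        assert population_triage(make_variant(population_af=af)) == label


def _roles():
    return {"T": Role.TUMOR, "N": Role.MATCHED_NORMAL, "U": Role.UNMATCHED_NORMAL}


def _cascade_variant(depth=200, alt=40, hotspot=False, pon=0.0,
                     normal_alt=0, unmatched_alt=0, pos=1000):
    return make_variant(depth=depth, alt=alt, hotspot=hotspot, pon=pon, pos=pos,
                        normal_evidence={"N": (200, normal_alt),
                                         "U": (200, unmatched_alt)})


class TestCascade:
    def test_toy_set_trips_each_rule_once(self):
        variants = [
            _cascade_variant(pos=1),                            # clean: PASS
            _cascade_variant(pos=2, depth=19, alt=10),          # min_depth
            _cascade_variant(pos=3, alt=4),                     # min_alt
            _cascade_variant(pos=4, pon=0.25),                  # panel_of_normals
            _cascade_variant(pos=5, unmatched_alt=20),          # unmatched_ratio
            _cascade_variant(pos=6, normal_alt=100),            # germline_ratio
        ]
        out = run_cascade(variants, _roles(), mode="matched")
        verdicts = [a.result.verdict for a in out]
        assert verdicts.count("PASS") == 1 and verdicts[0] == "PASS"
        expected = ["min_depth", "min_alt", "panel_of_normals",
                    "unmatched_ratio", "germline_ratio"]
        for a, rule in zip(out[1:], expected):
            assert rule in a.result.failed_rules

    def test_unmatched_mode_is_superset_of_matched(self):
        variants = [_cascade_variant(pos=i, normal_alt=a, alt=al)
                    for i, (a, al) in enumerate([(0, 40), (100, 40), (0, 9),
                                                 (10, 60), (80, 100)])]
        matched = run_cascade(variants, _roles(), mode="matched")
        roles_u = {"T": Role.TUMOR, "U": Role.UNMATCHED_NORMAL}
        unmatched = run_cascade(variants, roles_u, mode="unmatched")
        m_pass = {a.variant.key() for a in matched if a.result.verdict == "PASS"}
        u_pass = {a.variant.key() for a in unmatched if a.result.verdict == "PASS"}
        assert m_pass <= u_pass
        assert all(a.population_label is not None for a in unmatched)

    def test_empty_input(self):
        assert run_cascade([], _roles(), mode="matched") == []

    def test_mode_evidence_mismatch(self):
        with pytest.raises(ValueError, match="MATCHED_NORMAL"):
            run_cascade([], {"T": Role.TUMOR}, mode="matched")
        with pytest.raises(ValueError, match="donor"):
            run_cascade([], _roles(), mode="post_transplant")
        with pytest.raises(ValueError, match="unknown mode"):
            run_cascade([], _roles(), mode="bogus")

    def test_order_preserved(self):
        variants = [_cascade_variant(pos=p) for p in (30, 10, 20)]
        out = run_cascade(variants, _roles(), mode="matched")
        assert [a.variant.pos for a in out] == [30, 10, 20]

    def test_randomized_agreement_with_brute_force(self):
        """Vectorized cascade verdicts equal the independent per-rule oracle
        exactly on 2000 randomized variants (the acceptance run uses 10000)."""
        import numpy as np
        rng = np.random.default_rng(99)
        for _ in range(2000):
            depth = int(rng.integers(10, 1000))
            alt = int(rng.integers(0, depth + 1))
            n_depth = int(rng.integers(10, 1000))
            n_alt = int(rng.integers(0, n_depth + 1))
            u_depth = int(rng.integers(10, 1000))
            u_alt = int(rng.integers(0, u_depth + 1))
            v = make_variant(depth=depth, alt=alt, hotspot=bool(rng.integers(2)),
                             pon=float(rng.random()),
                             normal_evidence={"N": (n_depth, n_alt),
                                              "U": (u_depth, u_alt)})
            (a,) = run_cascade([v], _roles(), mode="matched")
            expected_verdict, expected_rules = brute_force_verdict(
                v, Fraction(u_alt, u_depth), Fraction(n_alt, n_depth))
            assert a.result.verdict == expected_verdict
            assert set(a.result.failed_rules) == expected_rules


class TestMonotonicity:
    @given(depth=st.integers(20, 1000), alt=st.integers(0, 1000),
           bump=st.integers(1, 50), hotspot=st.booleans())
    @settings(max_examples=200, deadline=None)
    def test_more_alt_reads_never_flip_pass_to_fail(self, depth, alt, bump, hotspot):
        alt = min(alt, depth)
        alt2 = min(alt + bump, depth)
        evidence = {"N": (500, 10), "U": (500, 1)}
        v1 = make_variant(depth=depth, alt=alt, hotspot=hotspot,
                          normal_evidence=evidence)
        v2 = make_variant(depth=depth, alt=alt2, hotspot=hotspot,
                          normal_evidence=evidence)
        (r1,), (r2,) = (run_cascade([v], _roles(), mode="matched") for v in (v1, v2))
        if r1.result.verdict == "PASS":
            assert r2.result.verdict == "PASS"


class TestConfig:
    def test_round_trip(self):
        cfg = FilterConfig(min_depth=25, pon_max=0.1)
        assert FilterConfig.from_dict(cfg.to_dict()) == cfg

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(pon_max=1.5)
        with pytest.raises(ValueError):
            FilterConfig(ratio_unmatched=0.5)
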