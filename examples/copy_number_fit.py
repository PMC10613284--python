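"""Allele-specific copy number on a simulated mid-purity marrow sample.

Builds a 60%-pure tumor carrying a 13q deletion and a 9p copy-neutral LOH,
runs reference-normal selection, two-pass segmentation and the
purity/ploidy fit, and prints the fitted states and arm-level calls.
"""
import warnings

import hemeascn as h
from hemeascn.resources import default_arm_table

warnings.filterwarnings("ignore")

cfg = h.SimConfig(
    seed=42, purity=0.6, n_snps=6000,
    segments=[h.SegmentSpec("13", 17_900_001, 115_169_878, 1, 0),   # 13q loss
              h.SegmentSpec("9", 1, 40_000_000, 2, 0)],             # 9p CN-LOH
    somatic=[h.SomaticSpec("13", 28_600_000, 0.4, gene="FLT3")],
)
case = h.simulate_case(cfg)
result = h.analyze_case(case.snp_matrix, case.variants,
                        arms=default_arm_table(cfg.chroms))

fit = result.fit
print(f"reference normal : {result.chosen_normal}")
print(f"purity           : {fit.purity:.2f}   (truth {cfg.purity})")
print(f"ploidy           : {fit.ploidy:.2f}")
print(f"dipLogR          : {fit.diplogr:+.3f}")
print(f"WGD              : {fit.wgd}")
print("\naberrant segments (chrom:start-end  tcn/lcn  CN-LOH):")
for s in fit.segments:
    if s.tcn != 2 or (s.lcn is not None and s.lcn != 1):
        print(f"  {s.chrom}:{s.start_pos // 10**6}-{s.end_pos // 10**6} Mb"
              f"   {s.tcn}/{s.lcn}   cnloh={s.cnloh}")
print("\narm-level calls:")
for c in result.arm_calls:
    print(f"  {c.chrom}{c.arm} {c.call} ({c.fraction_of_arm:.0%} of arm)")
# The purity is the tumor-cell fraction; tcn/lcn are total and minor
# integer copies, so 1/0 is a one-copy loss and 2/0 is copy-neutral LOH.
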