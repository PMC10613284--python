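"""The matched somatic filter cascade on a small hand-built variant set.

Each variant trips one printed rule (depth floor, alt-read floor, panel of
normals, unmatched 5x ratio, matched-normal germline ratio); one clean
variant passes everything.
"""
import hemeascn as h
from hemeascn.io import Role


def variant(pos, depth=200, alt=40, hotspot=False, pon=0.0,
            normal_alt=0, unmatched_alt=0):
    return h.VariantRecord(
        chrom="1", pos=pos, ref="C", alt="T", tumor_depth=depth,
        tumor_alt=alt, hotspot=hotspot, pon_fraction=pon,
        normal_evidence={"N": (200, normal_alt), "U": (200, unmatched_alt)})


variants = [
    variant(1),                       # clean
    variant(2, depth=19, alt=10),     # below 20-read depth floor
    variant(3, alt=4),                # below 5 alt reads
    variant(4, pon=0.25),             # in >= 20% of the panel of normals
    variant(5, unmatched_alt=20),     # tumor VAF < 5x unmatched-normal VAF
    variant(6, normal_alt=100),       # matched-normal:tumor VAF ratio > 0.35
]
roles = {"T": Role.TUMOR, "N": Role.MATCHED_NORMAL, "U": Role.UNMATCHED_NORMAL}

for a in h.run_cascade(variants, roles, mode="matched"):
    v = a.variant
    reasons = ", ".join(a.result.failed_rules) or "-"
    print(f"chr{v.chrom}:{v.pos}  VAF {v.vaf:.2f}  {a.result.verdict:4s}  {reasons}")
# PASS requires clearing every printed threshold; failed_rules lists the
# exact rules a call tripped, which is what a molecular pathologist reviews.
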