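"""Built-in genome geometry used by the simulator and as a fallback arm table.

Approximate GRCh37 chromosome lengths and centromere midpoints, rounded to
the nearest 0.1 Mb.  These only set the coordinate frame for simulated cases
and default chromosome-arm definitions; real analyses should supply their
own arm table matching the reference their pileups were produced on.
"""
from __future__ import annotations

import pandas as pd

# chrom -> (length, centromere midpoint), bp
GENOME_GRCH37: dict[str, tuple[int, int]] = {
    "1": (249_250_621, 125_000_000),
    "2": (243_199_373, 93_300_000),
    "3": (198_022_430, 91_000_000),
    "4": (191_154_276, 50_400_000),
    "5": (180_915_260, 48_400_000),
    "6": (171_115_067, 61_000_000),
    "7": (159_138_663, 59_900_000),
    "8": (146_364_022, 45_600_000),
    "9": (141_213_431, 49_000_000),
    "10": (135_534_747, 40_200_000),
    "11": (135_006_516, 53_700_000),
    "12": (133_851_895, 35_800_000),
    "13": (115_169_878, 17_900_000),
    "14": (107_349_540, 17_600_000),
    "15": (102_531_392, 19_000_000),
    "16": (90_354_753, 36_600_000),
    "17": (81_195_210, 24_000_000),
    "18": (78_077_248, 17_200_000),
    "19": (59_128_983, 26_500_000),
    "20": (63_025_520, 27_500_000),
    "21": (48_129_895, 13_200_000),
    "22": (51_304_566, 14_700_000),
    "X": (155_270_560, 60_600_000),
    "Y": (59_373_566, 12_500_000),
}


def default_arm_table(chroms: list[str] | None = None) -> pd.DataFrame:
    """Arm definitions (1-based inclusive) derived from the built-in genome.

    Columns: chrom, arm, start, end, arm_length.
    """
    rows = []
    for chrom, (length, cen) in GENOME_GRCH37.items():
        if chroms is not None and chrom not in chroms:
            continue
        rows.append((chrom, "p", 1, cen, cen))
        rows.append((chrom, "q", cen + 1, length, length - cen))
    return pd.DataFrame(rows, columns=["chrom", "arm", "start", "end", "arm_length"])
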