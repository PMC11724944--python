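"""Released summary figures for the Korean long-tailed chicken (KLC)
chromosome-level assembly and the 40-assembly Gallus gallus pangenome graph.

These constants are inputs for worked examples and reproduction checks: the
per-chromosome scaffold lengths of the KLC assembly (39 autosomes plus Z),
its headline assembly statistics, and the node/edge/length counts of the
pangenome graph the assembly was integrated into.
"""

from __future__ import annotations

# Chromosome-level scaffold lengths (bp) of the KLC assembly.
KLC_CHROMOSOME_LENGTHS: dict[str, int] = {
    "1": 195_432_966,
    "2": 148_948_886,
    "3": 110_375_418,
    "4": 90_511_606,
    "5": 59_345_498,
    "6": 35_192_565,
    "7": 36_216_801,
    "8": 29_284_060,
    "9": 23_499_132,
    "10": 19_909_730,
    "11": 19_513_749,
    "12": 20_096_594,
    "13": 18_023_899,
    "14": 15_117_088,
    "15": 12_737_682,
    "16": 1_176_078,
    "17": 10_679_723,
    "18": 11_299_519,
    "19": 10_034_254,
    "20": 13_953_091,
    "21": 6_807_633,
    "22": 4_736_118,
    "23": 5_818_881,
    "24": 6_365_640,
    "25": 2_932_729,
    "26": 5_325_154,
    "27": 5_718_884,
    "28": 5_174_667,
    "29": 436_614,
    "30": 970_373,
    "31": 1_572_772,
    "32": 234_640,
    "33": 2_109_227,
    "34": 2_859_599,
    "35": 745_058,
    "36": 367_897,
    "37": 123_200,
    "38": 769_429,
    "39": 192_591,
    "Z": 76_830_679,
}

# Headline KLC assembly statistics.
KLC_GENOME_SIZE: int = 1_023_165_347
KLC_SCAFFOLD_COUNT: int = 304
KLC_CHROMOSOME_SCALE_BP: int = 1_008_187_434

# 40-assembly chicken pangenome graph counts (reference GRCg7b).
PANGENOME_NODE_COUNT: int = 87_934_214
PANGENOME_EDGE_COUNT: int = 121_720_974
PANGENOME_TOTAL_BP: int = 1_709_850_352
PANGENOME_REFERENCE_BP: int = 1_041_122_857
PANGENOME_KLC_NOVEL_BP: int = 1_919_925
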