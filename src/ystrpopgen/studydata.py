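"""Published summary tables from the continent-wide native South American
Y-chromosome survey that this package's analyses reproduce.

Only values printed in the survey's main text live here (the full per-sample
supplementary tables were never deposited in a public archive); they serve as
observed inputs for the association statistics and the migration-scenario
configurations.
"""

import numpy as np

__all__ = [
    "HAPLOGROUP_LANGUAGE_CLASS_COUNTS",
    "LANGUAGE_CLASS_ROWS",
    "HAPLOGROUP_COLS",
    "WAORANI_N",
    "WAORANI_C3_CARRIERS",
    "KICHWA_C3_CARRIERS",
]

#: Haplogroup x language-class cross-tabulation of all 1011 samples.
LANGUAGE_CLASS_ROWS = (
    "Andean",
    "Chibchan-Paezan",
    "Equatorial-Tucanoan",
    "Ge-Pano-Carib",
    "Wao-Tiriro isolate",
)
HAPLOGROUP_COLS = ("C3*", "Q1a3", "Q1a3a", "Q1a3a-del", "Q1a3a1")
HAPLOGROUP_LANGUAGE_CLASS_COUNTS = np.array(
    [
        [11, 5, 150, 0, 0],
        [0, 22, 57, 0, 0],
        [0, 12, 387, 0, 0],
        [0, 19, 296, 6, 6],
        [3, 0, 37, 0, 0],
    ],
    dtype=np.int64,
)

#: The Waorani sample: 40 males from two villages, 3 carrying C3*.
WAORANI_N = 40
WAORANI_C3_CARRIERS = 3
#: Lowland Kichwa C3* carriers (out of the 14 C3* chromosomes in total).
KICHWA_C3_CARRIERS = 11
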