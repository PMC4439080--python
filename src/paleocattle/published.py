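"""Published reference tables for the North-East Baltic Sea region cattle survey.

Printed summary tables from the reference study of ancient N-EBSR cattle
(mtDNA D-loop/ND5 haplotypes and Y-chromosomal UTY19 haplotypes) used as
inputs for re-deriving the downstream statistics: per-cohort diversity
summaries, the 3 x 10 geographical haplotype-group count table, and the
temporal Y1/Y2 count tables.  Only printed counts and summaries are stored
here — everything derived from them (theta_W, Tajima's D, pi, chi-square,
Fisher p) is recomputed by the package.
"""

from __future__ import annotations

import pandas as pd

from .haplotyping import ContingencyTable

#: analysed D-loop fragment length (bp) behind the per-site diversities
DLOOP_LENGTH = 486

#: printed per-cohort mtDNA diversity inputs: N, S, h, Hd, K (D-loop, 486 bp)
COHORT_SUMMARIES = {
    "Prehistoric": {"N": 5, "S": 9, "h": 5, "Hd": 1.000, "K": 3.600},
    "Medieval": {"N": 14, "S": 15, "h": 11, "Hd": 0.956, "K": 3.055},
    "Post-Medieval": {"N": 26, "S": 22, "h": 20, "Hd": 0.972, "K": 2.788},
    "Total": {"N": 45, "S": 33, "h": 29, "Hd": 0.969, "K": 2.951},
}

#: printed derived values (used by tests as frozen expectations, never as inputs)
PRINTED_DERIVED = {
    "Prehistoric": {"theta_s": 4.320, "D": -1.184, "pi_e3": 7.41, "D_significant": False},
    "Medieval": {"theta_s": 4.717, "D": -1.437, "pi_e3": 6.29, "D_significant": False},
    "Post-Medieval": {"theta_s": 5.765, "D": -1.869, "pi_e3": 5.74, "D_significant": True},
    # the printed total-column theta_s (7.736) is inconsistent with S=33, n=45
    # and is deliberately not recorded here; D and pi are
    "Total": {"D": -2.067, "pi_e3": 6.07, "D_significant": True},
}

GEO_REGIONS = [
    "N-EBSR", "Scandinavia", "Western Europe", "Southern Europe",
    "South-Eastern Europe", "Eastern Europe", "Western Russia",
    "Near East and Central Asia", "Central Russia", "Siberia",
]

#: 3 x 10 distribution of haplotype groups in 2094 modern cattle by region
GEO_HAPLOTYPE_COUNTS = ContingencyTable(
    row_labels=["Common H", "Other Ancient H", "H not found in Ancient data"],
    col_labels=list(GEO_REGIONS),
    counts=[
        [31, 23, 93, 334, 8, 13, 16, 4, 12, 14],
        [10, 27, 17, 51, 7, 2, 9, 1, 10, 2],
        [8, 31, 134, 1152, 35, 11, 1, 20, 10, 8],
    ],
)


def _t2x2(rows: list[str], y1: tuple[int, int], y2: tuple[int, int]) -> ContingencyTable:
    return ContingencyTable(rows, ["Y1", "Y2"], [[y1[0], y2[0]], [y1[1], y2[1]]])


#: Fennoscandian temporal Y1/Y2 counts (Y1, Y2) per cohort
Y_FENNOSCANDIA = {
    "Iron Age": (1, 7),
    "Medieval": (1, 36),
    "Post-Medieval": (9, 10),
    "Modern": (33, 8),
}

#: the adjacent-cohort 2x2 comparisons actually tested
Y_TEMPORAL_PAIRS = {
    ("Iron Age", "Medieval"): _t2x2(
        ["Iron Age", "Medieval"], (1, 1), (7, 36)
    ),
    ("Medieval", "Post-Medieval"): _t2x2(
        ["Medieval", "Post-Medieval"], (1, 9), (36, 10)
    ),
    ("Post-Medieval", "Modern"): _t2x2(
        ["Post-Medieval", "Modern"], (9, 33), (10, 8)
    ),
}

#: Swiss Medieval vs modern Y1/Y2 counts
Y_SWISS = _t2x2(["Medieval", "Modern"], (1, 1), (13, 38))

#: printed Fisher/chi-square outcomes (frozen expectations for tests)
PRINTED_TESTS = {
    "geo_chisq": {"statistic": 355.0, "df": 18, "p_bound": 0.001},
    ("Iron Age", "Medieval"): 0.327,
    ("Medieval", "Post-Medieval"): 0.001,  # printed as p < 0.001
    ("Post-Medieval", "Modern"): 0.015,
    "swiss": 0.462,
}

#: temporal mtDNA cohort sizes of the N-EBSR comparison
MT_COHORT_SIZES = {"Prehistoric and Medieval": 19, "Post-Medieval": 26, "Modern": 49}


def cohort_summary_frame() -> pd.DataFrame:
    return pd.DataFrame(COHORT_SUMMARIES).T
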