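"""Published reference inputs and outcome tables for the bundled scenario.

These are the printed summary tables of the U.S. male cigarettes-plus-MST
modified-risk-claim assessment this simulator was designed around: the
behavioural-intention proportions that define the Modified Case, the
headline single-cohort and population comparisons, the published life-table
columns, and the census validation totals. They serve as worked-example
inputs and as frozen expected values for the desk-checkable arithmetic
(relative-percent changes, table aggregations, percent differences); they
are *not* sufficient to re-run the full simulation, whose external rate
tables are not published.
"""

from __future__ import annotations

import pandas as pd

from .statespace import UseCategory
from .transitions import IntentionSummary

__all__ = [
    "INTENTIONS",
    "INTENTION_EDGES",
    "intention_summaries",
    "BASE_SWITCH_RATE",
    "BASE_MST_INITIATION_RATE",
    "ERR_CURRENT",
    "ERR_FORMER",
    "WOULD_BE_SMOKER_FRACTION",
    "WOULD_BE_QUITTER_FRACTION",
    "SINGLE_COHORT_COMPARISON",
    "LIFE_TABLE_COLUMNS",
    "POPULATION_COMPARISON",
    "CENSUS_VALIDATION",
]

#: behavioural-intention proportions (percent of respondents likely to
#: engage in the behaviour, pre/post ad exposure, control vs test)
INTENTIONS = pd.DataFrame(
    [
        ("mst_initiation", 3.06, 2.42, 4.85, 3.65),
        ("switching", 17.73, 15.87, 13.99, 15.13),
        ("dual_uptake", 24.04, 19.90, 17.86, 18.33),
        ("dual_to_mst", 34.14, 32.38, 35.48, 35.57),
    ],
    columns=["behavior", "control_pre", "control_post", "test_pre", "test_post"],
)

#: transition edge each behaviour maps onto
INTENTION_EDGES = {
    "mst_initiation": (UseCategory.NEVER, UseCategory.CUR_MST),
    "switching": (UseCategory.CUR_CIG, UseCategory.CUR_MST),
    "dual_uptake": (UseCategory.CUR_CIG, UseCategory.DUAL),
    "dual_to_mst": (UseCategory.DUAL, UseCategory.CUR_MST),
}


def intention_summaries(frame: pd.DataFrame | None = None) -> dict[str, IntentionSummary]:
    """Behaviour → IntentionSummary from an intention table (default bundled)."""
    if frame is None:
        frame = INTENTIONS
    return {
        r.behavior: IntentionSummary(r.control_pre, r.control_post, r.test_pre, r.test_post)
        for r in frame.itertuples()
    }


# headline scenario constants (per-5-year-step probabilities / dimensionless)
BASE_SWITCH_RATE = 0.014  # current smoker -> exclusive MST
BASE_MST_INITIATION_RATE = 0.016  # never user -> exclusive MST
ERR_CURRENT = 0.09
ERR_FORMER = 0.04
WOULD_BE_SMOKER_FRACTION = 0.01
WOULD_BE_QUITTER_FRACTION = 0.05

#: published single-cohort comparison (1,000,000 males followed from 13):
#: mean survivors and premature deaths prevented with 95% credible interval
SINGLE_COHORT_COMPARISON = pd.DataFrame(
    [
        (43, 954_680, 954_754, 74, 64, 85),
        (48, 931_920, 932_117, 197, 174, 221),
        (53, 902_538, 902_907, 369, 324, 417),
        (58, 865_346, 865_929, 583, 507, 665),
        (63, 817_980, 818_792, 812, 700, 936),
        (68, 756_831, 757_842, 1010, 866, 1169),
        (73, 676_903, 678_023, 1120, 958, 1301),
    ],
    columns=["age", "survivors_base", "survivors_modified", "deaths_prevented", "ci_low", "ci_high"],
)

#: published life-table columns (l_x and T_x per scenario; final row 73+)
LIFE_TABLE_COLUMNS = pd.DataFrame(
    [
        (13, 1_000_000, 59_914_223, 1_000_000, 59_881_367),
        (18, 997_317, 58_912_882, 997_317, 58_880_026),
        (23, 993_963, 53_934_688, 993_963, 53_901_832),
        (28, 989_041, 48_977_188, 989_036, 48_944_346),
        (33, 981_605, 44_050_596, 981_594, 44_017_793),
        (38, 970_653, 39_170_002, 970_627, 39_137_291),
        (43, 954_754, 34_356_594, 954_680, 34_324_134),
        (48, 932_117, 29_639_644, 931_920, 29_607_864),
        (53, 902_907, 25_052_474, 902_538, 25_022_113),
        (58, 865_929, 20_631_030, 865_346, 20_603_055),
        (63, 818_792, 16_420_329, 817_980, 16_395_852),
        (68, 757_842, 12_480_710, 756_831, 12_460_804),
        (73, 678_023, 8_894_749, 676_903, 8_880_185),
    ],
    columns=["age", "l_modified", "T_modified", "l_base", "T_base"],
)

#: published population comparison at the end of the 60-year follow-up:
#: survivors by age band under the Modified and Base Case scenarios
POPULATION_COMPARISON = pd.DataFrame(
    [
        (0, 11_659_500, 11_659_500),
        (5, 11_503_227, 11_503_227),
        (10, 11_343_808, 11_343_808),
        (15, 11_384_863, 11_384_863),
        (20, 11_210_354, 11_210_354),
        (25, 10_975_495, 10_975_342),
        (30, 10_691_665, 10_691_192),
        (35, 10_398_367, 10_397_394),
        (40, 10_101_332, 10_099_412),
        (45, 9_787_295, 9_783_564),
        (50, 9_355_425, 9_348_637),
        (55, 8_757_301, 8_747_530),
        (60, 8_050_922, 8_038_615),
        (65, 7_691_177, 7_676_364),
        (70, 6_889_508, 6_873_894),
        (75, 5_774_009, 5_759_539),
        (80, 4_761_915, 4_749_605),
    ],
    columns=["age_group", "modified", "base"],
)

#: multicohort validation: model total vs census total, 2015 native-born males
CENSUS_VALIDATION = {"model": 140_297_321, "census": 137_187_000}
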