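"""Bundled worked-example data.

The dual-knockout sequencing summary below is the standard worked example
used throughout the documentation and tests: per-sample read totals,
mapped reads, zero-count constructs and threshold coverage for a
52,900-construct dual-guide library (plasmid pool, baseline triplicate,
and day-28 triplicate).
"""

from __future__ import annotations

import pandas as pd

CDKO_LIBRARY_SIZE = 52900

_CDKO_SEQ_ROWS = [
    # sample, total_reads, mapped_reads, mapped_pct, zero_count, zero_pct,
    # gini, above_threshold_count, above_threshold_pct
    ("Library/Plasmid", 9_272_549, 8_159_448, 88.00, 141, 0.27, 0.05, 48_921, 92.48),
    ("T0_1", 12_431_419, 11_383_720, 91.57, 892, 1.69, 0.06, 47_101, 89.04),
    ("T0_2", 15_647_051, 14_281_485, 91.27, 722, 1.36, 0.06, 47_669, 90.11),
    ("T0_3", 15_104_601, 13_610_181, 90.11, 1371, 2.59, 0.05, 47_547, 89.88),
    ("Tend_1", 10_004_498, 9_114_027, 91.10, 109, 0.21, 0.05, 50_658, 95.76),
    ("Tend_2", 15_386_447, 13_994_094, 90.95, 48, 0.09, 0.05, 51_875, 98.06),
    ("Tend_3", 15_837_762, 14_264_603, 90.07, 39, 0.07, 0.05, 51_866, 98.05),
]


def cdko_sequencing_stats() -> pd.DataFrame:
    """Worked-example sequencing summary of a 52,900-construct CDKO screen.

    Columns mirror a screen sequencing report: ``total_reads``,
    ``mapped_reads`` and the derived percentages, per-sample zero-count
    constructs, the Gini index of the count distribution, and the number of
    constructs above the read threshold.  The integer columns are inputs;
    the percentage columns are the published two-decimal values the QC
    functions reproduce exactly.
    """
    frame = pd.DataFrame(
        _CDKO_SEQ_ROWS,
        columns=[
            "sample_id",
            "total_reads",
            "mapped_reads",
            "mapped_pct",
            "zero_count",
            "zero_pct",
            "gini",
            "above_threshold_count",
            "above_threshold_pct",
        ],
    ).set_index("sample_id")
    return frame
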