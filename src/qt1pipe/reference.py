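"""Reference regional case-control statistics for single-echo cortical qT1.

The published regional table from the case-control study this pipeline
models (14 SSD patients vs 7 controls): per cortical ROI, the SSD - HC
mean qT1 difference with its standard error, the reported Cohen's d with
its standard error, and the FDR-adjusted p-value. These numbers are input
data for the effect-size arithmetic checks: given the printed difference
and SE, d and SE(d) must be recoverable from

    d = (diff / SE) * sqrt(1/n1 + 1/n2)
    SE(d) = sqrt((n1 + n2)/(n1 n2) + d^2 / (2 (n1 + n2)))

``d_decimals`` records the precision each d was printed at (0.9 and 1.3
carry one decimal, the rest two).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["N_SSD", "N_HC", "case_control_table"]

N_SSD = 14
N_HC = 7

_ROWS = [
    # roi_name, hemisphere, mean_diff, diff_se, d, d_decimals, d_se, p_fdr
    ("temporalpole",        "right", 171.05, 87.30, 0.90, 1, 0.48, 0.037),
    ("superiorparietal",    "right", 120.54, 43.06, 1.30, 1, 0.50, 0.021),
    ("inferiorparietal",    "right",  80.76, 36.58, 1.02, 2, 0.49, 0.037),
    ("parstriangularis",    "right",  95.31, 49.95, 0.88, 2, 0.48, 0.037),
    ("parsorbitalis",       "right", 110.80, 63.16, 0.81, 2, 0.48, 0.037),
    ("precuneus",           "right",  81.76, 27.55, 1.37, 2, 0.51, 0.021),
    ("cuneus",              "right",  85.90, 25.05, 1.59, 2, 0.52, 0.021),
    ("superiorparietal",    "left",   88.93, 44.45, 0.93, 2, 0.48, 0.049),
    ("parstriangularis",    "left",   82.00, 43.03, 0.88, 2, 0.48, 0.049),
    ("parsorbitalis",       "left",  158.38, 58.21, 1.26, 2, 0.50, 0.049),
    ("parsopercularis",     "left",   56.23, 43.88, 0.59, 2, 0.47, 0.049),
    ("paracentral",         "left",   73.79, 41.29, 0.83, 2, 0.48, 0.049),
    ("medialorbitofrontal", "left",   72.12, 56.78, 0.59, 2, 0.47, 0.049),
]


def case_control_table() -> pd.DataFrame:
    """The 13-row reference table as a DataFrame (one row per significant ROI)."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "roi_name", "hemisphere", "mean_diff", "diff_se",
            "d_printed", "d_decimals", "d_se_printed", "p_fdr",
        ],
    )
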