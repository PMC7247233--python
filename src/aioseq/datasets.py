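"""Bundled worked example: the 14-rice-library AIO-seq pooling worksheet.

Two groups of seven rice whole-genome libraries (A and B) were pooled with
equal expected yields — 20.0 ng of target region per library — size-selected
once per group, and sequenced.  The worksheet records, per library: the
whole-library concentration (ng/µL), the percent of library mass in the
420–520 bp window, the published TRC and pipetting volume (both displayed at
2 dp), and the demultiplexed data yield (Gb).

Group-level summaries for the larger published pooling experiments are also
bundled (mean ± SD yields, lane totals, CVs, RE tallies) so that the yield
statistics can be exercised without the per-sample supplementary tables.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["rice_pool_worksheet", "group_summaries", "EQUAL_WEIGHT_MASS_NG"]

EQUAL_WEIGHT_MASS_NG = 20.0

# group, sample, conc (ng/µL), target %, published TRC, published volume (µL),
# demultiplexed yield (Gb)
_WORKSHEET = [
    ("A", 1, 21.00, 11, 2.31, 8.66, 6.38),
    ("A", 2, 25.60, 13, 3.33, 6.01, 6.02),
    ("A", 3, 19.60, 13, 2.55, 7.85, 7.20),
    ("A", 4, 20.40, 12, 2.45, 8.17, 6.97),
    ("A", 5, 24.80, 13, 3.22, 6.20, 7.03),
    ("A", 6, 22.20, 12, 2.66, 7.51, 6.50),
    ("A", 7, 24.20, 12, 2.90, 6.89, 6.74),
    ("B", 1, 20.20, 10, 2.02, 9.90, 5.79),
    ("B", 2, 25.80, 13, 3.35, 5.96, 5.88),
    ("B", 3, 22.00, 12, 2.64, 7.58, 6.44),
    ("B", 4, 24.60, 12, 2.95, 6.78, 5.95),
    ("B", 5, 21.40, 13, 2.78, 7.19, 5.46),
    ("B", 6, 24.60, 13, 3.20, 6.25, 5.96),
    ("B", 7, 26.20, 13, 3.41, 5.87, 5.74),
]


def rice_pool_worksheet() -> pd.DataFrame:
    """The 14-library pooling worksheet as a DataFrame.

    ``published_trc`` / ``published_volume`` are the worksheet's displayed
    values; recompute them with :mod:`aioseq.pooling` from ``conc`` and
    ``target_pct`` to reproduce the worksheet.
    """
    return pd.DataFrame(
        _WORKSHEET,
        columns=[
            "group",
            "sample",
            "conc",
            "target_pct",
            "published_trc",
            "published_volume",
            "yield_gb",
        ],
    )


# Published group-level summaries of demultiplexed yields.
# n: libraries pooled; lane_total: Gb sequenced; mean/sd: per-sample yield Gb;
# cv_pct: published CV; n_re_lt_10 / n_re_gt_25: samples with relative error
# < 10% / > 25% of the equal-share expectation.
_GROUPS = {
    "A": dict(n=7, lane_total=46.8, mean=6.7, sd=0.39, cv_pct=5.8,
              n_re_lt_10=6, n_re_gt_25=0),
    "B": dict(n=7, lane_total=41.2, mean=5.9, sd=0.27, cv_pct=4.7,
              n_re_lt_10=7, n_re_gt_25=0),
    "C": dict(n=30, lane_total=135.0, mean=4.5, sd=0.38, cv_pct=8.4,
              n_re_lt_10=26, n_re_gt_25=2),
    "D": dict(n=55, lane_total=128.1, mean=2.3, sd=0.25, cv_pct=10.6,
              n_re_lt_10=37, n_re_gt_25=2),
    # group E pooled 6 maize at 5× the yield of each of 26 rice libraries
    "E_maize": dict(n=6, lane_total=None, mean=0.21, sd=0.03, cv_pct=13.9,
                    n_re_lt_10=3, n_re_gt_25=0),
    "E_rice": dict(n=26, lane_total=None, mean=0.04, sd=0.004, cv_pct=9.5,
                   n_re_lt_10=20, n_re_gt_25=0),
}


def group_summaries() -> pd.DataFrame:
    """Published group summaries, one row per pooled group."""
    df = pd.DataFrame.from_dict(_GROUPS, orient="index")
    df.index.name = "group"
    return df.reset_index()
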