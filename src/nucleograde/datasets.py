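"""Reference values shipped with the package.

The table below reproduces the published per-feature screening results
of a 22 low-grade vs 22 high-grade CIN biopsy cohort (the study design
this package implements): the 22 of 63 features whose two-group Wilcoxon
test reached the 5% level, with the FDR-adjusted p-value, point-biserial
correlation against the grade label, and per-group mean and standard
error, at the precision at which they were reported.  The clinical
images themselves are not publicly deposited, so these rows serve as
arithmetic anchors (e.g. for checking the Benjamini-Hochberg step-up
over m = 63 tests), not as a regeneratable fixture.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # feature, p_raw, p_adj, r_pb, mean_low, se_low, mean_high, se_high
    ("dwt2d_mean_absolute_deviation", 4.48e-2, 1.34e-1, -0.34, 6.23, 0.13, 5.50, 0.28),
    ("dwt2h_mean_absolute_deviation", 2.02e-3, 1.82e-2, -0.39, 10.44, 0.24, 8.67, 0.59),
    ("dwt2h_mean_value", 6.25e-3, 3.03e-2, 0.27, -0.84, 0.029, -0.68, 0.080),
    ("dwt2h_median_absolute_deviation", 7.20e-3, 3.24e-2, -0.33, 1.17, 0.065, 0.95, 0.072),
    ("dwt2h_median_value", 5.03e-5, 3.17e-3, 0.18, -0.014, 0.0024, -0.0079, 0.0048),
    ("dwt2h_standard_deviation", 2.50e-2, 7.87e-2, -0.31, 23.33, 0.39, 20.80, 1.10),
    ("gray_level_nonuniformity", 2.02e-3, 2.13e-2, 0.52, 85.21, 1.98, 116.83, 7.71),
    ("kurtosis", 2.98e-3, 2.35e-2, 0.37, 2.59, 0.02, 2.71, 0.04),
    ("local_binary_pattern_mean_value", 1.02e-2, 3.77e-2, 0.40, 16.61, 0.23, 18.03, 0.45),
    ("local_binary_pattern_standard_deviation", 1.37e-4, 4.30e-3, -0.47, 0.12, 0.00082, 0.12, 0.0014),
    ("nucleus_area", 7.20e-3, 3.02e-2, 0.46, 1141.0, 50.0, 1640.0, 137.0),
    ("nucleus_convex_area", 8.27e-3, 3.26e-2, 0.45, 1253.0, 53.0, 1772.0, 147.0),
    ("nucleus_equivalent_diameter", 5.03e-3, 2.64e-2, 0.47, 36.53, 0.78, 43.59, 1.85),
    ("nucleus_extent", 5.00e-2, 1.43e-1, 0.22, 0.64, 0.0045, 0.66, 0.0079),
    ("nucleus_major_axis_length", 1.16e-2, 4.07e-2, 0.37, 52.6, 1.7, 60.1, 2.3),
    ("nucleus_minor_axis_length", 3.75e-3, 2.36e-2, 0.47, 28.0, 0.5, 34.1, 1.7),
    ("nucleus_perimeter", 1.24e-2, 4.12e-2, 0.40, 135.9, 3.2, 156.6, 6.4),
    ("nucleus_solidity", 1.37e-4, 2.87e-3, 0.52, 0.91, 0.0027, 0.93, 0.0037),
    ("tamura_coarseness_1", 1.15e-3, 1.81e-2, 0.45, 7.12, 0.12, 8.01, 0.24),
    ("tamura_coarseness_2", 4.04e-3, 2.31e-2, 0.48, 23.88, 0.57, 33.99, 2.77),
    ("tamura_coarseness_3", 2.98e-3, 2.09e-2, 0.45, 9.11, 0.37, 14.27, 1.51),
    ("tamura_coarseness_4", 1.73e-3, 2.18e-2, 0.49, 18.21, 0.70, 23.94, 1.40),
]

#: Number of features screened in the reference study.
REFERENCE_M_TESTS = 63


def reference_screening_table() -> pd.DataFrame:
    """The published 22-row significant-feature screening table."""
    return pd.DataFrame(
        _ROWS,
        columns=["feature", "p_raw", "p_adj", "r_pb",
                 "mean_low", "se_low", "mean_high", "se_high"],
    )
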