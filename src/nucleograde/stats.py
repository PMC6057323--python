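"""Per-feature two-group screening.

For each of the 63 features: a two-sided Wilcoxon rank-sum
(Mann-Whitney) test between the low- and high-grade patient groups, a
point-biserial correlation of the feature with the 0/1 grade label
(positive r = higher values in high grade), Benjamini-Hochberg step-up
FDR adjustment across the m = 63 tests, and per-group mean and standard
error (sample SD / sqrt(n)) -- the schema of the published screening
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .cohort import CohortTable
from .features import FEATURE_NAMES

REPORT_COLUMNS = ("feature", "p_raw", "p_adj", "r_pb",
                  "mean_low", "se_low", "mean_high", "se_high")

#: Largest combined sample size for which the exact rank-sum null
#: distribution is enumerated (ties force the normal approximation).
EXACT_LIMIT = 25


def wilcoxon_ranksum(x, y) -> float:
    """Two-sided p-value of the rank-sum test for two independent samples.

    Exact enumeration when ``len(x) + len(y) <= 25`` and there are no
    ties; otherwise the normal approximation with mid-ranks, tie
    correction and continuity correction.  Identical constant samples
    give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_LIMIT and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(min(res.pvalue, 1.0))


def point_biserial(values, labels) -> float:
    """Pearson correlation between a feature and the 0/1 group label.

    Returns 0 for a zero-variance feature (degenerate case).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(labels, dtype=float)
    if v.shape != g.shape:
        raise ValueError("values and labels must have equal length")
    if not (np.any(g == 0) and np.any(g == 1)):
        raise ValueError("both groups must be present")
    sv = v.std()
    sg = g.std()
    if sv == 0 or sg == 0:
        return 0.0
    return float(np.mean((v - v.mean()) * (g - g.mean())) / (sv * sg))


def bh_fdr(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adjusted_(i) = min_{j >= i} (m * p_(j) / j)`` capped at 1, mapped
    back to the input order.  ``m`` defaults to the number of supplied
    p-values but may be set larger when the list is a subset of a wider
    screen (e.g. the significant rows of a 63-feature comparison).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else int(m)
    if m < p.size:
        raise ValueError("m cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@dataclass
class ScreeningReport:
    """Result of :func:`compare_groups`: one row per feature, sorted
    alphabetically by feature name."""

    rows: pd.DataFrame = field(repr=False)
    alpha: float = 0.05
    m_tests: int = 63

    @property
    def significant_raw(self) -> list[str]:
        sub = self.rows[self.rows["p_raw"] < self.alpha]
        return sub["feature"].tolist()

    @property
    def significant_adj(self) -> list[str]:
        sub = self.rows[self.rows["p_adj"] < self.alpha]
        return sub["feature"].tolist()


def compare_groups(cohort: CohortTable, alpha: float = 0.05,
                   m_tests: int | None = None) -> ScreeningReport:
    """Screen all 63 features between the two patient groups.

    Features with fewer than two defined values in either group are
    reported with missing statistics and excluded from the FDR
    adjustment denominator only if absent (m defaults to the number of
    tested features, normally 63).
    """
    n_low, n_high = cohort.group_sizes
    if n_low < 2 or n_high < 2:
        raise ValueError("need >= 2 patients per group")
    low = cohort.X[cohort.y == 0]
    high = cohort.X[cohort.y == 1]

    records = []
    for name in FEATURE_NAMES:
        a = low[name].dropna().to_numpy()
        b = high[name].dropna().to_numpy()
        rec = {"feature": name, "p_raw": np.nan, "r_pb": np.nan,
               "mean_low": np.nan, "se_low": np.nan,
               "mean_high": np.nan, "se_high": np.nan}
        if a.size:
            rec["mean_low"] = a.mean()
            rec["se_low"] = a.std(ddof=1) / np.sqrt(a.size) if a.size > 1 else np.nan
        if b.size:
            rec["mean_high"] = b.mean()
            rec["se_high"] = b.std(ddof=1) / np.sqrt(b.size) if b.size > 1 else np.nan
        if a.size >= 2 and b.size >= 2:
            rec["p_raw"] = wilcoxon_ranksum(a, b)
            vals = np.concatenate([a, b])
            labels = np.concatenate([np.zeros(a.size), np.ones(b.size)])
            rec["r_pb"] = point_biserial(vals, labels)
        records.append(rec)

    frame = pd.DataFrame(records).sort_values("feature", kind="stable").reset_index(drop=True)
    tested = frame["p_raw"].notna()
    m = int(m_tests) if m_tests is not None else int(tested.sum())
    frame["p_adj"] = np.nan
    if tested.any():
        frame.loc[tested, "p_adj"] = bh_fdr(frame.loc[tested, "p_raw"].to_numpy(), m=m)
    frame = frame[list(REPORT_COLUMNS)]
    return ScreeningReport(rows=frame, alpha=alpha, m_tests=m)


class GroupScreen(BaseEstimator):
    """Estimator-style interface to :func:`compare_groups`.

    ``fit(X, y)`` accepts a patients-by-features DataFrame (or array)
    and 0/1 group labels; fitted attributes expose the report.
    """

    def __init__(self, alpha: float = 0.05, m_tests: int | None = None):
        self.alpha = alpha
        self.m_tests = m_tests

    def fit(self, X, y):
        if isinstance(X, CohortTable):
            cohort = X
        else:
            frame = pd.DataFrame(X)
            if frame.shape[1] == len(FEATURE_NAMES):
                frame.columns = list(FEATURE_NAMES)
            cohort = CohortTable(X=frame, y=pd.Series(np.asarray(y), index=frame.index, name="group"))
        report = compare_groups(cohort, alpha=self.alpha, m_tests=self.m_tests)
        self.results_ = report.rows
        self.significant_raw_ = report.significant_raw
        self.significant_adj_ = report.significant_adj
        self.m_tests_ = report.m_tests
        self.n_features_in_ = cohort.X.shape[1]
        return self

    def report(self) -> ScreeningReport:
        return ScreeningReport(rows=self.results_, alpha=self.alpha, m_tests=self.m_tests_)
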