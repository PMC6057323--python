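import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from nucleograde.cohort import CohortTable
from nucleograde.features import FEATURE_NAMES
from nucleograde.stats import (
    GroupScreen, bh_fdr, compare_groups, point_biserial, wilcoxon_ranksum,
)
import oracles


class TestWilcoxon:
    def test_disjoint_triples_exact(self):
        assert wilcoxon_ranksum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_constant_samples(self):
        assert wilcoxon_ranksum([5, 5, 5], [5, 5, 5]) == 1.0

    def test_same_sample_symmetric_null(self):
        x = [1.0, 2.5, 7.0, 9.0]
        assert wilcoxon_ranksum(x, x) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 4), (5, 5), (4, 2)])
    def test_exact_path_matches_enumeration(self, rng, n1, n2):
        for _ in range(10):
            pooled = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
            x, y = pooled[:n1], pooled[n1:]
            assert wilcoxon_ranksum(x, y) == pytest.approx(
                oracles.wilcoxon_exact_oracle(x, y), abs=1e-12)

    def test_large_sample_asymptotic_reasonable(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(2, 1, 30)
        assert wilcoxon_ranksum(x, y) < 1e-6


class TestPointBiserial:
    def test_perfect_separation(self):
        assert point_biserial([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_equal_group_means(self):
        assert point_biserial([1, 2, 1, 2], [0, 0, 1, 1]) == pytest.approx(0.0)

    def test_hand_example(self):
        assert point_biserial([1, 2, 3, 4], [0, 0, 1, 1]) == pytest.approx(0.8944, abs=1e-4)

    def test_zero_variance_degenerate(self):
        assert point_biserial([7, 7, 7, 7], [0, 0, 1, 1]) == 0.0

    def test_matches_scipy(self, rng):
        for _ in range(10):
            v = rng.normal(size=12)
            g = rng.integers(0, 2, size=12)
            if g.min() == g.max():
                continue
            assert point_biserial(v, g) == pytest.approx(
                sps.pointbiserialr(g, v).correlation, abs=1e-12)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_textbook_formula_identity(self, values):
        n = len(values)
        labels = np.array([0, 1] * (n // 2) + [0] * (n % 2))
        v = np.asarray(values)
        if v.std() == 0:
            return
        n1, n0 = labels.sum(), n - labels.sum()
        m1, m0 = v[labels == 1].mean(), v[labels == 0].mean()
        textbook = (m1 - m0) / v.std() * np.sqrt(n1 * n0 / n ** 2)
        assert point_biserial(v, labels) == pytest.approx(textbook, abs=1e-12)


class TestBHFDR:
    def test_hand_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_rank_one_with_wider_screen(self):
        # smallest of 63 tests: adjusted = 63 * p
        assert bh_fdr([5.03e-5], m=63)[0] == pytest.approx(3.1689e-3, rel=1e-4)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(size=63)
        ours = bh_fdr(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([])
        with pytest.raises(ValueError):
            bh_fdr([0.1, 0.2], m=1)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=80))
    @settings(deadline=None, max_examples=80)
    def test_monotone_and_idempotent(self, p):
        adj = bh_fdr(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        # sorted by raw p, adjusted values are nondecreasing
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)
        # re-application can only move values further up (the step-up is
        # inflationary and monotone, though not idempotent in general)
        assert np.all(bh_fdr(adj) >= adj - 1e-15)


def make_cohort(rng, n_per_group=8, shift=None):
    """Gaussian patient table with an optional per-feature mean shift in
    the high-grade group."""
    rows = []
    for g in (0, 1):
        for i in range(n_per_group):
            vec = rng.normal(0, 1, len(FEATURE_NAMES))
            if g == 1 and shift:
                for name, s in shift.items():
                    vec[FEATURE_NAMES.index(name)] += s
            rows.append((f"g{g}p{i}", g, vec))
    X = pd.DataFrame([r[2] for r in rows], columns=list(FEATURE_NAMES),
                     index=pd.Index([r[0] for r in rows], name="patient_id"))
    y = pd.Series([r[1] for r in rows], index=X.index, name="group")
    return CohortTable(X=X, y=y)


class TestCompareGroups:
    def test_report_schema(self, rng):
        report = compare_groups(make_cohort(rng))
        assert len(report.rows) == 63
        assert list(report.rows["feature"]) == sorted(FEATURE_NAMES)
        assert report.m_tests == 63
        assert (report.rows["p_adj"] >= report.rows["p_raw"] - 1e-15).all()

    def test_constant_feature_not_significant(self, rng):
        cohort = make_cohort(rng)
        cohort.X["kurtosis"] = 3.0
        report = compare_groups(cohort)
        row = report.rows[report.rows["feature"] == "kurtosis"].iloc[0]
        assert row["p_raw"] == 1.0
        assert "kurtosis" not in report.significant_raw

    def test_planted_shift_detected(self, rng):
        cohort = make_cohort(rng, n_per_group=22, shift={"nucleus_area": 2.5})
        report = compare_groups(cohort)
        assert "nucleus_area" in report.significant_adj
        row = report.rows[report.rows["feature"] == "nucleus_area"].iloc[0]
        assert row["r_pb"] > 0
        assert row["mean_high"] > row["mean_low"]

    def test_missing_patient_values_pairwise_deleted(self, rng):
        cohort = make_cohort(rng)
        cohort.X.loc[cohort.X.index[0], "skewness"] = np.nan
        report = compare_groups(cohort)
        assert len(report.rows) == 63
        assert np.isfinite(report.rows.set_index("feature").loc["skewness", "p_raw"])

    def test_group_size_guard(self, rng):
        cohort = make_cohort(rng, n_per_group=1)
        with pytest.raises(ValueError):
            compare_groups(cohort)

    def test_se_is_sd_over_sqrt_n(self, rng):
        cohort = make_cohort(rng)
        report = compare_groups(cohort)
        row = report.rows.set_index("feature").loc["entropy"]
        vals = cohort.X.loc[cohort.y == 0, "entropy"]
        assert row["se_low"] == pytest.approx(vals.std(ddof=1) / np.sqrt(len(vals)))


class TestGroupScreen:
    def test_sklearn_interface(self, rng):
        cohort = make_cohort(rng)
        screen = GroupScreen(alpha=0.05).fit(cohort.X, cohort.y)
        assert screen.results_.shape[0] == 63
        assert screen.m_tests_ == 63
        assert screen.get_params()["alpha"] == 0.05
        clone_params = GroupScreen(**screen.get_params())
        assert clone_params.alpha == screen.alpha
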