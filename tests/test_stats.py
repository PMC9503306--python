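"""Cohort statistics against direct-formula and enumeration oracles."""

import numpy as np
import pytest
from scipy.stats import chi2

from ccfd import (
    EyeRecord,
    FDReport,
    ScanGeometry,
    ValidationError,
    fd_regression,
    kruskal_wallis,
    mann_whitney,
    welch_t,
)

from oracles import kruskal_h_oracle, mann_whitney_exact_oracle, welch_oracle

GEOM = ScanGeometry(6.0, 6.0, 100, 100)


def _record(eye_id, group, fd_percent, covariates=None):
    n_px = fd_percent / 100 * 10000
    reports = {
        r: FDReport(
            fd_percent=fd_percent, fd_count=10,
            fd_mean_size_um2=n_px * GEOM.pixel_area_um2 / 10,
            fd_total_area_mm2=n_px * GEOM.pixel_area_um2 / 1e6,
            radius_px=r, geometry=GEOM,
        )
        for r in (4, 8)
    }
    return EyeRecord(eye_id, group, reports, covariates)


class TestKruskalWallis:
    def test_identical_groups_no_separation(self):
        res = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_rank_formula_oracle(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        res = kruskal_wallis(groups)
        h = kruskal_h_oracle(groups)
        assert h == pytest.approx(32 / 7)
        assert res.statistic == pytest.approx(h)
        assert res.p_value == pytest.approx(chi2.sf(h, df=2))

    def test_invariant_under_group_relabeling(self):
        groups = [[1.0, 4.0, 7.0], [2.0, 5.0, 8.0], [3.0, 6.0, 9.0]]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([groups[2], groups[0], groups[1]]).statistic
        assert h1 == pytest.approx(h2)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1], [2, 3], [4, 5]])


class TestMannWhitney:
    def test_exact_p_for_fully_separated_triplets(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        u, p = mann_whitney_exact_oracle([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)
        assert res.statistic == 0
        assert res.p_value == pytest.approx(0.1)
        assert "exact" in res.test

    def test_identical_multisets_p_one(self):
        res = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3])
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_symmetry_under_swap(self):
        a, b = [1.2, 3.4, 2.2, 9.9], [0.5, 4.4, 6.1]
        assert mann_whitney(a, b).p_value == pytest.approx(mann_whitney(b, a).p_value)

    def test_exact_branch_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            a = rng.permutation(np.arange(1.0, 13.0))[:5]
            b = np.setdiff1d(np.arange(1.0, 13.0), a)[:5]
            res = mann_whitney(list(a), list(b))
            _, p = mann_whitney_exact_oracle(list(a), list(b))
            assert res.p_value == pytest.approx(p)

    def test_large_samples_use_normal_approximation(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        res = mann_whitney(a, b)
        assert "asymptotic" in res.test
        assert 0 <= res.p_value <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1, 2])


class TestWelchT:
    def test_identical_groups_t_zero_p_one(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        a, b = [1, 2, 3], [1, 2, 3, 4, 5]
        res = welch_t(a, b)
        t, df = welch_oracle(a, b)
        assert res.statistic == pytest.approx(t)
        assert t == pytest.approx(-1 / np.sqrt(5 / 6))
        assert df == pytest.approx(5.882352941)

    def test_scale_invariance(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 5.0, 9.0]
        r1 = welch_t(a, b)
        r2 = welch_t([10 * x for x in a], [10 * x for x in b])
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_degenerate_variances(self):
        assert welch_t([2, 2, 2], [2, 2, 2]).p_value == 1.0
        with pytest.raises(ValidationError):
            welch_t([2, 2, 2], [3, 3, 3])


class TestRegression:
    COVS = ("age", "treatment_duration", "daily_dose_mg_per_kg", "cumulative_dose_g")

    def _cohort(self, rng, n, slope_age=0.0, noise=0.0):
        records = []
        for i in range(n):
            cov = {
                "age": rng.uniform(30, 80),
                "treatment_duration": rng.uniform(1, 20),
                "daily_dose_mg_per_kg": rng.uniform(3, 7),
                "cumulative_dose_g": rng.uniform(500, 3000),
            }
            fd = 40.0 + slope_age * cov["age"] + noise * rng.standard_normal()
            records.append(_record(f"e{i}", "1a", float(np.clip(fd, 0, 100)), cov))
        return records

    def test_noiseless_linear_recovery(self, rng):
        records = self._cohort(rng, 30, slope_age=0.2, noise=0.0)
        table = fd_regression(records, "fd_percent", 4)
        assert table.loc["age", "estimate"] == pytest.approx(0.2, abs=1e-9)
        assert table.loc["age", "p_value"] < 1e-12

    def test_null_covariates_rarely_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            records = self._cohort(rng, 200, slope_age=0.0, noise=5.0)
            table = fd_regression(records, "fd_percent", 8)
            if (table.loc[list(self.COVS), "p_value"] > 0.01).all():
                hits += 1
        assert hits >= 9

    def test_duplicate_covariate_is_singularity_error(self, rng):
        records = []
        for i in range(12):
            age = rng.uniform(30, 80)
            cov = {"age": age, "treatment_duration": rng.uniform(1, 20),
                   "daily_dose_mg_per_kg": rng.uniform(3, 7),
                   "cumulative_dose_g": age}  # exact duplicate of age
            records.append(_record(f"e{i}", "1a", 40.0, cov))
        with pytest.raises(ValidationError, match="collinear"):
            fd_regression(records, "fd_percent", 4)

    def test_too_few_records_rejected(self, rng):
        with pytest.raises(ValidationError):
            fd_regression(self._cohort(rng, 4), "fd_percent", 4)

    def test_missing_covariates_rejected(self):
        rec = _record("e0", "1a", 40.0, {"age": 50.0})
        with pytest.raises(ValidationError, match="missing"):
            fd_regression([rec] * 10, "fd_percent", 4)
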