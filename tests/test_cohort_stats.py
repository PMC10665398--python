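"""Cohort statistics: formula oracles, calibration, and analysis chain."""

import numpy as np
import pytest
import scipy.stats as st
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as hst

from stiffwave import (
    CohortConfig,
    OUT_OF_RANGE,
    PowerSpec,
    SubjectRecord,
    bland_altman,
    fit_regression,
    gen_cohort,
    grubbs_outliers,
    parallel_lines_test,
    pearson,
    required_sample_size,
    run_cohort_analysis,
)
from stiffwave.cohort_stats import grubbs_critical_value, regression_f_power


class TestPearson:
    def test_exact_linear_relationships(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -3 * x)[0] == pytest.approx(-1.0)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_p_value_matches_permutation_oracle(self, rng):
        n = 12
        x = rng.normal(size=n)
        y = 0.8 * x + rng.normal(size=n)
        r, p = pearson(x, y)
        xc = x - x.mean()
        perm = np.argsort(rng.random((100_000, n)), axis=1)
        yp = (y - y.mean())[perm]
        r_perm = (yp @ xc) / np.sqrt((xc @ xc) * np.sum(yp[0] ** 2))
        p_perm = np.mean(np.abs(r_perm) >= abs(r) - 1e-12)
        se = np.sqrt(p_perm * (1 - p_perm) / 100_000)
        assert abs(p - p_perm) < max(4 * se, 0.003)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(a=hst.floats(0.1, 10.0), b=hst.floats(-5.0, 5.0))
    def test_affine_invariance_and_sign_flip(self, a, b):
        rng = np.random.default_rng(17)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r0 = pearson(x, y)[0]
        assert pearson(a * x + b, y)[0] == pytest.approx(r0, abs=1e-9)
        assert pearson(-a * x + b, y)[0] == pytest.approx(-r0, abs=1e-9)


class TestFitRegression:
    def test_exact_line_is_recovered(self):
        x = np.array([10.0, 30.0, 50.0, 70.0])
        y = -0.27 * x + 28.81
        slope, intercept, pred, resid_sd = fit_regression(x, y)
        assert slope == pytest.approx(-0.27)
        assert intercept == pytest.approx(28.81)
        assert np.allclose(pred, y)
        assert resid_sd == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self, rng):
        x = rng.uniform(10, 80, 25)
        y = rng.normal(size=25)
        slope, intercept, _, _ = fit_regression(x, y)
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        assert slope == pytest.approx(sxy / sxx, rel=1e-10)
        assert intercept == pytest.approx(y.mean() - sxy / sxx * x.mean(),
                                          rel=1e-10)

    def test_constant_x_raises(self):
        with pytest.raises(ValueError):
            fit_regression([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


class TestGrubbs:
    def test_symmetric_triple_is_clean(self):
        assert grubbs_outliers([-1.0, 0.0, 1.0]) == []
        assert grubbs_critical_value(3) == pytest.approx(1.1543, abs=1e-4)

    def test_gross_outlier_is_flagged(self):
        assert grubbs_outliers([0.0, 0.1, -0.1, 0.05, 100.0]) == [4]

    def test_iterative_removal_finds_second_outlier(self):
        base = list(np.linspace(-1, 1, 18))
        flagged = grubbs_outliers(base + [40.0, -35.0])
        assert set(flagged) == {18, 19}

    def test_zero_sd_warns_and_flags_nothing(self):
        with pytest.warns(UserWarning):
            assert grubbs_outliers([2.0, 2.0, 2.0, 2.0]) == []


class TestParallelLines:
    def test_identical_datasets_do_not_reject(self, rng):
        x = rng.uniform(10, 80, 20)
        y = -0.27 * x + 28.81 + rng.normal(0, 5, 20)
        p_slope, p_intercept = parallel_lines_test(x, y, x, y)
        assert p_slope == pytest.approx(1.0, abs=1e-6)
        assert p_intercept == pytest.approx(1.0, abs=1e-6)

    def test_opposite_slopes_are_separated(self, rng):
        x = np.linspace(0, 10, 20)
        noise = rng.normal(0, 1e-6, 20)
        p_slope, _ = parallel_lines_test(x, x + noise, x, -x + noise)
        assert p_slope < 1e-6

    def test_matches_statsmodels_ancova(self, rng):
        x1 = rng.uniform(10, 80, 15)
        y1 = -0.3 * x1 + 30 + rng.normal(0, 5, 15)
        x2 = rng.uniform(10, 80, 18)
        y2 = -0.2 * x2 + 25 + rng.normal(0, 5, 18)
        p_slope, p_intercept = parallel_lines_test(x1, y1, x2, y2)
        x = np.concatenate([x1, x2])
        y = np.concatenate([y1, y2])
        g = np.concatenate([np.zeros(15), np.ones(18)])
        full = sm.OLS(y, sm.add_constant(
            np.column_stack([x, g, x * g]))).fit()
        reduced = sm.OLS(y, sm.add_constant(
            np.column_stack([x, g]))).fit()
        assert p_slope == pytest.approx(full.pvalues[3], rel=1e-8)
        assert p_intercept == pytest.approx(reduced.pvalues[2], rel=1e-8)

    def test_degenerate_design_raises(self):
        with pytest.raises(ValueError):
            parallel_lines_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0],
                                [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_perfect_agreement(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0.0 and res.precision == 0.0

    def test_constant_offset(self):
        res = bland_altman([3.0, 4.0, 5.0], [1.0, 2.0, 3.0])
        assert res.bias == pytest.approx(2.0)
        assert res.sd == pytest.approx(0.0, abs=1e-12)

    def test_matches_formula_oracle(self, rng):
        p = rng.normal(size=29)
        m = rng.normal(size=29)
        res = bland_altman(p, m)
        d = p - m
        assert res.bias == pytest.approx(d.mean())
        assert res.sd == pytest.approx(d.std(ddof=1))
        assert res.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
        assert res.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        assert res.precision == pytest.approx(1.96 * d.std(ddof=1))
        assert res.loa_high - res.bias == pytest.approx(res.bias - res.loa_low)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])


class TestRequiredSampleSize:
    def test_study_power_analysis_case(self):
        assert required_sample_size(PowerSpec(r2_assumed=0.25)) == 26

    def test_returned_n_brackets_the_target_power(self):
        for r2 in (0.25, 0.52):
            spec = PowerSpec(r2_assumed=r2)
            n = required_sample_size(spec)
            assert regression_f_power(n, spec.f2) >= 0.8
            if n > spec.n_min_floor:
                assert regression_f_power(n - 1, spec.f2) < 0.8

    def test_huge_effect_returns_floor(self):
        assert required_sample_size(PowerSpec(r2_assumed=0.99)) == 4
        assert required_sample_size(
            PowerSpec(r2_assumed=0.99, n_min_floor=8)) == 8

    def test_monotone_in_effect_alpha_and_power(self):
        ns_r2 = [required_sample_size(PowerSpec(r2_assumed=r2))
                 for r2 in (0.1, 0.25, 0.5, 0.8)]
        assert ns_r2 == sorted(ns_r2, reverse=True)
        ns_alpha = [required_sample_size(PowerSpec(0.25, alpha=a))
                    for a in (0.01, 0.05, 0.1)]
        assert ns_alpha == sorted(ns_alpha, reverse=True)
        ns_power = [required_sample_size(PowerSpec(0.25, power=p))
                    for p in (0.5, 0.8, 0.95)]
        assert ns_power == sorted(ns_power)

    def test_correlation_mode_needs_more_cases(self):
        # the exact-correlation alternative is more conservative than the
        # fixed-design regression F model at the same assumed R^2
        n_f = required_sample_size(PowerSpec(0.25), method="regression_f")
        n_c = required_sample_size(PowerSpec(0.25), method="correlation")
        assert n_c >= n_f

    def test_invalid_spec_raises(self):
        with pytest.raises(ValueError):
            PowerSpec(r2_assumed=1.5)
        with pytest.raises(ValueError):
            PowerSpec(r2_assumed=0.25, n_min_floor=3)


class TestRunCohortAnalysis:
    def _noise_free(self, n=20, slope=-0.27, intercept=28.81):
        cfg = CohortConfig(n_subjects=n, slope=slope, intercept=intercept,
                           residual_sd=0.0, seed=42)
        return gen_cohort(cfg)

    def test_noise_free_cohort_is_perfectly_correlated(self):
        subjects = self._noise_free()
        res = run_cohort_analysis(
            subjects, external_equation=(-0.27, 28.81))
        assert res.r == pytest.approx(-1.0)
        assert res.slope == pytest.approx(-0.27)
        assert res.intercept == pytest.approx(28.81)
        assert res.grubbs_outliers == []
        assert res.bland_altman.bias == pytest.approx(0.0, abs=1e-10)

    def test_gross_outlier_subject_is_flagged(self):
        cfg = CohortConfig(n_subjects=30, residual_sd=2.0, seed=5)
        subjects = gen_cohort(cfg)
        in_range = [s for s in subjects if s.in_range]
        victim = in_range[7]
        victim.rocbp_pct += 10 * 2.0  # +10 residual SDs
        res = run_cohort_analysis(subjects)
        assert res.grubbs_outliers == [victim.subject_id]

    def test_out_of_range_subjects_are_excluded(self):
        subjects = self._noise_free(n=25)
        subjects.append(SubjectRecord("S_OOR", OUT_OF_RANGE, None))
        res = run_cohort_analysis(subjects)
        assert res.n_analyzed == len(subjects) - res.n_out_of_range
        assert "S_OOR" not in res.grubbs_outliers

    def test_two_group_cohort_reports_parallel_lines(self):
        from stiffwave import GroupSpec
        cfg = CohortConfig(
            n_subjects=40, residual_sd=4.0, seed=8,
            groups=(GroupSpec("healthy", 0.4),
                    GroupSpec("athero_risk", 0.6)))
        res = run_cohort_analysis(gen_cohort(cfg))
        assert res.p_parallel_slope is not None
        assert 0.0 <= res.p_parallel_slope <= 1.0
        assert set(res.group_r) == {"healthy", "athero_risk"}

    def test_too_few_in_range_subjects_raises(self):
        subjects = [SubjectRecord(f"S{i}", OUT_OF_RANGE, None)
                    for i in range(5)]
        subjects.append(SubjectRecord("S6", 30, 20.0))
        with pytest.raises(ValueError):
            run_cohort_analysis(subjects)
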