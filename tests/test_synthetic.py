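"""Synthetic cohort generator: marginals, calibration, monotonicity, outliers."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from dvhpredict.preprocessing import chi2_threshold, squared_mahalanobis
from dvhpredict.regression import fit_curve
from dvhpredict.synthetic import (
    CohortSpec,
    generate_cohort,
    noise_variance_for_target_r2,
    read_cohort,
    response_surface,
    sample_features,
    write_cohort,
)


class TestNoiseCalibrationIdentity:
    @pytest.mark.parametrize(
        "signal_var, r2, expected",
        [
            (4.0, 0.2, 16.0),
            (1.0, 0.5, 1.0),
            # closed form: 9 * (1 - 0.177) / 0.177
            (9.0, 0.177, 9.0 * (1.0 - 0.177) / 0.177),
        ],
    )
    def test_closed_form(self, signal_var, r2, expected):
        sigma2 = noise_variance_for_target_r2(signal_var, r2)
        assert sigma2 == pytest.approx(expected, rel=1e-12)
        # the defining identity round-trips
        assert signal_var / (signal_var + sigma2) == pytest.approx(r2, rel=1e-12)

    @pytest.mark.parametrize("bad_r2", [0.0, 1.0, -0.3, 1.7])
    def test_rejects_r2_outside_unit_interval(self, bad_r2):
        with pytest.raises(ValueError):
            noise_variance_for_target_r2(1.0, bad_r2)


class TestFeatureSampling:
    def test_p_median_matches_published_summary(self, default_spec):
        feats = sample_features(default_spec, 10_000)
        assert np.median(feats[:, 0]) == pytest.approx(0.38, abs=0.02)

    def test_single_draw_within_bounds(self, default_spec):
        feats = sample_features(default_spec, 1)
        assert feats.shape == (1, 3)
        p, l, s = feats[0]
        assert np.all(np.isfinite(feats))
        assert 0.0 <= p <= 1.0 and 0.0 < l <= 1.0 and s > 0.0

    def test_seeded_reproducibility(self, default_spec):
        a = sample_features(default_spec, 50)
        b = sample_features(default_spec, 50)
        np.testing.assert_array_equal(a, b)

    def test_l_s_ranges_and_correlation(self, default_spec):
        feats = sample_features(default_spec, 20_000)
        l, s = feats[:, 1], feats[:, 2]
        assert l.min() >= default_spec.l_range[0] and l.max() <= default_spec.l_range[1]
        assert s.min() >= default_spec.s_range[0] and s.max() <= default_spec.s_range[1]
        assert np.corrcoef(l, s)[0, 1] == pytest.approx(default_spec.ls_corr, abs=0.1)

    def test_invalid_spec_names_offending_field(self):
        with pytest.raises(ValueError, match="p_quantiles"):
            sample_features(
                dataclasses.replace(CohortSpec(), p_quantiles=(0.5, 0.4, 0.3, 0.2, 0.1)), 5
            )
        with pytest.raises(ValueError, match="outlier_count"):
            CohortSpec(n_cases=5, outlier_count=5).validate()


class TestGenerateCohort:
    def test_record_count_and_planted_flags(self, default_spec, default_cohort):
        assert len(default_cohort) == default_spec.n_cases
        planted = [r for r in default_cohort if r.planted_outlier]
        assert len(planted) == default_spec.outlier_count

    def test_every_record_satisfies_bounds_and_dvh_monotonicity(self):
        # large cohort to exercise the invariant broadly
        cohort = generate_cohort(CohortSpec(n_cases=10_000, outlier_count=0, seed=7))
        out = np.array([r.outcomes() for r in cohort])
        assert np.all(out >= 0.0) and np.all(out <= 100.0)
        assert np.all(np.diff(out, axis=1) <= 0.0)
        feats = np.array([r.features() for r in cohort])
        assert np.all((feats[:, 0] >= 0) & (feats[:, 0] <= 1))
        assert np.all((feats[:, 1] > 0) & (feats[:, 1] <= 1))
        assert np.all(feats[:, 2] > 0)

    def test_zero_noise_outcomes_equal_response_surface(self):
        spec = CohortSpec(n_cases=60, outlier_count=0, noise_scale=0.0, seed=3)
        cohort = generate_cohort(spec)
        feats = np.array([r.features() for r in cohort])
        surface = response_surface(spec, feats[:, 0], feats[:, 1], feats[:, 2])
        out = np.array([r.outcomes() for r in cohort])
        # compare where the raw surface is already physical (no clip/sort active)
        ok = (np.diff(surface, axis=1) <= 0).all(axis=1) & (surface > 0).all(axis=1)
        assert ok.mean() > 0.9
        np.testing.assert_allclose(out[ok], surface[ok], rtol=1e-12)

    def test_zero_noise_response_shapes_in_p(self, default_spec):
        # V5 rises then falls over the P range; V20/V30 strictly decrease.
        p = np.linspace(0.11, 0.83, 200)
        surf = response_surface(default_spec, p, np.full_like(p, 0.65), np.full_like(p, 16.0))
        v5 = surf[:, 0]
        peak = np.argmax(v5)
        assert 0 < peak < len(p) - 1
        assert np.all(np.diff(v5[: peak + 1]) > 0) and np.all(np.diff(v5[peak:]) < 0)
        assert np.all(np.diff(surf[:, 2]) < 0) and np.all(np.diff(surf[:, 3]) < 0)

    def test_seeded_cohort_file_is_byte_identical(self, default_spec, tmp_path):
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(generate_cohort(default_spec), pa, spec=default_spec)
        write_cohort(generate_cohort(default_spec), pb, spec=default_spec)
        assert pa.read_bytes() == pb.read_bytes()
        roundtrip = read_cohort(pa)
        assert [r.case_id for r in roundtrip] == [r.case_id for r in generate_cohort(default_spec)]

    def test_planted_outliers_exceed_cutoff_under_inlier_statistics(self, default_cohort):
        inliers = np.array([r.features() for r in default_cohort if not r.planted_outlier])
        planted = np.array([r.features() for r in default_cohort if r.planted_outlier])
        mean, cov = inliers.mean(axis=0), np.cov(inliers, rowvar=False)
        cutoff = chi2_threshold(0.05, 3)
        d2_out = squared_mahalanobis(planted, mean, cov)
        d2_in = squared_mahalanobis(inliers, mean, cov)
        assert np.all(d2_out > cutoff)
        # planted squared distance is 2x the cutoff by construction
        np.testing.assert_allclose(d2_out, 2.0 * cutoff, rtol=1e-6)
        assert np.mean(d2_in <= cutoff) >= 0.95


class TestCalibration:
    def test_mean_adjusted_r2_tracks_targets(self):
        """Fitted adjusted R² over many cohorts matches the calibration targets."""
        r2_v5, r2_v30 = [], []
        for seed in range(60):
            cohort = generate_cohort(CohortSpec(n_cases=96, outlier_count=0, seed=9000 + seed))
            p = np.array([r.p for r in cohort])
            r2_v5.append(fit_curve(p, np.array([r.v5 for r in cohort]), "quadratic").adj_r2)
            r2_v30.append(fit_curve(p, np.array([r.v30 for r in cohort]), "linear").adj_r2)
        assert np.mean(r2_v5) == pytest.approx(0.177, abs=0.05)
        assert np.mean(r2_v30) == pytest.approx(0.072, abs=0.05)

    def test_quadratic_v5_has_negative_curvature(self):
        neg = 0
        for seed in range(20):
            cohort = generate_cohort(CohortSpec(n_cases=96, outlier_count=0, seed=400 + seed))
            p = np.array([r.p for r in cohort])
            fit = fit_curve(p, np.array([r.v5 for r in cohort]), "quadratic")
            neg += fit.coefficients[2] < 0
        assert neg >= 19  # rise-then-fall shape recovered in >= 95% of cohorts
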