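"""Calibration, precision components, detection limits, linearity."""

import numpy as np
import pytest

from chromacard.assay_eval import (
    LoqUndeterminableError,
    fit_calibration,
    lab_feature,
    limits_of_detection,
    linearity_order_test,
    loq_from_precision_profile,
    precision_analysis,
    simulate_assay_study,
)


def _scaled_sample(rng, n, mean, sd):
    """Sample with exact mean and exact ddof=1 standard deviation."""
    x = rng.normal(size=n)
    return (x - x.mean()) / x.std(ddof=1) * sd + mean


class TestCalibration:
    def test_exact_affine_response_recovered(self):
        feature = np.repeat(np.linspace(-2, 2, 5), 3)
        conc = 2.5 * feature + 4.0
        model = fit_calibration(feature, conc)
        assert model.slope == pytest.approx(2.5, abs=1e-10)
        assert model.intercept == pytest.approx(4.0, abs=1e-10)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError, match="zero feature variance"):
            fit_calibration(np.ones(12), np.repeat([1.0, 2, 3, 4], 3))

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_calibration(np.arange(6.0), np.repeat([1.0, 2, 3], 2))

    def test_noisy_slope_recovery(self, rng):
        feature = np.repeat(np.linspace(0, 10, 6), 5)
        conc = 1.0 * feature + rng.normal(0, 0.2, feature.size)
        model = fit_calibration(feature, conc)
        assert model.slope == pytest.approx(1.0, abs=0.05)

    def test_lab_feature_projection_tracks_dominant_axis(self, rng):
        t = np.linspace(0, 1, 30)
        lab = np.column_stack([80 - 40 * t, 5 * t, 10 * t]) + rng.normal(0, 0.1, (30, 3))
        f, axis = lab_feature(lab)
        assert abs(np.corrcoef(f, t)[0, 1]) > 0.999
        model = fit_calibration(None, np.round(t * 10, 3), lab=lab)
        assert abs(np.corrcoef(model.predict_lab(lab), t)[0, 1]) > 0.999


class TestPrecision:
    def test_identical_replicates_give_zero_sds(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "level": [4.0] * 8,
                "site": ["a"] * 4 + ["b"] * 4,
                "prediction": [4.2] * 8,
            }
        )
        row = precision_analysis(df).rows[0]
        assert row.repeatability_sd == 0.0
        assert row.reproducibility_sd == 0.0
        assert row.repeatability_cv == 0.0

    def test_cv_is_sd_over_mean_in_percent(self):
        # the published mid-level precision row: mean 4.640, reproducibility
        # SD 0.939 -> CV 20.2 %
        assert 100 * 0.939 / 4.640 == pytest.approx(20.2, abs=0.05)

    def test_reproducibility_at_least_repeatability(self, rng):
        df = simulate_assay_study(seed=8)
        for row in precision_analysis(df).rows:
            assert row.reproducibility_sd >= row.repeatability_sd

    def test_variance_component_recovery(self):
        df = simulate_assay_study(
            within_sd=0.3, between_sd=0.4, n_sites=12, replicates_per_site=12, seed=0
        )
        frame = precision_analysis(df).to_frame()
        sw = np.sqrt((frame.repeatability_sd**2).mean())
        sb = np.sqrt((frame.reproducibility_sd**2 - frame.repeatability_sd**2).mean())
        assert sw == pytest.approx(0.3, rel=0.15)
        assert sb == pytest.approx(0.4, rel=0.15)

    def test_single_replicate_rejected(self):
        import pandas as pd

        df = pd.DataFrame(
            {"level": [4.0] * 3, "site": ["a", "a", "b"], "prediction": [4.0, 4.1, 4.2]}
        )
        with pytest.raises(ValueError, match="replicates"):
            precision_analysis(df)

    def test_uncorrected_arm_inflates_cv(self):
        corrected = simulate_assay_study(illumination_sd=0.0, seed=21)
        uncorrected = simulate_assay_study(illumination_sd=1.0, seed=21)
        cv_c = precision_analysis(corrected).reproducibility_cvs()
        cv_u = precision_analysis(uncorrected).reproducibility_cvs()
        assert np.all(cv_u >= 2.0 * cv_c * 0.9)  # roughly doubled or worse


class TestDetectionLimits:
    def test_parametric_formulas(self, rng):
        blanks = _scaled_sample(rng, 30, 0.2, 0.3)
        lows = _scaled_sample(rng, 30, 1.0, 0.5)
        limits = limits_of_detection(blanks, lows)
        assert limits.lob == pytest.approx(0.2 + 1.645 * 0.3, abs=1e-9)
        assert limits.lod == pytest.approx(limits.lob + 1.645 * 0.5, abs=1e-9)

    def test_all_zero_blanks_give_zero_lob(self, rng):
        limits = limits_of_detection(np.zeros(25), _scaled_sample(rng, 25, 1.0, 0.2))
        assert limits.lob == 0.0

    def test_lob_monotone_in_blank_sd(self, rng):
        lows = _scaled_sample(rng, 30, 1.0, 0.2)
        lobs = [
            limits_of_detection(_scaled_sample(rng, 30, 0.2, sd), lows).lob
            for sd in (0.1, 0.2, 0.4)
        ]
        assert lobs[0] < lobs[1] < lobs[2]

    def test_small_samples_warn(self, rng):
        with pytest.warns(UserWarning, match="fewer than 20"):
            limits_of_detection(np.arange(5.0), np.arange(5.0))

    def test_nonparametric_option(self, rng):
        blanks = rng.normal(0.2, 0.3, 200)
        limits = limits_of_detection(blanks, rng.normal(1, 0.2, 200), parametric=False)
        assert limits.lob == pytest.approx(np.percentile(blanks, 95))


class TestLoq:
    def test_closed_form_crossing(self):
        levels = np.array([1.0, 2.0, 4.0, 8.0])
        assert loq_from_precision_profile(levels, 40.0 / levels, 20.0) == pytest.approx(2.0)

    def test_undeterminable_when_cvs_too_high(self):
        levels = np.array([1.0, 2.0, 4.0, 8.0])
        with pytest.raises(LoqUndeterminableError):
            loq_from_precision_profile(levels, 400.0 / levels, 20.0)

    def test_recovery_from_noisy_profile(self, rng):
        levels = np.array([1.0, 1.5, 2.5, 4.0, 6.5, 9.0])
        true = 50.0 * levels**-1.3  # crosses 20 % at (20/50)^(-1/1.3) ≈ 2.02
        noisy = true * np.exp(rng.normal(0, 0.05, levels.size))
        loq = loq_from_precision_profile(levels, noisy, 20.0)
        assert loq == pytest.approx((20 / 50) ** (-1 / 1.3), rel=0.10)

    def test_non_monotone_profile_flagged(self):
        with pytest.warns(UserWarning, match="not decreasing"):
            with pytest.raises(LoqUndeterminableError):
                loq_from_precision_profile(
                    np.array([1.0, 2, 4]), np.array([30.0, 40, 50]), 20.0
                )


class TestLinearity:
    def test_linear_data_verdict(self, rng):
        x = np.repeat(np.arange(1.0, 8.0), 6)
        res = linearity_order_test(x, 2 * x + rng.normal(0, 0.05, x.size))
        assert res.verdict == "linear" and res.best_order == 1

    def test_quadratic_data_detected(self, rng):
        x = np.repeat(np.arange(1.0, 8.0), 10)
        res = linearity_order_test(x, x + 0.5 * x**2 + rng.normal(0, 0.05, x.size))
        assert res.verdict == "nonlinear(order 2)"

    def test_identity_data(self):
        x = np.repeat(np.arange(1.0, 7.0), 3)
        res = linearity_order_test(x, x.copy())
        assert res.verdict == "linear"
        assert res.coefficients[1] == pytest.approx([0.0, 1.0], abs=1e-10)

    def test_insufficient_levels_rejected(self):
        with pytest.raises(ValueError, match="5 distinct"):
            linearity_order_test(np.repeat([1.0, 2, 3, 4], 3), np.zeros(12))
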