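"""Biomarker bridge: log-log regression, inversion, biomarker risks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from benzrisk.biomarker import (
    MetaboliteMeasurement,
    SPMA_PUBLISHED,
    TTMA_PUBLISHED,
    fit_loglog_regression,
    invert_to_air,
    predict_ln_metabolite,
    risk_from_metabolite,
)
from benzrisk.exceptions import InversionError, RankDeficiencyError
from benzrisk.risk import risk_from_twa


class TestPredict:
    @pytest.mark.parametrize(
        "fit,smo,expected",
        [
            (SPMA_PUBLISHED, 0, 0.54),
            (SPMA_PUBLISHED, 1, 0.66),
            (TTMA_PUBLISHED, 0, 4.73),
        ],
    )
    def test_unit_air_prediction(self, fit, smo, expected):
        """At C_TWA = 1 mg/m³ the prediction is intercept (+ smoking term)."""
        assert predict_ln_metabolite(fit, 1.0, smo) == pytest.approx(expected)

    def test_nonpositive_air_rejected(self):
        with pytest.raises(ValueError):
            predict_ln_metabolite(SPMA_PUBLISHED, 0.0, 0)


class TestInvert:
    def test_below_lod_ttma_inversion(self):
        """Median t,t-MA of the below-detection workers implies ~0.011 mg/m³."""
        m = MetaboliteMeasurement(5.18, "t,t-MA", smoker=0)
        expected = math.exp((math.log(5.18) - 4.73) / 0.68)
        air = invert_to_air(TTMA_PUBLISHED, m)
        assert air == pytest.approx(expected, rel=1e-12)
        assert air == pytest.approx(0.0107, abs=2e-4)

    def test_intercept_only_case(self):
        m = MetaboliteMeasurement(math.exp(0.54), "S-PMA", smoker=0)
        assert invert_to_air(SPMA_PUBLISHED, m) == pytest.approx(1.0, rel=1e-12)

    @given(
        x=st.floats(1e-3, 1e3),
        smo=st.sampled_from([0, 1]),
    )
    @settings(max_examples=60, deadline=None)
    def test_round_trip_identity(self, x, smo):
        ln_m = predict_ln_metabolite(TTMA_PUBLISHED, x, smo)
        m = MetaboliteMeasurement(math.exp(ln_m), "t,t-MA", smoker=smo)
        assert invert_to_air(TTMA_PUBLISHED, m) == pytest.approx(x, rel=1e-9)

    def test_zero_slope_raises(self):
        from benzrisk.biomarker import RegressionFit

        flat = RegressionFit("t,t-MA", 0.0, 0.0, 1.0, 0.0, 0.0, 20)
        with pytest.raises(InversionError):
            invert_to_air(flat, MetaboliteMeasurement(5.0, "t,t-MA"))

    def test_smoker_implies_lower_air_at_equal_metabolite(self, published_lms):
        """Part of a smoker's metabolite load is tobacco, not benzene."""
        non = MetaboliteMeasurement(50.0, "S-PMA", smoker=0)
        smo = MetaboliteMeasurement(50.0, "S-PMA", smoker=1)
        assert invert_to_air(SPMA_PUBLISHED, smo) < invert_to_air(SPMA_PUBLISHED, non)
        assert risk_from_metabolite(published_lms, SPMA_PUBLISHED, smo, 2.0) < (
            risk_from_metabolite(published_lms, SPMA_PUBLISHED, non, 2.0)
        )


class TestRiskFromMetabolite:
    def test_below_lod_worker_risk(self, published_lms):
        """The published below-detection scenario lands on 4.32e-4."""
        m = MetaboliteMeasurement(5.18, "t,t-MA", smoker=0)
        risk = risk_from_metabolite(published_lms, TTMA_PUBLISHED, m, t=1.78)
        assert round(risk * 1e4, 2) == 4.32

    def test_zero_duration_returns_background(self, published_lms):
        m = MetaboliteMeasurement(100.0, "t,t-MA", smoker=0)
        assert risk_from_metabolite(published_lms, TTMA_PUBLISHED, m, 0.0) == (
            published_lms.r
        )

    def test_composition_identity_with_twa_route(self, published_lms):
        """Metabolite at its predicted value gives exactly the TWA risk."""
        for fit in (SPMA_PUBLISHED, TTMA_PUBLISHED):
            for c in np.geomspace(0.01, 100, 25):
                for smo in (0, 1):
                    m = MetaboliteMeasurement(
                        math.exp(predict_ln_metabolite(fit, c, smo)), fit.metabolite, smo
                    )
                    assert risk_from_metabolite(published_lms, fit, m, 3.0) == (
                        pytest.approx(float(risk_from_twa(published_lms, c, 3.0)), rel=1e-12)
                    )

    def test_strictly_increasing_in_value_and_duration(self, published_lms):
        vals = [
            risk_from_metabolite(
                published_lms, TTMA_PUBLISHED,
                MetaboliteMeasurement(v, "t,t-MA", 0), 2.0,
            )
            for v in (10.0, 100.0, 1000.0)
        ]
        assert vals[0] < vals[1] < vals[2]
        ts = [
            risk_from_metabolite(
                published_lms, TTMA_PUBLISHED,
                MetaboliteMeasurement(100.0, "t,t-MA", 0), t,
            )
            for t in (0.5, 2.0, 8.0)
        ]
        assert ts[0] < ts[1] < ts[2]


class TestFitRegression:
    def _synth(self, rng, n, truth, resid_sd):
        ln_air = rng.normal(1.0, 1.2, size=n)
        smo = (rng.random(n) < 0.235).astype(float)
        ln_met = (
            truth.slope * ln_air + truth.smoking_coef * smo + truth.intercept
            + rng.normal(0, resid_sd, size=n)
        )
        return np.exp(ln_air), np.exp(ln_met), smo

    def test_noise_free_recovery_is_exact(self):
        rng = np.random.default_rng(0)
        air, met, smo = self._synth(rng, 50, TTMA_PUBLISHED, resid_sd=0.0)
        fit = fit_loglog_regression(air, met, smo, "t,t-MA")
        assert fit.slope == pytest.approx(0.68, abs=1e-10)
        assert fit.smoking_coef == pytest.approx(0.08, abs=1e-10)
        assert fit.intercept == pytest.approx(4.73, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_noisy_recovery_within_ci(self):
        rng = np.random.default_rng(1)
        air, met, smo = self._synth(rng, 217, SPMA_PUBLISHED, resid_sd=0.8)
        fit = fit_loglog_regression(air, met, smo, "S-PMA")
        se_approx = 0.8 / (np.sqrt(217) * 1.2)  # resid_sd / (sqrt(n)·sd(lnC))
        assert abs(fit.slope - 0.77) < 2.5 * se_approx

    def test_all_nonsmokers_rank_deficient(self):
        rng = np.random.default_rng(2)
        air, met, _ = self._synth(rng, 30, SPMA_PUBLISHED, resid_sd=0.1)
        with pytest.raises(RankDeficiencyError):
            fit_loglog_regression(air, met, np.zeros(30), "S-PMA")

    def test_minimum_sample_size_enforced(self):
        with pytest.raises(ValueError):
            fit_loglog_regression([1.0] * 5, [1.0] * 5, [0] * 5, "S-PMA")

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_loglog_regression([1.0, 0.0] + [1.0] * 10, [1.0] * 12, [0] * 12, "S-PMA")


class TestMeasurementValidation:
    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError):
            MetaboliteMeasurement(0.0, "S-PMA")

    def test_bad_smoker_flag_rejected(self):
        with pytest.raises(ValueError):
            MetaboliteMeasurement(1.0, "S-PMA", smoker=2)
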