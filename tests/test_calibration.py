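import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from h2oflux import (
    LinearCalibrator,
    PoolMeasurement,
    WaterEnrichmentCalibrator,
    WaterEnrichmentMeasurement,
    fit_calibration,
    quantify,
    total_content,
    water_enrichment,
)
from h2oflux.calibration import BelowCurveWarning, ExtrapolationWarning


class TestFitCalibration:
    def test_exact_line(self):
        curve = fit_calibration([(0, 0), (1, 1), (2, 2)])
        assert curve.slope == pytest.approx(1.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r == pytest.approx(1.0)

    def test_flat_response_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            fit_calibration([(0, 0.1), (2, 0.1)])

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_calibration([(1, 0.2), (1, 0.4)])

    def test_noisy_slope_recovery(self, rng):
        x = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0])
        y = 2.5 * x + 0.02 + rng.normal(0, 0.001, x.size)
        curve = fit_calibration(x=x, y=y)
        assert 2.45 <= curve.slope <= 2.55
        assert curve.r_squared > 0.999

    def test_weighted_fit_available(self):
        curve = fit_calibration(
            [(0.1, 0.25), (1, 2.5), (10, 25.0)], weighting="1/x"
        )
        assert curve.slope == pytest.approx(2.5, rel=1e-6)


class TestLinearCalibrator:
    def test_fit_predict_inverse(self):
        cal = LinearCalibrator().fit([0, 1, 2, 4], [0.1, 2.1, 4.1, 8.1])
        assert cal.slope_ == pytest.approx(2.0)
        assert cal.intercept_ == pytest.approx(0.1)
        assert cal.inverse(4.1) == pytest.approx(2.0)
        assert np.allclose(cal.predict([3]), [6.1])

    def test_sklearn_clone(self):
        from sklearn.base import clone

        assert clone(LinearCalibrator(weighting="1/x")).weighting == "1/x"


class TestWaterEnrichment:
    STANDARDS = [(0.00, 0.03), (0.02, 0.15), (0.04, 0.27), (0.06, 0.39)]

    def test_interpolation_at_a_node(self):
        meas = WaterEnrichmentMeasurement("s1", ratio=0.27, standards=self.STANDARDS)
        assert water_enrichment(meas) == pytest.approx(0.04, abs=1e-12)

    def test_linearity_through_origin(self):
        standards = [(0.0, 0.0), (0.05, 1.0)]
        meas = WaterEnrichmentMeasurement("s1", ratio=0.4, standards=standards)
        assert water_enrichment(meas) == pytest.approx(0.02)

    def test_extrapolation_flagged(self):
        meas = WaterEnrichmentMeasurement("s1", ratio=0.50, standards=self.STANDARDS)
        with pytest.warns(ExtrapolationWarning):
            water_enrichment(meas)

    def test_standards_validated(self):
        with pytest.raises(ValueError, match="standards"):
            WaterEnrichmentMeasurement("s1", ratio=0.1, standards=[(0.0, 0.03)])
        with pytest.raises(ValueError, match="outside"):
            WaterEnrichmentMeasurement(
                "s1", ratio=0.1, standards=[(0.0, 0.03), (0.5, 3.0)]
            )

    def test_noisy_recovery_at_dosing_target(self, rng):
        """Standards at {0,1,2,4,6}% with 0.5% noise recover p=4% within 0.1pp."""
        fracs = np.array([0.0, 0.01, 0.02, 0.04, 0.06])
        slope, intercept = 6.0, 0.0334
        estimates = []
        for _ in range(200):
            ratios = (intercept + slope * fracs) * (1 + rng.normal(0, 0.005, 5))
            sample = (intercept + slope * 0.04) * (1 + rng.normal(0, 0.005))
            cal = WaterEnrichmentCalibrator(warn_extrapolation=False).fit(
                fracs, ratios
            )
            estimates.append(cal.predict([sample])[0])
        assert abs(np.mean(estimates) - 0.04) < 0.001
        assert np.all(np.abs(np.array(estimates) - 0.04) < 0.004)


class TestQuantify:
    CURVE = fit_calibration([(0, 0.02), (50, 0.52), (100, 1.02), (200, 2.02)])

    def test_response_at_node(self):
        # response for 100 µg/g is 1.02 with IS area 1e5
        assert quantify(1.02e5, 1e5, self.CURVE) == pytest.approx(100.0)

    def test_response_at_intercept_is_zero(self):
        assert quantify(0.02e5, 1e5, self.CURVE) == pytest.approx(0.0, abs=1e-9)

    def test_below_curve_floors_with_warning(self):
        with pytest.warns(BelowCurveWarning):
            assert quantify(0.001e5, 1e5, self.CURVE) == 0.0

    def test_missing_internal_standard(self):
        with pytest.raises(ValueError, match="internal standard"):
            quantify(1.0, 0.0, self.CURVE)

    def test_simulated_concentration_roundtrip(self, rng):
        """Areas generated from 118.30 µg/g through the curve come back."""
        true_conc = 118.30
        response = self.CURVE.response(true_conc)
        is_area = 2.4e5
        noisy = response * is_area * (1 + rng.normal(0, 0.02))
        conc = quantify(noisy, is_area, self.CURVE)
        assert conc == pytest.approx(true_conc, rel=0.08)


class TestTotalContent:
    def test_arithmetic(self):
        pool = PoolMeasurement("T-CA", 10.0, 5.0, 500.0, compartment="intestine")
        assert total_content(pool) == pytest.approx(0.1)

    def test_zero_concentration(self):
        assert total_content(PoolMeasurement("T-CA", 0.0, 5.0, 500.0)) == 0.0

    def test_body_mass_homogeneity(self):
        a = total_content(PoolMeasurement("x", 10.0, 5.0, 500.0))
        b = total_content(PoolMeasurement("x", 10.0, 5.0, 1000.0))
        assert a == pytest.approx(2 * b)

    @given(
        conc=st.floats(min_value=0.01, max_value=1e3),
        mass=st.floats(min_value=0.1, max_value=50),
        body=st.floats(min_value=10, max_value=1000),
        c=st.floats(min_value=0.1, max_value=10),
    )
    def test_unit_consistent_rescaling(self, conc, mass, body, c):
        base = total_content(PoolMeasurement("x", conc, mass, body))
        scaled = total_content(PoolMeasurement("x", conc * c, mass / c, body))
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_missing_field_named(self):
        with pytest.raises(ValueError, match="body_mass_g"):
            total_content(PoolMeasurement("x", 1.0, 5.0, None))
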