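"""Universal calibration: hydrodynamic volume, curve fitting, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pectinsec as ps
from pectinsec.calibration import AVOGADRO, CalibrationError, DL_TO_NM3


def vh_oracle(m, k, a):
    # independent unit-tracked evaluation: (2/5) K M^(1+a) / N_A, dL -> nm^3
    return 0.4 * k * m ** (1 + a) / 6.02214076e23 * 1e23


class TestHydrodynamicVolume:
    def test_pullulan_hand_value(self):
        vh = ps.hydrodynamic_volume(1e5, ps.PULLULAN_MH)
        assert vh == pytest.approx(vh_oracle(1e5, 1.0176e-3, 0.525), rel=1e-12)
        assert vh == pytest.approx(2.85e3, rel=2e-3)

    def test_linear_when_exponent_zero(self):
        mh = ps.MarkHouwink(k=5e-3, a=0.0)
        assert ps.hydrodynamic_volume(2e5, mh) == pytest.approx(
            2 * ps.hydrodynamic_volume(1e5, mh), rel=1e-12
        )

    def test_pure_function(self):
        assert ps.hydrodynamic_volume(1234.5, ps.PULLULAN_MH) == ps.hydrodynamic_volume(
            1234.5, ps.PULLULAN_MH
        )

    def test_rejects_nonpositive_mass(self):
        with pytest.raises(CalibrationError):
            ps.hydrodynamic_volume(-1.0, ps.PULLULAN_MH)

    @given(
        m1=st.floats(1e2, 1e7),
        factor=st.floats(1.001, 100.0),
        k=st.floats(1e-5, 1e-1),
        a=st.floats(0.0, 1.5),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_strictly_increasing_in_mass(self, m1, factor, k, a):
        mh = ps.MarkHouwink(k=k, a=a)
        assert ps.hydrodynamic_volume(m1 * factor, mh) > ps.hydrodynamic_volume(m1, mh)


class TestSphereGeometry:
    def test_unit_sphere(self):
        assert ps.vh_to_rh(4 * np.pi / 3) == pytest.approx(1.0, rel=1e-12)

    def test_cube_root_oracle(self):
        assert ps.vh_to_rh(2.85e3) == pytest.approx((3 * 2.85e3 / (4 * np.pi)) ** (1 / 3), rel=1e-12)
        assert ps.vh_to_rh(2.85e3) == pytest.approx(8.8, rel=5e-3)

    def test_zero_and_roundtrip(self):
        assert ps.vh_to_rh(0.0) == 0.0
        assert ps.rh_to_vh(ps.vh_to_rh(123.4)) == pytest.approx(123.4, rel=1e-12)

    def test_negative_volume_rejected(self):
        with pytest.raises(CalibrationError):
            ps.vh_to_rh(-1.0)


class TestFitCalibration:
    def test_exact_line_zero_residuals(self):
        mh = ps.PULLULAN_MH
        masses = [1e3, 1e4, 1e5]
        x = np.log10([ps.hydrodynamic_volume(m, mh) for m in masses])
        standards = [ps.Standard(m, 20.0 - 1.5 * xi) for m, xi in zip(masses, x)]
        curve = ps.fit_calibration(standards, mh, order=1)
        assert np.allclose(curve.residuals, 0.0, atol=1e-9)

    def test_recovers_known_cubic(self, truth_curve):
        standards = ps.simulate_standards_run(seed=0)
        curve = ps.fit_calibration(standards, ps.PULLULAN_MH, order=3)
        assert np.allclose(curve.coefficients, truth_curve.coefficients, rtol=1e-9, atol=1e-9)

    def test_pullulan_kit_range_fits_decreasing(self):
        standards = ps.simulate_standards_run()
        vels = [s.peak_elution_volume for s in standards]
        assert np.all(np.diff(vels) < 0)  # masses ascending -> earlier is larger
        curve = ps.fit_calibration(standards, ps.PULLULAN_MH, order=3)
        lo, hi = curve.log10_vh_range
        xs = np.linspace(lo, hi, 100)
        assert np.all(np.diff(curve.elution_volume(xs)) < 0)

    def test_round_trip_inversion(self, fitted_curve):
        lo, hi = fitted_curve.log10_vh_range
        x = np.linspace(lo, hi, 50)
        vel = fitted_curve.elution_volume(x)
        assert np.max(np.abs(fitted_curve.elution_volume(fitted_curve.log10_vh(vel)) - vel)) < 1e-6

    def test_matches_normal_equations(self):
        # brute-force least squares via the normal equations, order <= 3
        standards = ps.simulate_standards_run(noise_ml=0.05, seed=7)
        for order in (1, 2, 3):
            curve = ps.fit_calibration(standards, ps.PULLULAN_MH, order=order)
            masses = np.array([s.molar_mass for s in standards])
            vels = np.array([s.peak_elution_volume for s in standards])
            x = np.log10(ps.hydrodynamic_volume(masses, ps.PULLULAN_MH))
            design = np.vander(x, order + 1, increasing=True)
            beta = np.linalg.solve(design.T @ design, design.T @ vels)
            assert np.allclose(curve.coefficients, beta, rtol=1e-9, atol=1e-9)

    def test_too_few_standards(self):
        standards = ps.simulate_standards_run(standard_masses=(1e3, 1e4, 1e5))
        with pytest.raises(CalibrationError, match="at least"):
            ps.fit_calibration(standards, ps.PULLULAN_MH, order=3)

    def test_non_monotone_fit_rejected(self):
        # V-shaped data cannot produce a decreasing polynomial
        masses = [1e3, 1e4, 1e5, 1e6]
        vels = [20.0, 15.0, 16.0, 21.0]
        standards = [ps.Standard(m, v) for m, v in zip(masses, vels)]
        with pytest.raises(CalibrationError, match="not strictly decreasing"):
            ps.fit_calibration(standards, ps.PULLULAN_MH, order=2)

    def test_extrapolation_clamps_with_warning(self, fitted_curve):
        # beyond the monotone extension the curve clamps to the edge
        lo, hi = fitted_curve.inversion_range
        assert hi > fitted_curve.log10_vh_range[1]  # some extension exists
        with pytest.warns(UserWarning, match="clamping"):
            v = fitted_curve.elution_volume(hi + 1.0)
        with pytest.warns(UserWarning, match="clamping"):
            edge = fitted_curve.elution_volume(hi + 1e-9)
        assert v == pytest.approx(edge)

    def test_inversion_extrapolates_with_warning(self, fitted_curve):
        # slightly outside the standards' window but inside the monotone
        # extension: inversion succeeds and warns
        d_lo, d_hi = fitted_curve.log10_vh_range
        target = d_hi + 0.3
        vel = np.polynomial.Polynomial(fitted_curve.coefficients)(target)
        with pytest.warns(UserWarning, match="extrapolating"):
            x = fitted_curve.log10_vh(vel)
        assert x == pytest.approx(target, abs=1e-6)

    def test_persistence_roundtrip(self, fitted_curve):
        restored = ps.CalibrationCurve.from_dict(fitted_curve.to_dict())
        assert restored.coefficients == fitted_curve.coefficients
        assert restored.log10_vh_range == fitted_curve.log10_vh_range
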