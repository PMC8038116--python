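"""Per-slice Zimm fitting, optical constant and conformation slope."""

import numpy as np
import pytest

import pectinsec as ps
from pectinsec.calibration import AVOGADRO
from pectinsec.light_scattering import DEFAULT_ANGLES, zimm_fit_slice


def forward_kc_over_r(mw, rg, cfg):
    """Generate exact per-angle Kc/R from the Zimm relation."""
    lam = cfg.wavelength_medium_nm
    s2 = np.sin(np.radians(np.asarray(cfg.angles)) / 2.0) ** 2
    return 1.0 / mw + (16.0 * np.pi**2 / (3.0 * lam**2)) * rg**2 / mw * s2


class TestOpticalConstant:
    def test_closed_form_hand_value(self):
        cfg = ps.OpticalConfig(wavelength_nm=660.0, solvent_refractive_index=1.333, dndc=0.146)
        lam_cm = 660e-7
        expected = 4 * np.pi**2 * 1.333**2 * 0.146**2 / (AVOGADRO * lam_cm**4)
        assert ps.optical_constant(cfg) == pytest.approx(expected, rel=1e-12)
        assert ps.optical_constant(cfg) > 0

    def test_quadratic_in_dndc(self):
        base = ps.OpticalConfig(dndc=0.1)
        doubled = ps.OpticalConfig(dndc=0.2)
        assert ps.optical_constant(doubled) == pytest.approx(4 * ps.optical_constant(base), rel=1e-12)

    def test_zero_dndc(self):
        assert ps.optical_constant(ps.OpticalConfig(dndc=0.0)) == 0.0


class TestSliceConcentration:
    def test_zero_dri_zero_concentration(self):
        c = ps.slice_concentration(np.zeros(10), 0.146, 1e5)
        assert np.all(c == 0.0)

    def test_rescales_to_injected_mass(self):
        vel = np.linspace(10, 20, 200)
        dri = np.exp(-0.5 * ((vel - 15) / 1.0) ** 2)
        c = ps.slice_concentration(dri, 0.146, 123.0, elution_volume=vel, injected_mass=5e-4)
        assert np.trapezoid(c, vel) == pytest.approx(5e-4, rel=1e-9)

    def test_known_profile_recovered(self, truth_curve, no_warnings):
        # generator emits DRI = f * dndc * c; dividing back recovers c(V)
        mwd = ps.MwdSpec.lognormal(59000, 1.3)
        chrom = ps.simulate_chromatogram(mwd, truth_curve, noise=ps.NoiseSpec())
        c = ps.slice_concentration(chrom.dri, 0.146, 1e5,
                                   elution_volume=chrom.elution_volume,
                                   injected_mass=chrom.injected_mass)
        eluted = np.trapezoid(c, chrom.elution_volume)
        assert eluted == pytest.approx(chrom.injected_mass, rel=1e-3)

    def test_zero_response_factor_rejected(self):
        with pytest.raises(ValueError, match="response factor"):
            ps.slice_concentration(np.ones(3), 0.146, 0.0)


class TestZimmFit:
    def test_exact_recovery_from_forward_model(self):
        cfg = ps.OpticalConfig(angles=DEFAULT_ANGLES)
        y = forward_kc_over_r(1e5, 30.0, cfg)
        fit = zimm_fit_slice(y, cfg)
        assert fit.mw == pytest.approx(1e5, rel=1e-6)
        assert fit.rg == pytest.approx(30.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_flat_line_when_rg_zero(self):
        cfg = ps.OpticalConfig(angles=DEFAULT_ANGLES)
        y = forward_kc_over_r(2e5, 0.0, cfg)
        assert np.allclose(y, y[0])
        fit = zimm_fit_slice(y, cfg)
        assert fit.mw == pytest.approx(2e5, rel=1e-9)
        assert fit.rg is None  # zero slope carries no size information

    def test_noisy_median_within_two_percent(self):
        cfg = ps.OpticalConfig(angles=DEFAULT_ANGLES)
        y0 = forward_kc_over_r(1e5, 30.0, cfg)
        rng = np.random.default_rng(42)
        mws = []
        for _ in range(200):
            y = y0 * (1 + rng.normal(0, 0.01, size=y0.shape))
            fit = zimm_fit_slice(y, cfg)
            if fit.ok:
                mws.append(fit.mw)
        assert abs(np.median(mws) - 1e5) / 1e5 < 0.02

    def test_angle_order_invariance(self):
        cfg = ps.OpticalConfig(angles=DEFAULT_ANGLES)
        y = forward_kc_over_r(8e4, 25.0, cfg)
        perm = np.array([3, 0, 6, 1, 5, 2, 4])
        cfg_p = ps.OpticalConfig(angles=tuple(np.asarray(DEFAULT_ANGLES)[perm]))
        fit_p = zimm_fit_slice(y[perm], cfg_p)
        fit = zimm_fit_slice(y, cfg)
        assert fit_p.mw == pytest.approx(fit.mw, rel=1e-12)
        assert fit_p.rg == pytest.approx(fit.rg, rel=1e-12)

    def test_drop_any_single_angle_stable(self):
        cfg = ps.OpticalConfig(angles=DEFAULT_ANGLES)
        y = forward_kc_over_r(8e4, 25.0, cfg)
        for drop in range(len(DEFAULT_ANGLES)):
            keep = [i for i in range(len(DEFAULT_ANGLES)) if i != drop]
            sub = ps.OpticalConfig(angles=tuple(np.asarray(DEFAULT_ANGLES)[keep]))
            fit = zimm_fit_slice(y[keep], sub)
            assert fit.mw == pytest.approx(8e4, rel=1e-9)

    def test_nonpositive_intercept_flags_failure(self):
        cfg = ps.OpticalConfig(angles=(35.0, 90.0, 145.0))
        fit = zimm_fit_slice(np.array([-1e-5, -2e-5, -3e-5]), cfg)
        assert not fit.ok
        assert fit.mw is None

    def test_single_angle_mw_only(self):
        cfg = ps.OpticalConfig(angles=(90.0,))
        fit = zimm_fit_slice(np.array([1e-5]), cfg)
        assert fit.mw == pytest.approx(1e5, rel=1e-12)
        assert fit.rg is None


class TestConformationSlope:
    def test_compact_sphere_limit(self):
        rh = np.linspace(2.0, 30.0, 20)
        mw = 5.0 * rh**3
        assert ps.conformation_slope(mw, rh) == pytest.approx(3.0, rel=1e-9)

    def test_linear_coil_law(self):
        # swollen coil: Rh ~ M^0.588, so Mw ~ Rh^(1/0.588) = Rh^1.701
        rh = np.linspace(2.0, 30.0, 20)
        mw = 12.0 * rh ** (1 / 0.588)
        assert ps.conformation_slope(mw, rh) == pytest.approx(1 / 0.588, rel=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        rh = np.linspace(2.0, 30.0, 15)
        mw = 4.0 * rh**2.2 * np.exp(rng.normal(0, 0.05, 15))
        perm = rng.permutation(15)
        assert ps.conformation_slope(mw[perm], rh[perm]) == pytest.approx(
            ps.conformation_slope(mw, rh), rel=1e-12
        )

    def test_insufficient_slices(self):
        with pytest.raises(ValueError, match=">= 5"):
            ps.conformation_slope(np.array([1e4, 2e4]), np.array([3.0, 4.0]))


class TestPipelineRecovery:
    def test_p3_like_recovery_under_noise(self, truth_curve, fitted_curve, no_warnings):
        # high-molar-mass fraction conditions: Mw 59 kDa, dispersity 1.3,
        # 1% detector noise; Mw within 5%, D within 10%
        from pectinsec.sec import SECMALLSModel

        mwd = ps.MwdSpec.lognormal(59000, 1.3)
        mws, ds = [], []
        for seed in range(20):
            noise = ps.NoiseSpec(dri_relative=0.01, ls_relative=0.01,
                                 band_broadening_ml=0.1, seed=seed)
            chrom = ps.simulate_chromatogram(mwd, truth_curve, noise=noise)
            res = SECMALLSModel(chrom, fitted_curve).fit()
            mws.append(res.moments.mw)
            ds.append(res.moments.dispersity)
        assert abs(np.median(mws) - 59000) / 59000 < 0.05
        assert abs(np.median(ds) - 1.3) / 1.3 < 0.10
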