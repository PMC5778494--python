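"""LQ/MKM engine: α from z*₁D, dose inversion, RBE, depth profiles."""

import numpy as np
import pytest
from scipy.optimize import brentq

from mkmdose import (SET_A, SET_B, DepthProfile, Endpoint, LQCoefficients,
                     ReferenceRadiation, SpectrumSeries, X200KVP,
                     alpha_from_zstar, dose_for_survival, normalize_profile,
                     rbe_at_endpoint, rbe_depth_profile, sobp_center_depth,
                     survival_depth_profile, survival_for_dose, z_star_1d)

from conftest import make_delta_spectrum, make_uniform_spectrum


class TestAlphaFromZstar:
    def test_intercept_at_zero(self):
        assert alpha_from_zstar(SET_B, 0.0) == SET_B.alpha0

    def test_printed_parameter_arithmetic(self):
        assert alpha_from_zstar(SET_B, 1.0) == pytest.approx(0.18)
        assert alpha_from_zstar(SET_A, 2.0) == pytest.approx(0.278)

    def test_strictly_increasing_and_rejects_negative(self):
        z = np.linspace(0.0, 10.0, 50)
        alpha = alpha_from_zstar(SET_B, z)
        assert np.all(np.diff(alpha) > 0)
        with pytest.raises(ValueError):
            alpha_from_zstar(SET_B, -0.1)


class TestDoseInversion:
    def test_pure_linear_limit(self):
        lq = LQCoefficients(alpha=1.0, beta=0.0)
        assert dose_for_survival(lq, np.exp(-1.0)) == pytest.approx(1.0,
                                                                    abs=1e-12)

    def test_reference_radiation_ten_percent_dose(self):
        # root of exp(−0.19 D − 0.05 D²) = 0.1, found independently
        lq = LQCoefficients(alpha=0.19, beta=0.05)
        oracle = brentq(lambda d: survival_for_dose(lq, d) - 0.1, 0.0, 50.0,
                        xtol=1e-13)
        d = dose_for_survival(lq, 0.1)
        assert d == pytest.approx(oracle, abs=1e-10)
        assert d == pytest.approx(5.147, abs=2e-3)

    def test_near_pure_quadratic_limit(self):
        lq = LQCoefficients(alpha=1e-12, beta=0.05)
        expected = np.sqrt(-np.log(0.1) / 0.05)
        assert dose_for_survival(lq, 0.1) == pytest.approx(expected,
                                                           rel=1e-9)

    def test_rejects_survival_outside_unit_interval(self):
        lq = LQCoefficients(alpha=0.19, beta=0.05)
        for s in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                dose_for_survival(lq, s)

    def test_round_trip_identity_grid(self):
        for alpha in np.linspace(0.05, 0.5, 6):
            for beta in np.linspace(0.0, 0.1, 5):
                lq = LQCoefficients(alpha, beta)
                for s in np.logspace(-3, np.log10(0.9), 7):
                    d = dose_for_survival(lq, s)
                    assert survival_for_dose(lq, d) == pytest.approx(
                        s, abs=1e-10)

    def test_beta_zero_limit_matches_series_safe_form(self):
        lq0 = LQCoefficients(alpha=0.2, beta=0.0)
        lq_eps = LQCoefficients(alpha=0.2, beta=1e-13)
        for s in (1e-3, 0.1, 0.9):
            assert dose_for_survival(lq0, s) == pytest.approx(
                -np.log(s) / 0.2, abs=1e-8)
            assert dose_for_survival(lq_eps, s) == pytest.approx(
                dose_for_survival(lq0, s), abs=1e-8)


class TestSurvivalForDose:
    def test_zero_dose_and_closed_form(self):
        lq = LQCoefficients(alpha=1.0, beta=0.0)
        assert survival_for_dose(lq, 0.0) == 1.0
        assert survival_for_dose(lq, 2.0) == pytest.approx(np.exp(-2.0))
        with pytest.raises(ValueError):
            survival_for_dose(lq, -1.0)

    def test_strictly_decreasing(self):
        lq = LQCoefficients(alpha=0.19, beta=0.05)
        doses = np.linspace(0.0, 10.0, 30)
        s = [survival_for_dose(lq, d) for d in doses]
        assert np.all(np.diff(s) < 0)


class TestRBE:
    def test_self_reference_is_unity(self):
        lq = LQCoefficients(X200KVP.alpha_x, X200KVP.beta_x)
        assert rbe_at_endpoint(lq, X200KVP) == pytest.approx(1.0, abs=1e-14)

    def test_monotone_in_alpha(self):
        alphas = np.linspace(0.05, 0.5, 20)
        rbes = [rbe_at_endpoint(LQCoefficients(a, 0.05), X200KVP)
                for a in alphas]
        assert np.all(np.diff(rbes) > 0)

    def test_low_let_alpha_gives_rbe_below_one(self):
        # α₀ of SET_B < α_X: an un-hardened beam is less effective than
        # the 200 kVp reference
        lq = LQCoefficients(0.13, 0.05)
        assert rbe_at_endpoint(lq, X200KVP) < 1.0

    def test_mkm_fixed_point_z_star_1p2(self):
        # α = 0.13 + 0.05·1.2 = 0.19 = α_X and β matches: RBE = 1 exactly
        alpha = alpha_from_zstar(SET_B, 1.2)
        assert alpha == pytest.approx(X200KVP.alpha_x, abs=1e-15)
        rbe = rbe_at_endpoint(LQCoefficients(alpha, SET_B.beta), X200KVP)
        assert rbe == pytest.approx(1.0, abs=1e-12)

    def test_rbe_strictly_increasing_in_z_star(self):
        z = np.linspace(0.0, 5.0, 60)
        rbes = [rbe_at_endpoint(
            LQCoefficients(alpha_from_zstar(SET_B, zi), SET_B.beta), X200KVP)
            for zi in z]
        assert np.all(np.diff(rbes) > 0)

    def test_reference_validation(self):
        with pytest.raises(ValueError):
            ReferenceRadiation(alpha_x=0.0, beta_x=0.05)
        with pytest.raises(ValueError):
            Endpoint(survival=1.0)


def _flat_series(spec, depths, doses):
    return SpectrumSeries(np.asarray(depths, float),
                          [spec] * len(depths),
                          np.asarray(doses, float))


class TestRbeDepthProfile:
    def test_reference_matched_spectrum_preserves_dose(self):
        spec = make_uniform_spectrum(1.0, 5.0)
        zs = z_star_1d(spec, SET_B)
        ref = ReferenceRadiation(alpha_x=alpha_from_zstar(SET_B, zs),
                                 beta_x=SET_B.beta)
        series = _flat_series(spec, [10.0], [3.0])
        prof = rbe_depth_profile(series, [3.0], SET_B, ref)
        assert prof.rbe[0] == pytest.approx(1.0, abs=1e-12)
        assert prof.rbe_weighted_dose[0] == pytest.approx(3.0, abs=1e-10)

    def test_linearity_in_physical_dose(self):
        spec = make_uniform_spectrum(1.0, 5.0)
        series = _flat_series(spec, [0.0, 10.0], [1.0, 2.0])
        prof = rbe_depth_profile(series, [1.0, 2.0], SET_B)
        assert prof.rbe[0] == pytest.approx(prof.rbe[1], rel=1e-12)
        assert prof.rbe_weighted_dose[1] == pytest.approx(
            2.0 * prof.rbe_weighted_dose[0], rel=1e-12)

    def test_missing_spectra_excluded_not_zeroed(self):
        spec = make_uniform_spectrum(1.0, 5.0)
        series = SpectrumSeries(np.array([0.0, 10.0, 20.0]),
                                [spec, None, spec],
                                np.array([1.0, 1.0, 1.0]))
        prof = rbe_depth_profile(series, [1.0, 1.0, 1.0], SET_B)
        assert prof.excluded_depths == [10.0]
        assert np.isnan(prof.rbe[1]) and np.isnan(prof.z_star[1])
        assert np.isfinite(prof.rbe[[0, 2]]).all()

    def test_sobp_rbe_rises_across_distal_half(self, sobp_chain):
        profile, _, augmented = sobp_chain
        lo, hi = profile.metadata["plateau_mm"]
        center = sobp_center_depth(augmented.depths,
                                   augmented.physical_dose)
        mask = (augmented.depths >= center) & (augmented.depths <= hi)
        assert np.all(np.diff(augmented.rbe[mask]) > 0)


class TestNormalizeProfile:
    def _profile(self):
        spec = make_uniform_spectrum(1.0, 5.0)
        depths = np.arange(0.0, 50.0, 5.0)
        dose = np.concatenate([np.linspace(1.0, 2.0, 5),
                               np.linspace(4.0, 1.0, 5)])
        series = _flat_series(spec, depths, dose)
        return rbe_depth_profile(series, dose, SET_B)

    def test_identity_when_already_at_target(self):
        prof = self._profile()
        once = normalize_profile(prof, "bragg_peak", target_dose=2.0)
        twice = normalize_profile(once, "bragg_peak", target_dose=2.0)
        np.testing.assert_allclose(twice.physical_dose, once.physical_dose,
                                   rtol=1e-14)

    def test_scalar_rescale_to_target(self):
        prof = self._profile()  # peak dose 4 Gy
        out = normalize_profile(prof, "bragg_peak", target_dose=2.0)
        assert out.physical_dose.max() == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(out.physical_dose,
                                   prof.physical_dose / 2.0, rtol=1e-14)

    def test_rbe_invariant_under_normalization(self):
        prof = self._profile()
        out = normalize_profile(prof, "sobp_center", target_dose=2.0)
        np.testing.assert_allclose(out.rbe, prof.rbe, rtol=1e-14)

    def test_rbe_weighted_anchor_identity(self):
        prof = self._profile()
        out = normalize_profile(prof, "bragg_peak", target_dose=2.0,
                                on="rbe_weighted")
        i = int(np.nanargmax(prof.physical_dose))
        assert out.rbe_weighted_dose[i] == pytest.approx(2.0, abs=1e-12)
        assert out.physical_dose[i] == pytest.approx(2.0 / out.rbe[i],
                                                     rel=1e-12)

    def test_empty_or_undefined_anchor_raises(self):
        with pytest.raises(ValueError):
            DepthProfile(depths=np.array([]), physical_dose=np.array([]))


class TestSurvivalDepthProfile:
    def test_survival_prescription_is_fixed_point(self, sobp_chain):
        _, _, augmented = sobp_chain
        sv = survival_depth_profile(augmented, SET_B.beta,
                                    survival_at_center=0.1)
        i = int(np.argmin(np.abs(sv.depths
                                 - sv.metadata["center_depth_mm"])))
        assert sv.survival[i] == pytest.approx(0.1, abs=1e-8)

    def test_zero_dose_prescription_gives_unit_survival(self, sobp_chain):
        _, _, augmented = sobp_chain
        sv = survival_depth_profile(augmented, SET_B.beta,
                                    dose_at_center=0.0)
        finite = np.isfinite(augmented.alpha)
        np.testing.assert_allclose(sv.survival[finite], 1.0, atol=1e-14)

    def test_uniform_alpha_flat_dose_gives_flat_survival(self):
        spec = make_uniform_spectrum(1.0, 5.0)
        depths = np.arange(0.0, 30.0, 5.0)
        dose = np.full(depths.size, 2.0)
        prof = rbe_depth_profile(_flat_series(spec, depths, dose), dose,
                                 SET_B)
        sv = survival_depth_profile(prof, SET_B.beta, dose_at_center=2.0)
        assert np.ptp(sv.survival) == pytest.approx(0.0, abs=1e-14)

    def test_requires_exactly_one_prescription(self, sobp_chain):
        _, _, augmented = sobp_chain
        with pytest.raises(ValueError):
            survival_depth_profile(augmented, SET_B.beta)
        with pytest.raises(ValueError):
            survival_depth_profile(augmented, SET_B.beta,
                                   dose_at_center=2.0,
                                   survival_at_center=0.1)
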