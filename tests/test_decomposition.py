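"""The two-source least-squares core and its scikit-learn surface."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.base import clone

from vfrkit.decomposition import (
    CalibrationScale,
    CollinearFingerprintsError,
    DegenerateBaselineError,
    FingerprintDecomposer,
    calibrate_scale,
    cardiac_output,
    compute_weights,
    relative_change,
    solve_alpha_psi,
    stroke_volume,
    volume_curve,
)


class TestRelativeChange:
    def test_no_change_gives_zero(self):
        phi = 2.0 * np.ones((6, 10))
        np.testing.assert_allclose(relative_change(phi, phi[:, 0]), 0.0)

    def test_simple_arithmetic(self):
        phi = np.full((6, 1), 2.1)
        out = relative_change(phi, np.full(6, 2.0))
        np.testing.assert_allclose(out, 0.05)

    def test_scale_free(self, rng):
        phi = 1.0 + 0.1 * rng.standard_normal((6, 40))
        base = phi[:, 0]
        np.testing.assert_allclose(
            relative_change(3.0 * phi, 3.0 * base), relative_change(phi, base), rtol=1e-12
        )

    def test_zero_baseline_names_channel(self):
        base = np.ones(6)
        base[3] = 0.0
        with pytest.raises(DegenerateBaselineError, match="channel 4"):
            relative_change(np.ones((6, 5)), base)


def unit(i):
    e = np.zeros(6)
    e[i] = 1.0
    return e


class TestWeights:
    def test_orthonormal_case_reduces_to_fingerprints(self):
        w = compute_weights(unit(0), unit(1))
        np.testing.assert_allclose(w.w_a, unit(0))
        np.testing.assert_allclose(w.w_v, unit(1))

    def test_equals_pseudo_inverse(self):
        f_a = np.array([1.0, 1, 0, 0, 0, 0])
        f_v = np.array([1.0, -1, 1, 0, 0, 0])
        w = compute_weights(f_a, f_v)
        pinv = np.linalg.pinv(np.column_stack([f_a, f_v]))
        np.testing.assert_allclose(w.w_a, pinv[0], rtol=1e-12)
        np.testing.assert_allclose(w.w_v, pinv[1], rtol=1e-12)

    def test_collinear_rejected(self):
        with pytest.raises(CollinearFingerprintsError):
            compute_weights(unit(0) + unit(1), 2.0 * (unit(0) + unit(1)))

    @given(arrays(float, 12, elements=st.floats(-2, 2, allow_nan=False)))
    @settings(max_examples=200, deadline=None)
    def test_biorthogonality_invariants(self, flat):
        f_a, f_v = flat[:6], flat[6:]
        gram = (f_a @ f_a) * (f_v @ f_v) - (f_a @ f_v) ** 2
        if gram <= 1e-6 * max(f_a @ f_a, 1e-30) * max(f_v @ f_v, 1e-30):
            return  # collinear inputs are covered by the error test
        w = compute_weights(f_a, f_v)
        na, nv = np.linalg.norm(f_a), np.linalg.norm(f_v)
        assert abs(w.w_a @ f_v) <= 1e-8 * np.linalg.norm(w.w_a) * nv
        assert abs(w.w_v @ f_a) <= 1e-8 * np.linalg.norm(w.w_v) * na
        assert w.w_a @ f_a == pytest.approx(1.0, abs=1e-8 * np.linalg.norm(w.w_a) * na)
        assert w.w_v @ f_v == pytest.approx(1.0, abs=1e-8 * np.linalg.norm(w.w_v) * nv)
        assert w.gram_det > 0


class TestSolve:
    def test_pure_ventricular_pattern_gives_psi_one(self):
        w = compute_weights(unit(0), unit(1))
        alpha, psi = solve_alpha_psi(unit(1), w)
        assert psi == pytest.approx(1.0)
        assert alpha == pytest.approx(0.0)

    def test_exact_recovery_of_planted_coefficients(self, rng):
        for _ in range(50):
            f_a, f_v = rng.standard_normal((2, 6))
            a_true, p_true = rng.standard_normal(2)
            w = compute_weights(f_a, f_v)
            alpha, psi = solve_alpha_psi(a_true * f_a + p_true * f_v, w)
            assert alpha == pytest.approx(a_true, rel=1e-9, abs=1e-11)
            assert psi == pytest.approx(p_true, rel=1e-9, abs=1e-11)

    def test_orthogonal_input_maps_to_zero(self):
        w = compute_weights(unit(0), unit(1))
        alpha, psi = solve_alpha_psi(unit(4), w)
        assert alpha == psi == 0.0

    def test_residual_orthogonal_to_both_fingerprints(self, rng):
        f_a, f_v = rng.standard_normal((2, 6))
        w = compute_weights(f_a, f_v)
        v = rng.standard_normal(6)
        alpha, psi = solve_alpha_psi(v, w)
        resid = v - (alpha * f_a + psi * f_v)
        scale = np.linalg.norm(v) * max(np.linalg.norm(f_a), np.linalg.norm(f_v))
        assert abs(resid @ f_a) <= 1e-10 * scale
        assert abs(resid @ f_v) <= 1e-10 * scale

    def test_linearity_in_measurements(self, rng):
        f_a, f_v = rng.standard_normal((2, 6))
        w = compute_weights(f_a, f_v)
        v1, v2 = rng.standard_normal((2, 6))
        _, p1 = solve_alpha_psi(v1, w)
        _, p2 = solve_alpha_psi(v2, w)
        _, p12 = solve_alpha_psi(v1 + v2, w)
        _, p3 = solve_alpha_psi(3.0 * v1, w)
        assert p12 == pytest.approx(p1 + p2, rel=1e-10, abs=1e-12)
        assert p3 == pytest.approx(3.0 * p1, rel=1e-10, abs=1e-12)


class TestSklearnSurface:
    def test_fit_transform_roundtrip(self, rng):
        F = rng.standard_normal((2, 6))
        dec = FingerprintDecomposer().fit(F)
        C = rng.standard_normal((20, 2))
        V = dec.inverse_transform(C)
        np.testing.assert_allclose(dec.transform(V), C, rtol=1e-9, atol=1e-12)

    def test_get_set_params_and_clone(self):
        dec = FingerprintDecomposer(collinearity_rtol=1e-10)
        assert dec.get_params()["collinearity_rtol"] == 1e-10
        dec2 = clone(dec)
        assert dec2.get_params() == dec.get_params()

    def test_fitted_attributes(self, rng):
        dec = FingerprintDecomposer().fit(rng.standard_normal((2, 6)))
        assert dec.weights_a_.shape == (6,)
        assert dec.weights_v_.shape == (6,)
        assert dec.gram_det_ > 0
        assert dec.components_.shape == (2, 6)

    def test_transform_before_fit_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            FingerprintDecomposer().transform(np.zeros((1, 6)))


class TestVolumeAndSV:
    def test_unit_psi_returns_calibration_volume(self):
        np.testing.assert_allclose(volume_curve(np.array([1.0]), 50.0), [50.0])

    def test_zero_psi_zero_volume(self):
        np.testing.assert_allclose(volume_curve(np.zeros(5), 50.0), 0.0)

    def test_volunteer_scale_applies(self):
        scale = CalibrationScale(k_volunteer=2.0, source="test")
        np.testing.assert_allclose(volume_curve(np.array([0.4]), 50.0, scale), [40.0])

    def test_sv_from_dipping_curve(self):
        tau = np.linspace(0, 800, 161)
        dv = np.zeros_like(tau)
        dv[40:120] = -73.0
        assert stroke_volume(dv) == pytest.approx(73.0)

    def test_flat_curve_gives_zero_sv(self):
        assert stroke_volume(np.zeros(100)) == 0.0

    def test_half_wave_closed_form(self):
        tau = np.linspace(0, 1, 401)
        dv = -50.0 * np.sin(np.pi * tau)
        assert stroke_volume(dv) == pytest.approx(50.0, rel=1e-5)

    def test_noise_unbiased_at_known_end_systole(self, rng):
        """With 1%-of-signal channel noise, the end-systolic volume reading is
        unbiased over 200 seeded beats (the reading is linear in the noise)."""
        f_a, f_v = np.linalg.qr(rng.standard_normal((6, 2)))[0].T
        w = compute_weights(f_a, f_v)
        tau = np.linspace(0, 1, 161)
        psi_true = -np.sin(np.pi * tau)  # dips to -1 at tau index 80
        v_clean = np.outer(f_v, psi_true)
        sigma = 0.01 * np.abs(psi_true).max() * np.linalg.norm(f_v)
        i_es = int(np.argmin(psi_true))
        readings = []
        for _ in range(200):
            v = v_clean + sigma * rng.standard_normal(v_clean.shape)
            _, psi = solve_alpha_psi(v, w)
            readings.append(-psi[i_es] * 50.0)
        readings = np.array(readings)
        se = readings.std(ddof=1) / np.sqrt(len(readings))
        assert abs(readings.mean() - 50.0) <= 2.0 * se + 1e-9


class TestCalibrationAndCO:
    def test_scale_is_ratio_of_means(self):
        assert calibrate_scale([40.0, 40.0], [60.0, 60.0]).k_volunteer == pytest.approx(1.5)

    def test_identity_for_identical_lists(self):
        assert calibrate_scale([55.0, 60.0], [55.0, 60.0]).k_volunteer == pytest.approx(1.0)

    def test_zero_mean_method_sv_rejected(self):
        with pytest.raises(ValueError):
            calibrate_scale([0.0, 0.0], [60.0])

    @pytest.mark.parametrize(
        "sv,hr,co", [(73.0, 69.0, 5.0), (50.0, 94.0, 4.7), (0.0, 60.0, 0.0)]
    )
    def test_cardiac_output_examples(self, sv, hr, co):
        assert cardiac_output(sv, hr) == pytest.approx(co)
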