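"""Linear and thin-plate-spline color correction fits."""

import numpy as np
import pytest

from skincal.calibration import (
    ControlPointSet,
    DuplicateControlPointError,
    SingularFitError,
    apply_linear,
    apply_tps,
    calibration_residuals,
    fit_linear,
    fit_tps,
    load_calibration,
    save_calibration,
    tps_kernel,
)


def random_cps(rng, n=16):
    return ControlPointSet(rng.uniform(0, 255, (n, 3)), rng.uniform(0, 255, (n, 3)))


AFFINE_M = np.array([[0.85, 0.05, 0.02], [0.03, 0.80, 0.04], [0.01, 0.02, 0.90]])
AFFINE_C = np.array([12.0, 5.0, 8.0])


def affine_cps(rng, n=16):
    measured = rng.uniform(0, 255, (n, 3))
    return ControlPointSet(measured, measured @ AFFINE_M.T + AFFINE_C)


class TestKernel:
    def test_zero_distance_is_zero(self):
        # the guard term keeps the K diagonal exactly zero
        assert tps_kernel(0.0) == 0.0

    def test_unit_distance_vanishes(self):
        assert tps_kernel(1.0) == pytest.approx(0.0, abs=1e-15)

    def test_natural_log_at_e(self):
        assert tps_kernel(np.e) == pytest.approx(2.0 * np.e**2, rel=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            tps_kernel(-1.0)

    def test_vectorized(self):
        r = np.array([0.0, 1.0, np.e])
        assert np.allclose(tps_kernel(r), [0.0, 0.0, 2 * np.e**2], atol=1e-12)


class TestControlPointSet:
    def test_shape_and_range_validation(self):
        with pytest.raises(ValueError):
            ControlPointSet(np.zeros((4, 3)), np.zeros((4, 3)))  # too few
        with pytest.raises(ValueError):
            ControlPointSet(np.zeros((6, 3)), np.zeros((5, 3)))
        bad = np.zeros((6, 3))
        bad[0, 0] = 300.0
        with pytest.raises(ValueError):
            ControlPointSet(bad, np.zeros((6, 3)))
        with pytest.raises(ValueError):
            ControlPointSet(np.full((6, 3), np.nan), np.zeros((6, 3)))


class TestFitLinear:
    def test_identity_data_gives_identity_map(self, rng):
        m = rng.uniform(0, 255, (16, 3))
        cal = fit_linear(ControlPointSet(m, m))
        assert np.allclose(cal.A_lin, np.hstack([np.zeros((3, 1)), np.eye(3)]), atol=1e-9)

    def test_recovers_exact_affine_map(self, rng):
        cal = fit_linear(affine_cps(rng))
        assert np.allclose(cal.A_lin[:, 0], AFFINE_C, atol=1e-8)
        assert np.allclose(cal.A_lin[:, 1:], AFFINE_M, atol=1e-10)

    @pytest.mark.parametrize("n", [5, 8, 16, 50])
    def test_matches_normal_equations_oracle(self, rng, n):
        cps = random_cps(rng, n)
        X = np.hstack([np.ones((n, 1)), cps.measured])
        oracle = np.linalg.inv(X.T @ X) @ X.T @ cps.reference
        cal = fit_linear(cps)
        assert np.allclose(cal.A_lin, oracle.T, atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        # all control colors on the neutral axis: R=G=B columns are collinear
        gray = np.tile(np.linspace(10, 240, 8)[:, None], (1, 3))
        with pytest.raises(SingularFitError, match="rank"):
            fit_linear(ControlPointSet(gray, gray))


class TestApplyLinear:
    def test_identity_calibration_is_identity(self, rng):
        from skincal.calibration import LinearCalibration

        ident = LinearCalibration(np.hstack([np.zeros((3, 1)), np.eye(3)]))
        img = rng.uniform(0, 255, (8, 8, 3))
        assert np.array_equal(apply_linear(ident, img), img)

    def test_offset_on_zero_image(self):
        from skincal.calibration import LinearCalibration

        cal = LinearCalibration(np.hstack([np.full((3, 1), 10.0), np.eye(3)]))
        out = apply_linear(cal, np.zeros((4, 4, 3)))
        assert np.allclose(out, 10.0)

    def test_output_clamped(self):
        from skincal.calibration import LinearCalibration

        cal = LinearCalibration(np.hstack([np.full((3, 1), 100.0), np.eye(3)]))
        out = apply_linear(cal, np.full((2, 2, 3), 250.0))
        assert np.all(out == 255.0)


class TestFitTPS:
    def test_exact_interpolation_on_random_sets(self, rng):
        for _ in range(20):
            cps = random_cps(rng)
            cal = fit_tps(cps)
            out = apply_tps(cal, cps.measured)
            assert np.max(np.abs(out - cps.reference)) < 1e-6 * 255

    def test_side_condition_orthogonality(self, rng):
        cps = random_cps(rng)
        cal = fit_tps(cps)
        assert np.max(np.abs(cps.design_matrix().T @ cal.W)) < 1e-6

    def test_identity_data_fixes_control_points(self, rng):
        m = rng.uniform(0, 255, (16, 3))
        cal = fit_tps(ControlPointSet(m, m))
        assert np.max(np.abs(cal.W)) < 1e-6
        assert np.allclose(apply_tps(cal, m), m, atol=1e-6)

    def test_affine_data_reduces_to_affine_map(self, rng):
        cps = affine_cps(rng)
        cal = fit_tps(cps)
        assert np.max(np.abs(cal.W)) < 1e-6
        # off-control pixels follow the pure affine map
        pix = rng.uniform(0, 255, (500, 3))
        expected = np.clip(pix @ AFFINE_M.T + AFFINE_C, 0, 255)
        assert np.allclose(apply_tps(cal, pix), expected, atol=1e-6)

    def test_duplicate_control_colors_rejected(self, rng):
        m = rng.uniform(0, 255, (16, 3))
        m[7] = m[2]
        with pytest.raises(DuplicateControlPointError):
            fit_tps(ControlPointSet(m, rng.uniform(0, 255, (16, 3))))

    def test_order_invariance(self, rng):
        cps = random_cps(rng)
        perm = rng.permutation(cps.n)
        cal_a = fit_tps(cps)
        cal_b = fit_tps(ControlPointSet(cps.measured[perm], cps.reference[perm]))
        pix = rng.uniform(0, 255, (200, 3))
        assert np.allclose(apply_tps(cal_a, pix), apply_tps(cal_b, pix), atol=1e-8)

    def test_regularization_handles_near_duplicates(self, rng):
        m = rng.uniform(0, 255, (16, 3))
        m[7] = m[2] + 1e-9
        cps = ControlPointSet(m, rng.uniform(0, 255, (16, 3)))
        cal = fit_tps(cps, regularization=1e-3)
        assert np.all(np.isfinite(cal.W))


class TestApplyTPS:
    def test_control_pixel_maps_to_reference(self, rng):
        cps = random_cps(rng)
        cal = fit_tps(cps)
        img = np.tile(cps.measured[3], (4, 4, 1))
        out = apply_tps(cal, img)
        assert np.allclose(out, np.clip(cps.reference[3], 0, 255), atol=1e-6)

    def test_deterministic_and_chunk_invariant(self, rng):
        cps = random_cps(rng)
        cal = fit_tps(cps)
        img = rng.uniform(0, 255, (16, 16, 3))
        a = apply_tps(cal, img)
        b = apply_tps(cal, img)
        c = apply_tps(cal, img, chunk_size=7)
        assert np.array_equal(a, b)  # identical inputs: bit-identical
        assert np.allclose(a, c, atol=1e-9)  # chunking only reorders BLAS sums

    def test_midpoint_under_affine_fit_is_affine_image(self, rng):
        cps = affine_cps(rng)
        cal = fit_tps(cps)
        mid = (cps.measured[0] + cps.measured[1]) / 2.0
        expected = mid @ AFFINE_M.T + AFFINE_C
        assert np.allclose(apply_tps(cal, mid[None, :])[0], expected, atol=1e-6)


class TestResiduals:
    def test_tps_residuals_vanish_on_control_points(self, rng):
        cps = random_cps(rng)
        res = calibration_residuals(fit_tps(cps), cps, space="LAB")
        assert res.mean < 1e-6

    def test_linear_residuals_vanish_on_affine_data(self, rng):
        cps = affine_cps(rng)
        res = calibration_residuals(fit_linear(cps), cps, space="RGB")
        assert res.mean < 1e-8

    def test_tps_beats_linear_under_gamma_distortion(self, rng):
        # non-affine device response: linear least squares cannot fit it,
        # the spline interpolates it exactly
        measured = rng.uniform(20, 235, (16, 3))
        reference = np.clip(255.0 * (measured / 255.0) ** 2.2, 0, 255)
        cps = ControlPointSet(measured, reference)
        lin = calibration_residuals(fit_linear(cps), cps, space="LAB")
        tps = calibration_residuals(fit_tps(cps), cps, space="LAB")
        assert tps.mean < lin.mean

    def test_summary_consistent_with_vector(self, rng):
        cps = random_cps(rng)
        res = calibration_residuals(fit_linear(cps), cps, space="RGB")
        assert res.mean == pytest.approx(float(np.mean(res.per_segment)), abs=1e-12)
        assert res.sd == pytest.approx(float(np.std(res.per_segment, ddof=1)), abs=1e-12)


class TestSerialization:
    @pytest.mark.parametrize("method", ["linear", "tps"])
    def test_json_round_trip(self, rng, tmp_path, method):
        cps = random_cps(rng)
        cal = fit_linear(cps) if method == "linear" else fit_tps(cps)
        path = tmp_path / "cal.json"
        save_calibration(cal, path)
        loaded = load_calibration(path)
        img = rng.uniform(0, 255, (6, 6, 3))
        from skincal.calibration import apply_calibration

        assert np.allclose(apply_calibration(loaded, img), apply_calibration(cal, img), atol=1e-12)
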