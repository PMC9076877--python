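"""Landmark transform estimation and image warping."""

import numpy as np
import pytest

from drusemap.errors import DegenerateGeometryError, ValidationError
from drusemap.registration import (
    LandmarkSet,
    SpatialTransform,
    check_alignment,
    estimate_transform,
    read_landmarks_csv,
    warp_image,
    write_landmarks_csv,
)

from conftest import apply_affine, make_affine


class TestEstimateTransform:
    def test_identity_on_identical_points(self, eight_landmarks):
        lms = LandmarkSet(eight_landmarks, eight_landmarks.copy())
        tf = estimate_transform(lms, "affine")
        np.testing.assert_allclose(tf.matrix, [[1, 0, 0], [0, 1, 0]], atol=1e-9)
        assert tf.residual_rmse == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("model", ["affine", "similarity"])
    def test_exact_recovery_of_planted_transform(self, eight_landmarks, model):
        # rotation 5 deg, scale 1.02, translation (3, -2): inside both model classes
        true = make_affine(5.0, 1.02, (3.0, -2.0))
        fixed = apply_affine(true, eight_landmarks)
        tf = estimate_transform(LandmarkSet(eight_landmarks, fixed), model)
        np.testing.assert_allclose(tf.matrix, true, atol=1e-9)
        assert tf.residual_rmse < 1e-9

    def test_noise_rmse_bounded_over_seeds(self, eight_landmarks):
        # sigma=0.5 px landmark jitter keeps residual RMSE <= 1.5 px
        true = make_affine(3.0, 0.99, (-1.0, 4.0))
        worst = 0.0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fixed = apply_affine(true, eight_landmarks) + rng.normal(
                0, 0.5, size=eight_landmarks.shape
            )
            tf = estimate_transform(LandmarkSet(eight_landmarks, fixed), "affine")
            worst = max(worst, tf.residual_rmse)
        assert worst <= 1.5

    def test_residual_invariant_to_pair_order(self, eight_landmarks):
        true = make_affine(2.0, 1.01, (0.5, 0.5))
        fixed = apply_affine(true, eight_landmarks) + np.random.default_rng(0).normal(
            0, 0.3, size=eight_landmarks.shape
        )
        tf1 = estimate_transform(LandmarkSet(eight_landmarks, fixed))
        perm = np.random.default_rng(1).permutation(len(eight_landmarks))
        tf2 = estimate_transform(LandmarkSet(eight_landmarks[perm], fixed[perm]))
        assert tf1.residual_rmse == pytest.approx(tf2.residual_rmse, rel=1e-12)

    def test_collinear_points_rejected(self):
        pts = np.array([[0.0, i] for i in range(8)])
        with pytest.raises(DegenerateGeometryError):
            estimate_transform(LandmarkSet(pts, pts + 1.0), "affine")

    def test_too_few_points_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(DegenerateGeometryError):
            estimate_transform(LandmarkSet(pts, pts), "affine")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            LandmarkSet(np.zeros((4, 2)), np.zeros((5, 2)))


class TestWarpImage:
    def test_identity_transform_preserves_image(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(16, 18))
        out = warp_image(img, SpatialTransform.identity(), (16, 18))
        np.testing.assert_allclose(out, img, atol=1e-12)

    def test_integer_translation_moves_impulse_exactly(self):
        img = np.zeros((20, 20))
        img[5, 7] = 1.0
        tf = SpatialTransform("affine", np.array([[1.0, 0, 5.0], [0, 1.0, 0]]))
        out = warp_image(img, tf, (20, 20))
        assert out[10, 7] == pytest.approx(1.0)
        assert out.sum() == pytest.approx(1.0)

    def test_round_trip_close_away_from_borders(self):
        rr, cc = np.mgrid[0:64, 0:64]
        img = 0.5 + 0.3 * np.sin(rr / 9.0) * np.cos(cc / 7.0)
        tf = SpatialTransform("affine", make_affine(4.0, 1.01, (2.0, -1.0)))
        back = warp_image(warp_image(img, tf, (64, 64)), tf.inverse(), (64, 64))
        interior = np.s_[10:-10, 10:-10]
        mad = np.mean(np.abs(back[interior] - img[interior]))
        assert mad <= 0.01 * (img.max() - img.min())

    def test_bilinear_warp_preserves_value_range(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0.2, 0.9, size=(32, 32))
        tf = SpatialTransform("affine", make_affine(7.0, 0.97, (1.5, 2.5)))
        out = warp_image(img, tf, (32, 32))
        assert out.min() >= 0.0  # fill value
        assert out.max() <= img.max() + 1e-12

    def test_singular_transform_rejected(self):
        img = np.ones((8, 8))
        tf = SpatialTransform("affine", np.array([[1.0, 0, 0], [1.0, 0, 0]]))
        with pytest.raises(DegenerateGeometryError):
            warp_image(img, tf, (8, 8))


class TestCheckAlignment:
    def test_identical_images_and_landmarks(self, eight_landmarks):
        rng = np.random.default_rng(5)
        img = rng.uniform(size=(30, 30))
        rep = check_alignment(img, img, LandmarkSet(eight_landmarks, eight_landmarks))
        assert rep.landmark_rmse == 0.0
        assert rep.correlation == pytest.approx(1.0)

    def test_planted_shift_reported(self, eight_landmarks):
        rng = np.random.default_rng(6)
        img = rng.uniform(size=(30, 30))
        shifted = np.roll(img, 2, axis=0)
        lms = LandmarkSet(eight_landmarks + [2.0, 0.0], eight_landmarks)
        rep = check_alignment(img, shifted, lms)
        assert rep.landmark_rmse == pytest.approx(2.0, abs=0.5)

    def test_uncorrelated_noise_near_zero_correlation(self, eight_landmarks):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.uniform(size=(40, 40))
            b = rng.uniform(size=(40, 40))
            rep = check_alignment(a, b, LandmarkSet(eight_landmarks, eight_landmarks))
            assert abs(rep.correlation) < 0.1


class TestLandmarkCsv:
    def test_round_trip(self, tmp_path, eight_landmarks):
        lms = LandmarkSet(eight_landmarks, eight_landmarks + 2.5)
        path = tmp_path / "lm.csv"
        write_landmarks_csv(lms, path)
        back = read_landmarks_csv(path)
        np.testing.assert_allclose(back.moving, lms.moving)
        np.testing.assert_allclose(back.fixed, lms.fixed)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("moving_row,moving_col,fixed_row\n1,2,3\n")
        with pytest.raises(ValidationError):
            read_landmarks_csv(path)
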