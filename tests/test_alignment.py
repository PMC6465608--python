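import numpy as np
import pytest

from tls2d.alignment import (
    IDENTITY,
    affine_warp,
    compose_transforms,
    image_jacobian,
    invert_transform,
    normalize_columns,
    update_transform_increment,
    warp_mask,
)

from oracles import finite_difference_jacobian

GENERIC_TAU = np.array(
    [np.cos(0.05), -np.sin(0.05), 0.3, np.sin(0.05), np.cos(0.05), -0.7]
)


class TestAffineWarp:
    def test_identity_is_exact(self, smooth_image):
        assert np.array_equal(affine_warp(smooth_image, IDENTITY), smooth_image)

    def test_integer_translation_of_constant_image(self):
        img = np.full((20, 20), 0.42)
        tau = IDENTITY.copy()
        tau[2] = 2.0
        assert np.allclose(affine_warp(img, tau), img)

    def test_rotation_round_trip(self, smooth_image):
        th = np.deg2rad(5.0)
        fwd = np.array(
            [np.cos(th), -np.sin(th), 0, np.sin(th), np.cos(th), 0]
        )
        back = np.array(
            [np.cos(th), np.sin(th), 0, -np.sin(th), np.cos(th), 0]
        )
        rt = affine_warp(affine_warp(smooth_image, fwd), back)
        assert np.abs(rt - smooth_image).max() <= 0.02

    def test_singular_linear_part_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            affine_warp(np.zeros((8, 8)), np.array([1, 0, 0, 1, 0, 0.0]))

    def test_composition_matches_single_warp(self, smooth_image):
        a = np.array([1.0, 0.0, 1.3, 0.0, 1.0, -0.8])
        th = np.deg2rad(3.0)
        b = np.array([np.cos(th), -np.sin(th), 0.4, np.sin(th), np.cos(th), 0.2])
        two = affine_warp(affine_warp(smooth_image, a), b)
        one = affine_warp(smooth_image, compose_transforms(a, b))
        assert np.abs(two - one).max() <= 0.02

    def test_invert_round_trips_parameters(self):
        inv = invert_transform(GENERIC_TAU)
        assert np.allclose(
            compose_transforms(GENERIC_TAU, inv), IDENTITY, atol=1e-12
        )

    def test_warp_mask_nearest_binary(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[5:9, 6:10] = True
        out = warp_mask(mask, GENERIC_TAU)
        assert out.dtype == bool
        assert 0 < out.sum() < mask.size


class TestImageJacobian:
    def test_constant_image_zero_jacobian(self):
        J = image_jacobian(np.full((12, 12), 0.3), GENERIC_TAU)
        assert np.abs(J).max() == 0.0

    def test_matches_finite_differences(self, smooth_image):
        J = image_jacobian(smooth_image, GENERIC_TAU)
        Jfd = finite_difference_jacobian(
            lambda t: affine_warp(smooth_image, t).ravel(), GENERIC_TAU
        )
        rel = np.linalg.norm(J - Jfd) / np.linalg.norm(Jfd)
        assert rel < 1e-3

    def test_translation_columns_are_sampled_gradients(self, smooth_image):
        # the tx / ty columns must equal the finite differences of pure
        # translation, i.e. the warped spatial gradients
        J = image_jacobian(smooth_image, GENERIC_TAU)
        Jfd = finite_difference_jacobian(
            lambda t: affine_warp(smooth_image, t).ravel(), GENERIC_TAU
        )
        for col in (2, 5):
            rel = np.linalg.norm(J[:, col] - Jfd[:, col]) / np.linalg.norm(
                Jfd[:, col]
            )
            assert rel < 1e-3

    def test_linearization_error_second_order(self, smooth_image):
        # base warp at cell centers, perturbation below half a pixel:
        # the remainder is the pure quadratic term, so halving the
        # perturbation divides the error by ~4
        tau = np.array([1.0, 0.0, 0.5, 0.0, 1.0, 0.5])
        J = image_jacobian(smooth_image, tau)
        delta = np.array([0.004, -0.003, 0.1, 0.002, 0.005, -0.08])

        def lin_err(d):
            return np.linalg.norm(
                affine_warp(smooth_image, tau + d).ravel()
                - affine_warp(smooth_image, tau).ravel()
                - J @ d
            )

        ratio = lin_err(delta) / lin_err(delta / 2)
        assert 3.5 < ratio < 4.5


class TestTransformIncrement:
    def test_zero_residual_gives_zero_increment(self, smooth_image):
        A = np.column_stack(
            [affine_warp(smooth_image, IDENTITY).ravel() for _ in range(3)]
        )
        J = [image_jacobian(smooth_image, IDENTITY) for _ in range(3)]
        dtau = update_transform_increment(
            A / 2, A / 2, A, np.zeros_like(A), 1.0, J
        )
        assert np.abs(dtau).max() < 1e-12

    def test_matches_normal_equations(self, smooth_image):
        rng = np.random.default_rng(0)
        J = [image_jacobian(smooth_image, GENERIC_TAU)]
        r = rng.normal(size=(J[0].shape[0], 1))
        A = np.zeros_like(r)
        dtau = update_transform_increment(
            r, np.zeros_like(r), A, np.zeros_like(r), 1.0, J
        )
        ref = np.linalg.lstsq(J[0], r[:, 0], rcond=None)[0]
        assert np.abs(dtau[:, 0] - ref).max() < 1e-8

    def test_output_shape(self, smooth_image):
        n = 4
        A = np.column_stack(
            [affine_warp(smooth_image, GENERIC_TAU).ravel()] * n
        )
        J = [image_jacobian(smooth_image, GENERIC_TAU)] * n
        dtau = update_transform_increment(
            A, np.zeros_like(A), A, np.zeros_like(A), 2.0, J
        )
        assert dtau.shape == (6, n)


class TestNormalizeColumns:
    def test_unit_columns_unchanged(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(30, 3))
        A /= np.linalg.norm(A, axis=0)
        An, _, norms = normalize_columns(A, [np.zeros((30, 6))] * 3)
        assert np.abs(An - A).max() < 1e-12
        assert np.allclose(norms, 1.0)

    def test_output_columns_unit_norm(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(40, 5)) * 3
        An, _, _ = normalize_columns(A, [np.zeros((40, 6))] * 5)
        assert np.allclose(np.linalg.norm(An, axis=0), 1.0, atol=1e-12)

    def test_zero_column_rejected(self):
        A = np.zeros((10, 2))
        A[:, 0] = 1.0
        with pytest.raises(ValueError, match="image 1"):
            normalize_columns(A, [np.zeros((10, 6))] * 2)

    def test_corrected_jacobian_matches_finite_differences(self, smooth_image):
        A = np.column_stack(
            [
                affine_warp(smooth_image, GENERIC_TAU).ravel(),
                smooth_image.ravel(),
            ]
        )
        J = [
            image_jacobian(smooth_image, GENERIC_TAU),
            image_jacobian(smooth_image, IDENTITY),
        ]
        _, Jc, _ = normalize_columns(A, J)

        def normwarp(t):
            v = affine_warp(smooth_image, t).ravel()
            return v / np.linalg.norm(v)

        Jfd = finite_difference_jacobian(normwarp, GENERIC_TAU)
        rel = np.linalg.norm(Jc[0] - Jfd) / np.linalg.norm(Jfd)
        assert rel < 1e-3
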