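"""Affine/nonrigid registration, field composition and chaining."""

import numpy as np
import pytest
from scipy import ndimage

from tractcluster.registration import (
    DisplacementField,
    RegistrationConfig,
    apply_field,
    compose,
    estimate_affine,
    estimate_nonrigid,
    stepwise_chain,
)


def constant_field(shape, dr, dc):
    v = np.zeros((*shape, 2))
    v[..., 0], v[..., 1] = dr, dc
    return DisplacementField(v)


def bump_field(shape, amp_r, amp_c, center=(32, 32), width=10.0):
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    g = np.exp(-(((rows - center[0]) / width) ** 2 + ((cols - center[1]) / width) ** 2))
    return DisplacementField(np.stack([amp_r * g, amp_c * g], axis=-1))


class TestApplyField:
    def test_identity_nearest_is_bit_exact(self, blob_image):
        ident = DisplacementField.identity(blob_image.shape)
        assert np.array_equal(apply_field(ident, blob_image, "nearest"), blob_image)

    def test_identity_linear_within_float_tolerance(self, blob_image):
        ident = DisplacementField.identity(blob_image.shape)
        assert np.allclose(apply_field(ident, blob_image, "linear"), blob_image)

    def test_integer_translation_nearest_equals_shifted_input(self):
        img = np.arange(48, dtype=float).reshape(6, 8)
        out = apply_field(constant_field(img.shape, 2, 1), img, "nearest", cval=-1)
        assert np.array_equal(out[:4, :7], img[2:, 1:])

    def test_labels_never_gain_new_values(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 5, size=(32, 32)).astype(np.int32)
        fld = bump_field((32, 32), 2.0, -1.5, center=(16, 16))
        warped = apply_field(fld, labels, "nearest")
        assert set(np.unique(warped)) <= set(np.unique(labels))

    def test_unknown_interpolation_rejected(self, blob_image):
        with pytest.raises(ValueError, match="interpolation"):
            apply_field(DisplacementField.identity((64, 64)), blob_image, "cubic")

    def test_out_of_grid_metric_samples_become_nan(self, blob_image):
        out = apply_field(constant_field(blob_image.shape, 100, 0), blob_image)
        assert np.all(np.isnan(out))


class TestCompose:
    def test_compose_with_identity_returns_other_field(self):
        fld = bump_field((40, 40), 1.5, -0.5, center=(20, 20))
        ident = DisplacementField.identity((40, 40))
        assert np.allclose(compose(ident, fld).vectors, fld.vectors, atol=1e-9)
        assert np.allclose(compose(fld, ident).vectors, fld.vectors, atol=1e-9)

    def test_two_constant_translations_add(self):
        a = constant_field((20, 20), 1.0, -2.0)
        b = constant_field((20, 20), 0.5, 3.0)
        comp = compose(a, b)
        inner = comp.vectors[5:15, 5:15]  # away from edge clamping
        assert np.allclose(inner[..., 0], 1.5) and np.allclose(inner[..., 1], 1.0)

    def test_composition_matches_sequential_application(self, blob_image):
        """warp(compose(f,g), img) ≈ warp(f, warp(g, img)) inside the grid."""
        f = bump_field((64, 64), 1.8, -1.0, center=(28, 36), width=14)
        g = bump_field((64, 64), -1.2, 1.5, center=(36, 28), width=12)
        once = apply_field(compose(f, g), blob_image, "linear", cval=0.0)
        twice = apply_field(f, apply_field(g, blob_image, "linear", cval=0.0), "linear", cval=0.0)
        diff = np.abs(once - twice)
        assert diff.mean() < 0.01 * np.ptp(blob_image)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compose(DisplacementField.identity((10, 10)), DisplacementField.identity((12, 12)))


class TestEstimateAffine:
    def test_identical_images_recover_identity(self, blob_image):
        tf = estimate_affine(blob_image, blob_image)
        assert np.allclose(tf.matrix, np.eye(2), atol=0.02)
        assert np.allclose(tf.translation, 0, atol=0.2)

    def test_known_translation_recovered_within_half_pixel(self, blob_image):
        moving = np.roll(np.roll(blob_image, 3, axis=0), -2, axis=1)
        tf = estimate_affine(blob_image, moving)
        assert np.allclose(tf.translation, [3, -2], atol=0.5)

    def test_known_scale_recovered_within_5_percent(self, blob_image):
        # moving = fixed magnified by 1.2 about the grid center: the map
        # from fixed to moving coordinates has scale 1.2
        c = np.array([31.5, 31.5])
        moving = ndimage.affine_transform(
            blob_image, np.eye(2) / 1.2, offset=c - c / 1.2, order=1
        )
        tf = estimate_affine(blob_image, moving)
        assert np.allclose(np.diag(tf.matrix), 1.2, rtol=0.05)

    def test_empty_image_rejected(self, blob_image):
        with pytest.raises(ValueError, match="empty"):
            estimate_affine(np.zeros((32, 32)), blob_image[:32, :32])


class TestEstimateNonrigid:
    def test_already_aligned_gives_near_zero_field(self, blob_image):
        fld = estimate_nonrigid(blob_image, blob_image)
        assert fld.magnitude().max() <= 0.1

    def test_known_two_pixel_bump_recovered_below_one_pixel_epe(self, blob_image):
        true = bump_field((64, 64), 2.0, 1.0, width=10)
        moving = apply_field(true, blob_image, "linear", cval=0.0)
        est = estimate_nonrigid(blob_image, moving)
        mask = blob_image > 0.05 * blob_image.max()
        epe = np.hypot(*(est.vectors - true.vectors).transpose(2, 0, 1))
        assert epe[mask].mean() < 1.0

    def test_ssd_never_worse_than_identity(self, blob_image):
        rng = np.random.default_rng(3)
        moving = blob_image + 0.3 * rng.standard_normal(blob_image.shape)
        est = estimate_nonrigid(blob_image, moving)
        before = float(((moving - blob_image) ** 2).sum())
        after = float(((apply_field(est, moving, "linear", cval=0.0) - blob_image) ** 2).sum())
        assert after <= before

    def test_disk_dice_improves_after_registration(self):
        rows, cols = np.mgrid[0:48, 0:48].astype(float)
        disk = ((rows - 24) ** 2 + (cols - 24) ** 2 <= 100).astype(float)
        shifted = ((rows - 28) ** 2 + (cols - 21) ** 2 <= 100).astype(float)

        def dice(a, b):
            return 2 * np.sum((a > 0.5) & (b > 0.5)) / (np.sum(a > 0.5) + np.sum(b > 0.5))

        est = estimate_nonrigid(disk, shifted)
        warped = apply_field(est, shifted, "linear", cval=0.0)
        assert dice(disk, warped) >= dice(disk, shifted)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RegistrationConfig(control_spacing=1)
        with pytest.raises(ValueError):
            RegistrationConfig(levels=0)
        with pytest.raises(ValueError):
            RegistrationConfig(metric="mutual_information")


class TestStepwiseChain:
    def test_identical_slices_give_near_identity_chain(self, blob_image):
        chain = stepwise_chain([blob_image] * 4, ref_index=1)
        for fld in chain.fields:
            assert fld.magnitude().max() <= 0.1

    def test_single_slice_chain_is_identity(self, blob_image):
        chain = stepwise_chain([blob_image], ref_index=0)
        assert len(chain.fields) == 1
        assert chain.fields[0].magnitude().max() == 0.0

    def test_translated_stack_recovers_cumulative_translation(self, blob_image):
        """Slice at distance k is shifted k pixels: the chained field must
        recover the cumulative shift within a pixel."""
        slices = [np.roll(blob_image, k, axis=0) for k in range(4)]
        chain = stepwise_chain(slices, ref_index=0)
        mask = blob_image > 0.1 * blob_image.max()
        far = chain.fields[3].vectors
        assert abs(far[mask][:, 0].mean() - 3.0) < 1.0
        assert abs(far[mask][:, 1].mean()) < 1.0

    def test_chained_field_equals_composition_of_pairwise_fields(self, blob_image):
        slices = [np.roll(blob_image, k, axis=1) for k in range(3)]
        cfg = RegistrationConfig()
        chain = stepwise_chain(slices, ref_index=0, cfg=cfg)
        f01 = estimate_nonrigid(slices[0], slices[1], cfg)
        f12 = estimate_nonrigid(slices[1], slices[2], cfg)
        refit = compose(f01, f12)
        assert np.allclose(chain.fields[2].vectors, refit.vectors, atol=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            stepwise_chain([], ref_index=0)
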