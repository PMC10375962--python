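"""Probability-map providers, augmentation and the toy CNN backend."""

import numpy as np
import pytest

from unls import dice
from unls.grid import ImageGrid, LabelMask
from unls.phantom import CorruptionConfig
from unls.probmap import (CnnConfig, ProviderConfig, augment_pair, build_model,
                          provide_probability_map, train_provider)


@pytest.fixture()
def two_level_phantom():
    """Noiseless image: kidney at 0.8, background at 0.2."""
    yy, xx = np.mgrid[0:32, 0:32]
    kid = ((yy - 16) ** 2 + (xx - 16) ** 2 <= 8 ** 2)
    img = ImageGrid(np.where(kid, 0.8, 0.2))
    return img, LabelMask(kid.astype(np.uint8))


class TestProviders:
    def test_oracle_zero_corruption_is_truth(self, two_level_phantom):
        img, truth = two_level_phantom
        u = provide_probability_map(img, ProviderConfig("oracle_corrupted"),
                                    truth=truth)
        assert np.array_equal(u.p_kidney, truth.labels.astype(float))

    def test_oracle_requires_truth(self, two_level_phantom):
        with pytest.raises(ValueError, match="truth"):
            provide_probability_map(two_level_phantom[0],
                                    ProviderConfig("oracle_corrupted"))

    def test_intensity_bayes_separates_two_level_phantom(self, two_level_phantom):
        img, truth = two_level_phantom
        u = provide_probability_map(img, ProviderConfig("intensity_bayes"),
                                    truth=truth)
        assert np.array_equal(u.threshold(0.5).labels, truth.labels)

    def test_midpoint_intensity_gets_half_probability(self):
        img = ImageGrid(np.full((16, 16), 0.5))
        img.pixels[0, 0] = 0.0  # give the normaliser some contrast
        img.pixels[0, 1] = 1.0
        cfg = ProviderConfig("intensity_bayes", bayes_means=(0.8, 0.2),
                             bayes_variances=(0.01, 0.01))
        u = provide_probability_map(img, cfg)
        assert u.p_kidney[5, 5] == pytest.approx(0.5, abs=1e-12)

    def test_posterior_monotone_in_intensity(self):
        vals = np.linspace(0, 1, 256).reshape(16, 16)
        cfg = ProviderConfig("intensity_bayes", bayes_means=(0.7, 0.3),
                             bayes_variances=(0.02, 0.02))
        u = provide_probability_map(ImageGrid(vals), cfg)
        assert np.all(np.diff(u.p_kidney.ravel()) >= 0)

    def test_tiny_class_variance_rejected(self):
        cfg = ProviderConfig("intensity_bayes", bayes_means=(0.8, 0.2),
                             bayes_variances=(1e-14, 0.01))
        with pytest.raises(ValueError, match="variance"):
            provide_probability_map(ImageGrid(np.eye(16)), cfg)

    def test_provider_output_in_unit_interval(self, two_level_phantom):
        img, truth = two_level_phantom
        cfg = ProviderConfig("oracle_corrupted",
                             corruption=CorruptionConfig(n_fp_blobs=1,
                                                         fp_blob_radius=(2, 3),
                                                         label_noise_level=0.3,
                                                         boundary_blur_sigma=2.0,
                                                         rng_seed=1))
        u = provide_probability_map(img, cfg, truth=truth)
        assert u.p_kidney.min() >= 0.0 and u.p_kidney.max() <= 1.0


class TestAugmentation:
    def test_emits_exactly_twelve_variants(self, two_level_phantom):
        assert len(augment_pair(*two_level_phantom, seed=0)) == 12

    def test_half_turn_is_involution(self, two_level_phantom):
        img, mask = two_level_phantom
        variants = augment_pair(img, mask, seed=0)
        rot180_img, rot180_mask = variants[5]  # translation + 4 rotations first
        assert np.array_equal(np.rot90(rot180_img.pixels, 2), img.pixels)
        assert np.array_equal(np.rot90(rot180_mask.labels, 2), mask.labels)

    def test_noise_variants_leave_mask_untouched(self, two_level_phantom):
        img, mask = two_level_phantom
        variants = augment_pair(img, mask, seed=3)
        from unls.io import normalize_intensity
        norm = normalize_intensity(img).pixels
        for (aug_img, aug_mask), var in zip(variants[8:11], (0.01, 0.02, 0.05)):
            assert np.array_equal(aug_mask.labels, mask.labels)
            resid = aug_img.pixels - norm
            assert resid.var() == pytest.approx(var, rel=0.2)

    def test_geometric_variants_transform_mask_and_image_together(
            self, two_level_phantom):
        """The mask tracks the image exactly: re-thresholding the augmented
        two-level image reproduces the augmented mask away from edges."""
        img, mask = two_level_phantom
        for aug_img, aug_mask in augment_pair(img, mask, seed=1)[:8]:
            rethresh = aug_img.pixels > 0.5
            assert dice(LabelMask(rethresh.astype(np.uint8)), aug_mask) > 0.95

    def test_deterministic_per_seed(self, two_level_phantom):
        a = augment_pair(*two_level_phantom, seed=7)
        b = augment_pair(*two_level_phantom, seed=7)
        for (ia, ma), (ib, mb) in zip(a, b):
            assert np.array_equal(ia.pixels, ib.pixels)
            assert np.array_equal(ma.labels, mb.labels)


class TestBuildModel:
    def test_output_shape_matches_input(self):
        desc = build_model(CnnConfig("unt", depth=4, base_filters=64), (256, 256))
        assert desc.output_shape == (256, 256, 1)
        assert desc.layers[-1]["activation"] == "sigmoid"

    def test_bcd_unt_has_three_dense_stages_in_deepest_block(self):
        desc = build_model(CnnConfig("bcd_unt"), (256, 256))
        dense = [l for l in desc.layers if l.get("dense")]
        assert len(dense) == 3
        assert all(l["name"].startswith("enc3") for l in dense)
        assert any("bconvlstm" in l["name"] for l in desc.layers)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_model(CnnConfig("unt", depth=4), (250, 250))


@pytest.fixture(scope="module")
def toy_pairs():
    from unls import PhantomConfig, make_cohort
    from unls.pipeline import pick_frame
    cfg = PhantomConfig(image_size=(32, 32), n_frames=4, semi_axes=(7, 4),
                        t0=1, alpha=2.0, beta_t=1.0, sigma2=0.005,
                        angle_deg=15)
    cohort = make_cohort(8, cfg, variability={"center_px": 3.0}, seed=21)
    return [(pick_frame(s.frames), s.truth) for s in cohort]


class TestTraining:
    def test_seeded_initialisation_reproducible(self, toy_pairs):
        cfg = CnnConfig("unt", depth=1, base_filters=2, epochs=1, batch_size=4,
                        initial_learning_rate=1e-3, rng_seed=5)
        _, c1 = train_provider(toy_pairs[:6], toy_pairs[6:], cfg)
        _, c2 = train_provider(toy_pairs[:6], toy_pairs[6:], cfg)
        assert c1.val_loss[0] == c2.val_loss[0]
        assert c1.val_loss[-1] == c2.val_loss[-1]

    def test_training_reduces_validation_loss(self, toy_pairs):
        cfg = CnnConfig("unt", depth=1, base_filters=4, epochs=4, batch_size=2,
                        initial_learning_rate=5e-3, rng_seed=0)
        provider, curves = train_provider(toy_pairs[:6], toy_pairs[6:], cfg)
        assert curves.val_loss[-1] < curves.val_loss[0]
        u = provider.predict(toy_pairs[6][0])
        assert u.p_kidney.min() >= 0.0 and u.p_kidney.max() <= 1.0

    def test_empty_training_set_rejected(self, toy_pairs):
        cfg = CnnConfig("unt", epochs=1)
        with pytest.raises(ValueError):
            train_provider([], toy_pairs[6:], cfg)

    def test_curves_csv_round_trip(self, tmp_path, toy_pairs):
        cfg = CnnConfig("unt", depth=1, base_filters=2, epochs=1, batch_size=4,
                        initial_learning_rate=1e-3, rng_seed=5)
        _, curves = train_provider(toy_pairs[:6], toy_pairs[6:], cfg)
        out = tmp_path / "curves.csv"
        curves.to_csv(out)
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "epoch,train_loss,val_loss,train_acc,val_acc"
        assert len(lines) == len(curves.epoch) + 1
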