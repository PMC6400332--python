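import numpy as np
import pytest
from sklearn.base import clone

from petctseg.augment import (
    AugmentationConfig,
    AugmentationConfigError,
    DEFAULT_AUG_CONFIG,
    NoiseSpec,
    SliceAugmenter,
    add_noise,
    apply_affine,
    augment_dataset,
    split_by_patient,
)
from petctseg.labels import SlicePair
from tests.conftest import random_pair


class TestConfigValidation:
    def test_default_config_counts(self):
        assert DEFAULT_AUG_CONFIG.transformed_per_slice == 27
        assert DEFAULT_AUG_CONFIG.variants_per_slice == 54

    @pytest.mark.parametrize("kwargs", [
        dict(rotation_angles=(45.0,)),                      # identity angle missing
        dict(rotation_angles=(0.0, 200.0)),                 # beyond max angle
        dict(scale_factors_x=(0.9, 1.1)),                   # identity scale missing
        dict(scale_factors_x=(1.0, 1.2)),                   # beyond max scale delta
        dict(scale_factors_y=(1.0, 0.5)),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(AugmentationConfigError):
            AugmentationConfig(**kwargs)

    @pytest.mark.parametrize("spec", [
        ("gaussian", 11.0, 1), ("uniform", 10.5, 1), ("salt_pepper", 0.6, 1),
        ("gaussian", 5.0, 0), ("perlin", 1.0, 1),
    ])
    def test_invalid_noise_specs_rejected(self, spec):
        with pytest.raises(AugmentationConfigError):
            NoiseSpec(*spec)

    def test_round_trips_through_dict(self):
        d = DEFAULT_AUG_CONFIG.to_dict()
        assert AugmentationConfig.from_dict(d) == DEFAULT_AUG_CONFIG


class TestApplyAffine:
    def test_identity_is_exact(self, rng):
        p = random_pair(rng)
        t = apply_affine(p, 0.0, 1.0, 1.0)
        np.testing.assert_array_equal(t.image, p.image)
        np.testing.assert_array_equal(t.mask, p.mask)

    def test_right_angle_equals_index_rotation(self, rng):
        """+90 deg about the center of a square image is an exact index permutation."""
        p = random_pair(rng, shape=(15, 15))
        t = apply_affine(p, 90.0, 1.0, 1.0)
        np.testing.assert_array_equal(t.mask, np.rot90(p.mask, 1))
        np.testing.assert_allclose(t.image, np.rot90(p.image, 1), atol=1e-4)
        t2 = apply_affine(p, -90.0, 1.0, 1.0)
        np.testing.assert_array_equal(t2.mask, np.rot90(p.mask, 3))

    @pytest.mark.parametrize("angle, sx, sy", [(37.0, 1.1, 0.9), (-120.0, 0.85, 1.15), (180.0, 1.0, 1.0)])
    def test_masks_stay_binary_and_shapes_fixed(self, rng, angle, sx, sy):
        p = random_pair(rng, shape=(21, 21))
        t = apply_affine(p, angle, sx, sy)
        assert t.image.shape == p.image.shape
        assert set(np.unique(t.mask)) <= {0, 1}
        assert t.provenance.angle_deg == angle

    def test_out_of_bounds_filled_with_image_minimum(self, rng):
        img = rng.uniform(100, 200, size=(16, 16)).astype(np.float32)
        p = SlicePair(img, np.zeros((16, 16), dtype=np.uint8))
        t = apply_affine(p, 45.0, 1.0, 1.0)
        assert t.image.min() == pytest.approx(img.min(), abs=1e-3)
        assert t.image[0, 0] == pytest.approx(img.min(), abs=1e-3)  # corner rotated out of field

    def test_scale_beyond_table_bound_rejected(self, rng):
        p = random_pair(rng)
        with pytest.raises(AugmentationConfigError):
            apply_affine(p, 0.0, 1.2, 1.0)
        with pytest.raises(AugmentationConfigError):
            apply_affine(p, 0.0, 1.0, 0.8)


class TestAddNoise:
    def test_zero_sd_gaussian_is_identity(self, rng):
        p = random_pair(rng)
        t = add_noise(p, NoiseSpec("gaussian", 0.0), np.random.default_rng(0))
        np.testing.assert_array_equal(t.image, p.image)

    @pytest.mark.parametrize("spec", [NoiseSpec("gaussian", 5.0), NoiseSpec("uniform", 3.0),
                                      NoiseSpec("salt_pepper", 0.1)])
    def test_mask_never_touched(self, rng, spec):
        p = random_pair(rng)
        t = add_noise(p, spec, np.random.default_rng(3))
        np.testing.assert_array_equal(t.mask, p.mask)
        assert t.provenance.noise == spec.tag

    def test_gaussian_moments_on_constant_image(self):
        img = np.full((128, 128), 1000.0, dtype=np.float32)
        p = SlicePair(img, np.zeros_like(img, dtype=np.uint8))
        t = add_noise(p, NoiseSpec("gaussian", 5.0), np.random.default_rng(7))
        assert t.image.mean() == pytest.approx(1000.0, abs=0.5)
        assert 4.5 <= t.image.std() <= 5.5

    def test_uniform_amplitude_bounds(self, rng):
        img = np.zeros((64, 64), dtype=np.float32)
        p = SlicePair(img, np.zeros_like(img, dtype=np.uint8))
        t = add_noise(p, NoiseSpec("uniform", 4.0), np.random.default_rng(9))
        assert t.image.min() >= -4.0 and t.image.max() <= 4.0
        assert t.image.std() > 1.0

    def test_salt_pepper_density_count(self, rng):
        img = rng.uniform(0, 100, size=(50, 50)).astype(np.float32)
        p = SlicePair(img, np.zeros_like(img, dtype=np.uint8))
        t = add_noise(p, NoiseSpec("salt_pepper", 0.2), np.random.default_rng(5))
        changed = int(np.sum(t.image != img))
        n_expected = int(round(0.2 * img.size))
        # a flipped pixel may coincide with its previous value; bound, not equality
        assert changed <= n_expected
        assert changed >= int(0.9 * n_expected)
        assert set(np.unique(t.image[t.image != img])) <= {img.min(), img.max()}


class TestAugmentDataset:
    def test_default_magnification_factors(self, rng):
        pairs = [random_pair(rng, patient_id="a"), random_pair(rng, patient_id="b")]
        assert len(augment_dataset(pairs, DEFAULT_AUG_CONFIG)) == 2 * 54
        no_noise = AugmentationConfig(rotation_angles=(-45.0, 0.0, 45.0),
                                      scale_factors_x=(0.9, 1.0, 1.1),
                                      scale_factors_y=(0.9, 1.0, 1.1))
        assert len(augment_dataset(pairs[:1], no_noise)) == 27

    def test_identity_only_config(self, rng):
        out = augment_dataset([random_pair(rng)], AugmentationConfig())
        assert len(out) == 1
        assert not out[0].provenance.is_augmented

    def test_count_law_for_random_configs(self, rng):
        """|output| = |P| * |angles| * |sx| * |sy| * (1 + sum copies) for random configs."""
        pairs = [random_pair(rng, shape=(8, 8)) for _ in range(2)]
        for _ in range(10):
            angles = tuple({0.0} | set(rng.uniform(-180, 180, rng.integers(0, 3))))
            sxs = tuple({1.0} | set(rng.uniform(0.85, 1.15, rng.integers(0, 3))))
            sys_ = tuple({1.0} | set(rng.uniform(0.85, 1.15, rng.integers(0, 3))))
            n_specs = rng.integers(0, 3)
            specs = tuple(NoiseSpec("gaussian", float(rng.uniform(0, 10)), int(rng.integers(1, 4)))
                          for _ in range(n_specs))
            cfg = AugmentationConfig(angles, sxs, sys_, specs, rng_seed=0)
            expected = len(pairs) * len(angles) * len(sxs) * len(sys_) * (1 + sum(s.copies for s in specs))
            assert len(augment_dataset(pairs, cfg)) == expected

    def test_masks_binary_under_every_variant(self, rng):
        out = augment_dataset([random_pair(rng, shape=(12, 12))], DEFAULT_AUG_CONFIG)
        for p in out:
            assert set(np.unique(p.mask)) <= {0, 1}

    def test_same_seed_byte_identical(self, rng):
        pairs = [random_pair(rng)]
        a = augment_dataset(pairs, DEFAULT_AUG_CONFIG)
        b = augment_dataset(pairs, DEFAULT_AUG_CONFIG)
        for pa, pb in zip(a, b):
            assert pa.image.tobytes() == pb.image.tobytes()
            assert pa.mask.tobytes() == pb.mask.tobytes()

    def test_empty_input_rejected(self):
        with pytest.raises(AugmentationConfigError):
            augment_dataset([], DEFAULT_AUG_CONFIG)


class TestSplitByPatient:
    def _cohort(self, sizes):
        return [random_pair(np.random.default_rng(i), patient_id=f"p{i}")
                for i, n in enumerate(sizes) for _ in range(n)]

    def test_exact_fraction_five_patients(self):
        pairs = self._cohort([10] * 5)
        train, test = split_by_patient(pairs, 0.8, seed=0)
        assert (len(train), len(test)) == (40, 10)

    def test_two_patients_half(self):
        pairs = self._cohort([7, 7])
        train, test = split_by_patient(pairs, 0.5, seed=1)
        assert len(train) == len(test) == 7

    @pytest.mark.parametrize("seed", range(5))
    def test_no_patient_leaks_across_sides(self, seed):
        pairs = self._cohort([3, 9, 5, 7, 2, 4])
        train, test = split_by_patient(pairs, 0.7, seed=seed)
        assert {p.patient_id for p in train} & {p.patient_id for p in test} == set()
        assert len(train) + len(test) == len(pairs)
        assert train and test

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            split_by_patient(self._cohort([10]), 0.8, seed=0)


class TestSliceAugmenter:
    def test_sklearn_protocol(self, rng):
        est = SliceAugmenter(rng_seed=3)
        cloned = clone(est)
        assert cloned.get_params()["rng_seed"] == 3
        out = cloned.fit([]).transform([random_pair(rng)])
        assert len(out) == 54
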