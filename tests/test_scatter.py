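"""Scatter-assay texture scoring: resampling, LBP descriptor (with an
independent brute-force oracle), and the validation protocols."""

import numpy as np
import pytest

from multicellseg.image import CalibratedImage, InputError
from multicellseg.scatter import (DescriptorError, ScatterClassifier,
                                  ValidationError, lbp_code, loo_classify,
                                  reduced_descriptor, resample_to_target,
                                  scatter_descriptor, split_validate)


def brute_force_descriptor(arr: np.ndarray) -> np.ndarray:
    """Straightforward per-pixel rotation-invariant uniform LBP histogram:
    explicit circular sampling with bilinear interpolation, independent of
    the package's implementation path."""
    h, w = arr.shape
    angles = np.arange(8) * np.pi / 4
    offsets = np.stack([np.sin(angles), np.cos(angles)], axis=1)
    hist = np.zeros(10)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            center = arr[r, c]
            bits = []
            for dy, dx in offsets:
                y, x = r + dy, c + dx
                y0, x0 = int(np.floor(y)), int(np.floor(x))
                fy, fx = y - y0, x - x0
                y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
                val = (arr[y0, x0] * (1 - fy) * (1 - fx)
                       + arr[y0, x1] * (1 - fy) * fx
                       + arr[y1, x0] * fy * (1 - fx)
                       + arr[y1, x1] * fy * fx)
                bits.append(1 if val >= center else 0)
            trans = sum(bits[i] != bits[(i + 1) % 8] for i in range(8))
            hist[sum(bits) if trans <= 2 else 9] += 1
    return hist / hist.sum()


class TestResampling:
    def test_integer_factor_reduction(self):
        img = CalibratedImage(np.random.default_rng(0).random((400, 400)), 1.25)
        out = resample_to_target(img, 5.0)
        assert out.shape == (100, 100)
        assert out.pixel_size_um == 5.0

    def test_already_at_target_is_unchanged(self):
        arr = np.random.default_rng(1).random((50, 50))
        out = resample_to_target(CalibratedImage(arr, 5.0), 5.0)
        np.testing.assert_array_equal(out.intensities, arr)

    def test_eightfold_factor_for_high_resolution_input(self):
        img = CalibratedImage(np.random.default_rng(2).random((160, 160)), 0.625)
        out = resample_to_target(img, 5.0)
        assert out.shape == (20, 20)

    def test_non_integer_ratio_uses_bilinear_adjustment(self):
        img = CalibratedImage(np.random.default_rng(3).random((100, 100)), 2.0)
        out = resample_to_target(img, 5.0)  # ratio 2.5: blocks of 2 then resize
        assert out.pixel_size_um == 5.0
        assert out.shape == (40, 40)

    def test_block_mean_preserves_mean_intensity(self):
        arr = np.random.default_rng(4).random((80, 80))
        out = resample_to_target(CalibratedImage(arr, 2.5), 5.0)
        assert out.intensities.mean() == pytest.approx(arr.mean(), abs=1e-12)

    def test_upsampling_rejected(self):
        with pytest.raises(InputError):
            resample_to_target(CalibratedImage(np.zeros((10, 10)), 6.0), 5.0)


class TestLBPDescriptor:
    def test_constant_image_is_one_hot_at_bin_eight(self):
        """Ties count as 1, so a flat image gives the all-ones pattern."""
        img = CalibratedImage(np.full((12, 12), 0.4), 5.0)
        desc = scatter_descriptor(img, np.ones((12, 12), bool))
        expected = np.zeros(10)
        expected[8] = 1.0
        np.testing.assert_allclose(desc, expected)

    def test_descriptor_sums_to_one(self):
        rng = np.random.default_rng(5)
        img = CalibratedImage(rng.random((30, 30)), 5.0)
        desc = scatter_descriptor(img, rng.random((30, 30)) < 0.6)
        assert desc.sum() == pytest.approx(1.0, abs=1e-9)
        assert (desc >= 0).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        arr = np.random.default_rng(seed).random((16, 16))
        img = CalibratedImage(arr, 5.0)
        desc = scatter_descriptor(img, np.ones((16, 16), bool))
        np.testing.assert_allclose(desc, brute_force_descriptor(arr), atol=1e-12)

    def test_gray_scale_shift_and_scale_invariance(self):
        arr = np.random.default_rng(6).random((20, 20)) * 0.4
        a = scatter_descriptor(CalibratedImage(arr, 5.0), np.ones((20, 20), bool))
        b = scatter_descriptor(CalibratedImage(arr * 1.7 + 0.2, 5.0),
                               np.ones((20, 20), bool))
        np.testing.assert_allclose(a, b)

    def test_rotation_by_quarter_turn_is_exact(self):
        arr = np.random.default_rng(7).random((18, 18))
        a = scatter_descriptor(CalibratedImage(arr, 5.0), np.ones(arr.shape, bool))
        rot = np.rot90(arr)
        b = scatter_descriptor(CalibratedImage(rot, 5.0), np.ones(rot.shape, bool))
        np.testing.assert_allclose(a, b)

    def test_empty_mask_rejected(self):
        img = CalibratedImage(np.random.default_rng(8).random((10, 10)), 5.0)
        with pytest.raises(DescriptorError):
            scatter_descriptor(img, np.zeros((10, 10), bool))

    def test_single_code_constant_neighborhood(self):
        assert lbp_code(np.full((3, 3), 0.5)) == 8

    def test_code_for_isolated_bright_center(self):
        nb = np.zeros((3, 3))
        nb[1, 1] = 1.0
        assert lbp_code(nb) == 0  # all neighbors below center

    def test_non_uniform_pattern_maps_to_bin_nine(self):
        nb = np.array([[1.0, 0.0, 1.0],
                       [0.0, 0.5, 0.0],
                       [1.0, 0.0, 1.0]])
        assert lbp_code(nb) == 9


class TestReducedDescriptor:
    def test_all_bins_is_identity(self):
        d = np.linspace(0, 0.18, 10)
        np.testing.assert_array_equal(reduced_descriptor(d, tuple(range(10))), d)

    def test_one_hot_at_eight_reduces_to_zeros(self):
        d = np.zeros(10)
        d[8] = 1.0
        np.testing.assert_array_equal(reduced_descriptor(d, (6, 7, 9)),
                                      np.zeros(3))

    def test_uniform_descriptor(self):
        d = np.full(10, 0.1)
        np.testing.assert_allclose(reduced_descriptor(d, (6, 7, 9)),
                                   [0.1, 0.1, 0.1])

    def test_out_of_range_bin_rejected(self):
        with pytest.raises(InputError):
            reduced_descriptor(np.zeros(10), (6, 12))


class TestValidation:
    SEP_X = np.array([[0.0, 0.1], [0.05, 0.12], [0.02, 0.08], [0.01, 0.11],
                      [0.9, 0.5], [0.85, 0.55], [0.92, 0.48], [0.88, 0.52]])
    SEP_Y = np.array([False] * 4 + [True] * 4)

    def test_loo_on_separable_data_is_perfect(self):
        loo = loo_classify(self.SEP_X, self.SEP_Y)
        assert (loo["predicted"] == loo["label"]).all()

    def test_loo_requires_two_per_class(self):
        with pytest.raises(ValidationError):
            loo_classify(self.SEP_X[:3], [False, False, True])

    def test_split_validation_on_separable_data_is_perfect(self):
        accs = split_validate(self.SEP_X, self.SEP_Y, n_repeats=20,
                              min_minority_train=1, seed=0)
        assert (accs == 1.0).all()

    def test_unsatisfiable_minority_constraint_rejected(self):
        with pytest.raises(ValidationError):
            split_validate(self.SEP_X, self.SEP_Y, min_minority_train=4)

    def test_shuffled_labels_give_chance_level_accuracy(self):
        rng = np.random.default_rng(10)
        X = np.vstack([self.SEP_X + rng.normal(0, 0.01, self.SEP_X.shape)
                       for _ in range(4)])
        y = np.tile(self.SEP_Y, 4)
        shuffled = rng.permutation(y)
        accs = split_validate(X, shuffled, n_repeats=100,
                              min_minority_train=3, seed=11)
        assert abs(accs.mean() - 0.5) <= 0.15

    def test_classifier_serialization_round_trip(self, tmp_path):
        clf = ScatterClassifier().fit(self.SEP_X, self.SEP_Y)
        path = tmp_path / "scatter.json"
        clf.save(path)
        loaded = ScatterClassifier.load(path)
        np.testing.assert_array_equal(clf.decision_function(self.SEP_X),
                                      loaded.decision_function(self.SEP_X))
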