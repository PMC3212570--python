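"""Cascade classifier: training, scoring, thresholding, serialization."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from multicellseg.cascade import (CascadePatchClassifier, LinearModel,
                                  Standardizer, TrainingError,
                                  threshold_confidence)
from multicellseg.image import InputError
from multicellseg.patches import (build_patch_grid, extract_feature_sets,
                                  patch_labels_from_mask)
from multicellseg.synth import SynthParams, generate_wound_image


def held_out_scores(cascade, pairs):
    ys, scores = [], []
    for pair in pairs:
        grid = build_patch_grid(pair.image, cascade.patch_size)
        feats = extract_feature_sets(pair.image, grid, cascade.feature_config)
        ys.append(patch_labels_from_mask(pair.mask, grid).ravel())
        scores.append(cascade.score_features(feats).ravel())
    return np.concatenate(ys), np.concatenate(scores)


class TestTraining:
    def test_combiner_spans_five_stage_models(self, trained_cascade):
        assert len(trained_cascade.stage_models_) == 5
        assert len(trained_cascade.combiner_.weights) == 5

    def test_held_out_patch_auc_is_high(self, trained_cascade, test_pairs):
        y, s = held_out_scores(trained_cascade, test_pairs)
        assert roc_auc_score(y, s) >= 0.95

    def test_background_patches_score_above_cellular(self, trained_cascade,
                                                     single_pair):
        grid = build_patch_grid(single_pair.image, 20)
        feats = extract_feature_sets(single_pair.image, grid)
        conf = trained_cascade.score_features(feats).ravel()
        y = patch_labels_from_mask(single_pair.mask, grid).ravel()
        assert conf[y].mean() > conf[~y].mean()

    def test_single_class_training_is_rejected(self):
        params = SynthParams(image_size=(100, 100), wound_shape="none",
                             wound_area_fraction=0.0)
        pairs = [generate_wound_image(params.replace(rng_seed=i)) for i in range(2)]
        with pytest.raises(TrainingError, match="single"):
            CascadePatchClassifier().fit([p.image for p in pairs],
                                         [p.mask for p in pairs])

    def test_training_is_deterministic(self, training_pairs):
        images = [p.image for p in training_pairs[:3]]
        masks = [p.mask for p in training_pairs[:3]]
        a = CascadePatchClassifier(random_state=1).fit(images, masks)
        b = CascadePatchClassifier(random_state=1).fit(images, masks)
        np.testing.assert_array_equal(a.combiner_.weights, b.combiner_.weights)

    def test_cascade_auc_not_below_best_stage_model(self):
        """Stacking must not meaningfully lose to any single feature set (the
        rationale for the combiner), checked across seeds.  When a single set
        already saturates near AUC 1.0 the cascade can only tie it, so the
        comparison carries a small finite-sample tolerance (a handful of
        discordant patch pairs out of ~10^6)."""
        for seed in range(3):
            params = SynthParams(image_size=(160, 160), wound_area_fraction=0.35)
            train = [generate_wound_image(params.replace(rng_seed=seed * 10 + i))
                     for i in range(3)]
            m = CascadePatchClassifier(random_state=seed).fit(
                [p.image for p in train], [p.mask for p in train])
            test = [generate_wound_image(params.replace(
                rng_seed=900 + seed * 50 + i, wound_area_fraction=0.25))
                for i in range(6)]
            ys, stage, casc = [], [], []
            for pair in test:
                grid = build_patch_grid(pair.image, 20)
                feats = extract_feature_sets(pair.image, grid)
                ys.append(patch_labels_from_mask(pair.mask, grid).ravel())
                stage.append(m.stage_scores(feats))
                casc.append(m.score_features(feats).ravel())
            y = np.concatenate(ys)
            stage_aucs = [roc_auc_score(y, s) for s in np.vstack(stage).T]
            cascade_auc = roc_auc_score(y, np.concatenate(casc))
            assert cascade_auc >= max(stage_aucs) - 2e-3


class TestScoring:
    def test_point_on_hyperplane_scores_zero(self):
        model = LinearModel(np.array([1.0, 2.0]), -3.0)
        assert model.signed_distance(np.array([[1.0, 1.0]]))[0] == pytest.approx(0.0)

    def test_rescaled_model_gives_identical_distances(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal(5)
        x = rng.standard_normal((10, 5))
        a = LinearModel(w, 0.7).signed_distance(x)
        b = LinearModel(3.5 * w, 3.5 * 0.7).signed_distance(x)
        np.testing.assert_allclose(a, b)

    def test_zero_weight_vector_rejected(self):
        with pytest.raises(InputError):
            LinearModel(np.zeros(5), 0.0)

    def test_uniform_combiner_reduces_to_scaled_mean_of_stage_scores(self,
                                                                     trained_cascade,
                                                                     single_pair):
        import copy

        m = copy.deepcopy(trained_cascade)
        k = len(m.stage_models_)
        m.combiner_ = LinearModel(np.full(k, 1.0 / k), 0.0)
        m.combiner_scaler_ = Standardizer(np.zeros(k), np.ones(k))
        grid = build_patch_grid(single_pair.image, 20)
        feats = extract_feature_sets(single_pair.image, grid)
        conf = m.score_features(feats).ravel()
        mean_stage = m.stage_scores(feats).mean(axis=1)
        np.testing.assert_allclose(conf, np.sqrt(k) * mean_stage, atol=1e-12)

    def test_feature_config_mismatch_rejected(self, trained_cascade, single_pair):
        from multicellseg.cascade import ModelCompatibilityError
        from multicellseg.patches import FeatureConfig

        grid = build_patch_grid(single_pair.image, 20)
        feats = extract_feature_sets(single_pair.image, grid,
                                     FeatureConfig(intensity_bins=8))
        with pytest.raises(ModelCompatibilityError):
            trained_cascade.score_features(feats)


class TestThreshold:
    def test_otsu_splits_symmetric_bimodal_scores(self):
        scores = np.array([-1.0] * 50 + [1.0] * 50)
        labels = threshold_confidence(scores, "otsu")
        assert labels.sum() == 50
        assert labels[50:].all() and not labels[:50].any()

    def test_svm_zero_with_all_negative_scores_gives_no_background(self):
        scores = -np.abs(np.random.default_rng(0).standard_normal(64)) - 0.1
        assert threshold_confidence(scores, "svm-zero").sum() == 0

    def test_otsu_matches_brute_force_on_separated_scores(self):
        """On well-separated bimodal scores the binned Otsu threshold lands in
        the gap found by exhaustively maximizing between-class variance."""
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.normal(-2, 0.1, 40), rng.normal(2, 0.1, 60)])
        # brute-force: try every midpoint between consecutive sorted scores
        srt = np.sort(scores)
        best, best_var = None, -1
        for t in (srt[:-1] + srt[1:]) / 2:
            lo, hi = scores[scores <= t], scores[scores > t]
            var = len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
            if var > best_var:
                best, best_var = t, var
        otsu_labels = threshold_confidence(scores, "otsu")
        brute_labels = scores > best
        np.testing.assert_array_equal(otsu_labels, brute_labels)
        np.testing.assert_array_equal(otsu_labels,
                                      threshold_confidence(scores, "svm-zero"))

    def test_single_sign_unimodal_scores_clamp_to_zero(self):
        rng = np.random.default_rng(2)
        scores = -np.abs(rng.normal(2.0, 0.3, 100))  # all cellular
        assert threshold_confidence(scores, "otsu").sum() == 0


class TestSerialization:
    def test_round_trip_preserves_scores_exactly(self, trained_cascade,
                                                 single_pair, tmp_path):
        path = tmp_path / "model.json"
        trained_cascade.save(path)
        loaded = CascadePatchClassifier.load(path)
        a = trained_cascade.decision_function(single_pair.image)
        b = loaded.decision_function(single_pair.image)
        np.testing.assert_array_equal(a, b)

    def test_wrong_kind_rejected(self, trained_cascade, tmp_path):
        from multicellseg.cascade import ModelCompatibilityError

        d = trained_cascade.to_dict()
        d["kind"] = "mystery"
        with pytest.raises(ModelCompatibilityError):
            CascadePatchClassifier.from_dict(d)
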