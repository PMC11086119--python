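"""SNN classifier: activation identities, pipeline contracts, learning."""

import numpy as np
import pytest

from lactowave.classifier import (
    DEFAULT_DEVIATION_SCALES,
    DEFAULT_FEATURE_CENTERS,
    SELU_ALPHA,
    SELU_LAMBDA,
    FeatureSet,
    SNNSpec,
    TrainConfig,
    balance_downsample,
    build_snn,
    evaluate,
    holdout_split,
    scale_features,
    selu,
    train,
)
from lactowave.model import ValidationError


def make_featureset(n_pregnant, n_nonpregnant, seed=0, shift=0.0):
    rng = np.random.default_rng(seed)
    xp = rng.normal(shift, 1.0, size=(n_pregnant, 4))
    xn = rng.normal(-shift, 1.0, size=(n_nonpregnant, 4))
    feats = np.vstack([xp, xn])
    labels = np.array(["PREGNANT"] * n_pregnant + ["NONPREGNANT"] * n_nonpregnant)
    return FeatureSet(feats, labels, np.arange(len(labels)))


class TestSelu:
    def test_closed_form_values(self):
        assert selu(0.0) == 0.0
        assert selu(1.0) == pytest.approx(SELU_LAMBDA)
        assert selu(1.0) == pytest.approx(1.0507, abs=1e-4)
        assert selu(-30.0) == pytest.approx(-SELU_LAMBDA * SELU_ALPHA, rel=1e-6)
        assert selu(-1.0) == pytest.approx(SELU_LAMBDA * SELU_ALPHA * (np.exp(-1) - 1))


class TestArchitecture:
    def test_parameter_count(self):
        model = build_snn(SNNSpec())
        expected = (4 * 50 + 50) + 7 * (50 * 50 + 50) + (50 * 1 + 1)
        assert expected == 18151
        assert model.n_parameters == expected

    def test_self_normalization_through_depth(self):
        """Pre-activations stay near zero mean / unit variance over 8 layers."""
        model = build_snn(SNNSpec(), seed=0)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((1000, 4))
        h = x
        for layer in range(model.spec.n_layers):
            z = h @ model.weights[layer] + model.biases[layer]
            assert -0.3 < z.mean() < 0.3, f"layer {layer} mean {z.mean():.3f}"
            assert 0.5 < z.var() < 1.5, f"layer {layer} var {z.var():.3f}"
            h = selu(z)

    def test_inference_is_dropout_free_and_deterministic(self):
        model = build_snn(SNNSpec(), seed=2)
        x = np.random.default_rng(0).normal(size=(20, 4))
        p1 = model.predict_proba(x)
        p2 = model.predict_proba(x)
        np.testing.assert_array_equal(p1, p2)


class TestBalanceDownsample:
    def test_pool_downsampled_to_minority_size(self):
        fs = make_featureset(168, 642)
        balanced = balance_downsample(fs, seed=0)
        assert (balanced.labels == "NONPREGNANT").sum() == 168
        assert (balanced.labels == "PREGNANT").sum() == 168

    def test_already_balanced_unchanged_up_to_order(self):
        fs = make_featureset(30, 30)
        balanced = balance_downsample(fs, seed=1)
        assert sorted(balanced.ids) == sorted(fs.ids)

    def test_deterministic_given_seed(self):
        fs = make_featureset(40, 100)
        a = balance_downsample(fs, seed=5)
        b = balance_downsample(fs, seed=5)
        np.testing.assert_array_equal(a.ids, b.ids)

    def test_empty_class_rejected(self):
        fs = make_featureset(10, 10)
        fs.labels[:] = "PREGNANT"
        with pytest.raises(ValidationError):
            balance_downsample(FeatureSet(fs.features, fs.labels, fs.ids))


class TestScaleFeatures:
    def test_reference_division(self):
        out = scale_features(np.array([[70.0, 10.0, 1.0, 1.0]]))
        np.testing.assert_allclose(out, [[1.0, 1.0, 1.0, 1.0]])

    def test_zero_maps_to_zero(self):
        out = scale_features(np.zeros((3, 4)))
        np.testing.assert_array_equal(out, np.zeros((3, 4)))

    def test_round_trip_identity(self):
        x = np.random.default_rng(0).normal(60, 5, size=(10, 4))
        scales = (70.0, 10.0, 1.0, 1.0)
        back = scale_features(x, scales) * np.asarray(scales)
        np.testing.assert_allclose(back, x, rtol=1e-12)

    def test_centered_scaling(self):
        x = np.array([DEFAULT_FEATURE_CENTERS], dtype=float)
        out = scale_features(x, DEFAULT_DEVIATION_SCALES, DEFAULT_FEATURE_CENTERS)
        np.testing.assert_allclose(out, 0.0)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValidationError):
            scale_features(np.ones((2, 4)), scales=(1, 0, 1, 1))


class TestHoldoutSplit:
    def test_balanced_pool_gives_requested_test_size(self):
        fs = make_featureset(168, 168)
        train_set, test_set = holdout_split(fs, test_per_class=15, seed=0)
        assert test_set.n_samples == 30
        assert train_set.n_samples == 306

    def test_partition_contract(self):
        fs = make_featureset(40, 40)
        tr, te = holdout_split(fs, test_per_class=10, seed=3)
        assert set(tr.ids) | set(te.ids) == set(fs.ids)
        assert set(tr.ids) & set(te.ids) == set()

    def test_zero_test_per_class(self):
        fs = make_featureset(20, 20)
        tr, te = holdout_split(fs, test_per_class=0, seed=0)
        assert te.n_samples == 0
        assert tr.n_samples == fs.n_samples

    def test_different_seeds_differ(self):
        fs = make_featureset(60, 60)
        _, t1 = holdout_split(fs, test_per_class=15, seed=1)
        _, t2 = holdout_split(fs, test_per_class=15, seed=2)
        assert set(t1.ids) != set(t2.ids)

    def test_insufficient_class_rejected(self):
        with pytest.raises(ValidationError):
            holdout_split(make_featureset(5, 40), test_per_class=15)


class TestTraining:
    def test_loss_decreases_on_separable_problem(self):
        fs = make_featureset(100, 100, shift=1.0)
        model = build_snn(SNNSpec(), seed=0)
        curves = train(model, fs, TrainConfig(seed=0))
        assert curves.train_loss[-1] <= curves.train_loss[0]
        assert evaluate(model, fs)[1] > 0.9

    def test_full_reproducibility_from_one_seed(self):
        fs = make_featureset(50, 50, shift=0.5)
        runs = []
        for _ in range(2):
            model = build_snn(SNNSpec(), seed=4)
            curves = train(model, fs, TrainConfig(seed=4))
            runs.append((model, curves))
        np.testing.assert_array_equal(runs[0][1].train_loss, runs[1][1].train_loss)
        for w0, w1 in zip(runs[0][0].weights, runs[1][0].weights):
            np.testing.assert_array_equal(w0, w1)

    def test_permutation_null_accuracy_near_chance(self):
        """With shuffled labels, held-out accuracy hovers around 0.5."""
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            fs = make_featureset(60, 60, seed=seed, shift=1.0)
            shuffled = FeatureSet(fs.features, rng.permutation(fs.labels), fs.ids)
            tr, te = holdout_split(shuffled, test_per_class=15, seed=seed)
            model = build_snn(SNNSpec(), seed=seed)
            train(model, tr, TrainConfig(seed=seed))
            accs.append(evaluate(model, te)[1])
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_constant_predictor_scores_half_on_balanced_test(self):
        model = build_snn(SNNSpec(), seed=0)
        model.biases[-1][:] = 50.0  # saturate the output head to "pregnant"
        fs = make_featureset(20, 20)
        _, acc = evaluate(model, fs)
        assert acc == pytest.approx(0.5)
        all_pregnant = FeatureSet(fs.features[:20], fs.labels[:20], fs.ids[:20])
        assert evaluate(model, all_pregnant)[1] == 1.0

    def test_cohort_pipeline_accuracy_exceeds_chance(self):
        """Through simulate->fit->features->train, mean holdout accuracy > 0.6.

        The pregnancy signal of the synthetic herd (displaced, tightened
        stage-2/3 parameter distributions) must survive instrument noise
        and fitting well enough for the SNN to beat chance clearly.
        """
        import pandas as pd

        from lactowave.classifier import balance_downsample, features_from_table
        from lactowave.cohort import CohortDesign, simulate_cohort
        from lactowave.pipeline import fit_cohort

        accs = []
        for seed in range(10):
            tables = [
                fit_cohort(simulate_cohort(design))
                for design in (CohortDesign.pregnant_fixture(seed=3 * seed),
                               CohortDesign.nonpregnant_fixture(seed=3 * seed + 1),
                               CohortDesign.random_survey(seed=3 * seed + 2))
            ]
            pool = pd.concat(tables, ignore_index=True)
            fs = features_from_table(pool, stage_column="stage_truth")
            balanced = balance_downsample(fs, seed=seed)
            tr, te = holdout_split(balanced, test_per_class=15, seed=seed)
            model = build_snn(SNNSpec(), seed=seed)
            train(model, tr, TrainConfig(seed=seed), validation_set=te)
            accs.append(evaluate(model, te)[1])
        assert np.mean(accs) > 0.6

    def test_empty_evaluation_rejected(self):
        model = build_snn(SNNSpec(), seed=0)
        fs = make_featureset(5, 5)
        with pytest.raises(ValidationError):
            evaluate(model, fs.subset(np.array([], dtype=int)))
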