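"""Training and maximum-likelihood classification behaviour."""

import numpy as np
import pytest

from canondx import (
    BenchmarkConfig,
    ClassSpec,
    Criterion,
    InvalidInputError,
    TrainingError,
    TrainingSet,
    classify,
    evaluate_accuracy,
    make_benchmark,
    run_benchmark,
    simulate_class,
    train_classifier,
)


def _two_separated_classes(seed=0, sep=10.0, L=200):
    specs = [
        ClassSpec("a", alpha=0.2, sigma=1.0, mean_offset=0.0, init_mean=0.0),
        ClassSpec("b", alpha=0.2, sigma=1.0, mean_offset=sep, init_mean=sep),
    ]
    train = [simulate_class(s, I=6, L=L, seed=seed + i) for i, s in enumerate(specs)]
    test = [simulate_class(s, I=6, L=250, seed=seed + 10 + i) for i, s in enumerate(specs)]
    return train, test


class TestTraining:
    def test_single_class_maps_everything_to_it(self, rng):
        ts = TrainingSet("only", rng.standard_normal((50, 4)))
        clf = train_classifier([ts], Criterion.linear())
        res = classify(clf, rng.standard_normal(4) * 100)
        assert res.label == "only"
        assert evaluate_accuracy(clf, [ts])["overall"] == 100.0

    def test_identical_training_data_ties_break_to_smallest_label(self, rng):
        X = rng.standard_normal((60, 4))
        clf = train_classifier(
            [TrainingSet("b", X), TrainingSet("a", X.copy())], Criterion.linear()
        )
        res = classify(clf, rng.standard_normal(4))
        assert res.label == "a"
        assert res.log_likelihoods["a"] == res.log_likelihoods["b"]

    def test_constant_class_raises_training_error(self):
        sets = [
            TrainingSet("flat", np.full((20, 3), 1.0)),
            TrainingSet("ok", np.random.default_rng(0).standard_normal((20, 3))),
        ]
        with pytest.raises(TrainingError, match="flat"):
            train_classifier(sets, Criterion.linear())

    def test_inconsistent_feature_counts_rejected(self, rng):
        sets = [
            TrainingSet("a", rng.standard_normal((20, 3))),
            TrainingSet("b", rng.standard_normal((20, 4))),
        ]
        with pytest.raises(InvalidInputError):
            train_classifier(sets, Criterion.linear())

    def test_duplicate_labels_rejected(self, rng):
        sets = [TrainingSet("a", rng.standard_normal((20, 3))) for _ in range(2)]
        with pytest.raises(InvalidInputError):
            train_classifier(sets, Criterion.linear())


class TestClassification:
    def test_large_separation_sanity(self):
        train, test = _two_separated_classes()
        clf = train_classifier(train, Criterion.linear())
        acc = evaluate_accuracy(clf, test)
        assert acc["overall"] >= 99.0

    def test_unknown_threshold_extremes(self):
        train, test = _two_separated_classes()
        clf = train_classifier(train, Criterion.linear())
        probe = test[0].values[0]
        clf.unknown_threshold = -1e6
        assert classify(clf, probe).label in ("a", "b")
        clf.unknown_threshold = +1e6
        assert classify(clf, probe).label == "unknown"

    def test_length_mismatch_rejected(self):
        train, _ = _two_separated_classes()
        clf = train_classifier(train, Criterion.linear())
        with pytest.raises(InvalidInputError):
            classify(clf, np.zeros(5))

    def test_affine_invariance_of_predictions(self, rng):
        train, test = _two_separated_classes(sep=3.0)
        clf = train_classifier(train, Criterion.polynomial(2))
        probe = np.vstack([t.values[:50] for t in test])
        base = [r.label for r in classify(clf, probe)]
        scale = np.array([2.0, 0.5, -1.5, 10.0, 1.0, 0.1])
        shift = np.array([5.0, -3.0, 0.0, 100.0, 2.0, -7.0])
        mapped_train = [
            TrainingSet(t.label, t.values * scale + shift) for t in train
        ]
        clf2 = train_classifier(mapped_train, Criterion.polynomial(2))
        mapped = [r.label for r in classify(clf2, probe * scale + shift)]
        assert mapped == base


class TestAccuracyEvaluation:
    def test_permuted_labels_give_complement(self):
        train, test = _two_separated_classes()
        clf = train_classifier(train, Criterion.linear())
        swapped = [
            TrainingSet("b", test[0].values),
            TrainingSet("a", test[1].values),
        ]
        acc = evaluate_accuracy(clf, swapped)
        assert acc["overall"] <= 1.0

    def test_unseen_label_rejected(self, rng):
        train, _ = _two_separated_classes()
        clf = train_classifier(train, Criterion.linear())
        with pytest.raises(InvalidInputError):
            evaluate_accuracy(clf, [TrainingSet("zz", rng.standard_normal((5, 6)))])


class TestComparativeCriteria:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_nonlinear_exceeds_linear_on_quadratic_coupling(self, seed):
        """Third-order coupled classes: the full cross-time dictionary must
        beat the purely second-order criterion on every default draw."""
        cfg = BenchmarkConfig(kind="quadratic_coupling", seed=seed)
        train, test = make_benchmark(cfg)
        nl = evaluate_accuracy(train_classifier(train, Criterion.nonlinear(4)), test)
        li = evaluate_accuracy(train_classifier(train, Criterion.linear()), test)
        assert nl["overall"] > li["overall"]

    def test_benchmark_table_shape(self):
        cfg = BenchmarkConfig(
            kind="quadratic_coupling", I=6, L_train=200, L_test=100, seed=5
        )
        table = run_benchmark(cfg)
        assert list(table.index) == ["linear", "polynomial", "nonlinear"]
        assert set(table.columns) == {"class1", "class2", "overall"}
        assert ((table.values >= 0) & (table.values <= 100)).all()

    def test_full_scale_shape_trains_and_degenerate_blocks_skipped(self):
        """K=9, L=200, I=14, N=4: the dictionary (679 entries) exceeds the
        sample-rank budget (199), so late blocks are degenerate and must be
        skipped rather than aborting training."""
        specs = [
            ClassSpec(f"d{k}", alpha=0.3, sigma=np.sqrt(0.91),
                      mean_offset=0.4 * k, init_mean=0.4 * k)
            for k in range(9)
        ]
        train = [simulate_class(s, I=14, L=200, seed=50 + k) for k, s in enumerate(specs)]
        clf = train_classifier(train, Criterion.nonlinear(4))
        assert len(clf.classes) == 9
        assert 1 <= len(clf.usable_blocks) < 14
        res = classify(clf, train[0].values[0])
        assert res.label in clf.labels
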