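import math

import numpy as np
import pytest

from facesym.evaluate import (
    CLASSIFIER_FAMILIES,
    ClassifierConfig,
    ConfusionMatrix,
    EvaluationError,
    LabeledDataset,
    LabeledSample,
    assemble_experiment,
    compute_metrics,
    get_preset,
    load_presets,
    repeated_kfold,
    train_predict,
)
from facesym.features import FeatureVector, REGIONS
from facesym.synthetic import SyntheticConfig, generate_subjects

from oracles import metrics_oracle


def _toy_dataset(X, y, region="face", task="detect"):
    pad = np.zeros(len(REGIONS[region].indices))
    samples = []
    for i, (row, label) in enumerate(zip(X, y)):
        vals = pad.copy()
        vals[: len(row)] = row
        fv = FeatureVector(vals, region_tag=region, source_id=f"s{i}")
        samples.append(LabeledSample(features=fv, label=str(label), subject_id=f"s{i}"))
    return LabeledDataset(tuple(samples), region_tag=region, task=task)


@pytest.fixture(scope="module")
def detection_subjects():
    cfg = SyntheticConfig(n_per_class=6, images_per_subject=5, rng_seed=17,
                          classes=("SL0", "SL1", "SL2"))
    return generate_subjects(cfg)


class TestMetrics:
    def test_worked_example(self):
        m = compute_metrics(ConfusionMatrix.binary(tp=9, tn=8, fp=2, fn=1))
        assert m.Acc == pytest.approx(17 / 20)
        assert m.Rec == pytest.approx(0.90)
        assert m.Prec == pytest.approx(9 / 11)
        assert m.F1s == pytest.approx(18 / 21)
        assert m.TNR == pytest.approx(0.80)
        assert m.FNR == pytest.approx(0.10)
        assert m.FPR == pytest.approx(0.20)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionMatrix.binary(tp=5, tn=7, fp=0, fn=0))
        assert (m.Acc, m.Rec, m.Prec, m.F1s, m.TNR) == (1.0, 1.0, 1.0, 1.0, 1.0)
        assert (m.FNR, m.FPR) == (0.0, 0.0)

    def test_random_matrices_match_formula_oracle(self, rng):
        for _ in range(200):
            tp, tn, fp, fn = rng.integers(0, 50, 4)
            if tp + tn + fp + fn == 0:
                continue
            cm = ConfusionMatrix.binary(int(tp), int(tn), int(fp), int(fn))
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                got = compute_metrics(cm).as_dict()
            exp = metrics_oracle(int(tp), int(tn), int(fp), int(fn))
            for k, v in exp.items():
                if math.isnan(v):
                    assert math.isnan(got[k])
                else:
                    assert got[k] == pytest.approx(v, abs=1e-15)

    def test_identities(self, rng):
        for _ in range(100):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 50, 4))
            m = compute_metrics(ConfusionMatrix.binary(tp, tn, fp, fn))
            assert m.Rec + m.FNR == pytest.approx(1.0, abs=1e-12)
            assert m.TNR + m.FPR == pytest.approx(1.0, abs=1e-12)

    def test_zero_denominator_warns_nan(self):
        with pytest.warns(RuntimeWarning, match="Rec"):
            m = compute_metrics(ConfusionMatrix.binary(tp=0, tn=5, fp=0, fn=0))
        assert math.isnan(m.Rec)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(EvaluationError):
            compute_metrics(ConfusionMatrix.binary(0, 0, 0, 0))

    def test_multiclass_accuracy_is_trace_over_total(self, rng):
        counts = rng.integers(0, 30, (3, 3))
        counts[0, 0] += 1
        cm = ConfusionMatrix(counts, ("SL0", "SL1", "SL2"))
        m = compute_metrics(cm)
        assert m.Acc == pytest.approx(np.trace(counts) / counts.sum())

    def test_negative_counts_rejected(self):
        with pytest.raises(EvaluationError):
            ConfusionMatrix(np.array([[1, -1], [0, 2]]), ("0", "1"))


class TestPresets:
    def test_all_experiments_cover_all_families(self):
        presets = load_presets()
        assert len(presets) == 11
        for fams in presets.values():
            assert set(fams) == set(CLASSIFIER_FAMILIES)

    def test_first_experiment_parameters_verbatim(self):
        mlp = get_preset("exp1_face", "MLP").parameters
        assert mlp == {"L": 0.2045, "M": 0.1909, "H": 59, "N": 5000, "S": 0}
        svm = get_preset("exp1_face", "SVM").parameters
        assert svm["C"] == 1000.0 and svm["G"] == 0.1 and svm["kernel"] == "rbf"
        assert get_preset("exp1_eyes", "SVM").parameters["G"] == 0.001
        assert get_preset("exp1_mouth", "SVM").parameters["G"] == 0.01
        assert get_preset("exp1_face", "KNN").parameters == {"k": 1, "distance": "euclidean"}
        assert get_preset("exp1_face", "MNLR").parameters["R"] == 1e-8

    def test_second_and_third_experiment_parameters(self):
        assert get_preset("exp2_test1_eyes", "MLP").parameters["N"] == 500
        assert get_preset("exp2_test1_mouth", "MLP").parameters["S"] == 37
        assert get_preset("exp2_test2_eyes", "SVM").parameters["C"] == 10.0
        assert get_preset("exp3_test1_mouth", "SVM").parameters["C"] == 1000.0
        assert get_preset("exp3_test2_mouth", "KNN").parameters["distance"] == "euclidean"
        assert get_preset("exp2_test1_eyes", "KNN").parameters["distance"] == "manhattan"

    def test_incomplete_config_rejected(self):
        with pytest.raises(EvaluationError, match="missing"):
            ClassifierConfig("MLP", {"L": 0.1})
        with pytest.raises(EvaluationError, match="family"):
            ClassifierConfig("RandomForest", {})

    def test_missing_preset_rejected(self):
        with pytest.raises(EvaluationError):
            get_preset("exp9_nose", "SVM")


class TestTrainPredict:
    def _blobs(self, n=20, d=4, gap=50.0, seed=0):
        local = np.random.default_rng(seed)
        X0 = local.normal(0.0, 1.0, (n, d))
        X1 = local.normal(gap, 1.0, (n, d))
        X = np.vstack([X0, X1])
        y = [0] * n + [1] * n
        return _toy_dataset(X, y)

    def test_knn_identical_sample_returns_its_label(self):
        train = self._blobs(seed=1)
        test = _toy_dataset(train.X[:3], train.y[:3])
        pred = train_predict(get_preset("exp1_face", "KNN"), train, test)
        assert list(pred) == list(train.y[:3])

    @pytest.mark.parametrize("family", CLASSIFIER_FAMILIES)
    def test_separable_blobs_all_families_perfect(self, family):
        train = self._blobs(seed=2)
        test = self._blobs(seed=3)
        pred = train_predict(get_preset("exp1_face", family), train, test, max_epochs=300)
        assert (pred == test.y).all()

    def test_mlp_deterministic_given_seed(self):
        train = self._blobs(seed=4, gap=3.0)
        test = self._blobs(seed=5, gap=3.0)
        cfg = get_preset("exp1_face", "MLP")
        p1 = train_predict(cfg, train, test, max_epochs=100)
        p2 = train_predict(cfg, train, test, max_epochs=100)
        assert (p1 == p2).all()

    def test_dimensionality_mismatch_rejected(self):
        train = self._blobs()
        test = _toy_dataset(np.zeros((2, 3)), [0, 1], region="eyes")
        with pytest.raises(EvaluationError, match="mismatch"):
            train_predict(get_preset("exp1_face", "KNN"), train, test)


class TestRepeatedKFold:
    def test_each_repeat_tests_every_sample_once(self):
        ds = _toy_dataset(np.random.default_rng(0).normal(size=(40, 3)),
                          [0] * 20 + [1] * 20)
        rep = repeated_kfold(ds, get_preset("exp1_face", "KNN"), k=5, repeats=3, seed=0)
        assert rep.confusion.total == 3 * 40
        assert len(rep.repeat_metrics) == 3
        assert all(len(folds) == 5 for folds in rep.fold_metrics)

    def test_label_leak_oracle_reaches_perfect_accuracy(self):
        """Harness sanity check: a feature that encodes the label yields 1.0."""
        y = [0] * 15 + [1] * 15
        X = np.array([[float(v)] for v in y])
        ds = _toy_dataset(X, y)
        rep = repeated_kfold(ds, get_preset("exp1_face", "KNN"), k=5, repeats=2, seed=1)
        assert rep.mean.Acc == 1.0

    def test_stratified_folds_balanced(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.array([0] * 37 + [1] * 23)
        X = np.zeros((60, 1))
        for train_idx, test_idx in StratifiedKFold(5, shuffle=True, random_state=0).split(X, y):
            for cls, total in ((0, 37), (1, 23)):
                got = int((y[test_idx] == cls).sum())
                assert math.floor(total / 5) <= got <= math.ceil(total / 5)

    def test_class_smaller_than_k_rejected(self):
        ds = _toy_dataset(np.zeros((6, 2)), [0, 0, 0, 0, 1, 1])
        with pytest.raises(EvaluationError, match="fewer members"):
            repeated_kfold(ds, get_preset("exp1_face", "KNN"), k=5, repeats=1)

    def test_deterministic_given_seed(self):
        ds = _toy_dataset(np.random.default_rng(2).normal(size=(30, 3)),
                          [0] * 15 + [1] * 15)
        cfg = get_preset("exp1_face", "SVM")
        a = repeated_kfold(ds, cfg, k=5, repeats=2, seed=7)
        b = repeated_kfold(ds, cfg, k=5, repeats=2, seed=7)
        assert np.array_equal(a.confusion.counts, b.confusion.counts)

    def test_group_by_subject_keeps_subjects_together(self, detection_subjects):
        ds = assemble_experiment(detection_subjects, task="detect", region="face")
        from sklearn.model_selection import StratifiedGroupKFold

        groups = ds.subject_ids
        for train_idx, test_idx in StratifiedGroupKFold(5, shuffle=True, random_state=0).split(ds.X, ds.y, groups):
            assert not set(groups[train_idx]) & set(groups[test_idx])
        rep = repeated_kfold(ds, get_preset("exp1_face", "KNN"), k=5, repeats=1,
                             seed=0, group_by_subject=True)
        assert rep.confusion.total == len(ds)


class TestAssembleExperiment:
    def test_balanced_detection_dataset_760(self):
        cfg = SyntheticConfig(n_per_class=19, images_per_subject=20, rng_seed=23,
                              classes=("SL0", "SL2"))
        subjects = generate_subjects(cfg)
        ds = assemble_experiment(subjects, task="detect", per_subject_cap=20)
        assert len(ds) == 760
        assert ds.class_counts() == {"0": 380, "1": 380}

    def test_per_subject_cap(self, detection_subjects):
        capped = assemble_experiment(detection_subjects, task="detect", per_subject_cap=2)
        assert len(capped) == 2 * len(detection_subjects)

    def test_augmentation_triples(self, detection_subjects):
        plain = assemble_experiment(detection_subjects, task="three_level")
        aug = assemble_experiment(detection_subjects, task="three_level", augment=True)
        assert len(aug) == 3 * len(plain)
        assert {c: 3 * n for c, n in plain.class_counts().items()} == aug.class_counts()

    def test_augment_off_unchanged(self, detection_subjects):
        a = assemble_experiment(detection_subjects, task="detect")
        b = assemble_experiment(detection_subjects, task="detect", augment=False)
        assert len(a) == len(b)

    def test_two_level_drops_healthy(self, detection_subjects):
        ds = assemble_experiment(detection_subjects, task="two_level")
        assert set(ds.label_set) == {"SL1", "SL2"}

    def test_regional_projection_applied(self, detection_subjects):
        ds = assemble_experiment(detection_subjects, task="detect", region="mouth")
        assert ds.X.shape[1] == 15

    def test_empty_class_rejected(self, detection_subjects):
        healthy_only = [r for r in detection_subjects if r.severity == "SL0"]
        with pytest.raises(EvaluationError):
            assemble_experiment(healthy_only, task="detect")

    def test_unknown_task_rejected(self, detection_subjects):
        with pytest.raises(EvaluationError, match="unknown task"):
            assemble_experiment(detection_subjects, task="four_level")

    def test_augmented_siblings_reference_parent(self, detection_subjects):
        aug = assemble_experiment(detection_subjects, task="detect", augment=True)
        parents = [s for s in aug.samples if s.augmented_from is None]
        children = [s for s in aug.samples if s.augmented_from is not None]
        assert len(children) == 2 * len(parents)
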