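"""Protocol harness: folds, classifiers, case runs, reporting."""

import numpy as np
import pytest

from deepeeg.harness import (
    CLASSIFIER_NAMES,
    HarnessError,
    PipelineConfig,
    classifier_scores,
    format_report,
    long_report,
    make_classifier,
    run_all_cases,
    run_case,
    stratified_folds,
)
from deepeeg.network import TrainingConfig

from conftest import TEST_SEED


class TestStratifiedFolds:
    def test_balanced_binary_exact_split(self):
        labels = np.repeat([0, 1], 100)
        folds = stratified_folds(labels, k=10, seed=1)
        for fold in range(10):
            test = folds.test_indices(fold)
            assert test.size == 20
            assert (labels[test] == 0).sum() == 10
            assert (labels[test] == 1).sum() == 10

    def test_screening_geometry_40_plus_10_per_fold(self):
        """400 vs 100 records split 10-fold: every fold tests 40 + 10."""
        labels = np.repeat([0, 1], [400, 100])
        folds = stratified_folds(labels, k=10, seed=2)
        for fold in range(10):
            test = folds.test_indices(fold)
            assert (labels[test] == 0).sum() == 40
            assert (labels[test] == 1).sum() == 10

    def test_partition_is_disjoint_and_exhaustive(self):
        labels = np.repeat([0, 1, 2], [53, 47, 50])
        folds = stratified_folds(labels, k=10, seed=3)
        all_test = np.concatenate(
            [folds.test_indices(f) for f in range(10)]
        )
        assert np.array_equal(np.sort(all_test), np.arange(labels.size))
        # per-class counts across folds differ by at most one
        for cls in range(3):
            counts = [
                (labels[folds.test_indices(f)] == cls).sum() for f in range(10)
            ]
            assert max(counts) - min(counts) <= 1

    def test_seed_reproducibility(self):
        labels = np.repeat([0, 1], 50)
        a = stratified_folds(labels, k=5, seed=9)
        b = stratified_folds(labels, k=5, seed=9)
        np.testing.assert_array_equal(a.fold_of, b.fold_of)
        c = stratified_folds(labels, k=5, seed=10)
        assert not np.array_equal(a.fold_of, c.fold_of)

    def test_class_smaller_than_k_rejected(self):
        labels = np.repeat([0, 1], [50, 5])
        with pytest.raises(HarnessError, match="fewer than k"):
            stratified_folds(labels, k=10, seed=0)


class TestMakeClassifier:
    def test_all_seven_names_build_distinct_handles(self):
        handles = [make_classifier(name, seed=0) for name in CLASSIFIER_NAMES]
        assert len({type(h) for h in handles}) == 7

    def test_unknown_name_rejected(self):
        with pytest.raises(HarnessError, match="unknown classifier"):
            make_classifier("LDA")

    def test_svc_exposes_decision_scores(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 4))
        y = (x[:, 0] > 0).astype(int)
        clf = make_classifier("SVC", seed=0)
        clf.fit(x, y)
        scores = classifier_scores(clf, x, 2)
        assert scores.shape == (40, 2)

    def test_gnb_is_deterministic_without_seed(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 3))
        y = (x[:, 0] > 0).astype(int)
        a = make_classifier("GNB", seed=0).fit(x, y).predict(x)
        b = make_classifier("GNB", seed=99).fit(x, y).predict(x)
        np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def tiny_strict_result(tiny_dataset, tiny_case):
    config = PipelineConfig(
        training=TrainingConfig(epochs=2, batch_size=16, seed=TEST_SEED),
        mode="strict",
        architecture="scaled",
        k_folds=4,
        fold_seed=TEST_SEED + 1,
        classifier_seed=TEST_SEED + 2,
    )
    return run_case(tiny_dataset, tiny_case, config)


class TestRunCase:
    def test_metric_set_bookkeeping(self, tiny_strict_result):
        result = tiny_strict_result
        assert len(result.fold_outcomes) == 4
        assert result.n_metric_sets == 7 * 4
        for outcomes in result.fold_outcomes:
            assert set(outcomes) == set(CLASSIFIER_NAMES)

    def test_strict_mode_fingerprints_isolate_test_folds(self, tiny_strict_result):
        """Leakage guard: network and projector fits must be fingerprinted
        on exactly the training indices, never the test indices."""
        for prints in tiny_strict_result.fingerprints:
            assert prints["network_fit"] == prints["train"]
            assert prints["projector_fit"] == prints["train"]
            assert prints["projector_fit"] != prints["test"]

    def test_micro_aggregation_identity(self, tiny_strict_result):
        """Micro-aggregated ACC equals total correct test predictions over
        total test predictions across folds."""
        result = tiny_strict_result
        for name in CLASSIFIER_NAMES:
            pooled = result.pooled_confusion(name)
            expected = 100.0 * pooled.trace() / pooled.sum()
            agg = result.aggregated(name, "micro")
            assert agg.ACC == pytest.approx(expected, abs=1e-9)

    def test_aggregates_lie_within_fold_range(self, tiny_strict_result):
        result = tiny_strict_result
        for name in CLASSIFIER_NAMES:
            fold_accs = [
                f[name].metrics.ACC
                for f in result.fold_outcomes
                if f[name].metrics.ACC is not None
            ]
            agg = result.aggregated(name, "mean").ACC
            assert min(fold_accs) - 1e-9 <= agg <= max(fold_accs) + 1e-9

    def test_separable_data_classified_well(self, tiny_strict_result):
        assert tiny_strict_result.aggregated("SVC", "micro").ACC >= 95.0

    def test_one_test_instance_per_class_per_fold_degenerate_limit(
        self, tiny_dataset, tiny_case
    ):
        """With k equal to the per-class count every fold tests exactly one
        record per class and micro aggregation reduces to a plain
        proportion over all records."""
        config = PipelineConfig(
            training=TrainingConfig(epochs=1, batch_size=16, seed=1),
            mode="shared",
            architecture="scaled",
            k_folds=20,
            fold_seed=5,
            classifier_seed=6,
        )
        result = run_case(tiny_dataset, tiny_case, config)
        for outcomes in result.fold_outcomes:
            assert outcomes["SVC"].confmat.sum() == 2  # one per class
        pooled = result.pooled_confusion("SVC")
        assert pooled.sum() == len(tiny_dataset)

    def test_shared_extractor_reuses_shared_network(self, tiny_dataset, tiny_case):
        from deepeeg.harness import train_dataset_network

        config = PipelineConfig(
            training=TrainingConfig(epochs=1, batch_size=16, seed=2),
            mode="shared",
            architecture="scaled",
            k_folds=4,
            fold_seed=3,
            classifier_seed=4,
        )
        net = train_dataset_network(tiny_dataset, config)
        result = run_case(tiny_dataset, tiny_case, config, shared_network=net)
        assert all(
            p["network_fit"] == "dataset" for p in result.fingerprints
        )


class TestReporting:
    def test_summary_frame_column_order(self, tiny_strict_result):
        frame = tiny_strict_result.summary_frame()
        assert list(frame.columns) == [
            "case", "classifier",
            "ACC", "SPF", "SEN", "PPV", "NPV", "MCC", "F1", "AUC",
        ]
        assert list(frame["classifier"]) == list(CLASSIFIER_NAMES)

    def test_long_report_shape(self, tiny_strict_result):
        frame = long_report([tiny_strict_result])
        assert len(frame) == 7 * 7  # 7 classifiers x 7 metrics
        assert set(frame.columns) == {"case", "classifier", "metric", "value"}

    def test_format_report_renders_two_decimals(self, tiny_strict_result):
        text = format_report([tiny_strict_result])
        assert "ACC" in text and "SVC" in text
        assert "100.00" in text or "." in text


@pytest.fixture(scope="module")
def mini_family():
    """Five tiny synthetic sets with the A-E naming, 512-sample epochs."""
    from deepeeg.synthetic import (
        BONN_LIKE_PRESETS, SynthesisConfig, generate_dataset,
    )

    config = SynthesisConfig(
        class_specs=BONN_LIKE_PRESETS, n_per_class=8,
        epoch_length=512, sampling_rate=173.61, seed=31,
    )
    dataset = generate_dataset(config)
    by_set = {}
    for record in dataset.records:
        by_set.setdefault(record.set_id, []).append(record)
    return by_set


class TestRunAllCases:
    def test_runs_selected_cases_and_reports(self, mini_family):
        from deepeeg.data import get_case

        cases = [get_case("case1"), get_case("case8")]
        config = PipelineConfig(
            training=TrainingConfig(epochs=1, batch_size=16, seed=1),
            mode="shared",
            architecture="scaled",
            k_folds=4,
            fold_seed=2,
            classifier_seed=3,
        )
        results, frame = run_all_cases(mini_family, cases, config)
        assert [r.case_id for r in results] == ["case1", "case8"]
        assert len(frame) == 2 * 7 * 7
        # identical rerun produces identical bytes
        results2, frame2 = run_all_cases(mini_family, cases, config)
        assert frame.to_csv(index=False) == frame2.to_csv(index=False)
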