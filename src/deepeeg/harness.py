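"""The experimental protocol: deep features + shallow classifiers under
stratified 10-fold cross-validation.

For each case, epochs are partitioned into k stratified folds.  Two
training scopes for the feature extractor are provided:

* ``strict`` (default): the network is retrained inside every fold on
  that fold's training records only, and the per-channel PCA is fitted on
  the training maps only — no test-fold record can influence any fitted
  stage (fingerprints of the index sets are recorded per stage so tests
  can assert this).
* ``shared``: one network is trained per dataset on all of its records
  with the dataset's full set-level labels (five classes for the A-E
  family, three for F/G/H) and its features are reused across that
  dataset's cases.  This mirrors a protocol with a single training run
  per dataset and is much cheaper, at the cost of the feature extractor
  having seen test folds' raw signals during training.

Seven shallow classifiers are evaluated on the projected 1 x C features:
SVC, KNN, RF, GNB, GB, DT and MLP, with library-default hyperparameters
frozen in ``CLASSIFIER_DEFAULTS`` and seeded where stochastic.  Folds are
shuffled by a dedicated fold seed, independent of classifier seeds, so
all classifiers see identical splits (a paired design).
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC as _SVC
from sklearn.tree import DecisionTreeClassifier

from .architecture import ArchitectureSpec, build_architecture, build_scaled_architecture
from .data import CaseDefinition, EpochValidationError, LabeledDataset, assemble_case, pad_records
from .features import extract_feature_maps, fit_channel_projectors, project
from .metrics import (
    METRIC_ORDER,
    MetricSet,
    ROCCurve,
    average_metric_sets,
    confusion_matrix,
    metrics_from_predictions,
    multiclass_metrics,
    binary_metrics,
    roc_curve_auc,
)
from .metrics import _ovr_counts  # shared one-vs-rest collapse
from .network import TrainedNetwork, TrainingConfig, train_network

logger = logging.getLogger("deepeeg")

CLASSIFIER_NAMES = ("SVC", "KNN", "RF", "GNB", "GB", "DT", "MLP")

#: Frozen hyperparameters for the seven shallow classifiers.  These are
#: the scikit-learn defaults except where noted (MLP iteration cap raised
#: so small feature sets converge without warnings).
CLASSIFIER_DEFAULTS: dict[str, dict] = {
    "SVC": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    "KNN": {"n_neighbors": 5, "weights": "uniform"},
    "RF": {"n_estimators": 100},
    "GNB": {},
    "GB": {"n_estimators": 100, "learning_rate": 0.1},
    "DT": {},
    "MLP": {"hidden_layer_sizes": (100,), "max_iter": 1000},
}


class HarnessError(ValueError):
    """Invalid protocol configuration or input."""


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified partition into k folds; ``fold_of[i]`` is record i's fold."""

    fold_of: np.ndarray
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def stratified_folds(labels: np.ndarray, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Stratified k-fold partition, reproducible from ``seed``.

    Every class must have at least k members; per-class fold counts
    differ by at most one.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    too_small = classes[counts < k]
    if too_small.size:
        raise HarnessError(
            f"classes {too_small.tolist()} have fewer than k={k} members"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(labels.size, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(labels.size), labels)):
        fold_of[test_idx] = fold
    return FoldAssignment(fold_of=fold_of, k=k, seed=seed)


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the seven shallow classifiers, seeded where stochastic."""
    params = CLASSIFIER_DEFAULTS.get(name)
    if params is None:
        raise HarnessError(
            f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}"
        )
    if name == "SVC":
        return _SVC(**params)
    if name == "KNN":
        return KNeighborsClassifier(**params)
    if name == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    if name == "GNB":
        return GaussianNB(**params)
    if name == "GB":
        return GradientBoostingClassifier(random_state=seed, **params)
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    return MLPClassifier(random_state=seed, **params)


def classifier_scores(clf, x: np.ndarray, n_classes: int) -> np.ndarray:
    """(N, K) real-valued class scores: probabilities where available,
    otherwise decision-function margins."""
    if hasattr(clf, "predict_proba"):
        return np.asarray(clf.predict_proba(x))
    scores = np.asarray(clf.decision_function(x))
    if scores.ndim == 1:  # binary margin: column per class
        return np.column_stack([-scores, scores])
    return scores


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce a case run."""

    training: TrainingConfig = field(default_factory=TrainingConfig)
    mode: str = "strict"  # feature-extractor training scope: strict | shared
    pca_scope: str = "fold"  # projector fit scope: fold | full
    architecture: str = "canonical"  # canonical (pad short epochs) | scaled
    pad_to: int = 4097
    k_folds: int = 10
    fold_seed: int = 0
    classifier_seed: int = 0
    metric_scheme: str = "macro_ovr"
    positive_class: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "shared"):
            raise HarnessError("mode must be 'strict' or 'shared'")
        if self.pca_scope not in ("fold", "full"):
            raise HarnessError("pca_scope must be 'fold' or 'full'")
        if self.architecture not in ("canonical", "scaled"):
            raise HarnessError("architecture must be 'canonical' or 'scaled'")


@dataclass
class ClassifierFoldOutcome:
    """One classifier scored on one test fold."""

    metrics: MetricSet
    confmat: np.ndarray
    roc: ROCCurve | None
    auc: float | None


@dataclass
class CaseResult:
    """All folds and classifiers for one case, plus aggregates and provenance."""

    case_id: str
    class_names: tuple[str, ...]
    fold_outcomes: list[dict[str, ClassifierFoldOutcome]]
    fingerprints: list[dict[str, str]]
    config: PipelineConfig

    @property
    def n_metric_sets(self) -> int:
        return sum(len(f) for f in self.fold_outcomes)

    def pooled_confusion(self, classifier: str) -> np.ndarray:
        return np.sum([f[classifier].confmat for f in self.fold_outcomes], axis=0)

    def aggregated(self, classifier: str, how: str = "micro") -> MetricSet:
        """Fold-aggregated metrics: ``micro`` pools confusion counts over
        folds (so ACC = total correct / total predictions); ``mean``
        averages the per-fold metric values."""
        if how == "mean":
            return average_metric_sets(
                [f[classifier].metrics for f in self.fold_outcomes]
            )
        if how != "micro":
            raise HarnessError("how must be 'micro' or 'mean'")
        pooled = self.pooled_confusion(classifier)
        if len(self.class_names) == 2:
            return binary_metrics(
                _ovr_counts(pooled, self.config.positive_class)
            )
        return multiclass_metrics(pooled, self.config.metric_scheme)

    def mean_auc(self, classifier: str) -> float | None:
        aucs = [
            f[classifier].auc
            for f in self.fold_outcomes
            if f[classifier].auc is not None
        ]
        return float(np.mean(aucs)) if aucs else None

    def summary_frame(self, how: str = "micro") -> pd.DataFrame:
        """Per-classifier aggregated metrics in the report column order."""
        rows = []
        for name in CLASSIFIER_NAMES:
            if name not in self.fold_outcomes[0]:
                continue
            agg = self.aggregated(name, how)
            row = {"case": self.case_id, "classifier": name}
            for metric in METRIC_ORDER:
                value = getattr(agg, metric)
                row[metric] = np.nan if value is None else value
            row["AUC"] = np.nan if self.mean_auc(name) is None else self.mean_auc(name)
            rows.append(row)
        return pd.DataFrame(rows)


def _fingerprint(indices: np.ndarray) -> str:
    return hashlib.sha256(np.sort(np.asarray(indices)).tobytes()).hexdigest()[:16]


def _architecture_for(dataset: LabeledDataset, config: PipelineConfig,
                      n_classes: int) -> tuple[ArchitectureSpec, LabeledDataset]:
    """Resolve the geometry policy: pad short epochs to the canonical
    length, or build a proportionally scaled architecture."""
    if config.architecture == "canonical":
        if dataset.epoch_length < config.pad_to:
            dataset = pad_records(dataset, config.pad_to)
        arch = build_architecture(dataset.epoch_length, n_classes)
    else:
        arch = build_scaled_architecture(dataset.epoch_length, n_classes)
    return arch, dataset


def train_dataset_network(
    dataset: LabeledDataset, config: PipelineConfig
) -> TrainedNetwork:
    """Shared-mode extractor: one network per dataset, trained on all
    records with the dataset's set-level labels."""
    set_ids = sorted({r.set_id for r in dataset.records})
    label_of = {s: i for i, s in enumerate(set_ids)}
    set_labels = np.array([label_of[r.set_id] for r in dataset.records])
    full = LabeledDataset(
        records=dataset.records, labels=set_labels, class_names=tuple(set_ids)
    )
    arch, full = _architecture_for(full, config, n_classes=max(2, len(set_ids)))
    t0 = time.perf_counter()
    net, _ = train_network(arch, full, config.training)
    logger.info(
        "stage=train_dataset_network n=%d classes=%d seed=%d duration=%.1fs",
        len(full), len(set_ids), config.training.seed, time.perf_counter() - t0,
    )
    return net


def _subset(dataset: LabeledDataset, indices: np.ndarray) -> LabeledDataset:
    return LabeledDataset(
        records=[dataset.records[i] for i in indices],
        labels=dataset.labels[indices],
        class_names=dataset.class_names,
    )


def run_case(
    dataset: LabeledDataset,
    case: CaseDefinition,
    config: PipelineConfig | None = None,
    shared_network: TrainedNetwork | None = None,
) -> CaseResult:
    """Run the full protocol for one case.

    ``shared_network`` supplies a pre-trained shared mode extractor (it is
    ignored in strict mode, where each fold retrains from scratch).
    """
    config = config or PipelineConfig()
    n_classes = dataset.n_classes
    folds = stratified_folds(dataset.labels, config.k_folds, config.fold_seed)

    network = None
    all_maps = None
    if config.mode == "shared":
        network = shared_network or train_dataset_network(dataset, config)
        arch_dataset = dataset
        if dataset.epoch_length != network.architecture.input_length:
            arch_dataset = pad_records(dataset, network.architecture.input_length)
        all_maps = extract_feature_maps(network, arch_dataset)

    fold_outcomes: list[dict[str, ClassifierFoldOutcome]] = []
    fingerprints: list[dict[str, str]] = []

    for fold in range(config.k_folds):
        t0 = time.perf_counter()
        train_idx = folds.train_indices(fold)
        test_idx = folds.test_indices(fold)
        prints = {
            "train": _fingerprint(train_idx),
            "test": _fingerprint(test_idx),
        }

        if config.mode == "strict":
            train_ds = _subset(dataset, train_idx)
            arch, train_ds = _architecture_for(train_ds, config, n_classes)
            seeded = replace(config.training, seed=config.training.seed + fold)
            net, _ = train_network(arch, train_ds, seeded)
            test_ds = _subset(dataset, test_idx)
            if test_ds.epoch_length != arch.input_length:
                test_ds = pad_records(test_ds, arch.input_length)
            train_maps = extract_feature_maps(net, train_ds)
            test_maps = extract_feature_maps(net, test_ds)
            prints["network_fit"] = _fingerprint(train_idx)
        else:
            assert all_maps is not None
            from .features import FeatureMapBatch

            train_maps = FeatureMapBatch(all_maps.values[train_idx],
                                         all_maps.provenance)
            test_maps = FeatureMapBatch(all_maps.values[test_idx],
                                        all_maps.provenance)
            prints["network_fit"] = "dataset"

        if config.pca_scope == "fold" or config.mode == "strict":
            projectors = fit_channel_projectors(train_maps)
            prints["projector_fit"] = _fingerprint(train_idx)
        else:
            assert all_maps is not None
            projectors = fit_channel_projectors(all_maps)
            prints["projector_fit"] = "dataset"

        x_train = project(train_maps, projectors)
        x_test = project(test_maps, projectors)
        y_train = dataset.labels[train_idx]
        y_test = dataset.labels[test_idx]

        outcomes: dict[str, ClassifierFoldOutcome] = {}
        for name in CLASSIFIER_NAMES:
            clf = make_classifier(name, config.classifier_seed)
            clf.fit(x_train, y_train)
            y_pred = clf.predict(x_test)
            scores = classifier_scores(clf, x_test, n_classes)
            metrics = metrics_from_predictions(
                y_test, y_pred, n_classes,
                positive_class=config.positive_class,
                scheme=config.metric_scheme,
            )
            confmat = confusion_matrix(y_test, y_pred, n_classes)
            if n_classes == 2:
                roc = roc_curve_auc(
                    y_test, scores[:, config.positive_class], config.positive_class
                )
                auc = roc.auc
            else:
                roc = None
                aucs = [
                    roc_curve_auc(y_test, scores[:, c], c).auc
                    for c in range(n_classes)
                ]
                defined = [a for a in aucs if a is not None]
                auc = float(np.mean(defined)) if defined else None
            outcomes[name] = ClassifierFoldOutcome(
                metrics=metrics, confmat=confmat, roc=roc, auc=auc
            )
        fold_outcomes.append(outcomes)
        fingerprints.append(prints)
        logger.info(
            "stage=fold case=%s fold=%d train=%s test=%s duration=%.1fs",
            case.case_id, fold, prints["train"], prints["test"],
            time.perf_counter() - t0,
        )

    return CaseResult(
        case_id=case.case_id,
        class_names=case.class_names,
        fold_outcomes=fold_outcomes,
        fingerprints=fingerprints,
        config=config,
    )


def run_all_cases(
    records_by_set: Mapping[str, Sequence],
    cases: Sequence[CaseDefinition],
    config: PipelineConfig | None = None,
) -> tuple[list[CaseResult], pd.DataFrame]:
    """Run every case; in shared mode one network is trained per dataset
    family and reused.  Returns results plus a long-format report frame
    (case, classifier, metric, value)."""
    config = config or PipelineConfig()
    shared: dict[str, TrainedNetwork] = {}
    results = []
    for case in cases:
        dataset = assemble_case(records_by_set, case)
        network = None
        if config.mode == "shared":
            if case.dataset_id not in shared:
                family_sets = sorted(
                    {s for c in cases if c.dataset_id == case.dataset_id
                     for s in c.member_sets}
                )
                family_records = []
                family_labels = []
                for idx, set_id in enumerate(family_sets):
                    if set_id not in records_by_set:
                        raise EpochValidationError(
                            f"set {set_id!r} missing from records_by_set"
                        )
                    for r in records_by_set[set_id]:
                        family_records.append(r)
                        family_labels.append(idx)
                family = LabeledDataset(
                    records=family_records,
                    labels=np.asarray(family_labels),
                    class_names=tuple(family_sets),
                )
                shared[case.dataset_id] = train_dataset_network(family, config)
            network = shared[case.dataset_id]
        results.append(run_case(dataset, case, config, shared_network=network))
    return results, long_report(results)


def long_report(results: Sequence[CaseResult], how: str = "micro") -> pd.DataFrame:
    """Long-format (case, classifier, metric, value) over aggregated metrics."""
    rows = []
    for result in results:
        frame = result.summary_frame(how)
        for _, row in frame.iterrows():
            for metric in METRIC_ORDER:
                rows.append(
                    {
                        "case": row["case"],
                        "classifier": row["classifier"],
                        "metric": metric,
                        "value": row[metric],
                    }
                )
    return pd.DataFrame(rows)


def format_report(results: Sequence[CaseResult], how: str = "micro") -> str:
    """Human-readable table mirroring the benchmark layout: one row per
    (case, classifier), columns ACC/SPF/SEN/PPV/NPV/MCC/F1 in percent to
    two decimals."""
    frames = [r.summary_frame(how) for r in results]
    table = pd.concat(frames, ignore_index=True)
    for metric in METRIC_ORDER + ("AUC",):
        if metric == "AUC":
            table[metric] = table[metric].map(
                lambda v: "-" if pd.isna(v) else f"{v:.3f}"
            )
        else:
            table[metric] = table[metric].map(
                lambda v: "-" if pd.isna(v) else f"{v:.2f}"
            )
    return table.to_string(index=False)
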