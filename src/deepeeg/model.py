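"""Model/Results front end over the seizure-detection protocol.

`SeizureCaseModel` binds a labeled dataset, a case definition and a
pipeline configuration; :meth:`~SeizureCaseModel.fit` runs the full
protocol (feature-extractor training, per-channel PCA, seven shallow
classifiers under stratified k-fold CV) and returns a
:class:`SeizureCaseResults` carrying every fold's metrics, aggregates,
ROC data and a printable summary table.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import CaseDefinition, LabeledDataset, assemble_case, get_case
from .harness import (
    CLASSIFIER_NAMES,
    CaseResult,
    PipelineConfig,
    format_report,
    run_case,
)
from .network import TrainedNetwork, TrainingHistory


class SeizureCaseModel:
    """One classification case, ready to fit.

    Parameters
    ----------
    dataset
        Case-assembled epochs with class labels.
    case
        The case definition (class grouping of sets).
    config
        Pipeline configuration; defaults to the strict leakage-safe
        protocol with 10 folds.
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        case: CaseDefinition,
        config: PipelineConfig | None = None,
    ) -> None:
        self.dataset = dataset
        self.case = case
        self.config = config or PipelineConfig()

    @classmethod
    def from_sets(
        cls,
        records_by_set: Mapping[str, Sequence],
        case: CaseDefinition | str,
        config: PipelineConfig | None = None,
    ) -> "SeizureCaseModel":
        """Build from per-set record lists and a case definition or id."""
        if isinstance(case, str):
            case = get_case(case)
        return cls(assemble_case(records_by_set, case), case, config)

    def fit(self, shared_network: TrainedNetwork | None = None
            ) -> "SeizureCaseResults":
        """Run the protocol and return results."""
        result = run_case(self.dataset, self.case, self.config, shared_network)
        return SeizureCaseResults(self, result)


class SeizureCaseResults:
    """Fitted results: per-fold metric sets, aggregates and ROC data."""

    def __init__(self, model: SeizureCaseModel, result: CaseResult) -> None:
        self.model = model
        self.result = result

    @property
    def case_id(self) -> str:
        return self.result.case_id

    def metrics_frame(self, how: str = "micro") -> pd.DataFrame:
        """Aggregated per-classifier metrics (percent), plus mean AUC."""
        return self.result.summary_frame(how)

    def fold_metrics(self, classifier: str) -> list:
        """Per-fold MetricSet list for one classifier."""
        return [f[classifier].metrics for f in self.result.fold_outcomes]

    def accuracy(self, classifier: str = "SVC", how: str = "micro") -> float:
        """Aggregated CV accuracy for one classifier, in percent."""
        value = getattr(self.result.aggregated(classifier, how), "ACC")
        return float("nan") if value is None else value

    def summary(self, how: str = "micro") -> str:
        """Printable report: one row per classifier, ACC..F1 in percent."""
        header = (
            f"Case {self.case_id}: "
            f"{' vs. '.join(self.model.case.class_names)}\n"
            f"{len(self.model.dataset)} epochs, "
            f"{self.result.config.k_folds}-fold stratified CV, "
            f"mode={self.result.config.mode}\n"
        )
        return header + format_report([self.result], how)

    def plot_roc(self, classifier: str = "SVC", ax=None):
        """Overlay per-fold ROC curves for a binary case."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for fold, outcomes in enumerate(self.result.fold_outcomes):
            roc = outcomes[classifier].roc
            if roc is not None:
                ax.plot(roc.fpr, roc.tpr, alpha=0.6, label=f"fold {fold}")
        ax.plot([0, 1], [0, 1], "k--", linewidth=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.set_title(f"{self.case_id} {classifier} ROC")
        return ax


def plot_history(history: TrainingHistory, axes=None):
    """Accuracy and loss curves of a network training run."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(10, 4))
    epochs = np.arange(1, len(history) + 1)
    axes[0].plot(epochs, history.accuracy, label="train")
    if history.val_accuracy:
        axes[0].plot(epochs, history.val_accuracy, label="validation")
    axes[0].set_xlabel("Epoch")
    axes[0].set_ylabel("Accuracy")
    axes[0].legend()
    axes[1].plot(epochs, history.loss, label="train")
    if history.val_loss:
        axes[1].plot(epochs, history.val_loss, label="validation")
    axes[1].set_xlabel("Epoch")
    axes[1].set_ylabel("Loss")
    axes[1].legend()
    return axes
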