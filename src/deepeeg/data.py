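"""Single-channel EEG epochs, labeled sets, and experimental case definitions.

The two benchmark collections this package targets are organised as small
families of labeled sets: five Bonn-style sets A-E (100 epochs each, 4,097
samples at 173.61 Hz) and three sets F/G/H of ictal / interictal / preictal
scalp recordings (50 epochs each, 1,024 samples at 200 Hz).  Epochs are
stored one per ASCII file, one numeric sample per line, and are kept raw:
no filtering, detrending or unit conversion is applied anywhere downstream.

Seventeen built-in classification cases combine these sets into binary,
ternary and five-class problems (e.g. healthy-vs-ictal ``A vs. E``, the
seizure screening case ``ABCD vs. E``, or the full five-way split).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

BONN_RATE_HZ = 173.61
EEG_EPILEPSY_RATE_HZ = 200.0
BONN_EPOCH_LEN = 4097
EEG_EPILEPSY_EPOCH_LEN = 1024

BONN_SETS = ("A", "B", "C", "D", "E")
EEG_EPILEPSY_SETS = ("F", "G", "H")


class EpochParseError(ValueError):
    """A line of an ASCII epoch file did not parse as a number."""


class EpochValidationError(ValueError):
    """An epoch, set or case failed a structural check."""


@dataclass(frozen=True)
class EEGRecord:
    """One EEG epoch: a raw amplitude trace plus provenance.

    Parameters
    ----------
    samples
        Amplitude values in acquisition units, one per time step.
    sampling_rate
        Sampling frequency in Hz.
    set_id
        Which labeled set the epoch belongs to (one of A-H).
    dataset_id
        ``"bonn"`` or ``"eeg_epilepsy"`` (or ``"synthetic"``).
    source_path
        Where the epoch came from, for audit trails.
    """

    samples: np.ndarray
    sampling_rate: float
    set_id: str
    dataset_id: str = "bonn"
    source_path: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise EpochValidationError("samples must be a non-empty 1-D vector")
        if not np.all(np.isfinite(samples)):
            raise EpochValidationError("samples contain non-finite values")
        if self.sampling_rate <= 0:
            raise EpochValidationError("sampling_rate must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class CaseDefinition:
    """One classification case: an ordered grouping of sets into classes."""

    case_id: str
    class_groups: tuple[tuple[str, tuple[str, ...]], ...]
    dataset_id: str

    def __post_init__(self) -> None:
        members = [s for _, sets in self.class_groups for s in sets]
        if len(set(members)) != len(members):
            raise EpochValidationError(
                f"{self.case_id}: member sets overlap across classes"
            )
        if len(self.class_groups) not in (2, 3, 5):
            raise EpochValidationError(
                f"{self.case_id}: {len(self.class_groups)} classes; expected 2, 3 or 5"
            )

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.class_groups)

    @property
    def member_sets(self) -> tuple[str, ...]:
        return tuple(s for _, sets in self.class_groups for s in sets)

    @property
    def n_classes(self) -> int:
        return len(self.class_groups)


@dataclass
class LabeledDataset:
    """Epochs plus integer class labels for one case (or one raw collection)."""

    records: list[EEGRecord]
    labels: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.records) != self.labels.size:
            raise EpochValidationError("records and labels length mismatch")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= len(self.class_names)
        ):
            raise EpochValidationError("labels index outside class_names")
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            raise EpochValidationError(f"mixed epoch lengths {sorted(lengths)}")
        datasets = {r.dataset_id for r in self.records}
        if len(datasets) > 1:
            raise EpochValidationError(f"mixed dataset ids {sorted(datasets)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def epoch_length(self) -> int:
        return len(self.records[0]) if self.records else 0

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def signal_matrix(self) -> np.ndarray:
        """Stack epochs into an (n_records, epoch_length) float array."""
        return np.stack([r.samples for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: record index, set_id, label, then one column per sample."""
        mat = self.signal_matrix()
        frame = pd.DataFrame(mat, columns=[f"s{i}" for i in range(mat.shape[1])])
        frame.insert(0, "label", self.labels)
        frame.insert(0, "set_id", [r.set_id for r in self.records])
        frame.insert(0, "record", np.arange(len(self.records)))
        return frame

    def save_csv(self, path: str | Path, case: CaseDefinition | None = None) -> None:
        """Write the dataset to CSV with a JSON sidecar of case metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "class_names": list(self.class_names),
            "n_records": len(self),
            "epoch_length": self.epoch_length,
            "dataset_id": self.records[0].dataset_id if self.records else None,
            "sampling_rate": self.records[0].sampling_rate if self.records else None,
        }
        if case is not None:
            meta["case_id"] = case.case_id
            meta["class_groups"] = [
                {"class_name": name, "sets": list(sets)}
                for name, sets in case.class_groups
            ]
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_ascii_epoch(
    path: str | Path,
    expected_length: int | None = None,
    *,
    sampling_rate: float = BONN_RATE_HZ,
    set_id: str = "?",
    dataset_id: str = "bonn",
) -> EEGRecord:
    """Read one epoch from an ASCII file with one numeric sample per line.

    Blank lines are ignored.  Raises :class:`EpochParseError` naming the
    offending line for non-numeric content, and
    :class:`EpochValidationError` if ``expected_length`` is given and the
    file holds a different number of samples.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise EpochParseError(
                    f"{path}: line {lineno} is not numeric: {text!r}"
                ) from None
    if not values:
        raise EpochValidationError(f"{path}: no samples found")
    if expected_length is not None and len(values) != expected_length:
        raise EpochValidationError(
            f"{path}: expected {expected_length} samples, found {len(values)}"
        )
    return EEGRecord(
        samples=np.asarray(values),
        sampling_rate=sampling_rate,
        set_id=set_id,
        dataset_id=dataset_id,
        source_path=str(path),
    )


def write_ascii_epoch(record: EEGRecord, path: str | Path) -> None:
    """Write an epoch in the one-sample-per-line layout ``read_ascii_epoch`` reads.

    Values are written with ``repr`` so a read-back round trip is bit-exact.
    """
    with open(path, "w") as fh:
        for v in record.samples:
            fh.write(f"{float(v)!r}\n")


def load_set(
    directory: str | Path,
    set_id: str,
    *,
    expected_length: int | None = None,
    sampling_rate: float | None = None,
    dataset_id: str | None = None,
    pattern: str = "*",
) -> list[EEGRecord]:
    """Load every epoch file in ``directory`` as one labeled set.

    Files are taken in lexicographic filename order so record order — and
    therefore every downstream fold assignment — is reproducible.
    """
    directory = Path(directory)
    if dataset_id is None:
        dataset_id = "eeg_epilepsy" if set_id in EEG_EPILEPSY_SETS else "bonn"
    if sampling_rate is None:
        sampling_rate = (
            EEG_EPILEPSY_RATE_HZ if dataset_id == "eeg_epilepsy" else BONN_RATE_HZ
        )
    paths = sorted(p for p in directory.glob(pattern) if p.is_file())
    if not paths:
        raise EpochValidationError(f"{directory}: no epoch files found")
    return [
        read_ascii_epoch(
            p,
            expected_length,
            sampling_rate=sampling_rate,
            set_id=set_id,
            dataset_id=dataset_id,
        )
        for p in paths
    ]


def _bonn_case(case_id: str, *groups: tuple[str, str]) -> CaseDefinition:
    return CaseDefinition(
        case_id=case_id,
        class_groups=tuple((name, tuple(sets)) for name, sets in groups),
        dataset_id="bonn",
    )


def _fgh_case(case_id: str, *groups: tuple[str, str]) -> CaseDefinition:
    return CaseDefinition(
        case_id=case_id,
        class_groups=tuple((name, tuple(sets)) for name, sets in groups),
        dataset_id="eeg_epilepsy",
    )


def builtin_cases() -> list[CaseDefinition]:
    """The 17 built-in classification cases (12 Bonn + 5 ictal/interictal/preictal).

    Ordering and class memberships follow the standard benchmark protocol:
    binary seizure-detection contrasts, the screening case ABCD vs. E, the
    normal-vs-epileptic split AB vs. CDE, two ternary cases, the five-way
    case, and the five F/G/H contrasts.
    """
    return [
        _bonn_case("case1", ("Normal (eyes open)", "A"), ("Ictal", "E")),
        _bonn_case("case2", ("Normal (eyes closed)", "B"), ("Ictal", "E")),
        _bonn_case("case3", ("Normal", "AB"), ("Ictal", "E")),
        _bonn_case("case4", ("Interictal", "C"), ("Ictal", "E")),
        _bonn_case("case5", ("Interictal", "D"), ("Ictal", "E")),
        _bonn_case("case6", ("Interictal", "CD"), ("Ictal", "E")),
        _bonn_case("case7", ("Normal", "A"), ("Interictal", "D")),
        _bonn_case("case8", ("Non-seizure", "ABCD"), ("Seizure", "E")),
        _bonn_case("case9", ("Normal", "AB"), ("Epileptic", "CDE")),
        _bonn_case("case10", ("Normal", "A"), ("Interictal", "C"), ("Ictal", "E")),
        _bonn_case("case11", ("Normal", "AB"), ("Interictal", "CD"), ("Ictal", "E")),
        _bonn_case(
            "case12",
            ("Normal (eyes open)", "A"),
            ("Normal (eyes closed)", "B"),
            ("Interictal", "C"),
            ("Interictal (epileptogenic)", "D"),
            ("Ictal", "E"),
        ),
        _fgh_case("caseI", ("Ictal", "F"), ("Interictal", "G")),
        _fgh_case("caseII", ("Ictal", "F"), ("Preictal", "H")),
        _fgh_case("caseIII", ("Interictal", "G"), ("Preictal", "H")),
        _fgh_case("caseIV", ("Seizure", "F"), ("Seizure-free", "GH")),
        _fgh_case("caseV", ("Ictal", "F"), ("Interictal", "G"), ("Preictal", "H")),
    ]


def get_case(case_id: str) -> CaseDefinition:
    """Look up one built-in case by id (e.g. ``"case8"``, ``"caseV"``)."""
    for case in builtin_cases():
        if case.case_id == case_id:
            return case
    known = ", ".join(c.case_id for c in builtin_cases())
    raise EpochValidationError(f"unknown case {case_id!r}; known cases: {known}")


def assemble_case(
    records_by_set: Mapping[str, Sequence[EEGRecord]],
    case: CaseDefinition,
) -> LabeledDataset:
    """Concatenate the case's member sets, in case order, with class-index labels."""
    records: list[EEGRecord] = []
    labels: list[int] = []
    for class_index, (_, sets) in enumerate(case.class_groups):
        for set_id in sets:
            if set_id not in records_by_set:
                raise EpochValidationError(
                    f"{case.case_id}: set {set_id!r} missing from records_by_set"
                )
            for record in records_by_set[set_id]:
                records.append(record)
                labels.append(class_index)
    return LabeledDataset(
        records=records,
        labels=np.asarray(labels),
        class_names=case.class_names,
    )


def pad_records(dataset: LabeledDataset, target_length: int) -> LabeledDataset:
    """Symmetric zero-padding of every epoch to ``target_length`` samples.

    Used to run short epochs (e.g. 1,024-sample recordings) through the
    fixed network geometry defined for 4,097-sample inputs, so the
    published 23x128 feature-map shape is preserved.  An odd remainder
    puts the extra zero at the end.
    """
    if not dataset.records:
        return dataset
    current = dataset.epoch_length
    if current > target_length:
        raise EpochValidationError(
            f"epoch length {current} exceeds pad target {target_length}"
        )
    if current == target_length:
        return dataset
    before = (target_length - current) // 2
    after = target_length - current - before
    padded = [
        EEGRecord(
            samples=np.pad(r.samples, (before, after)),
            sampling_rate=r.sampling_rate,
            set_id=r.set_id,
            dataset_id=r.dataset_id,
            source_path=r.source_path,
        )
        for r in dataset.records
    ]
    return LabeledDataset(
        records=padded, labels=dataset.labels.copy(), class_names=dataset.class_names
    )
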