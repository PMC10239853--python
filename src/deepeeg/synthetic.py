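"""Seeded generator of EEG-like epochs with controllable class structure.

Real benchmark recordings distinguish three regimes that any seizure
detector must separate: ongoing rhythmic background (normal alpha-band
activity), sparse high-amplitude interictal transients (spike/sharp-wave
discharges), and sustained high-amplitude low-frequency rhythmic activity
during seizures.  Each epoch here is a sum of

* a band-limited background oscillation (random frequency inside a band,
  random phase),
* Poisson-placed biphasic transients (difference-of-Gaussians spikes),
* an optional rhythmic burst covering a duty fraction of the epoch, and
* white Gaussian noise,

which reproduces that gross morphology without attempting physiological
realism (no 1/f spectrum, no channel correlations).  Every epoch draws
from its own counter-keyed random stream, so generating more epochs never
perturbs earlier ones and datasets are reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import yaml

from .data import EEGRecord, EpochValidationError, LabeledDataset, write_ascii_epoch


@dataclass(frozen=True)
class ClassSpec:
    """Generative recipe for one class of epochs.

    Amplitudes are in the same arbitrary units as the output samples;
    rates are per second; ``background_band`` is (low, high) in Hz and
    must sit below the Nyquist frequency of the target sampling rate.
    """

    class_name: str
    background_band: tuple[float, float] = (8.0, 13.0)
    background_amplitude: float = 40.0
    spike_rate: float = 0.0
    spike_amplitude: float = 0.0
    rhythmic_burst: tuple[float, float, float] | None = None  # (Hz, amplitude, duty)
    noise_sd: float = 10.0

    def validate(self, sampling_rate: float) -> None:
        low, high = self.background_band
        if not (0 < low < high):
            raise EpochValidationError(
                f"{self.class_name}: background band must satisfy 0 < low < high"
            )
        if high >= sampling_rate / 2:
            raise EpochValidationError(
                f"{self.class_name}: band edge {high} Hz at or above Nyquist "
                f"({sampling_rate / 2} Hz)"
            )
        if min(self.background_amplitude, self.spike_rate, self.spike_amplitude) < 0:
            raise EpochValidationError(
                f"{self.class_name}: amplitudes and rates must be non-negative"
            )
        if self.noise_sd < 0:
            raise EpochValidationError(f"{self.class_name}: noise_sd must be >= 0")
        if self.rhythmic_burst is not None:
            freq, amp, duty = self.rhythmic_burst
            if freq >= sampling_rate / 2:
                raise EpochValidationError(
                    f"{self.class_name}: burst frequency {freq} Hz above Nyquist"
                )
            if amp < 0 or not (0 < duty <= 1):
                raise EpochValidationError(
                    f"{self.class_name}: burst amplitude must be >= 0 and duty in (0, 1]"
                )


@dataclass(frozen=True)
class SynthesisConfig:
    """Full recipe for a labeled synthetic dataset."""

    class_specs: tuple[ClassSpec, ...]
    n_per_class: int = 100
    epoch_length: int = 4097
    sampling_rate: float = 173.61
    seed: int = 0
    dataset_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise EpochValidationError("n_per_class must be >= 1")
        if self.epoch_length < 64:
            raise EpochValidationError("epoch_length must be >= 64")
        for spec in self.class_specs:
            spec.validate(self.sampling_rate)


# Presets mimicking the qualitative morphology of the benchmark sets:
# awake alpha background for normals, sparse large transients for
# interictal epochs, sustained 3-5 Hz high-amplitude rhythm for seizures.
NORMAL_EYES_OPEN = ClassSpec(
    "normal_eyes_open", background_band=(8.0, 13.0), background_amplitude=40.0,
    noise_sd=10.0,
)
NORMAL_EYES_CLOSED = ClassSpec(
    "normal_eyes_closed", background_band=(8.0, 13.0), background_amplitude=65.0,
    noise_sd=10.0,
)
INTERICTAL_MILD = ClassSpec(
    "interictal_mild", background_band=(4.0, 8.0), background_amplitude=30.0,
    spike_rate=0.3, spike_amplitude=120.0, noise_sd=10.0,
)
INTERICTAL = ClassSpec(
    "interictal", background_band=(4.0, 8.0), background_amplitude=30.0,
    spike_rate=0.6, spike_amplitude=150.0, noise_sd=10.0,
)
ICTAL = ClassSpec(
    "ictal", background_band=(4.0, 8.0), background_amplitude=30.0,
    spike_rate=1.0, spike_amplitude=100.0,
    rhythmic_burst=(4.0, 250.0, 0.8), noise_sd=10.0,
)
PREICTAL = ClassSpec(
    "preictal", background_band=(8.0, 13.0), background_amplitude=45.0,
    spike_rate=0.05, spike_amplitude=60.0, noise_sd=10.0,
)

#: Five-set geometry: 100 epochs/class of 4,097 samples at 173.61 Hz.
BONN_LIKE_PRESETS = (
    replace(NORMAL_EYES_OPEN, class_name="A"),
    replace(NORMAL_EYES_CLOSED, class_name="B"),
    replace(INTERICTAL_MILD, class_name="C"),
    replace(INTERICTAL, class_name="D"),
    replace(ICTAL, class_name="E"),
)

#: Three-set geometry: 50 epochs/class of 1,024 samples at 200 Hz.
EEG_EPILEPSY_LIKE_PRESETS = (
    replace(ICTAL, class_name="F"),
    replace(INTERICTAL, class_name="G"),
    replace(PREICTAL, class_name="H"),
)


def bonn_like_config(seed: int = 0, n_per_class: int = 100) -> SynthesisConfig:
    """Synthetic stand-in with the five-set benchmark geometry."""
    return SynthesisConfig(
        class_specs=BONN_LIKE_PRESETS,
        n_per_class=n_per_class,
        epoch_length=4097,
        sampling_rate=173.61,
        seed=seed,
    )


def eeg_epilepsy_like_config(seed: int = 0, n_per_class: int = 50) -> SynthesisConfig:
    """Synthetic stand-in with the three-set (F/G/H) benchmark geometry."""
    return SynthesisConfig(
        class_specs=EEG_EPILEPSY_LIKE_PRESETS,
        n_per_class=n_per_class,
        epoch_length=1024,
        sampling_rate=200.0,
        seed=seed,
    )


def _biphasic_spike(fs: float) -> np.ndarray:
    """Unit-peak biphasic transient ~70 ms wide (difference of Gaussians)."""
    half = max(int(round(0.035 * fs)), 2)
    t = np.arange(-half, half + 1) / fs
    sigma = 0.010
    wave = np.exp(-0.5 * (t / sigma) ** 2) - 0.9 * np.exp(
        -0.5 * ((t - 0.012) / (1.6 * sigma)) ** 2
    )
    return wave / np.max(np.abs(wave))


def generate_epoch(
    spec: ClassSpec,
    length: int,
    fs: float,
    rng: np.random.Generator,
) -> EEGRecord:
    """Generate one epoch from a class recipe, deterministic given ``rng`` state."""
    spec.validate(fs)
    t = np.arange(length) / fs
    signal = np.zeros(length)

    if spec.background_amplitude > 0:
        freq = rng.uniform(*spec.background_band)
        phase = rng.uniform(0, 2 * np.pi)
        signal += spec.background_amplitude * np.sin(2 * np.pi * freq * t + phase)
    else:
        rng.uniform(size=2)  # keep the draw count fixed across recipes

    duration = length / fs
    n_spikes = rng.poisson(spec.spike_rate * duration)
    if spec.spike_amplitude > 0 and n_spikes > 0:
        template = _biphasic_spike(fs)
        half = len(template) // 2
        centers = rng.integers(half, length - half, size=n_spikes)
        amplitudes = spec.spike_amplitude * rng.uniform(0.8, 1.2, size=n_spikes)
        signs = rng.choice([-1.0, 1.0], size=n_spikes)
        for c, a, s in zip(centers, amplitudes, signs):
            signal[c - half : c + half + 1] += s * a * template

    if spec.rhythmic_burst is not None:
        freq, amp, duty = spec.rhythmic_burst
        burst_len = max(int(round(duty * length)), 1)
        start = int(rng.integers(0, length - burst_len + 1)) if burst_len < length else 0
        phase = rng.uniform(0, 2 * np.pi)
        window = np.zeros(length)
        window[start : start + burst_len] = 1.0
        # cosine ramps over 5% of the burst avoid step discontinuities
        ramp = max(int(0.05 * burst_len), 1)
        if 2 * ramp < burst_len:
            taper = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
            window[start : start + ramp] = taper
            window[start + burst_len - ramp : start + burst_len] = taper[::-1]
        signal += amp * window * np.sin(2 * np.pi * freq * t + phase)

    if spec.noise_sd > 0:
        signal += rng.normal(0.0, spec.noise_sd, size=length)

    return EEGRecord(
        samples=signal,
        sampling_rate=fs,
        set_id=spec.class_name,
        dataset_id="synthetic",
        source_path=f"synthetic:{spec.class_name}",
    )


def generate_dataset(config: SynthesisConfig) -> LabeledDataset:
    """Generate ``n_per_class`` epochs per class, labels in spec order.

    Each epoch's stream is keyed by (class index, epoch index) under the
    master seed, so the same epoch is produced regardless of how many
    others are requested.
    """
    records: list[EEGRecord] = []
    labels: list[int] = []
    for class_index, spec in enumerate(config.class_specs):
        for epoch_index in range(config.n_per_class):
            seq = np.random.SeedSequence(
                config.seed, spawn_key=(class_index, epoch_index)
            )
            rng = np.random.Generator(np.random.PCG64(seq))
            record = generate_epoch(
                spec, config.epoch_length, config.sampling_rate, rng
            )
            record = EEGRecord(
                samples=record.samples,
                sampling_rate=record.sampling_rate,
                set_id=record.set_id,
                dataset_id=config.dataset_id,
                source_path=f"{config.dataset_id}:{spec.class_name}:{epoch_index}",
            )
            records.append(record)
            labels.append(class_index)
    return LabeledDataset(
        records=records,
        labels=np.asarray(labels),
        class_names=tuple(s.class_name for s in config.class_specs),
    )


def write_dataset_ascii(dataset: LabeledDataset, directory: str | Path) -> None:
    """Write epochs as one ASCII file per record, one set per subdirectory."""
    directory = Path(directory)
    counters: dict[str, int] = {}
    for record in dataset.records:
        sub = directory / record.set_id
        sub.mkdir(parents=True, exist_ok=True)
        idx = counters.get(record.set_id, 0)
        counters[record.set_id] = idx + 1
        write_ascii_epoch(record, sub / f"{record.set_id}{idx:03d}.txt")


def config_from_yaml(path: str | Path) -> SynthesisConfig:
    """Load a :class:`SynthesisConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    specs = tuple(
        ClassSpec(
            class_name=entry["class_name"],
            background_band=tuple(entry.get("background_band", (8.0, 13.0))),
            background_amplitude=float(entry.get("background_amplitude", 40.0)),
            spike_rate=float(entry.get("spike_rate", 0.0)),
            spike_amplitude=float(entry.get("spike_amplitude", 0.0)),
            rhythmic_burst=(
                tuple(entry["rhythmic_burst"]) if entry.get("rhythmic_burst") else None
            ),
            noise_sd=float(entry.get("noise_sd", 10.0)),
        )
        for entry in raw["class_specs"]
    )
    return SynthesisConfig(
        class_specs=specs,
        n_per_class=int(raw.get("n_per_class", 100)),
        epoch_length=int(raw.get("epoch_length", 4097)),
        sampling_rate=float(raw.get("sampling_rate", 173.61)),
        seed=int(raw.get("seed", 0)),
        dataset_id=str(raw.get("dataset_id", "synthetic")),
    )


def config_to_yaml(config: SynthesisConfig, path: str | Path) -> None:
    """Write a :class:`SynthesisConfig` to YAML (inverse of ``config_from_yaml``)."""
    payload = {
        "n_per_class": config.n_per_class,
        "epoch_length": config.epoch_length,
        "sampling_rate": config.sampling_rate,
        "seed": config.seed,
        "dataset_id": config.dataset_id,
        "class_specs": [
            {
                "class_name": s.class_name,
                "background_band": list(s.background_band),
                "background_amplitude": s.background_amplitude,
                "spike_rate": s.spike_rate,
                "spike_amplitude": s.spike_amplitude,
                "rhythmic_burst": list(s.rhythmic_burst) if s.rhythmic_burst else None,
                "noise_sd": s.noise_sd,
            }
            for s in config.class_specs
        ],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
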