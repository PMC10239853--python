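"""Deep-feature export and per-channel one-component PCA compression.

The trained network's last pooling layer emits, for every epoch, a T x C
activation map (23 x 128 for the canonical 4,097-sample geometry).  Each
of the C channels is treated as its own T-dimensional variable observed
across the training epochs: the channel's columns are centred and
projected onto their first principal component, reducing T values to one
score per channel.  Concatenating the per-channel scores yields a single
1 x C feature vector per epoch (1 x 128 canonically) which feeds the
shallow classifiers.

PCA loadings follow a fixed sign convention (largest-magnitude
coefficient positive) so refits are reproducible; zero-variance channels
are flagged and produce constant-zero scores rather than errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import LabeledDataset
from .network import TrainedNetwork


class FeatureError(ValueError):
    """Invalid feature-extraction input."""


@dataclass(frozen=True)
class FeatureMapBatch:
    """N x T x C activations exported from the feature-tap layer."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise FeatureError("feature maps must be N x T x C")
        if not np.all(np.isfinite(values)):
            raise FeatureError("feature maps contain non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def map_shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]


@dataclass(frozen=True)
class ChannelProjector:
    """One-component PCA per channel: means (C x T), unit loadings (C x T).

    ``zero_variance`` flags channels whose training columns were constant;
    their loadings are all-zero and their scores identically zero.
    """

    means: np.ndarray
    loadings: np.ndarray
    zero_variance: np.ndarray

    def __post_init__(self) -> None:
        if self.means.shape != self.loadings.shape:
            raise FeatureError("means and loadings shape mismatch")
        if self.zero_variance.shape != (self.means.shape[0],):
            raise FeatureError("zero_variance must have one flag per channel")

    @property
    def n_channels(self) -> int:
        return self.means.shape[0]

    @property
    def map_length(self) -> int:
        return self.means.shape[1]

    def save_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.loadings).to_csv(directory / "loadings.csv", index=False)
        pd.DataFrame(self.means).to_csv(directory / "means.csv", index=False)


def extract_feature_maps(
    net: TrainedNetwork, dataset: LabeledDataset
) -> FeatureMapBatch:
    """Forward pass truncated at the feature tap, in inference mode.

    Row order matches dataset order; dropout is off and BatchNorm uses its
    moving statistics, so extraction is deterministic.
    """
    if dataset.epoch_length != net.architecture.input_length:
        raise FeatureError(
            f"dataset epoch length {dataset.epoch_length} incompatible with "
            f"network input length {net.architecture.input_length}"
        )
    maps = net.feature_maps(dataset.signal_matrix())
    return FeatureMapBatch(values=maps, provenance=f"tap_layer={net.feature_tap}")


def fit_channel_projectors(train_maps: FeatureMapBatch) -> ChannelProjector:
    """Fit the first principal component of each channel across training maps.

    For channel c the N x T matrix of that channel's columns is centred
    and its top right-singular vector stored as the loading, with the
    sign flipped so the largest-magnitude coefficient is positive.
    """
    values = train_maps.values
    n, t, c = values.shape
    if n < 2:
        raise FeatureError("need at least 2 training maps to fit projectors")
    means = np.empty((c, t))
    loadings = np.zeros((c, t))
    zero_variance = np.zeros(c, dtype=bool)
    for ch in range(c):
        columns = values[:, :, ch]
        mean = columns.mean(axis=0)
        means[ch] = mean
        centered = columns - mean
        if not np.any(np.abs(centered) > 1e-12):
            zero_variance[ch] = True
            continue
        # top right-singular vector of the centred data = first PC
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        loading = vt[0]
        peak = np.argmax(np.abs(loading))
        if loading[peak] < 0:
            loading = -loading
        loadings[ch] = loading
    return ChannelProjector(means=means, loadings=loadings,
                            zero_variance=zero_variance)


def project(maps: FeatureMapBatch, projectors: ChannelProjector) -> np.ndarray:
    """Project each map onto the per-channel loadings: an N x C score matrix.

    ``score[n, c] = loadings[c] . (map[n, :, c] - means[c])``.
    """
    n, t, c = maps.values.shape
    if c != projectors.n_channels or t != projectors.map_length:
        raise FeatureError(
            f"map shape ({t},{c}) does not match projectors "
            f"({projectors.map_length},{projectors.n_channels})"
        )
    centered = maps.values - projectors.means.T[None, :, :]
    return np.einsum("ntc,ct->nc", centered, projectors.loadings)


def scores_to_csv(scores: np.ndarray, path: str | Path) -> None:
    """Write an N x C score matrix as CSV with f0..f{C-1} columns."""
    pd.DataFrame(
        scores, columns=[f"f{i}" for i in range(scores.shape[1])]
    ).to_csv(path, index=False)
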