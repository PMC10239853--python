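# Methods

## Model

The detector classifies fixed-length single-channel EEG epochs. A 24-layer
1D convolutional network is trained on raw amplitude traces (no filtering,
detrending or normalisation of the input): five blocks of Conv1D (valid
padding, stride 1) → BatchNorm (channel axis, momentum 0.9) → ReLU →
MaxPool1D (window = stride), with filters 32/64/128/256/128, kernels
3/5/13/17/9 and pools 2/4/4/2/2, then Flatten → Dense(64, ReLU, L2 0.03 on
the kernel) → Dropout(0.4) → Dense(n_classes, softmax). For 4,097-sample
epochs the last pooling layer emits a 23×128 map; valid-padding arithmetic
(`floor((L − window)/stride) + 1`) makes the architecture undefined below
roughly 3,300 samples — 1,024-sample epochs reach length 6 before the
kernel-9 block and are rejected. Parameter accounting counts BatchNorm's
four per-channel statistics (scale, shift, moving mean, moving variance),
giving 1,160,645 parameters at the canonical geometry.

The softmax head exists to train the features. The deployed representation
is the tap-layer map compressed by per-channel PCA: channel c's 23-vectors
across the training epochs are centred and projected onto their first
principal component, so each epoch becomes a 1×128 score vector. This is
the only reading under which "reduce each 23×1 column to 1×1" is
well-defined, and it is fitted strictly on training data. Loadings are
unit-norm with the largest-magnitude coefficient made positive (PCA sign
is arbitrary; a fixed rule keeps refits reproducible). Channels whose
training columns are constant are flagged and yield constant-zero scores
rather than errors, so degenerate inputs still flow through classifiers.

Seven shallow classifiers consume the scores: SVC (RBF, C=1), k-NN (k=5),
random forest (100 trees), Gaussian naive Bayes, gradient boosting (100
stages, rate 0.1), decision tree, and an MLP (one hidden layer of 100,
iteration cap 1,000 so small problems converge cleanly). These are frozen
library defaults — none are tuned — and every stochastic model is seeded.
Scores are fed raw (no standardisation), matching the pipeline's
definition of the feature vector.

## Training engine

No deep-learning framework is used: layers, analytic gradients and Adam
(β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁷) are implemented in NumPy with im2col
convolutions routed through BLAS matrix products, in float32. Weight
initialisation is Glorot-uniform; BatchNorm uses ε = 10⁻³ and biased batch
variance, with moving statistics (momentum 0.9) applied at inference;
dropout is inverted and active only in training mode. The loss is mean
categorical cross-entropy plus 0.03·‖W‖² on the first dense kernel
(gradient 0.06·W). Defaults follow the published protocol: learning rate
10⁻⁴ (10⁻³ is also quoted in the source protocol and remains available via
`TrainingConfig`), batch 50, 300 epochs. All randomness — initialisation,
shuffling, dropout masks — derives from one seeded generator, so identical
configs give bit-identical weights and histories. A learning rate of 0
provably leaves weights unchanged (the degenerate closed-form limit, kept
as a test). Per-epoch history records training-mode accuracy/loss averaged
over the shuffled batches, plus inference-mode validation series when a
stratified hold-out fraction is requested. A non-finite loss aborts with
the offending epoch.

## Protocol

Cases assemble labeled sets (A–E at 100×4,097 samples, 173.61 Hz; F/G/H at
50×1,024 samples, 200 Hz) into 17 binary/ternary/five-class problems.
Evaluation is stratified 10-fold cross-validation; folds are shuffled by a
dedicated fold seed independent of classifier seeds, so all classifiers
share identical splits (paired design). Two feature-extractor scopes are
implemented because the source protocol is ambiguous:

* **strict** (default): the network is retrained inside every fold (fold
  index added to the training seed) and PCA is fitted on the training maps
  only. SHA-256 fingerprints of the index sets consumed by each fitted
  stage are recorded per fold, and tests assert that no test index ever
  reaches a fitting stage.
* **shared**: one network per dataset family, trained on all records with
  the family's set-level labels (five-way for A–E, three-way for F/G/H),
  its features reused across that family's cases. This mirrors a single
  training run per dataset; it is cheaper but lets the extractor see test
  folds' raw signals. PCA scope can independently be `fold` or `full`.

Binary metrics treat class index 1 (the second, typically
seizure/abnormal, group of the case definition) as positive. Multi-class
results are collapsed one-vs-rest: macro averaging by default for
SEN/SPF/PPV/NPV/MCC/F1 and trace/total for micro accuracy. Zero
denominators flag a metric undefined rather than zero, and fold averages
skip undefined entries; the default report instead pools confusion counts
over folds (micro aggregation), whose accuracy equals total correct over
total predictions. ROC curves use threshold sweeps with tied scores
grouped (scikit-learn's sweep) and trapezoid AUC, which equals the
Mann–Whitney concordance probability; one-class folds flag AUC undefined.
For multi-class cases the reported AUC is the macro mean of one-vs-rest
AUCs. Formatted reports print percentages to two decimals in the column
order ACC, SPF, SEN, PPV, NPV, MCC, F1.

Short epochs and the fixed geometry: 1,024-sample epochs are symmetrically
zero-padded to 4,097 by default, preserving the published 23×128 feature
shape; a `scaled` policy instead shrinks kernels proportionally (pools
unchanged, minimum kernel 2), used for cheap experiments and by the test
suite.

## Synthetic data

The generator emulates the gross morphology that distinguishes the three
clinical regimes, not physiological EEG: a band-limited background
sinusoid (random frequency in a band, random phase), Poisson-placed
biphasic spikes (difference-of-Gaussians, ~70 ms, ±20% amplitude jitter,
random polarity), an optional rhythmic burst covering a duty fraction of
the epoch with cosine-tapered edges, and white Gaussian noise. Presets:
normal (alpha 8–13 Hz background, amplitude 40–65 a.u., noise SD 10),
interictal (theta background with 0.3–0.6 spikes/s at amplitude 120–150),
ictal (sustained 4 Hz burst, amplitude 250, duty 0.8). Each epoch draws
from a stream keyed by (master seed, class index, epoch index), so
datasets are reproducible and extending a dataset never perturbs earlier
epochs. Default geometries mirror the benchmarks: 100 epochs/class at
4,097 samples (173.61 Hz) and 50 epochs/class at 1,024 samples (200 Hz).

What passing tests show — and do not show: the presets separate classes by
band power and burst amplitude (spike/burst amplitudes ≥ 5× the noise SD
give a ≥ 90% linear-classifier floor on plain band-power features), so
perfect end-to-end scores on synthetic data demonstrate that the pipeline
is wired correctly and leak-free, not that it attains any particular
accuracy on clinical recordings, which have 1/f spectra, artifacts and
inter-subject variability the generator deliberately omits.

## Problem sizes and numerical choices

The reference end-to-end run uses the binary synthetic contrast at the
full 4,097-sample geometry, 100 epochs/class, 30 training epochs in shared
mode (the per-dataset single-training protocol), with the label-permuted
null reusing the same extractor — the permutation affects only the labels
the classifier stage sees, never the extractor's inputs, so one training
suffices. Thirty epochs is the package's reduced profile for routine runs
and testing; 300 epochs reproduces the published schedule via
`TrainingConfig(epochs=300)`. Strict per-fold retraining is exercised on
the scaled geometry at 512 samples in the test suite. The permuted-label
check uses the two-sided 99% binomial band around 50% for the run's 200
predictions.

Tie-breaks and degenerate inputs: max-pool backward routes gradient to the
first maximal element per window (argmax convention); all-zero epochs
produce finite feature maps (BatchNorm shifts may make them non-zero);
PCA on a single training map is rejected (N ≥ 2 required).

## Known limitations

Single-channel epochs only (no montages, no EDF/BDF ingestion, no artifact
rejection); no hyperparameter search or nested CV; epoch-level (not
patient-level) fold stratification, as in the source protocol; the NumPy
trainer is single-process and CPU-bound, so 300-epoch runs on full
benchmark-sized datasets take hours rather than minutes.
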