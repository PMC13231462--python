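"""Canned end-to-end experiments on synthetic cohorts.

These are the study-level analyses the package exists for, wired together
at the package's default desk scale: generate a cohort under the default
effect configuration, featurize it, and evaluate classification
architectures under leave-dyad-out cross-validation — either on the true
labels (recovery), with synchrony features ablated, or on within-dyad
label permutations (null calibration).

The default stage configuration mirrors the best-performing published
combination for this task family: relief-based feature selection with
gradient boosting, in the serial valence-first architecture.
"""

from __future__ import annotations

import numpy as np

from .dataset import LabeledDataset, build_dataset, featurize_recording, permute_labels_within_dyad
from .pipeline import ArchitectureConfig, PipelineConfig, lodo_crossvalidate
from .simulate import EffectConfig, default_effect_config, generate_cohort

__all__ = [
    "default_arch",
    "featurized_datasets",
    "null_accuracy_distribution",
    "recovery_accuracy",
]


def default_arch(kind: str = "serial_valence_first",
                 selector: str = "relieff",
                 classifier: str = "gradient_boosting",
                 n_features: int = 10) -> ArchitectureConfig:
    """The package's reference architecture configuration."""
    return ArchitectureConfig.uniform(
        kind, PipelineConfig(selector=selector, classifier=classifier,
                             n_features_grid=(n_features,)))


def featurized_datasets(
    n_dyads: int, seed: int, effect: EffectConfig | None = None
) -> tuple[LabeledDataset, LabeledDataset]:
    """Generate + featurize a cohort once; return (full, synchrony-ablated)
    datasets built from the same per-dyad features."""
    effect = effect or default_effect_config()
    cohort = generate_cohort(n_dyads, effect, seed=seed)
    pre = {rec.dyad_id: featurize_recording(rec) for rec in cohort.recordings}
    cohort.recordings = None  # free the raw signals
    full = build_dataset(cohort, include_synchrony=True, precomputed=pre)
    ablated = build_dataset(cohort, include_synchrony=False, precomputed=pre)
    return full, ablated


def null_accuracy_distribution(
    dataset: LabeledDataset,
    arch: ArchitectureConfig,
    n_replicates: int,
    seed: int,
) -> np.ndarray:
    """Mean LODO accuracies over within-dyad label-permutation replicates."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_replicates)
    for b in range(n_replicates):
        permuted = permute_labels_within_dyad(dataset, rng)
        out[b] = lodo_crossvalidate(
            arch, permuted, seed=int(rng.integers(2**31))
        ).mean_accuracy
    return out


def recovery_accuracy(dataset: LabeledDataset, arch: ArchitectureConfig,
                      seed: int = 0) -> float:
    """Mean LODO accuracy on the true labels."""
    return lodo_crossvalidate(arch, dataset, seed=seed).mean_accuracy
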