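"""Accuracy metrics, permutation significance, and rank-based comparison.

Confusion-matrix conventions: rows are actual classes, columns predicted,
both in the canonical order (PV-HA, PV-LA, NV-HA, NV-LA). Collapsed
accuracies merge the quadrants along one axis; the stage-2 conditional
accuracy is defined over the cases whose *stage-1 axis was predicted
correctly* — the only definition under which a serial classifier's
stage-wise accuracies are recoverable from its overall 4-class confusion
matrix.

The permutation test shuffles scenario labels within each dyad and re-runs
the entire pipeline (selection + training) under leave-dyad-out CV per
replicate; p-values use the add-one estimator (1 + #{null >= observed}) /
(B + 1), which cannot reach zero.

The omnibus comparison of approaches is the Friedman test with dyads as
blocks and midrank ties — the standard nonparametric analogue of a
repeated-measures ANOVA on ranks — followed by all-pairs Wilcoxon
signed-rank tests with Holm family-wise correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

from .dataset import LabeledDataset, permute_labels_within_dyad
from .errors import InvalidArgumentError, UndefinedValueError
from .labels import AROUSAL, SCENARIOS, VALENCE
from .pipeline import ArchitectureConfig, lodo_crossvalidate

__all__ = [
    "accuracy_from_confusion",
    "valence_collapsed_accuracy",
    "arousal_collapsed_accuracy",
    "stage2_conditional_accuracy",
    "PermutationResult",
    "permutation_test",
    "compare_approaches_ranked",
]

_VAL = np.array([VALENCE[lab] for lab in SCENARIOS])
_ARO = np.array([AROUSAL[lab] for lab in SCENARIOS])


def _as_cm(cm) -> np.ndarray:
    cm = np.asarray(cm, dtype=float)
    if cm.shape != (4, 4) or cm.sum() <= 0 or (cm < 0).any():
        raise InvalidArgumentError("need a nonempty 4x4 confusion matrix")
    return cm


def accuracy_from_confusion(cm) -> float:
    """Overall accuracy in percent: 100 × trace / total."""
    cm = _as_cm(cm)
    return float(100.0 * np.trace(cm) / cm.sum())


def _collapsed(cm: np.ndarray, axis_labels: np.ndarray) -> float:
    same = axis_labels[:, None] == axis_labels[None, :]
    return float(100.0 * cm[same].sum() / cm.sum())


def valence_collapsed_accuracy(cm) -> float:
    """Percent of cases whose predicted valence matches the actual one."""
    return _collapsed(_as_cm(cm), _VAL)


def arousal_collapsed_accuracy(cm) -> float:
    """Percent of cases whose predicted arousal matches the actual one."""
    return _collapsed(_as_cm(cm), _ARO)


def stage2_conditional_accuracy(cm, valence: str) -> float:
    """Stage-2 arousal accuracy among valence-correct cases of one sign.

    Restricts the matrix to rows of actual valence ``valence`` ("P"/"N")
    and columns of the same predicted valence, then scores arousal.
    """
    cm = _as_cm(cm)
    if valence not in ("P", "N"):
        raise InvalidArgumentError("valence must be 'P' or 'N'")
    rows = _VAL == valence
    sub = cm[np.ix_(rows, rows)]
    total = sub.sum()
    if total == 0:
        raise UndefinedValueError("no valence-correct cases of this sign")
    aro = _ARO[rows]
    correct = sub[aro[:, None] == aro[None, :]].sum()
    return float(100.0 * correct / total)


@dataclass
class PermutationResult:
    observed_accuracy: float        # fraction in [0, 1]
    null_accuracies: np.ndarray     # length B
    p_value: float

    @property
    def null_mean(self) -> float:
        return float(self.null_accuracies.mean())


def permutation_test(
    dataset: LabeledDataset,
    arch: ArchitectureConfig,
    B: int = 1000,
    seed: int = 0,
    observed: float | None = None,
) -> PermutationResult:
    """Within-dyad label-permutation null of leave-dyad-out accuracy.

    Each replicate independently shuffles the four scenario labels within
    every dyad and re-runs the full pipeline. ``observed`` can be supplied
    to reuse a previously computed unpermuted accuracy.
    """
    if B < 1:
        raise InvalidArgumentError("B must be >= 1")
    rng = np.random.default_rng(seed)
    if observed is None:
        observed = lodo_crossvalidate(arch, dataset, seed=seed).mean_accuracy
    nulls = np.empty(B)
    for b in range(B):
        permuted = permute_labels_within_dyad(dataset, rng)
        nulls[b] = lodo_crossvalidate(
            arch, permuted, seed=int(rng.integers(2**31))
        ).mean_accuracy
    p = (1.0 + np.sum(nulls >= observed)) / (B + 1.0)
    return PermutationResult(float(observed), nulls, float(p))


@dataclass
class RankedComparison:
    """Friedman omnibus over approaches (blocks = dyads) + Holm-corrected
    pairwise Wilcoxon signed-rank results."""

    method: str
    statistic: float
    p_value: float
    pairwise: list[dict]


def _friedman(table: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square with midrank ties; table is blocks × treatments."""
    n, k = table.shape
    ranks = np.apply_along_axis(sst.rankdata, 1, table)
    col_sums = ranks.sum(axis=0)
    # tie correction per block
    tie_corr = 0.0
    for row in table:
        _, counts = np.unique(row, return_counts=True)
        tie_corr += float(np.sum(counts**3 - counts))
    denom = n * k * (k + 1) - tie_corr / (k - 1)
    if denom <= 0:
        return 0.0, 1.0
    stat = 12.0 * np.sum((col_sums - n * (k + 1) / 2.0) ** 2) / denom
    p = float(sst.chi2.sf(stat, k - 1))
    return float(stat), p


def compare_approaches_ranked(per_dyad_accuracy: np.ndarray,
                              approach_names: list[str] | None = None
                              ) -> RankedComparison:
    """Compare approaches on their per-dyad accuracies.

    ``per_dyad_accuracy`` is approaches × dyads. Within each dyad the
    approaches are ranked with midrank ties; the Friedman statistic tests
    the omnibus hypothesis, and all approach pairs are compared post hoc
    with Wilcoxon signed-rank tests under Holm correction.
    """
    table = np.asarray(per_dyad_accuracy, dtype=float).T  # blocks × treatments
    n, k = table.shape
    if k < 2 or n < 5:
        raise InvalidArgumentError("need >= 2 approaches and >= 5 dyads")
    names = approach_names or [f"approach{i}" for i in range(k)]

    if np.all(table == table[:, [0]]):
        warnings.warn("all approaches tied on every dyad; omnibus p = 1")
        return RankedComparison("friedman_on_ranks", 0.0, 1.0, [])

    stat, p = _friedman(table)

    pairs = []
    raw = []
    for i in range(k):
        for j in range(i + 1, k):
            d = table[:, i] - table[:, j]
            if np.all(d == 0):
                pw = 1.0
            else:
                pw = float(
                    sst.wilcoxon(table[:, i], table[:, j],
                                 zero_method="wilcox", method="auto").pvalue
                )
            raw.append(pw)
            pairs.append({"a": names[i], "b": names[j], "p_raw": pw})
    # Holm step-down correction
    order = np.argsort(raw)
    m = len(raw)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * raw[idx])
        adj[idx] = min(1.0, running)
    for pr, a in zip(pairs, adj):
        pr["p_holm"] = float(a)

    return RankedComparison("friedman_on_ranks + wilcoxon_holm", stat, p, pairs)
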