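"""Classifier training, the four classification architectures, and
leave-dyad-out cross-validation.

Architectures
-------------
direct
    One 4-class classifier over the scenario labels.
serial_valence_first / serial_arousal_first
    Stage 1 predicts one binary axis; stage 2 has one branch per stage-1
    outcome, each a binary classifier of the other axis. Branches are
    trained on the ground-truth-labelled halves of the training data and
    applied at test time according to stage 1's *prediction*.
parallel
    Independent binary arousal and valence classifiers whose outputs are
    crossed into the 4-class label.

Every stage is a (feature selector, classifier) pair. Hyperparameters are
chosen by inner 3-fold dyad-grouped cross-validation over a small
documented grid, evaluating at most ``hyperopt_budget`` candidates in grid
order (budget 1 = first/default candidate, no inner CV). When
``n_features_grid`` has several entries the subset size is chosen by the
same inner CV.

Leave-dyad-out cross-validation holds out all four segments of one dyad
per fold; selection, hyperparameter choice and fitting see only the
training dyads. Per-dyad accuracy over 4 segments takes values
{0, 0.25, 0.5, 0.75, 1}; the mean over dyads is the headline outcome.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import GroupKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dataset import LabeledDataset
from .errors import InvalidArgumentError
from .labels import AROUSAL, SCENARIOS, VALENCE, label_from_axes
from .selection import SELECTORS, select_features

__all__ = [
    "CLASSIFIERS",
    "PipelineConfig",
    "ArchitectureConfig",
    "ClassificationRun",
    "fit_classifier",
    "fit_stage",
    "predict_architecture",
    "lodo_crossvalidate",
    "enumerate_combinations",
    "grid_search_architectures",
]

CLASSIFIERS = ("knn", "lda", "svm", "naive_bayes", "gradient_boosting", "random_forest")

#: hyperparameter grids, in evaluation order (first entry = default)
_GRIDS: dict[str, list[dict]] = {
    "knn": [{"n_neighbors": k} for k in (5, 3, 7, 11)],
    "lda": [{"solver": "svd"}, {"solver": "lsqr", "shrinkage": "auto"}],
    "svm": [{"C": c, "kernel": "rbf", "gamma": "scale"} for c in (1.0, 0.1, 10.0)],
    "naive_bayes": [{"var_smoothing": v} for v in (1e-9, 1e-7)],
    "gradient_boosting": [{"n_estimators": n, "max_depth": 3} for n in (100, 300)],
    "random_forest": [{"n_estimators": n} for n in (100, 300)],
}


def _make_estimator(classifier: str, params: dict, seed: int):
    if classifier == "knn":
        est = KNeighborsClassifier(**params)
    elif classifier == "lda":
        est = LinearDiscriminantAnalysis(**params)
    elif classifier == "svm":
        est = SVC(random_state=seed, **params)
    elif classifier == "naive_bayes":
        est = GaussianNB(**params)
    elif classifier == "gradient_boosting":
        est = GradientBoostingClassifier(random_state=seed, **params)
    elif classifier == "random_forest":
        est = RandomForestClassifier(random_state=seed, **params)
    else:
        raise InvalidArgumentError(f"unknown classifier {classifier!r}")
    # distance/margin-based models need standardized inputs
    if classifier in ("knn", "svm"):
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


@dataclass(frozen=True)
class PipelineConfig:
    """One stage's selector/classifier configuration."""

    selector: str = "relieff"
    classifier: str = "gradient_boosting"
    n_features_grid: tuple[int, ...] = (10,)
    hyperopt_budget: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selector not in SELECTORS:
            raise InvalidArgumentError(f"unknown selector {self.selector!r}")
        if self.classifier not in CLASSIFIERS:
            raise InvalidArgumentError(f"unknown classifier {self.classifier!r}")
        if self.hyperopt_budget < 1:
            raise InvalidArgumentError("hyperopt_budget must be >= 1")


ARCHITECTURES = ("direct", "serial_valence_first", "serial_arousal_first", "parallel")


@dataclass(frozen=True)
class ArchitectureConfig:
    """An architecture plus its per-stage pipeline configurations.

    * direct: ``stages = (four_class,)``
    * serial_valence_first: ``(valence_stage, branch_P, branch_N)``
    * serial_arousal_first: ``(arousal_stage, branch_H, branch_L)``
    * parallel: ``(arousal_stage, valence_stage)``
    """

    kind: str
    stages: tuple[PipelineConfig, ...]

    def __post_init__(self) -> None:
        expected = {"direct": 1, "serial_valence_first": 3,
                    "serial_arousal_first": 3, "parallel": 2}
        if self.kind not in expected:
            raise InvalidArgumentError(f"unknown architecture {self.kind!r}")
        if len(self.stages) != expected[self.kind]:
            raise InvalidArgumentError(
                f"{self.kind} requires {expected[self.kind]} stage configs"
            )

    @classmethod
    def uniform(cls, kind: str, config: PipelineConfig) -> "ArchitectureConfig":
        """Same selector/classifier config in every stage."""
        n = {"direct": 1, "serial_valence_first": 3,
             "serial_arousal_first": 3, "parallel": 2}[kind]
        return cls(kind, tuple(replace(config) for _ in range(n)))


@dataclass
class FittedStage:
    model: object
    features: list[int]
    config: PipelineConfig
    classes: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X[:, self.features])


def _inner_cv_score(est, X, y, groups, seed: int) -> float:
    n_groups = len(np.unique(groups))
    if n_groups < 3 or len(np.unique(y)) < 2:
        return 0.0
    cv = GroupKFold(n_splits=min(3, n_groups))
    accs = []
    for tr, te in cv.split(X, y, groups):
        if len(np.unique(y[tr])) < 2:
            continue
        m = clone(est)
        m.fit(X[tr], y[tr])
        accs.append(float(np.mean(m.predict(X[te]) == y[te])))
    return float(np.mean(accs)) if accs else 0.0


def fit_classifier(config: PipelineConfig, X_train: np.ndarray, y_train: np.ndarray,
                   groups: np.ndarray | None = None):
    """Fit one classifier with budgeted inner-CV hyperparameter choice.

    With ``hyperopt_budget=1`` the first (default) grid entry is used
    without inner CV; larger budgets evaluate more grid entries by 3-fold
    dyad-grouped accuracy and refit the best on all training data.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise InvalidArgumentError("y_train must contain at least 2 classes")
    grid = _GRIDS[config.classifier][: config.hyperopt_budget]
    if len(grid) > 1 and groups is not None:
        scores = [
            _inner_cv_score(_make_estimator(config.classifier, g, config.seed),
                            X_train, y_train, groups, config.seed)
            for g in grid
        ]
        params = grid[int(np.argmax(scores))]
    else:
        params = grid[0]
    est = _make_estimator(config.classifier, params, config.seed)
    est.fit(X_train, y_train)
    return est


def fit_stage(config: PipelineConfig, X: np.ndarray, y: np.ndarray,
              groups: np.ndarray) -> FittedStage:
    """Feature selection + classifier fit for one stage.

    When ``n_features_grid`` has several entries the subset size is chosen
    by inner dyad-grouped CV of the full selector+classifier pipeline.
    """
    sizes = [min(s, X.shape[1]) for s in config.n_features_grid]
    if len(set(sizes)) > 1:
        scores = []
        for s in sizes:
            feats = select_features(config.selector, X, y, s, config.seed)
            est = _make_estimator(
                config.classifier, _GRIDS[config.classifier][0], config.seed
            )
            scores.append(_inner_cv_score(est, X[:, feats], y, groups, config.seed))
        size = sizes[int(np.argmax(scores))]
    else:
        size = sizes[0]
    feats = select_features(config.selector, X, y, size, config.seed)
    model = fit_classifier(config, X[:, feats], y, groups)
    return FittedStage(model, feats, config, np.unique(y))


def _fit_architecture(arch: ArchitectureConfig, X: np.ndarray, df_y: pd.DataFrame,
                      groups: np.ndarray) -> list[FittedStage]:
    """Train all stages of an architecture on one training split."""
    y4 = df_y["label"].to_numpy()
    yv = df_y["valence"].to_numpy()
    ya = df_y["arousal"].to_numpy()
    if arch.kind == "direct":
        return [fit_stage(arch.stages[0], X, y4, groups)]
    if arch.kind == "parallel":
        return [
            fit_stage(arch.stages[0], X, ya, groups),
            fit_stage(arch.stages[1], X, yv, groups),
        ]
    first_axis, branches = (
        (yv, ("P", "N")) if arch.kind == "serial_valence_first" else (ya, ("H", "L"))
    )
    stage1 = fit_stage(arch.stages[0], X, first_axis, groups)
    fitted = [stage1]
    second = ya if arch.kind == "serial_valence_first" else yv
    for cfg, side in zip(arch.stages[1:], branches):
        mask = first_axis == side  # ground-truth halves for branch training
        fitted.append(fit_stage(cfg, X[mask], second[mask], groups[mask]))
    return fitted


def predict_architecture(arch: ArchitectureConfig, stages: list[FittedStage],
                         X_test: np.ndarray) -> np.ndarray:
    """4-class predictions from trained stages.

    Serial architectures route each row through the branch matching stage
    1's prediction; parallel crosses the two binary predictions.
    """
    n_expected = {"direct": 1, "serial_valence_first": 3,
                  "serial_arousal_first": 3, "parallel": 2}[arch.kind]
    if len(stages) != n_expected:
        raise InvalidArgumentError("stage count does not match architecture")
    if arch.kind == "direct":
        return stages[0].predict(X_test)
    if arch.kind == "parallel":
        ya = stages[0].predict(X_test)
        yv = stages[1].predict(X_test)
        return np.array([label_from_axes(v, a) for v, a in zip(yv, ya)])
    s1 = stages[0].predict(X_test)
    out = np.empty(len(X_test), dtype=object)
    sides = ("P", "N") if arch.kind == "serial_valence_first" else ("H", "L")
    for branch, side in zip(stages[1:], sides):
        m = s1 == side
        if not m.any():
            continue
        s2 = branch.predict(X_test[m])
        if arch.kind == "serial_valence_first":
            out[m] = [label_from_axes(side, a) for a in s2]
        else:
            out[m] = [label_from_axes(v, side) for v in s2]
    return out.astype(str)


@dataclass
class ClassificationRun:
    """Result of one leave-dyad-out evaluation."""

    arch: ArchitectureConfig
    predictions: pd.DataFrame        # dyad_id, segment, label, predicted
    per_dyad_accuracy: pd.Series     # index dyad_id, values in {0,.25,.5,.75,1}
    mean_accuracy: float             # fraction in [0, 1]
    confusion: np.ndarray            # 4x4, canonical label order
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "architecture": self.arch.kind,
            "stages": [vars(s) | {"n_features_grid": list(s.n_features_grid)}
                       for s in self.arch.stages],
            "mean_accuracy": self.mean_accuracy,
            "per_dyad_accuracy": {str(k): float(v)
                                  for k, v in self.per_dyad_accuracy.items()},
            "confusion": self.confusion.tolist(),
            "label_order": list(SCENARIOS),
            "seed": self.seed,
        }


def confusion_matrix4(actual: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    idx = {lab: i for i, lab in enumerate(SCENARIOS)}
    cm = np.zeros((4, 4), dtype=int)
    for a, p in zip(actual, predicted):
        cm[idx[a], idx[p]] += 1
    return cm


def lodo_crossvalidate(arch: ArchitectureConfig, dataset: LabeledDataset,
                       seed: int = 0) -> ClassificationRun:
    """Leave-dyad-out cross-validation of one architecture.

    Each fold trains every stage (selection, hyperparameter choice, fit)
    on all dyads but one and predicts the held-out dyad's four segments.
    """
    dyads = dataset.dyad_ids
    if len(dyads) < 3:
        raise InvalidArgumentError("need at least 3 dyads")
    arch = ArchitectureConfig(
        arch.kind, tuple(replace(s, seed=seed + 1000 * i)
                         for i, s in enumerate(arch.stages))
    )
    X = dataset.X
    df = dataset.df
    groups = dataset.groups
    preds = np.empty(len(df), dtype=object)
    for dyad in dyads:
        test = groups == dyad
        train = ~test
        stages = _fit_architecture(
            arch, X[train], df.loc[train, ["label", "valence", "arousal"]],
            groups[train],
        )
        preds[test] = predict_architecture(arch, stages, X[test])
    preds = preds.astype(str)
    correct = preds == df["label"].to_numpy()
    per_dyad = pd.Series(correct).groupby(groups).mean()
    cm = confusion_matrix4(df["label"].to_numpy(), preds)
    out_df = df[["dyad_id", "segment", "label"]].copy()
    out_df["predicted"] = preds
    return ClassificationRun(
        arch=arch,
        predictions=out_df,
        per_dyad_accuracy=per_dyad,
        mean_accuracy=float(per_dyad.mean()),
        confusion=cm,
        seed=seed,
    )


def enumerate_combinations(arch_kind: str) -> int:
    """Number of selector × classifier assignments for an architecture.

    30 per stage-slot (5 selectors × 6 classifiers): direct has one slot
    (30), parallel two (900), serial three (27,000).
    """
    per_stage = len(SELECTORS) * len(CLASSIFIERS)
    slots = {"direct": 1, "parallel": 2,
             "serial_valence_first": 3, "serial_arousal_first": 3}
    if arch_kind == "serial":
        return per_stage ** 3
    if arch_kind not in slots:
        raise InvalidArgumentError(f"unknown architecture kind {arch_kind!r}")
    return per_stage ** slots[arch_kind]


def _stage_combos() -> list[tuple[str, str]]:
    return list(itertools.product(SELECTORS, CLASSIFIERS))


def grid_search_architectures(
    dataset: LabeledDataset,
    budget_policy: int | str = 200,
    seed: int = 0,
    base_config: PipelineConfig | None = None,
    kinds: tuple[str, ...] = ARCHITECTURES,
) -> pd.DataFrame:
    """Search selector×classifier assignments per architecture under LODO.

    ``budget_policy`` is either ``"all"`` (full enumeration) or a maximum
    number of combinations per architecture; over-budget spaces are
    subsampled uniformly with the given seed. Returns one row per
    architecture with the best assignment and accuracy, plus the count of
    combinations evaluated.
    """
    base = base_config or PipelineConfig()
    rng = np.random.default_rng(seed)
    rows = []
    per_stage = _stage_combos()
    for kind in kinds:
        n_slots = {"direct": 1, "parallel": 2,
                   "serial_valence_first": 3, "serial_arousal_first": 3}[kind]
        space = list(itertools.product(per_stage, repeat=n_slots))
        if budget_policy != "all" and len(space) > int(budget_policy):
            idx = rng.choice(len(space), size=int(budget_policy), replace=False)
            space = [space[i] for i in sorted(idx)]
        best = None
        for combo in space:
            stages = tuple(
                replace(base, selector=sel, classifier=clf) for sel, clf in combo
            )
            run = lodo_crossvalidate(ArchitectureConfig(kind, stages), dataset, seed)
            if best is None or run.mean_accuracy > best[1].mean_accuracy:
                best = (combo, run)
        combo, run = best
        rows.append({
            "architecture": kind,
            "stage_configs": "; ".join(f"{s}+{c}" for s, c in combo),
            "mean_accuracy": run.mean_accuracy,
            "sd_accuracy": float(run.per_dyad_accuracy.std()),
            "n_evaluated": len(space),
        })
    return pd.DataFrame(rows)
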