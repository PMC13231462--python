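"""Baseline normalization, dyad combination, and dataset assembly.

For each dyad the pipeline is: per-segment preprocessing and feature
extraction (18 individual features per participant, 16 synchrony features
per dyad) for all six segments, baseline normalization by subtracting the
first-baseline value of every feature ("for each dyad and each feature"),
then combination of the two participants' individual features into
dyad-level ``mean_of_*`` and ``absdiff_of_*`` values — the two
participants play the same role in the conversation, so only symmetric
combinations are meaningful.

Normalization order: individual features are baseline-subtracted per
participant *before* the mean/absdiff combination; synchrony features are
baseline-subtracted at the dyad level. The mean is unaffected by this
ordering; the absolute difference is not (|a−b| of normalized values
equals |(a−a0)−(b−b0)|, not |a−b| − |a0−b0|), and the per-participant-first
convention is the one this package commits to.

The resulting :class:`LabeledDataset` has one row per (dyad, conversation
segment): 52 features with synchrony included, 36 without, plus optional
trait (8) and self-report (10) channels combined with the same
mean/absdiff rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import QualityError, SchemaError
from .individual import INDIVIDUAL_FEATURE_NAMES, extract_individual
from .labels import AROUSAL, VALENCE
from .preprocess import (
    detect_breath_peaks,
    detect_r_peaks,
    detect_scrs,
    instantaneous_rate,
    lowpass_filter,
    split_segments,
)
from .recording import PARTICIPANTS, DyadRecording
from .simulate import SELFREPORT_ITEMS, TRAITS, Cohort
from .synchrony import (
    SYNC_GRID_FS,
    SYNCHRONY_FEATURE_NAMES,
    extract_synchrony,
    prepare_series,
)

logger = logging.getLogger(__name__)

__all__ = [
    "COMBINED_FEATURE_NAMES",
    "LabeledDataset",
    "normalize_by_baseline",
    "combine_dyad",
    "featurize_recording",
    "build_dataset",
    "permute_labels_within_dyad",
]

COMBINED_FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"mean_of_{f}" for f in INDIVIDUAL_FEATURE_NAMES]
    + [f"absdiff_of_{f}" for f in INDIVIDUAL_FEATURE_NAMES]
)

ALL_FEATURE_NAMES: tuple[str, ...] = COMBINED_FEATURE_NAMES + SYNCHRONY_FEATURE_NAMES


def normalize_by_baseline(
    segment_features: dict[str, float], baseline_features: dict[str, float]
) -> dict[str, float]:
    """Elementwise subtraction of first-baseline feature values."""
    if set(segment_features) != set(baseline_features):
        raise SchemaError("feature name sets differ between segment and baseline")
    return {k: segment_features[k] - baseline_features[k] for k in segment_features}


def combine_dyad(
    indiv_a: dict[str, float], indiv_b: dict[str, float]
) -> dict[str, float]:
    """Dyad-level mean and absolute difference of each individual feature."""
    if set(indiv_a) != set(indiv_b):
        raise SchemaError("participants' feature name sets differ")
    out: dict[str, float] = {}
    for f in indiv_a:
        out[f"mean_of_{f}"] = (indiv_a[f] + indiv_b[f]) / 2.0
    for f in indiv_a:
        out[f"absdiff_of_{f}"] = abs(indiv_a[f] - indiv_b[f])
    return out


def featurize_recording(recording: DyadRecording) -> dict[str, dict]:
    """Per-segment features for one dyad.

    Returns ``{segment_name: {"label": ..., "individual": {"p1": {...},
    "p2": {...}}, "synchrony": {...}}}`` for all six segments, with no
    normalization applied yet. Raises :class:`QualityError` if any segment
    fails event-detection quality checks.
    """
    fs = recording.fs
    out: dict[str, dict] = {}
    for seg in split_segments(recording):
        span_s = seg.n_samples / fs
        indiv: dict[str, dict[str, float]] = {}
        prepared: dict[str, list[np.ndarray]] = {s: [] for s in ("hr", "resp", "eda", "temp")}
        for p in PARTICIPANTS:
            ecg = recording.slice(p, "ecg", seg)
            eda = lowpass_filter(recording.slice(p, "eda", seg), fs)
            resp = lowpass_filter(recording.slice(p, "resp", seg), fs)
            temp = lowpass_filter(recording.slice(p, "temp", seg), fs)

            r_peaks = detect_r_peaks(ecg, fs)
            breaths = detect_breath_peaks(resp, fs)
            scrs = detect_scrs(eda, fs)

            indiv[p] = extract_individual(
                r_peaks, breaths, scrs, eda, temp, fs, (0.0, span_s)
            )

            hr = instantaneous_rate(r_peaks, 0.0, span_s, SYNC_GRID_FS)
            rr = instantaneous_rate(breaths, 0.0, span_s, SYNC_GRID_FS)
            t_samp = np.arange(len(eda)) / fs
            prepared["hr"].append(prepare_series(hr.values, hr.t, 0.0, span_s))
            prepared["resp"].append(prepare_series(rr.values, rr.t, 0.0, span_s))
            prepared["eda"].append(prepare_series(eda, t_samp, 0.0, span_s))
            prepared["temp"].append(prepare_series(temp, t_samp, 0.0, span_s))

        sync = extract_synchrony({s: tuple(v) for s, v in prepared.items()})
        out[seg.name] = {
            "label": seg.label,
            "individual": indiv,
            "synchrony": sync,
        }
    return out


def _dyad_rows(features: dict[str, dict], dyad_id: str) -> list[dict]:
    """Normalized, combined feature rows for one dyad's 4 conversation
    segments."""
    base = features["baseline1"]
    rows = []
    for name, seg in features.items():
        if seg["label"] is None:
            continue
        norm = {
            p: normalize_by_baseline(seg["individual"][p], base["individual"][p])
            for p in PARTICIPANTS
        }
        row: dict = {"dyad_id": dyad_id, "segment": name, "label": seg["label"]}
        row.update(combine_dyad(norm["p1"], norm["p2"]))
        row.update(normalize_by_baseline(seg["synchrony"], base["synchrony"]))
        rows.append(row)
    return rows


@dataclass
class LabeledDataset:
    """Rows = (dyad, conversation segment); columns = features + labels."""

    df: pd.DataFrame
    feature_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "valence" not in self.df.columns:
            self.df = self.df.assign(
                valence=self.df["label"].map(VALENCE),
                arousal=self.df["label"].map(AROUSAL),
            )

    @property
    def X(self) -> np.ndarray:
        return self.df[self.feature_columns].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.df["dyad_id"].to_numpy()

    @property
    def dyad_ids(self) -> list[str]:
        return list(pd.unique(self.df["dyad_id"]))

    def labels_for_axis(self, axis: str) -> np.ndarray:
        """Binary labels for ``"valence"`` / ``"arousal"``, or the 4-class
        labels for ``"label"``."""
        return self.df[axis].to_numpy()

    def select_features(self, columns: list[str]) -> "LabeledDataset":
        keep = [c for c in self.df.columns if c not in self.feature_columns]
        return LabeledDataset(self.df[keep + list(columns)].copy(), list(columns))

    def to_csv(self, path: str | Path) -> None:
        """CSV plus a JSON sidecar recording the feature schema."""
        path = Path(path)
        self.df.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".schema.json")
        sidecar.write_text(json.dumps({"feature_columns": self.feature_columns}, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabeledDataset":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".schema.json")
        cols = json.loads(sidecar.read_text())["feature_columns"]
        return cls(df, cols)


def build_dataset(
    cohort: Cohort,
    include_synchrony: bool = True,
    include_traits: bool = False,
    include_selfreport: bool = False,
    iiq_items: tuple[str, ...] = ("iiq_amount", "iiq_balance", "iiq_valence"),
    precomputed: dict[str, dict] | None = None,
) -> LabeledDataset:
    """Assemble the labeled dataset from a cohort.

    A dyad whose featurization fails a quality check is excluded with a
    logged reason. ``precomputed`` may map dyad_id to the output of
    :func:`featurize_recording` to avoid recomputation across dataset
    variants (e.g. the synchrony-ablated build).
    """
    if cohort.recordings is None and precomputed is None:
        raise ValueError("cohort has no signal recordings to featurize")

    rows: list[dict] = []
    if precomputed is not None:
        items = precomputed.items()
    else:
        items = ((rec.dyad_id, None) for rec in cohort.recordings)
        rec_by_id = {rec.dyad_id: rec for rec in cohort.recordings}

    for dyad_id, feats in items:
        try:
            if feats is None:
                feats = featurize_recording(rec_by_id[dyad_id])
            rows.extend(_dyad_rows(feats, dyad_id))
        except QualityError as exc:
            logger.warning("excluding dyad %s: %s", dyad_id, exc)
            continue

    df = pd.DataFrame(rows)
    feature_cols = list(COMBINED_FEATURE_NAMES)
    if include_synchrony:
        feature_cols += list(SYNCHRONY_FEATURE_NAMES)
    else:
        df = df.drop(columns=list(SYNCHRONY_FEATURE_NAMES))

    if include_traits:
        tw = cohort.traits.pivot(index="dyad_id", columns="participant",
                                 values=list(TRAITS))
        for tr in TRAITS:
            df[f"mean_of_{tr}"] = df["dyad_id"].map(
                (tw[(tr, "p1")] + tw[(tr, "p2")]) / 2.0)
            df[f"absdiff_of_{tr}"] = df["dyad_id"].map(
                (tw[(tr, "p1")] - tw[(tr, "p2")]).abs())
            feature_cols += [f"mean_of_{tr}", f"absdiff_of_{tr}"]

    if include_selfreport:
        items_used = ("sam_valence", "sam_arousal") + tuple(iiq_items)
        sw = cohort.selfreport.pivot(index=["dyad_id", "scenario"],
                                     columns="participant", values=list(items_used))
        key = pd.MultiIndex.from_frame(df[["dyad_id", "label"]])
        for it in items_used:
            mean = ((sw[(it, "p1")] + sw[(it, "p2")]) / 2.0).reindex(key)
            absd = (sw[(it, "p1")] - sw[(it, "p2")]).abs().reindex(key)
            df[f"mean_of_{it}"] = mean.to_numpy()
            df[f"absdiff_of_{it}"] = absd.to_numpy()
            feature_cols += [f"mean_of_{it}", f"absdiff_of_{it}"]

    # non-finite features (e.g. an undefined LF/HF ratio) invalidate the dyad
    bad = df.loc[~np.isfinite(df[feature_cols].to_numpy(float)).all(axis=1), "dyad_id"]
    for dyad_id in pd.unique(bad):
        logger.warning("excluding dyad %s: non-finite feature value", dyad_id)
    df = df[~df["dyad_id"].isin(set(bad))].reset_index(drop=True)

    return LabeledDataset(df, feature_cols)


def permute_labels_within_dyad(
    dataset: LabeledDataset, rng: np.random.Generator
) -> LabeledDataset:
    """A copy of the dataset with scenario labels shuffled within each dyad.

    Features stay attached to their rows; only the label assignment moves,
    which preserves each dyad's balanced 4-label design while destroying
    the feature–label association. This is the null used by the
    permutation test.
    """
    df = dataset.df.copy()
    labels = df["label"].to_numpy().copy()
    for dyad in pd.unique(df["dyad_id"]):
        idx = np.flatnonzero(df["dyad_id"].to_numpy() == dyad)
        labels[idx] = labels[idx[rng.permutation(len(idx))]]
    df["label"] = labels
    df["valence"] = df["label"].map(VALENCE)
    df["arousal"] = df["label"].map(AROUSAL)
    return LabeledDataset(df, list(dataset.feature_columns))
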