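"""Shared fixtures: seeded synthetic recordings and datasets.

Session-scoped fixtures keep the expensive signal generation /
featurization to one pass per test run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import dyadaffect as da
from dyadaffect.dataset import LabeledDataset
from dyadaffect.labels import SCENARIOS

CANONICAL_ORDER = ("PV-HA", "PV-LA", "NV-HA", "NV-LA")


def make_feature_dataset(
    n_dyads: int,
    n_features: int,
    rng: np.random.Generator,
    label_encoding_col: int | None = None,
) -> LabeledDataset:
    """A LabeledDataset of pure-noise features with balanced labels.

    If ``label_encoding_col`` is given, that column is set to a numeric
    encoding of the scenario label (a perfect feature).
    """
    rows = []
    X = rng.normal(size=(n_dyads * 4, n_features))
    for d in range(n_dyads):
        order = rng.permutation(SCENARIOS)
        for s, lab in enumerate(order):
            rows.append({"dyad_id": f"d{d:03d}", "segment": f"conversation{s+1}",
                         "label": lab})
    df = pd.DataFrame(rows)
    if label_encoding_col is not None:
        code = {lab: float(i) for i, lab in enumerate(SCENARIOS)}
        # small within-class jitter keeps scatter matrices nonsingular
        X[:, label_encoding_col] = (
            df["label"].map(code).to_numpy() + 0.01 * rng.normal(size=len(df))
        )
    cols = [f"f{j}" for j in range(n_features)]
    df[cols] = X
    return LabeledDataset(df, cols)


@pytest.fixture(scope="session")
def effect():
    return da.default_effect_config()


@pytest.fixture(scope="session")
def dyad_recording(effect):
    """One seeded default-condition dyad recording."""
    return da.generate_dyad_recording(effect, list(CANONICAL_ORDER), dyad_seed=42)


@pytest.fixture(scope="session")
def featurized(dyad_recording):
    return da.featurize_recording(dyad_recording)


@pytest.fixture(scope="session")
def small_cohort(effect):
    """Six-dyad cohort with full signals (used by several modules)."""
    return da.generate_cohort(6, effect, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return da.build_dataset(small_cohort)
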