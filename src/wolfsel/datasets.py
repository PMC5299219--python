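"""Tabular binary-classification datasets: loading, scaling, synthesis.

The container is a small immutable-by-convention :class:`Dataset` holding a
dense float feature matrix, labels encoded internally as +1 (positive class)
and -1 (negative class), and unique feature names.  Adapters are provided for
the two UCI clinical layouts commonly used with this kind of wrapper feature
selection (the Parkinson voice-measure table and the Wisconsin diagnostic
breast cancer table); the files themselves are not bundled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "SyntheticSpec",
    "load_table",
    "write_table",
    "normalize_minmax",
    "minmax_params",
    "apply_minmax",
    "generate_synthetic",
]


@dataclass
class Dataset:
    """A binary-labelled feature table.

    Parameters
    ----------
    features
        Real matrix of shape ``(n_samples, n_features)`` with no missing
        values.
    labels
        Vector of ``+1`` (positive class) / ``-1`` (negative class), one per
        sample.  Both classes must be present.
    feature_names
        Unique column names, one per feature.
    positive_label, negative_label
        The original label values the +1/-1 encoding was mapped from, kept so
        predictions can be reported in the caller's vocabulary.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    positive_label: object = 1
    negative_label: object = 0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, p = self.features.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if self.labels.shape != (n,):
            raise ValueError("labels length must match number of samples")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing or non-finite values")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must be encoded as +1/-1")
        if len({1, -1} - set(np.unique(self.labels))) > 0:
            raise ValueError("both classes must be present")
        self.feature_names = [str(f) for f in self.feature_names]
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must match number of features")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        self.labels = self.labels.astype(np.int8)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset_features(self, mask: np.ndarray) -> "Dataset":
        """Column-restricted copy for a boolean/0-1 feature mask."""
        mask = np.asarray(mask).astype(bool)
        if mask.shape != (self.n_features,):
            raise ValueError("mask length must equal n_features")
        if not mask.any():
            raise ValueError("cannot select an empty feature subset")
        names = [n for n, m in zip(self.feature_names, mask) if m]
        return replace(self, features=self.features[:, mask], feature_names=names)


# ---------------------------------------------------------------------------
# Loading / writing delimited text
# ---------------------------------------------------------------------------

#: Named column-layout adapters.  Each entry gives the label column, the
#: positive label value, and non-feature columns to drop.
ADAPTERS = {
    "parkinson": {"label_column": "status", "positive_label": 1, "drop": ["name"]},
    "wdbc": {"label_column": 1, "positive_label": "M", "drop": [0]},
}


def load_table(
    path: str | Path,
    label_column: str | int | None = None,
    positive_label: object | None = None,
    *,
    adapter: str | None = None,
    delimiter: str = ",",
    header: bool = True,
    drop_columns: Sequence[str | int] = (),
) -> Dataset:
    """Read a delimited text table into a :class:`Dataset`.

    ``adapter`` may be ``"parkinson"`` (drops the recording-name column, label
    column ``status`` with 1 = disease) or ``"wdbc"`` (drops the ID column,
    label is the diagnosis column with ``M`` = malignant = positive).  For a
    generic file, ``label_column`` must be given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    drop: list = list(drop_columns)
    if adapter is not None:
        if adapter not in ADAPTERS:
            raise ValueError(f"unknown adapter {adapter!r}; choose from {sorted(ADAPTERS)}")
        cfg = ADAPTERS[adapter]
        label_column = cfg["label_column"] if label_column is None else label_column
        positive_label = cfg["positive_label"] if positive_label is None else positive_label
        drop += cfg["drop"]
    if label_column is None:
        raise ValueError("label_column is required for generic tables")

    df = pd.read_csv(path, sep=delimiter, header=0 if header else None,
                     float_precision="round_trip")

    def _col(key):
        if isinstance(key, int) and key not in df.columns:
            return df.columns[key]
        return key

    try:
        label_key = _col(label_column)
        labels_raw = df[label_key]
    except (KeyError, IndexError):
        raise KeyError(f"label column {label_column!r} not found") from None
    df = df.drop(columns=[label_key])
    for d in drop:
        key = _col(d) if not isinstance(d, str) else d
        if key in df.columns:
            df = df.drop(columns=[key])

    values = pd.unique(labels_raw)
    if len(values) != 2:
        raise ValueError(f"expected exactly 2 label values, found {len(values)}")
    if positive_label is None:
        raise ValueError("positive_label is required")
    if positive_label not in set(values):
        raise ValueError(f"positive label {positive_label!r} not present in label column")
    negative_label = next(v for v in values if v != positive_label)

    if df.isna().any().any():
        raise ValueError("missing values in feature columns")
    try:
        features = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric feature cell: {exc}") from None

    labels = np.where(labels_raw.to_numpy() == positive_label, 1, -1)
    return Dataset(
        features=features,
        labels=labels,
        feature_names=list(df.columns.astype(str)),
        positive_label=positive_label,
        negative_label=negative_label,
    )


def write_table(data: Dataset, path: str | Path, *, delimiter: str = ",",
                label_column: str = "label") -> None:
    """Write a dataset back to delimited text (header row, original labels).

    Floats are written with Python's shortest round-trip repr, so
    ``load_table`` recovers the feature matrix exactly.
    """
    df = pd.DataFrame(data.features, columns=data.feature_names)
    df[label_column] = np.where(data.labels == 1, data.positive_label, data.negative_label)
    df.to_csv(path, sep=delimiter, index=False,
              float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# Min-max scaling to [-1, 1]
# ---------------------------------------------------------------------------


def minmax_params(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (min, max) as fitted scaling parameters."""
    features = np.asarray(features, dtype=float)
    return features.min(axis=0), features.max(axis=0)


def apply_minmax(features: np.ndarray, params: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Linearly map each column so the fitted min/max go to -1/+1.

    Zero-range (constant) columns map to 0, which keeps them inside the
    target interval without a division by zero.
    """
    lo, hi = params
    features = np.asarray(features, dtype=float)
    rng = hi - lo
    safe = np.where(rng == 0, 1.0, rng)
    out = 2.0 * (features - lo) / safe - 1.0
    return np.where(rng == 0, 0.0, out)


def normalize_minmax(data: Dataset) -> Dataset:
    """Return a new dataset with every feature scaled into [-1, 1]."""
    scaled = apply_minmax(data.features, minmax_params(data.features))
    return replace(data, features=scaled)


# ---------------------------------------------------------------------------
# Synthetic data with known informative structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a two-class table with planted structure.

    ``n_informative`` features are class-conditional Gaussians whose means sit
    ``class_separation`` apart (at :math:`\\pm` separation/2, unit variance);
    ``n_redundant`` features are random linear combinations of the informative
    block plus small noise (sd 0.1), so they carry the class signal only
    indirectly; ``n_noise`` features are standard Gaussians independent of the
    class.  Defaults mirror the benchmark conditions used throughout the test
    suite: 100 samples, 5 informative + 15 noise features, separation 2.
    """

    n_samples: int = 100
    n_informative: int = 5
    n_redundant: int = 0
    n_noise: int = 15
    class_separation: float = 2.0
    positive_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if min(self.n_informative, self.n_redundant, self.n_noise) < 0:
            raise ValueError("feature counts must be non-negative")
        if self.n_informative + self.n_redundant + self.n_noise < 1:
            raise ValueError("at least one feature is required")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("redundant features require informative features")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        if self.class_separation < 0:
            raise ValueError("class_separation must be non-negative")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


def generate_synthetic(spec: SyntheticSpec) -> Dataset:
    """Draw a dataset from a :class:`SyntheticSpec`; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n, sep = spec.n_samples, spec.class_separation

    n_pos = int(round(n * spec.positive_fraction))
    if n_pos == 0 or n_pos == n:
        raise ValueError("positive_fraction leaves a class empty at this n_samples")
    labels = np.full(n, -1, dtype=np.int8)
    labels[rng.permutation(n)[:n_pos]] = 1

    blocks, names = [], []
    if spec.n_informative:
        means = np.where(labels[:, None] == 1, sep / 2.0, -sep / 2.0)
        informative = means + rng.standard_normal((n, spec.n_informative))
        blocks.append(informative)
        names += [f"inf_{i + 1}" for i in range(spec.n_informative)]
    if spec.n_redundant:
        coeffs = rng.standard_normal((spec.n_informative, spec.n_redundant))
        redundant = blocks[0] @ coeffs + 0.1 * rng.standard_normal((n, spec.n_redundant))
        blocks.append(redundant)
        names += [f"red_{i + 1}" for i in range(spec.n_redundant)]
    if spec.n_noise:
        blocks.append(rng.standard_normal((n, spec.n_noise)))
        names += [f"noise_{i + 1}" for i in range(spec.n_noise)]

    return Dataset(
        features=np.hstack(blocks),
        labels=labels,
        feature_names=names,
        positive_label=1,
        negative_label=0,
    )
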