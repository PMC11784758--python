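"""Loading, cleaning and synthesis of the Wisconsin breast-cancer tables.

Two UCI dialects are supported:

* ``wbcd`` — the original Wisconsin Breast Cancer data: 11 comma-separated
  fields per row (sample code number, nine ordinal 1-10 cytology features,
  class 2=benign / 4=malignant), with ``?`` marking the 16 missing
  bare-nuclei values;
* ``wdbc`` — the diagnostic set: 32 fields (ID, diagnosis B/M, then mean,
  standard error and worst of ten nucleus characteristics).

Preprocessing drops the identifier, imputes missing bare nuclei with the
column mean, maps labels to 0=benign / 1=malignant, and for ``wdbc``
keeps the fixed 17-feature subset used by the study.  A synthetic
generator produces structurally matched two-class tables (class
imbalance, ordinal or continuous features, injected missing cells) so
everything downstream runs without a download.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, train_test_split

__all__ = [
    "WBCD_COLUMNS",
    "WDBC_COLUMNS",
    "WDBC_SELECTED_FEATURES",
    "RawTable",
    "Dataset",
    "SyntheticConfig",
    "load_uci",
    "preprocess",
    "minmax_fit_apply",
    "split_train_test",
    "kfold",
    "generate_synthetic",
]

WBCD_COLUMNS = [
    "sample_code_number",
    "clump_thickness",
    "uniformity_cell_size",
    "uniformity_cell_shape",
    "marginal_adhesion",
    "single_epithelial_cell_size",
    "bare_nuclei",
    "bland_chromatin",
    "normal_nucleoli",
    "mitoses",
    "class",
]

_WDBC_CHARACTERISTICS = [
    "radius",
    "texture",
    "perimeter",
    "area",
    "smoothness",
    "compactness",
    "concavity",
    "concave points",
    "symmetry",
    "fractal_dimension",
]

WDBC_COLUMNS = ["id", "diagnosis"] + [
    f"{name}_{stat}"
    for stat in ("mean", "se", "worst")
    for name in _WDBC_CHARACTERISTICS
]

# Fixed 17-feature subset for the diagnostic table, in its published order.
WDBC_SELECTED_FEATURES = [
    "texture_worst",
    "radius_worst",
    "perimeter_worst",
    "perimeter_mean",
    "radius_mean",
    "concave points_worst",
    "concave points_mean",
    "area_worst",
    "area_mean",
    "concavity_mean",
    "concavity_worst",
    "radius_se",
    "area_se",
    "perimeter_se",
    "compactness_mean",
    "compactness_worst",
    "texture_mean",
]

_WBCD_LABEL_MAP = {2: 0, 4: 1}
_WDBC_LABEL_MAP = {"B": 0, "N": 0, "M": 1}  # 'N' accepted as benign synonym


@dataclass
class RawTable:
    """A parsed but uncleaned UCI-dialect table."""

    frame: pd.DataFrame
    dialect: str


@dataclass
class Dataset:
    """Clean numeric design matrix with binary labels (1 = malignant)."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int).ravel()
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be 2-d with one row per label")
        if not np.all(np.isin(self.y, (0, 1))):
            raise ValueError("labels must be binary 0/1")
        if np.isnan(self.X).any():
            raise ValueError("Dataset must not contain missing values")

    def __len__(self) -> int:
        return self.y.size

    def subset(self, idx) -> "Dataset":
        return Dataset(self.X[idx], self.y[idx], list(self.feature_names),
                       self.provenance)


@dataclass
class SyntheticConfig:
    """Controls for the two-Gaussian synthetic stand-in.

    ``separation`` is the class-mean gap in units of the within-class
    spread ``sigma``; ``positive_fraction`` defaults to the 241/699
    malignant share of the original cytology table.  In ordinal mode
    features are rounded and clipped to the 1-10 scale.
    """

    n_samples: int = 699
    n_features: int = 9
    positive_fraction: float = 241 / 699
    separation: float = 2.0
    sigma: float = 1.5
    ordinal: bool = True
    missing_rate: float = 0.0
    missing_column: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.positive_fraction < 1.0):
            raise ValueError("positive_fraction must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_samples < 2 or self.n_features < 1:
            raise ValueError("need n_samples >= 2 and n_features >= 1")


def load_uci(path, dialect: str) -> RawTable:
    """Parse a UCI-dialect CSV, validating the column count.

    ``?`` cells (missing bare nuclei in the ``wbcd`` dialect) become NaN.
    """
    if dialect not in ("wbcd", "wdbc"):
        raise ValueError(f"unknown dialect {dialect!r}; use 'wbcd' or 'wdbc'")
    names = WBCD_COLUMNS if dialect == "wbcd" else WDBC_COLUMNS
    try:
        frame = pd.read_csv(path, header=None, na_values=["?"], skipinitialspace=True)
    except OSError as exc:
        raise OSError(f"cannot read {path}: {exc}") from exc
    if frame.shape[1] != len(names):
        raise ValueError(
            f"malformed {dialect} file {path}: expected {len(names)} columns, "
            f"found {frame.shape[1]}"
        )
    frame.columns = names
    return RawTable(frame=frame, dialect=dialect)


def preprocess(raw: RawTable) -> Dataset:
    """Clean a raw table into a numeric :class:`Dataset`.

    Drops the identifier column, imputes missing bare-nuclei values with
    the mean of the observed entries (computed over the whole table; see
    the methods note for the train-only alternative), maps class symbols
    to 0/1, and for the ``wdbc`` dialect restricts to the fixed
    17-feature subset.
    """
    frame = raw.frame
    if raw.dialect == "wbcd":
        labels = frame["class"]
        bad = set(labels.unique()) - set(_WBCD_LABEL_MAP)
        if bad:
            raise ValueError(f"unknown wbcd class symbols: {sorted(bad)}")
        y = labels.map(_WBCD_LABEL_MAP).to_numpy()
        feats = frame.drop(columns=["sample_code_number", "class"]).astype(float)
        if feats["bare_nuclei"].isna().any():
            feats["bare_nuclei"] = feats["bare_nuclei"].fillna(
                feats["bare_nuclei"].mean()
            )
        names = list(feats.columns)
    elif raw.dialect == "wdbc":
        labels = frame["diagnosis"]
        bad = set(labels.unique()) - set(_WDBC_LABEL_MAP)
        if bad:
            raise ValueError(f"unknown wdbc diagnosis symbols: {sorted(bad)}")
        y = labels.map(_WDBC_LABEL_MAP).to_numpy()
        feats = frame[WDBC_SELECTED_FEATURES].astype(float)
        names = list(WDBC_SELECTED_FEATURES)
    else:
        raise ValueError(f"unknown dialect {raw.dialect!r}")
    return Dataset(feats.to_numpy(), y, names, provenance=raw.dialect)


def minmax_fit_apply(train: Dataset, others: list[Dataset] | None = None):
    """Min-max scale features to [0, 1], statistics fitted on ``train`` only.

    Constant features map to 0.  Other datasets are transformed with the
    training statistics and may fall outside [0, 1]; callers relying on
    a strict range should clip explicitly.

    Returns ``(train_scaled, others_scaled, stats)`` with
    ``stats = {"min": ..., "max": ...}`` per feature.
    """
    if len(train) == 0:
        raise ValueError("cannot fit normalization on an empty training set")
    mins = train.X.min(axis=0)
    maxs = train.X.max(axis=0)
    span = maxs - mins
    safe = np.where(span == 0.0, 1.0, span)

    def apply(ds: Dataset) -> Dataset:
        Xs = (ds.X - mins) / safe
        Xs[:, span == 0.0] = 0.0
        return replace(ds, X=Xs)

    others_scaled = [apply(ds) for ds in (others or [])]
    stats = {"min": mins.copy(), "max": maxs.copy()}
    return apply(train), others_scaled, stats


def split_train_test(dataset: Dataset, train_fraction: float = 0.7,
                     seed: int | None = None) -> tuple[Dataset, Dataset]:
    """Stratified, seeded train/test partition."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=train_fraction,
        random_state=seed,
        stratify=dataset.y,
        shuffle=True,
    )
    train, test = dataset.subset(train_idx), dataset.subset(test_idx)
    for part, name in ((train, "train"), (test, "test")):
        if len(np.unique(part.y)) < 2:
            raise ValueError(f"a class is absent from the {name} split")
    return train, test


def kfold(n_or_dataset, k: int = 10, seed: int | None = None):
    """Seeded k-fold partition of indices into (fit, validate) pairs."""
    n = len(n_or_dataset) if isinstance(n_or_dataset, Dataset) else int(n_or_dataset)
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(fit, val) for fit, val in splitter.split(np.zeros(n))]


def generate_synthetic(cfg: SyntheticConfig, return_raw: bool = False):
    """Draw a two-class Gaussian table emulating the UCI structure.

    Benign features centre at 3.0 and malignant at
    ``3.0 + separation * sigma`` per feature (ordinal mode; continuous
    mode centres at 0 and ``separation * sigma``).  The positive count is
    exactly ``round(positive_fraction * n_samples)``.  With
    ``return_raw=True`` a ``wbcd``-dialect :class:`RawTable` is also
    returned, with exactly ``round(missing_rate * n_samples)`` cells of
    the designated column blanked.
    """
    rng = np.random.default_rng(cfg.seed)
    n, d = cfg.n_samples, cfg.n_features
    n_pos = int(round(cfg.positive_fraction * n))
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)

    base = 3.0 if cfg.ordinal else 0.0
    means = np.where(y[:, None] == 1, base + cfg.separation * cfg.sigma, base)
    X = rng.normal(means, cfg.sigma, size=(n, d))
    if cfg.ordinal:
        X = np.clip(np.rint(X), 1, 10)

    names = [f"feature_{j}" for j in range(d)]
    dataset = Dataset(X, y, names, provenance="synthetic")
    if not return_raw:
        return dataset

    frame = pd.DataFrame(X.copy())
    n_missing = int(round(cfg.missing_rate * n))
    if n_missing:
        col = cfg.missing_column
        if not (0 <= col < d):
            raise ValueError("missing_column outside the feature range")
        blank = rng.choice(n, size=n_missing, replace=False)
        frame.iloc[blank, col] = np.nan
    frame.insert(0, "id", 1000 + np.arange(n))
    frame["class"] = np.where(y == 1, 4, 2)
    if d == 9:
        frame.columns = WBCD_COLUMNS
    raw = RawTable(frame=frame, dialect="wbcd")
    return dataset, raw
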