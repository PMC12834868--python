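"""Labelled feature tables and feature subsets.

``LabeledDataset`` is the in-memory universe every feature subset refers
to: a dense numeric matrix (cases x features), unique feature names, and a
binary label vector with an explicit (negative, positive) level order.
Reading and writing delimited text goes through pandas; the ingest contract
is strict — no missing values, exactly two label levels, numeric features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset", "DataError", "read_dataset", "write_dataset"]


class DataError(ValueError):
    """Raised when an input table violates the ingest contract."""


@dataclass(frozen=True)
class LabeledDataset:
    """A numeric feature matrix with binary labels.

    Attributes
    ----------
    features : ndarray of shape (n, p)
    feature_names : tuple of str, unique
    labels : ndarray of shape (n,), values drawn from ``level_names``
    level_names : (negative, positive) pair fixing the positive class
    """

    features: np.ndarray
    feature_names: tuple[str, ...]
    labels: np.ndarray
    level_names: tuple[str, str]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels)
        names = tuple(str(n) for n in self.feature_names)
        if X.ndim != 2:
            raise DataError("features must be a 2-D matrix")
        n, p = X.shape
        if p != len(names):
            raise DataError(f"{len(names)} feature names for {p} columns")
        if len(set(names)) != len(names) or any(not n for n in names):
            raise DataError("feature names must be unique and non-empty")
        if n < 4 or p < 1:
            raise DataError(f"need at least 4 cases and 1 feature, got {n} x {p}")
        if labels.shape != (n,):
            raise DataError(f"labels must have length {n}")
        if not np.all(np.isfinite(X)):
            bad = np.argwhere(~np.isfinite(X))[0]
            raise DataError(f"non-finite feature value at row {bad[0]}, column {names[bad[1]]!r}")
        levels = tuple(str(v) for v in self.level_names)
        if len(levels) != 2 or levels[0] == levels[1]:
            raise DataError(f"level_names must be two distinct levels, got {levels}")
        present = set(str(v) for v in labels)
        if present != set(levels):
            raise DataError(f"labels must contain exactly the levels {levels}, found {sorted(present)}")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "feature_names", names)
        object.__setattr__(self, "labels", labels.astype(str))
        object.__setattr__(self, "level_names", levels)
        object.__setattr__(self, "_index", {name: j for j, name in enumerate(names)})

    # -- construction ----------------------------------------------------
    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        label_column: str,
        positive_level: str | None = None,
    ) -> "LabeledDataset":
        """Build a dataset from a DataFrame with one label column.

        Level order is (negative, positive): taken from ``positive_level``
        when given, otherwise lexicographic with the larger level positive.
        Balanced accuracy is symmetric in the two classes, so the choice
        cannot change any result.
        """
        if label_column not in frame.columns:
            raise DataError(f"label column {label_column!r} not found")
        na = frame.isna()
        if na.to_numpy().any():
            row, col = np.argwhere(na.to_numpy())[0]
            raise DataError(
                f"missing value at row {frame.index[row]}, column {frame.columns[col]!r}"
            )
        labels = frame[label_column].astype(str).to_numpy()
        levels = sorted(set(labels))
        if len(levels) != 2:
            raise DataError(f"label column must have exactly 2 levels, found {levels}")
        if positive_level is not None:
            positive_level = str(positive_level)
            if positive_level not in levels:
                raise DataError(f"positive level {positive_level!r} not among {levels}")
            levels = [next(l for l in levels if l != positive_level), positive_level]
        feats = frame.drop(columns=[label_column])
        try:
            X = feats.astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            for col in feats.columns:
                try:
                    feats[col].astype(float)
                except (TypeError, ValueError):
                    raise DataError(f"non-numeric value in feature column {col!r}") from exc
            raise
        return cls(X, tuple(map(str, feats.columns)), labels, (levels[0], levels[1]))

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        frame = pd.DataFrame(self.features, columns=list(self.feature_names))
        frame[label_column] = self.labels
        return frame

    # -- views -----------------------------------------------------------
    @property
    def n_cases(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def y01(self) -> np.ndarray:
        """Labels as 0/1 with 1 = positive level."""
        return (self.labels == self.level_names[1]).astype(int)

    def columns(self, names: Sequence[str]) -> np.ndarray:
        idx = [self._index[n] for n in self.check_subset(names)]
        return self.features[:, idx]

    def restrict(self, names: Sequence[str]) -> "LabeledDataset":
        """Dataset restricted to the named features (order as given)."""
        names = self.check_subset(names)
        idx = [self._index[n] for n in names]
        return LabeledDataset(self.features[:, idx], names, self.labels, self.level_names)

    def take(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(self.features[idx], self.feature_names, self.labels[idx], self.level_names)

    def check_subset(self, names: Iterable[str]) -> tuple[str, ...]:
        names = tuple(names)
        unknown = [n for n in names if n not in self._index]
        if unknown:
            raise DataError(f"unknown features: {unknown}")
        if len(set(names)) != len(names):
            raise DataError("duplicate feature names in subset")
        return names

    def class_counts(self) -> tuple[int, int]:
        """(negative count, positive count)."""
        y = self.y01
        return int(np.sum(y == 0)), int(np.sum(y == 1))


def read_dataset(
    path: str,
    label_column: str,
    positive_level: str | None = None,
) -> LabeledDataset:
    """Read a delimited feature table (comma, tab or semicolon separated).

    The delimiter is auto-detected. The table must have a header row, a
    binary label column and complete numeric features; violations raise
    ``DataError`` naming the offending column or cell.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    delims = {d: header.count(d) for d in (",", "\t", ";")}
    sep = max(delims, key=delims.get)
    if delims[sep] == 0:
        raise DataError(f"could not detect a delimiter in {path}")
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return LabeledDataset.from_frame(frame, label_column, positive_level)


def write_dataset(dataset: LabeledDataset, path: str, label_column: str = "label") -> None:
    # %.17g keeps doubles bit-exact across a write/read round trip
    dataset.to_frame(label_column).to_csv(path, index=False, float_format="%.17g")
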