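"""Core domain types and CSV I/O for labeled multivariate time series.

An MTS item is an ``m x n`` real matrix: ``m`` time points observed on ``n``
simultaneous channels (EEG electrodes, glove sensors, force/torque axes, ...).
Collections of labeled items support whole-sequence matching and 1NN
classification; a single long series supports subsequence matching.

Two on-disk layouts are supported, both plain UTF-8 CSV with a header row and
``.`` decimal separator so that read/write round-trips are bit-exact:

``per-item``
    one ``<id>.csv`` per item (columns = channels, rows = time points) plus a
    ``labels.csv`` manifest with columns ``id,label``.
``long``
    a single long-format table with columns ``item,t,v1..vn``; rows may be
    unsorted in ``t`` and are sorted on read.  An optional ``labels.csv`` next
    to the table supplies labels.

Time is indexed 0-based internally; a window "from t of length l" is the
half-open slice ``[t, t+l)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd

__all__ = [
    "MTSItem",
    "MTSDataset",
    "LongSeries",
    "ValidationError",
    "read_mts_dataset",
    "write_mts_dataset",
    "validate_dataset",
    "read_long_series",
    "write_long_series",
]

Layout = Literal["per-item", "long"]


class ValidationError(ValueError):
    """A dataset or item violates a structural invariant."""


def _as_matrix(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr


@dataclass
class MTSItem:
    """One multivariate time series: rows are time points, columns channels."""

    id: str
    values: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = _as_matrix(self.values)

    @property
    def m(self) -> int:
        return int(self.values.shape[0])

    @property
    def n(self) -> int:
        return int(self.values.shape[1]) if self.values.ndim == 2 else 0


@dataclass
class MTSDataset:
    """An ordered collection of MTS items sharing the same channel count."""

    items: list[MTSItem] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[MTSItem]:
        return iter(self.items)

    def __getitem__(self, idx: int) -> MTSItem:
        return self.items[idx]

    def get(self, item_id: str) -> MTSItem:
        for item in self.items:
            if item.id == item_id:
                return item
        raise KeyError(item_id)

    @property
    def ids(self) -> list[str]:
        return [item.id for item in self.items]

    @property
    def n(self) -> int:
        return self.items[0].n if self.items else 0

    @property
    def class_labels(self) -> set[str]:
        return {item.label for item in self.items if item.label is not None}


@dataclass
class LongSeries:
    """A long multivariate series searched by sliding a query window over it."""

    id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _as_matrix(self.values)

    @property
    def length(self) -> int:
        return int(self.values.shape[0])

    @property
    def n(self) -> int:
        return int(self.values.shape[1])


def _item_issues(item: MTSItem) -> list[str]:
    issues: list[str] = []
    if item.values.ndim != 2:
        issues.append(f"item {item.id!r}: values are not a 2-D matrix")
        return issues
    if item.m < 2:
        issues.append(f"item {item.id!r}: too short (m={item.m} < 2)")
    if item.n < 1:
        issues.append(f"item {item.id!r}: no variables (n=0)")
    bad = ~np.isfinite(item.values)
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        issues.append(f"item {item.id!r}: missing/non-finite value at row {row}")
    return issues


def validate_dataset(dataset: MTSDataset) -> list[str]:
    """Report every invariant violation; returns ``[]`` iff the dataset is valid.

    Pure: never raises, never mutates.
    """
    issues: list[str] = []
    seen: set[str] = set()
    arities: dict[int, str] = {}
    for item in dataset.items:
        if item.id in seen:
            issues.append(f"item {item.id!r}: duplicate id")
        seen.add(item.id)
        issues.extend(_item_issues(item))
        if item.values.ndim == 2 and item.n >= 1:
            arities.setdefault(item.n, item.id)
    if len(arities) > 1:
        detail = ", ".join(f"n={n} (first: {i!r})" for n, i in sorted(arities.items()))
        issues.append(f"variable-count mismatch across items: {detail}")
    return issues


def _check(dataset: MTSDataset) -> MTSDataset:
    issues = validate_dataset(dataset)
    if issues:
        raise ValidationError("; ".join(issues))
    return dataset


def _read_csv(path: Path) -> pd.DataFrame:
    # round_trip parser: shortest-repr floats written by to_csv read back
    # bit-exactly
    return pd.read_csv(path, float_precision="round_trip")


def _read_labels(path: Path) -> dict[str, str | None]:
    table = pd.read_csv(path, dtype=str)
    if "id" not in table.columns or "label" not in table.columns:
        raise ValidationError(f"{path}: labels manifest needs columns id,label")
    labels: dict[str, str | None] = {}
    for rec in table.itertuples(index=False):
        labels[str(rec.id)] = None if pd.isna(rec.label) else str(rec.label)
    return labels


def read_mts_dataset(path: str | Path, layout: Layout = "per-item") -> MTSDataset:
    """Read a labeled MTS dataset from ``path`` in the given layout.

    Raises :class:`ValidationError` naming the offending item and row when the
    data are ragged, contain missing cells, or duplicate ids; missing files
    raise the usual I/O errors.
    """
    path = Path(path)
    if layout == "per-item":
        labels = _read_labels(path / "labels.csv")
        items = []
        for item_id, label in labels.items():
            frame = _read_csv(path / f"{item_id}.csv")
            items.append(MTSItem(item_id, frame.to_numpy(dtype=float), label))
        return _check(MTSDataset(items))
    if layout == "long":
        table = _read_csv(path)
        required = {"item", "t"}
        if not required.issubset(table.columns):
            raise ValidationError(f"{path}: long layout needs columns item,t,v1..vn")
        value_cols = [c for c in table.columns if c not in ("item", "t", "label")]
        labels_path = Path(path).parent / "labels.csv"
        labels = _read_labels(labels_path) if labels_path.exists() else {}
        items = []
        for item_id, chunk in table.groupby("item", sort=False):
            chunk = chunk.sort_values("t", kind="stable")
            items.append(
                MTSItem(
                    str(item_id),
                    chunk[value_cols].to_numpy(dtype=float),
                    labels.get(str(item_id)),
                )
            )
        return _check(MTSDataset(items))
    raise ValueError(f"unknown layout {layout!r}")


def write_mts_dataset(
    dataset: MTSDataset, path: str | Path, layout: Layout = "per-item"
) -> None:
    """Write ``dataset`` so that :func:`read_mts_dataset` reproduces it exactly."""
    if len(dataset) == 0:
        raise ValidationError("refusing to write an empty dataset")
    _check(dataset)
    path = Path(path)
    if layout == "per-item":
        path.mkdir(parents=True, exist_ok=True)
        manifest = pd.DataFrame(
            {"id": dataset.ids, "label": [it.label for it in dataset]}
        )
        manifest.to_csv(path / "labels.csv", index=False)
        for item in dataset:
            cols = [f"v{j + 1}" for j in range(item.n)]
            pd.DataFrame(item.values, columns=cols).to_csv(
                path / f"{item.id}.csv", index=False
            )
        return
    if layout == "long":
        frames = []
        for item in dataset:
            cols = [f"v{j + 1}" for j in range(item.n)]
            frame = pd.DataFrame(item.values, columns=cols)
            frame.insert(0, "t", np.arange(item.m))
            frame.insert(0, "item", item.id)
            frames.append(frame)
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        if any(it.label is not None for it in dataset):
            manifest = pd.DataFrame(
                {"id": dataset.ids, "label": [it.label for it in dataset]}
            )
            manifest.to_csv(path.parent / "labels.csv", index=False)
        return
    raise ValueError(f"unknown layout {layout!r}")


def read_long_series(path: str | Path, series_id: str | None = None) -> LongSeries:
    """Read a long series from a plain CSV (columns = channels)."""
    path = Path(path)
    frame = _read_csv(path)
    values = frame.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        row = int(np.argwhere(~np.isfinite(values))[0, 0])
        raise ValidationError(f"{path}: missing/non-finite value at row {row}")
    return LongSeries(series_id or path.stem, values)


def write_long_series(series: LongSeries, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [f"v{j + 1}" for j in range(series.n)]
    pd.DataFrame(series.values, columns=cols).to_csv(path, index=False)


def warn_once(message: str) -> None:
    """Emit a runtime warning for recoverable protocol deviations."""
    warnings.warn(message, RuntimeWarning, stacklevel=3)
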