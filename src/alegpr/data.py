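"""Dataset containers, standardization and labeled/unlabeled splitting.

Process data are tabular: rows are time-indexed samples, columns are the
seven measured input variables of a fed-batch fermentation (culture volume,
agitator power, pH, substrate feed temperature, fermenter temperature,
substrate feed rate, aeration rate) plus an optional quality column
(penicillin concentration, g/L).  Samples carry stable integer identifiers;
all cross-module references use ids, never row positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

INPUT_COLUMNS = ("u1", "u2", "u3", "u4", "u5", "u6", "u7")
TARGET_COLUMN = "y"


class SchemaError(ValueError):
    """A declared column is missing or a cell cannot be parsed."""


class DegenerateScaleError(ValueError):
    """A column is constant over the rows used to fit a standardizer."""


@dataclass(frozen=True)
class Dataset:
    """Immutable table of process samples.

    Attributes
    ----------
    ids : (n,) int array of unique, stable sample identifiers.
    X : (n, m) float array of input variables.
    y : (n,) float array of quality values; NaN marks an unlabeled sample.
    columns : names of the m input columns.
    """

    ids: np.ndarray
    X: np.ndarray
    y: np.ndarray
    columns: tuple[str, ...] = INPUT_COLUMNS

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=np.int64)
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n = X.shape[0]
        if ids.shape != (n,):
            raise ValueError("ids and X row counts differ")
        if len(np.unique(ids)) != n:
            raise ValueError("sample ids must be unique")
        if y.shape != (n,):
            raise ValueError("y and X row counts differ")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite entries")
        if X.shape[1] != len(self.columns):
            raise ValueError("column names do not match X width")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean labeled flag per sample (finite quality value)."""
        return np.isfinite(self.y)

    @property
    def n_labeled(self) -> int:
        return int(self.mask.sum())

    def rows(self, index: np.ndarray) -> "Dataset":
        """Positional row subset (ids travel with their rows)."""
        return Dataset(self.ids[index], self.X[index], self.y[index], self.columns)

    def id_index(self, ids: Sequence[int]) -> np.ndarray:
        """Row positions of the given ids (errors on unknown id)."""
        lookup = {int(s): i for i, s in enumerate(self.ids)}
        try:
            return np.array([lookup[int(s)] for s in ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown sample id {exc.args[0]}") from exc


@dataclass(frozen=True)
class LabeledSet:
    """Samples with known quality values."""

    ids: np.ndarray
    X: np.ndarray
    y: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def extend(self, ids: np.ndarray, X: np.ndarray, y: np.ndarray) -> "LabeledSet":
        return LabeledSet(
            np.concatenate([self.ids, np.asarray(ids, dtype=np.int64)]),
            np.vstack([self.X, X]),
            np.concatenate([self.y, y]),
        )


@dataclass(frozen=True)
class UnlabeledPool:
    """Samples whose quality value has not been queried; inputs only."""

    ids: np.ndarray
    X: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def remove(self, ids: Sequence[int]) -> "UnlabeledPool":
        drop = set(int(s) for s in ids)
        keep = np.array([int(s) not in drop for s in self.ids], dtype=bool)
        return UnlabeledPool(self.ids[keep], self.X[keep])


@dataclass(frozen=True)
class SplitSpec:
    """How the initial labeled subset of the training block is chosen."""

    n_labeled_initial: int
    seed: int
    selection: Literal["random", "stratified-by-time"] = "random"


@dataclass(frozen=True)
class Scaler:
    """Column-wise z-scoring parameters, with an optional target channel."""

    mean: np.ndarray
    sd: np.ndarray
    y_mean: float | None = None
    y_sd: float | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.mean.shape[0]:
            raise ValueError("column count does not match scaler")
        return (X - self.mean) / self.sd

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        if Z.shape[-1] != self.mean.shape[0]:
            raise ValueError("column count does not match scaler")
        return Z * self.sd + self.mean

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        if self.y_mean is None or self.y_sd is None:
            raise ValueError("scaler has no target statistics")
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_sd

    def inverse_y(self, z: np.ndarray) -> np.ndarray:
        if self.y_mean is None or self.y_sd is None:
            raise ValueError("scaler has no target statistics")
        return np.asarray(z, dtype=float) * self.y_sd + self.y_mean


def load_dataset(path, schema: Mapping[str, str] | None = None) -> Dataset:
    """Read a process-data CSV into a :class:`Dataset`.

    The file must have a header; expected columns are ``id,u1..u7`` plus an
    optional quality column ``y`` (empty field = unlabeled).  ``schema`` maps
    canonical names (``id``, ``u1``.., ``y``) to file column names.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path, float_precision="round_trip")
    name = lambda c: schema.get(c, c)
    wanted = [name("id"), *[name(c) for c in INPUT_COLUMNS]]
    for col in wanted:
        if col not in df.columns:
            raise SchemaError(f"missing declared column {col!r}")
    for col in wanted[1:]:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            raise SchemaError(
                f"non-numeric cell in column {col!r} at row {int(np.flatnonzero(bad)[0])}"
            )
        if values.isna().any():
            raise SchemaError(f"missing value in input column {col!r}")
        df[col] = values
    ycol = name(TARGET_COLUMN)
    if ycol in df.columns:
        y = pd.to_numeric(df[ycol], errors="coerce").to_numpy(dtype=float)
    else:
        y = np.full(len(df), np.nan)
    X = df[[name(c) for c in INPUT_COLUMNS]].to_numpy(dtype=float)
    ids = df[name("id")].to_numpy(dtype=np.int64)
    return Dataset(ids=ids, X=X, y=y)


def save_dataset(data: Dataset, path) -> None:
    """Write a Dataset back to the canonical CSV layout.

    Floats use repr (shortest-roundtrip) formatting so a save/load cycle
    reproduces the arrays bit-identically.
    """
    df = pd.DataFrame(data.X, columns=list(data.columns))
    df.insert(0, "id", data.ids)
    df[TARGET_COLUMN] = data.y
    df.to_csv(path, index=False, na_rep="", float_format=lambda v: repr(float(v)))


def fit_standardizer(
    data: Dataset,
    rows: np.ndarray | None = None,
    with_target: bool = False,
) -> Scaler:
    """Column means/sds (ddof=1) over the selected rows only.

    ``rows`` is a boolean or integer row selector; default all rows.  When
    ``with_target`` is set, target statistics are computed over the labeled
    rows of the selection.
    """
    X = data.X if rows is None else data.X[rows]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a standardizer")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s <= 0:
            raise DegenerateScaleError(
                f"column {data.columns[j]!r} is constant over the selected rows"
            )
    y_mean = y_sd = None
    if with_target:
        y = data.y if rows is None else data.y[rows]
        y = y[np.isfinite(y)]
        if y.size < 2:
            raise ValueError("need >=2 labeled rows for target statistics")
        y_mean = float(y.mean())
        y_sd = float(y.std(ddof=1))
        if y_sd <= 0:
            raise DegenerateScaleError("target is constant over the labeled rows")
    return Scaler(mean=mean, sd=sd, y_mean=y_mean, y_sd=y_sd)


def fit_target_scaler(y: np.ndarray) -> tuple[float, float]:
    """Mean/sd (ddof=1) of a label vector; sd floored to keep z-scoring finite."""
    y = np.asarray(y, dtype=float)
    mu = float(y.mean())
    sd = float(y.std(ddof=1)) if y.size > 1 else 0.0
    if not np.isfinite(sd) or sd <= 0:
        sd = 1.0
    return mu, sd


def apply_standardizer(scaler: Scaler, data: Dataset) -> Dataset:
    """Z-scored copy of the inputs; the original dataset is untouched."""
    return replace(data, X=scaler.transform(data.X))


def split_initial(data: Dataset, spec: SplitSpec) -> tuple[LabeledSet, UnlabeledPool]:
    """Partition a training block into the initial labeled set and the pool.

    Only rows carrying a quality value are eligible for the labeled side;
    the pool keeps inputs only.  Selection is reproducible from the seed.
    """
    eligible = np.flatnonzero(data.mask)
    if spec.n_labeled_initial <= 0 or spec.n_labeled_initial > eligible.size:
        raise ValueError(
            f"n_labeled_initial={spec.n_labeled_initial} outside (0, {eligible.size}]"
        )
    if spec.selection == "random":
        rng = np.random.default_rng(spec.seed)
        chosen = rng.choice(eligible, size=spec.n_labeled_initial, replace=False)
        chosen.sort()
    elif spec.selection == "stratified-by-time":
        # evenly spaced through the (time-ordered) eligible rows
        pos = np.linspace(0, eligible.size - 1, spec.n_labeled_initial)
        chosen = eligible[np.unique(np.round(pos).astype(int))]
    else:  # pragma: no cover
        raise ValueError(f"unknown selection rule {spec.selection!r}")
    labeled_mask = np.zeros(data.n, dtype=bool)
    labeled_mask[chosen] = True
    pool_mask = ~labeled_mask
    labeled = LabeledSet(data.ids[labeled_mask], data.X[labeled_mask], data.y[labeled_mask])
    pool = UnlabeledPool(data.ids[pool_mask], data.X[pool_mask])
    return labeled, pool
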